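"""Breaking-contact classification: training, ranking, selection, metrics.

Breaking contacts are rare (a few percent of a protein's contacts), so the
training set undersamples maintained contacts at a 3:1 maintained:breaking
ratio per protein, and the margin classifier additionally weights classes
inversely to their frequency.  Scores are calibrated to probabilities by
Platt scaling; contacts at least four sequence positions apart are ranked by
decreasing probability of breaking, and a selection strategy (constant n,
relative fraction, or score threshold) picks the removal subset.
"""

from __future__ import annotations

import logging
import pickle
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from lmcenm.contacts import TransitionMap

log = logging.getLogger(__name__)

DEFAULT_COST = 100.0
DEFAULT_GAMMA = 1e-5
DEFAULT_RATIO = 3.0
MIN_SEQ_SEP = 4
MODEL_FORMAT_VERSION = 1


def protein_seed(corpus_seed: int, protein_id: str) -> int:
    """Stable per-protein sub-seed so corpus composition changes do not
    reshuffle unrelated proteins."""
    return (int(corpus_seed) ^ zlib.crc32(protein_id.encode())) % (2**31)


@dataclass
class TrainingSet:
    """Undersampled per-contact samples pooled over proteins."""

    values: np.ndarray  # (n_samples, n_features)
    available: np.ndarray  # boolean availability mask, same shape
    labels: np.ndarray  # 1 = breaking, 0 = maintained
    protein_ids: list[str]
    pairs: list[tuple[int, int]]
    ratio: float = DEFAULT_RATIO

    @property
    def n_samples(self) -> int:
        return len(self.labels)


def build_training_set(
    proteins,
    ratio: float = DEFAULT_RATIO,
    seed: int = 0,
    min_sep: int = MIN_SEQ_SEP,
) -> TrainingSet:
    """Pool positives (all breaking contacts at |i−j| ≥ min_sep) with
    per-protein undersampled negatives (maintained contacts).

    ``proteins`` is an iterable of (protein_id, pairs, values, available,
    tmap) where pairs/values/available come from
    :func:`lmcenm.features.feature_matrix` and tmap is the observed
    :class:`TransitionMap`.
    """
    vals, avail, labels, pids, out_pairs = [], [], [], [], []
    for pid, pairs, values, available, tmap in proteins:
        breaking = set(tmap.breaking_pairs(min_sep))
        maintained = set(tmap.maintained_pairs(min_sep))
        pos_rows = [r for r, p in enumerate(pairs) if p in breaking]
        neg_rows = [r for r, p in enumerate(pairs) if p in maintained]
        if not pos_rows:
            log.info("protein %s has no breaking contacts; skipped", pid)
            continue
        rng = np.random.default_rng(protein_seed(seed, pid))
        n_neg = min(int(round(ratio * len(pos_rows))), len(neg_rows))
        chosen = rng.choice(len(neg_rows), size=n_neg, replace=False)
        neg_rows = [neg_rows[c] for c in sorted(chosen)]
        for r in pos_rows + neg_rows:
            vals.append(values[r])
            avail.append(available[r])
            labels.append(1 if r in set(pos_rows) else 0)
            pids.append(pid)
            out_pairs.append(pairs[r])
    if not labels:
        raise ValueError("empty training set")
    return TrainingSet(
        values=np.array(vals),
        available=np.array(avail),
        labels=np.array(labels, dtype=int),
        protein_ids=pids,
        pairs=out_pairs,
        ratio=ratio,
    )


@dataclass
class FeatureScaler:
    """Column standardization fit on the training corpus.

    Masked (unavailable) entries do not contribute to the statistics and are
    set to the neutral value 0 after standardization.
    """

    mean: np.ndarray = field(default=None)
    std: np.ndarray = field(default=None)

    def fit(self, values: np.ndarray, available: np.ndarray) -> "FeatureScaler":
        import warnings

        masked = np.where(available, values, np.nan)
        with warnings.catch_warnings():
            # all-masked columns legitimately produce empty-slice statistics
            warnings.simplefilter("ignore", category=RuntimeWarning)
            self.mean = np.nan_to_num(np.nanmean(masked, axis=0))
            self.std = np.nan_to_num(np.nanstd(masked, axis=0))
        self.std[self.std == 0] = 1.0
        return self

    def transform(self, values: np.ndarray, available: np.ndarray) -> np.ndarray:
        z = (values - self.mean) / self.std
        return np.where(available, z, 0.0)


@dataclass
class BreakingContactModel:
    """Calibrated margin classifier plus its standardization statistics."""

    estimator: object
    scaler: FeatureScaler
    cost: float
    gamma: float
    corpus_availability: np.ndarray  # columns ever available during training
    format_version: int = MODEL_FORMAT_VERSION

    def predict_proba(self, values: np.ndarray, available: np.ndarray) -> np.ndarray:
        x = self.scaler.transform(values, available)
        return self.estimator.predict_proba(x)[:, 1]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "BreakingContactModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.format_version != MODEL_FORMAT_VERSION:
            raise ValueError("incompatible model format version")
        return model


def train(
    tset: TrainingSet,
    cost: float = DEFAULT_COST,
    gamma: float | str = DEFAULT_GAMMA,
    calibration_folds: int = 3,
    seed: int = 0,
) -> BreakingContactModel:
    """RBF-kernel classifier with inverse-class-frequency weights and Platt
    probability calibration (internal cross-validation folds)."""
    if len(np.unique(tset.labels)) < 2:
        raise ValueError("degenerate labels: training set has a single class")
    scaler = FeatureScaler().fit(tset.values, tset.available)
    x = scaler.transform(tset.values, tset.available)
    svc = SVC(C=cost, gamma=gamma, kernel="rbf", class_weight="balanced",
              random_state=seed)
    est = CalibratedClassifierCV(svc, method="sigmoid", cv=calibration_folds)
    est.fit(x, tset.labels)
    return BreakingContactModel(
        estimator=est,
        scaler=scaler,
        cost=cost,
        gamma=gamma if isinstance(gamma, float) else -1.0,
        corpus_availability=tset.available.any(axis=0),
    )


@dataclass
class RankedContacts:
    """Contacts ordered by decreasing probability of breaking."""

    pairs: list[tuple[int, int]]
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self, selected=()) -> pd.DataFrame:
        sel = set(selected)
        return pd.DataFrame({
            "i": [p[0] for p in self.pairs],
            "j": [p[1] for p in self.pairs],
            "score": self.scores,
            "selected": [p in sel for p in self.pairs],
        })


def rank_contacts(
    model: BreakingContactModel,
    pairs,
    values: np.ndarray,
    available: np.ndarray,
) -> RankedContacts:
    """Score contacts and sort by decreasing probability; score ties break
    toward the lexicographically smaller (i, j)."""
    if len(pairs) == 0:
        return RankedContacts(pairs=[], scores=np.array([]))
    scores = model.predict_proba(values, available)
    order = sorted(range(len(pairs)), key=lambda r: (-scores[r], pairs[r]))
    return RankedContacts(
        pairs=[pairs[r] for r in order],
        scores=np.array([scores[r] for r in order]),
    )


def select_removals(ranked: RankedContacts, strategy: str, param) -> list:
    """Choose the removal subset from the ranking.

    ``constant``: the top min(n, available) contacts; ``relative``: the top
    ⌊p·len(ranking)⌋; ``score``: every contact with probability strictly
    above the threshold.
    """
    if strategy == "constant":
        n = min(int(param), len(ranked))
    elif strategy == "relative":
        n = int(float(param) * len(ranked))
    elif strategy == "score":
        n = int(np.sum(ranked.scores > float(param)))
    else:
        raise ValueError(f"unknown selection strategy: {strategy!r}")
    return list(ranked.pairs[:n])


def classifier_metrics(
    predicted,
    tmap: TransitionMap,
    ranked: RankedContacts | None = None,
    min_sep: int = MIN_SEQ_SEP,
) -> dict:
    """Precision and coverage of a predicted breaking set, plus AUROC when
    the full ranking is supplied."""
    observed = set(tmap.breaking_pairs(min_sep))
    predicted = {(min(i, j), max(i, j)) for i, j in predicted}
    tp = len(predicted & observed)
    precision = tp / len(predicted) if predicted else 0.0
    coverage = tp / len(observed) if observed else 0.0
    auroc = None
    if ranked is not None and len(ranked):
        y = np.array([p in observed for p in ranked.pairs], dtype=int)
        if 0 < y.sum() < len(y):
            auroc = float(roc_auc_score(y, ranked.scores))
    return {"precision": precision, "coverage": coverage, "auroc": auroc}


def linear_feature_weights(tset: TrainingSet, cost: float = 1.0) -> pd.DataFrame:
    """Feature ranking from a linear maximum-margin fit on the standardized
    features; columns never available in the corpus are excluded.  Ties are
    broken by feature name for a deterministic ordering."""
    from lmcenm.features import FEATURE_NAMES

    scaler = FeatureScaler().fit(tset.values, tset.available)
    x = scaler.transform(tset.values, tset.available)
    keep = tset.available.any(axis=0)
    svc = SVC(kernel="linear", C=cost, class_weight="balanced")
    svc.fit(x[:, keep], tset.labels)
    names = [n for n, k in zip(FEATURE_NAMES, keep) if k]
    df = pd.DataFrame({"feature": names, "weight": svc.coef_[0]})
    return df.sort_values(["weight", "feature"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)


DEFAULT_GRID = tuple(
    (c, g) for c in (1.0, 10.0, 100.0, 1000.0)
    for g in (1e-3, 1e-4, 1e-5, 1e-6)
)


def tune_loocv(corpus, grid=DEFAULT_GRID, ratio: float = DEFAULT_RATIO,
               seed: int = 0, min_sep: int = MIN_SEQ_SEP) -> tuple[float, float]:
    """Leave-one-protein-out hyperparameter search.

    Objective: mean over held-out proteins of the precision among the top
    ⌊L/5⌋ scored contacts, L the protein length.  Ties prefer the smaller
    cost, then the smaller gamma.
    """
    corpus = list(corpus)
    best = None
    for cost, gamma in grid:
        precisions = []
        for hold in range(len(corpus)):
            rest = [corpus[k] for k in range(len(corpus)) if k != hold]
            try:
                tset = build_training_set(rest, ratio=ratio, seed=seed,
                                          min_sep=min_sep)
                model = train(tset, cost=cost, gamma=gamma, seed=seed)
            except ValueError:
                continue
            pid, pairs, values, available, tmap = corpus[hold]
            length = tmap.n_residues
            ranked = rank_contacts(model, pairs, values, available)
            top = ranked.pairs[: max(length // 5, 1)]
            m = classifier_metrics(top, tmap, min_sep=min_sep)
            precisions.append(m["precision"])
        score = float(np.mean(precisions)) if precisions else 0.0
        key = (-score, cost, gamma)
        if best is None or key < best[0]:
            best = (key, (cost, gamma))
    return best[1]
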