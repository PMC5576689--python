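"""Binary contact maps and contact-transition classification.

Two residues are in contact when their Cα–Cα distance d_ij ≤ r_c (boundary
inclusive).  Comparing the contact maps of a start and an end conformation
classifies every start contact as *maintained* or *breaking* according to its
strain e_ij = |d_ij^S − d_ij^E| / d_ij^S against a threshold e_c, and every
new end contact as *forming*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from lmcenm.structure import ConformationPair, Structure

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 10.0  # Å
DEFAULT_STRAIN_THRESHOLD = 0.09  # dimensionless

# transition label codes
NONE, MAINTAINED, BREAKING, FORMING = 0, 1, 2, 3
LABEL_NAMES = {NONE: "none", MAINTAINED: "maintained", BREAKING: "breaking",
               FORMING: "forming"}


@dataclass
class ContactMap:
    """Symmetric binary contact topology at cutoff ``cutoff`` (Å)."""

    cutoff: float
    distances: np.ndarray
    contacts: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.contacts.shape[0]

    def pairs(self, min_sep: int = 0) -> list[tuple[int, int]]:
        """Contact pairs (i < j) with sequence separation |i−j| ≥ min_sep."""
        ii, jj = np.nonzero(np.triu(self.contacts, k=max(min_sep, 1)))
        return list(zip(ii.tolist(), jj.tolist()))

    def to_edge_list(self) -> pd.DataFrame:
        rows = [(i, j, self.distances[i, j]) for i, j in self.pairs()]
        return pd.DataFrame(rows, columns=["i", "j", "distance"])


@dataclass
class TransitionMap:
    """Per-pair contact transition labels between two conformations.

    Labels and strain are indexed by the *start* structure's residue indices;
    pairs involving residues without a counterpart in the end conformation
    carry label ``NONE`` and undefined (NaN) strain.
    """

    cutoff: float
    strain_threshold: float
    labels: np.ndarray  # int matrix over {NONE, MAINTAINED, BREAKING, FORMING}
    strain: np.ndarray  # NaN where undefined
    matched: np.ndarray  # start-structure indices with an end counterpart

    @property
    def n_residues(self) -> int:
        return self.labels.shape[0]

    def pairs_with_label(self, label: int, min_sep: int = 0) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.labels == label, k=1))
        return [(int(i), int(j)) for i, j in zip(ii, jj) if abs(int(i) - int(j)) >= min_sep]

    def breaking_pairs(self, min_sep: int = 0) -> list[tuple[int, int]]:
        return self.pairs_with_label(BREAKING, min_sep)

    def maintained_pairs(self, min_sep: int = 0) -> list[tuple[int, int]]:
        return self.pairs_with_label(MAINTAINED, min_sep)

    def forming_pairs(self, min_sep: int = 0) -> list[tuple[int, int]]:
        return self.pairs_with_label(FORMING, min_sep)

    def to_table(self) -> pd.DataFrame:
        """Long-format table (i, j, label) over all labeled pairs."""
        rows = []
        for code in (MAINTAINED, BREAKING, FORMING):
            rows += [(i, j, LABEL_NAMES[code]) for i, j in self.pairs_with_label(code)]
        return pd.DataFrame(sorted(rows), columns=["i", "j", "label"])


def build_contact_map(structure_or_coords, cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """Contact map of one conformation: C_ij = 1 iff d_ij ≤ cutoff, i ≠ j."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = (
        structure_or_coords.coords
        if isinstance(structure_or_coords, Structure)
        else np.asarray(structure_or_coords, float)
    )
    if coords.shape[0] < 2:
        raise ValueError("need at least two residues")
    d = squareform(pdist(coords))
    contacts = (d <= cutoff)
    np.fill_diagonal(contacts, False)
    return ContactMap(cutoff=float(cutoff), distances=d, contacts=contacts)


def classify_transitions(
    pair: ConformationPair,
    cutoff: float = DEFAULT_CUTOFF,
    strain_threshold: float = DEFAULT_STRAIN_THRESHOLD,
) -> TransitionMap:
    """Label every residue pair of the start conformation.

    Start contacts are *maintained* when their strain stays within the
    threshold and *breaking* otherwise (stretch and compression both count);
    pairs in contact only in the end conformation are *forming*.  Distances
    are computed over matched residues only; unmatched residues contribute
    no labels.
    """
    if pair.n_matched < 2:
        raise ValueError("need at least two matched residues")
    n = len(pair.start)
    i_s = pair.matched_start
    coords_s = pair.start.coords[i_s]
    coords_e = pair.end_superposed[pair.matched_end]
    d_s = squareform(pdist(coords_s))
    d_e = squareform(pdist(coords_e))
    c_s = (d_s <= cutoff)
    c_e = (d_e <= cutoff)
    np.fill_diagonal(c_s, False)
    np.fill_diagonal(c_e, False)
    strain_m = np.abs(d_s - d_e) / np.where(d_s > 0, d_s, np.nan)

    sub = np.full((len(i_s), len(i_s)), NONE, dtype=int)
    sub[c_s & (strain_m <= strain_threshold)] = MAINTAINED
    sub[c_s & (strain_m > strain_threshold)] = BREAKING
    sub[~c_s & c_e] = FORMING

    labels = np.full((n, n), NONE, dtype=int)
    strain = np.full((n, n), np.nan)
    labels[np.ix_(i_s, i_s)] = sub
    strain_sub = np.where(c_s, strain_m, np.nan)
    strain[np.ix_(i_s, i_s)] = strain_sub
    np.fill_diagonal(labels, NONE)
    n_unmatched = n - len(i_s)
    if n_unmatched:
        log.info("%d start residues unmatched; their pairs are unlabeled", n_unmatched)
    return TransitionMap(
        cutoff=float(cutoff),
        strain_threshold=float(strain_threshold),
        labels=labels,
        strain=strain,
        matched=i_s,
    )


def transition_counts(tmap: TransitionMap, min_sep: int = 0) -> dict:
    """Counts and fractions of each transition label at |i−j| ≥ min_sep."""
    if min_sep < 0:
        raise ValueError("min_sep must be non-negative")
    counts = {}
    for code, name in LABEL_NAMES.items():
        if code == NONE:
            continue
        counts[name] = len(tmap.pairs_with_label(code, min_sep))
    n_start = counts["maintained"] + counts["breaking"]
    total = n_start + counts["forming"]
    fractions = {
        name: (c / n_start if n_start else 0.0)
        for name, c in counts.items()
        if name in ("maintained", "breaking")
    }
    return {
        "counts": counts,
        "n_start_contacts": n_start,
        "n_labeled": total,
        "fractions": fractions,
    }
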