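"""Synthetic Cα structures and conformation pairs with known ground truth.

Generators emit compact self-avoiding Cα chains (globules), two-domain hinge
pairs with a rotated domain, and loop-shift pairs where a surface loop is
displaced outward.  Motion ground truth (breaking/maintained/forming labels)
is produced by running the contact-transition classification on the exact
generated coordinates, so generator output is self-consistent with the
analysis stack by construction.  The toys caricature domain vs. localized
motion; they exercise machinery, not biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from lmcenm.contacts import TransitionMap, classify_transitions
from lmcenm.enm import ElasticNetwork, modify_network
from lmcenm.structure import ConformationPair, Structure, build_pair, assign_sse, write_ca_structure

BOND_LENGTH = 3.8  # Å, consecutive Cα distance
BOND_JITTER = 0.1
MIN_SEPARATION = 4.0  # Å, non-bonded excluded volume
LINKER_LENGTH = 5

_AA = sorted([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
])


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic conformation pair."""

    n_residues: int = 60
    motion: str = "hinge"  # "hinge" | "loop_shift" | "none"
    hinge_angle: float = 45.0  # degrees, in (0, 90]
    loop_span: int = 8
    loop_amplitude: float = 6.0  # Å
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 10:
            raise ValueError("need at least 10 residues")
        if self.motion == "hinge" and not 0 < self.hinge_angle <= 90:
            raise ValueError("hinge angle must be in (0, 90]")
        if self.motion == "loop_shift" and self.loop_amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def _grow_chain(n: int, rng, radius: float, start=None) -> np.ndarray:
    """Self-avoiding biased random walk confined to a sphere."""
    for _ in range(60):  # chain-level restarts
        pts = [np.zeros(3) if start is None else np.asarray(start, float)]
        ok = True
        for _ in range(1, n):
            placed = False
            for _ in range(300):
                step = rng.normal(size=3)
                # pull back toward the sphere center when drifting out
                r = np.linalg.norm(pts[-1])
                if r > 0.6 * radius:
                    step += 2.0 * (-pts[-1] / r)
                step /= np.linalg.norm(step)
                bond = BOND_LENGTH + rng.uniform(-BOND_JITTER, BOND_JITTER)
                cand = pts[-1] + bond * step
                if np.linalg.norm(cand) > radius:
                    continue
                if len(pts) > 1:
                    d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                    if d.min() < MIN_SEPARATION:
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("packing failed; re-seed the generator")


def _chain_to_structure(coords: np.ndarray, rng, chain_id: str = "A") -> Structure:
    names = [_AA[k] for k in rng.integers(0, 20, size=len(coords))]
    s = Structure(
        chain_id=chain_id,
        res_names=names,
        author_numbers=[str(k + 1) for k in range(len(coords))],
        coords=coords,
        b_factors=np.zeros(len(coords)),
    )
    return assign_sse(s)


def make_globule(n: int, seed: int = 0, chain_id: str = "A") -> Structure:
    """Compact self-avoiding Cα chain with radius of gyration ≈ 3·n^(1/3) Å."""
    rng = np.random.default_rng(seed)
    radius = 1.29 * 3.0 * n ** (1.0 / 3.0)  # sphere radius matching target Rg
    coords = _grow_chain(n, rng, radius)
    coords = coords - coords.mean(axis=0)
    return _chain_to_structure(coords, rng, chain_id)


def make_hinge_pair(spec: SyntheticSpec):
    """Two-domain hinge toy built from one compact globule.

    The chain is split at its midpoint into two rigid halves joined by a
    short linker around the pivot residue; the end conformation rotates the
    second half about an axis through the pivot, chosen so the domains swing
    apart (an opening motion).  Intra-domain contacts are untouched;
    breaking contacts concentrate at the inter-domain interface.

    Returns (pair, ground_truth, domain_of) with ``domain_of`` ∈ {0, 1, 2}
    per residue (0/1 = domains, 2 = linker).
    """
    n = spec.n_residues
    start = make_globule(n, seed=spec.seed)
    coords_s = start.coords
    split = n // 2
    pivot = coords_s[split]
    cent_a = coords_s[:split].mean(axis=0)
    cent_b = coords_s[split + 1 :].mean(axis=0)
    # axis ⊥ to both pivot→centroid vectors: rotation sweeps the halves
    # apart within their common plane
    axis = np.cross(cent_a - pivot, cent_b - pivot)
    norm = np.linalg.norm(axis)
    if norm < 1e-6:  # degenerate (collinear centroids): any ⊥ axis works
        ref = np.array([0.0, 0.0, 1.0])
        axis = np.cross(cent_b - pivot, ref)
        norm = np.linalg.norm(axis)
    axis /= norm
    coords_e = np.array(coords_s, copy=True)
    moving = np.arange(split + 1, n)
    best = None
    for sign in (1.0, -1.0):
        rot = Rotation.from_rotvec(sign * np.deg2rad(spec.hinge_angle) * axis)
        trial = rot.apply(coords_s[moving] - pivot) + pivot
        gap = np.linalg.norm(trial.mean(axis=0) - cent_a)
        if best is None or gap > best[0]:
            best = (gap, trial)
    coords_e[moving] = best[1]
    end = Structure(
        chain_id=start.chain_id,
        res_names=list(start.res_names),
        author_numbers=list(start.author_numbers),
        coords=coords_e,
        b_factors=np.zeros(n),
        sse=list(start.sse),
    )
    pair = build_pair(start, end)
    truth = classify_transitions(pair)
    half = LINKER_LENGTH // 2
    domain_of = np.full(n, 2, dtype=int)
    domain_of[: split - half] = 0
    domain_of[split + half + 1 :] = 1
    return pair, truth, domain_of


def make_loop_pair(spec: SyntheticSpec):
    """Loop-shift toy: a surface loop moves outward, the rest stays fixed.

    Returns (pair, ground_truth, loop_indices).
    """
    rng = np.random.default_rng(spec.seed)
    start = make_globule(spec.n_residues, seed=spec.seed)
    coords = start.coords
    centroid = coords.mean(axis=0)
    span = spec.loop_span
    # pick the window whose residues sit farthest from the centroid (surface)
    dist = np.linalg.norm(coords - centroid, axis=1)
    margin = 2  # keep the loop off the termini
    scores = [
        dist[k : k + span].mean()
        for k in range(margin, len(coords) - span - margin)
    ]
    loop_start = margin + int(np.argmax(scores))
    loop = np.arange(loop_start, loop_start + span)
    outward = coords[loop].mean(axis=0) - centroid
    outward /= np.linalg.norm(outward)
    coords_e = np.array(coords, copy=True)
    # smooth half-sine taper: zero amplitude just outside the loop ends
    taper = np.sin(math.pi * (np.arange(span) + 1) / (span + 1))
    coords_e[loop] += spec.loop_amplitude * taper[:, None] * outward
    end = Structure(
        chain_id=start.chain_id,
        res_names=list(start.res_names),
        author_numbers=list(start.author_numbers),
        coords=coords_e,
        b_factors=np.zeros(len(coords)),
        sse=list(start.sse),
    )
    pair = build_pair(start, end)
    truth = classify_transitions(pair)
    return pair, truth, loop


def make_pair(spec: SyntheticSpec):
    """Dispatch on the spec's motion type."""
    if spec.motion == "hinge":
        return make_hinge_pair(spec)
    if spec.motion == "loop_shift":
        return make_loop_pair(spec)
    if spec.motion == "none":
        start = make_globule(spec.n_residues, seed=spec.seed)
        end = Structure(
            chain_id=start.chain_id,
            res_names=list(start.res_names),
            author_numbers=list(start.author_numbers),
            coords=np.array(start.coords, copy=True),
            b_factors=np.zeros(len(start)),
            sse=list(start.sse),
        )
        pair = build_pair(start, end)
        return pair, classify_transitions(pair), np.array([], int)
    raise ValueError(f"unknown motion type: {spec.motion!r}")


def random_removal_control(
    network: ElasticNetwork, n_remove: int, seed: int = 0, min_sep: int = 4
) -> ElasticNetwork:
    """Remove n uniformly chosen native long-range springs (degree-protected);
    the null control matched to a classifier-guided removal."""
    rng = np.random.default_rng(seed)
    candidates = [
        (i, j) for (i, j), (_, origin) in sorted(network.edges.items())
        if origin == "native" and abs(i - j) >= min_sep
    ]
    rng.shuffle(candidates)
    out = network
    removed = 0
    for pair in candidates:
        if removed >= n_remove:
            break
        trial = modify_network(out, remove=[pair], min_sep=min_sep)
        if trial.n_edges < out.n_edges:
            out = trial
            removed += 1
    return out


def make_corpus(n_proteins: int = 20, seed: int = 0, n_residues: int = 60,
                motions: tuple = ("hinge",)):
    """Synthetic conformation-pair corpus for classifier experiments.

    Default is an all-hinge corpus (one coherent breaking-contact signature
    to learn); pass ``motions=("hinge", "loop_shift")`` for a mixed set.
    Hinge angles vary per protein (30–60°) and per-protein seeds derive
    from the corpus seed.  Returns a list of (protein_id, spec, pair,
    truth).
    """
    rng = np.random.default_rng(seed)
    corpus = []
    for k in range(n_proteins):
        motion = motions[k % len(motions)]
        spec = SyntheticSpec(
            n_residues=n_residues,
            motion=motion,
            hinge_angle=float(rng.uniform(30.0, 60.0)),
            seed=seed * 10_000 + k,
        )
        pair, truth, _ = make_pair(spec)
        corpus.append((f"syn{k:03d}_{motion}", spec, pair, truth))
    return corpus


def write_fixture_corpus(directory, n_proteins: int = 20, seed: int = 0,
                         n_residues: int = 60) -> list[str]:
    """Materialize a corpus as PDB files plus ground-truth label TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = []
    for pid, _, pair, truth in make_corpus(n_proteins, seed, n_residues):
        write_ca_structure(pair.start, directory / f"{pid}_start.pdb")
        write_ca_structure(pair.end, directory / f"{pid}_end.pdb")
        truth.to_table().to_csv(directory / f"{pid}_labels.tsv", sep="\t",
                                index=False)
        ids.append(pid)
    return ids
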