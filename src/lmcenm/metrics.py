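"""Agreement measures between network modes and observed transitions.

Covers per-mode overlap O_j and its cumulative form CO(k), mode variance
fractions and CFV(k), the entropy-based degree of collectivity κ, the
best-overlapping-mode record, mode counts to reach a target overlap,
fluctuation-profile correlations, subspace similarities (RMSIP, RWSIP), and
essential-dynamics PCA of conformational ensembles.

Conventions: overlaps are computed against the displacement field obtained
after superposing the end conformation onto the start; the "variance" of a
mode with eigenvalue λ is 1/λ (unit stiffness and masses — constant
prefactors cancel in every fraction and correlation reported here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from lmcenm.enm import ModeSet

UNREACHED = math.inf  # sentinel for modes_to_reach


def _as_flat(v) -> np.ndarray:
    return np.asarray(v, float).reshape(-1)


def mode_overlap(mode, displacement) -> float:
    """|cos| of the angle between a mode and the displacement field, in [0, 1]."""
    m = _as_flat(mode)
    d = _as_flat(displacement)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("undefined overlap: zero displacement")
    return float(abs(m @ d) / (np.linalg.norm(m) * nd))


def overlaps(modes: ModeSet, displacement) -> np.ndarray:
    """Per-mode overlaps for all nonzero modes, in rank order."""
    d = _as_flat(displacement)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("undefined overlap: zero displacement")
    m = modes.nonzero_modes  # columns are unit vectors
    return np.abs(m.T @ d) / nd


def cumulative_overlap(modes: ModeSet, displacement, k: int) -> float:
    """CO(k): root-sum-square of the first k per-mode overlaps."""
    if k > modes.n_nonzero:
        raise ValueError("k exceeds the number of nonzero modes")
    o = overlaps(modes, displacement)[:k]
    return float(np.sqrt(np.sum(o**2)))


def variance_fractions(modes: ModeSet, k: int | None = None):
    """Per-mode variance fractions (1/λ normalized over all nonzero modes)
    and the cumulative fraction CFV(k)."""
    lam = modes.nonzero_eigenvalues
    inv = 1.0 / lam
    fractions = inv / inv.sum()
    if k is None:
        k = len(fractions)
    return fractions, float(fractions[:k].sum())


def collectivity(mode, n_residues: int | None = None) -> float:
    """Degree of collectivity κ ∈ [1/N, 1] of a 3N mode vector.

    κ = exp(−Σ u_i² log u_i²)/N with u_i² the normalized per-residue squared
    amplitude; 1 means every residue moves equally, 1/N a single residue.
    """
    m = _as_flat(mode)
    if len(m) % 3:
        raise ValueError("mode length must be a multiple of 3")
    amp2 = (m.reshape(-1, 3) ** 2).sum(axis=1)
    total = amp2.sum()
    if total == 0:
        raise ValueError("zero mode vector")
    n = n_residues or len(amp2)
    u2 = amp2 / total
    nz = u2[u2 > 0]
    return float(np.exp(-(nz * np.log(nz)).sum()) / n)


@dataclass
class BestModeRecord:
    """The best-overlapping nonzero mode and its context."""

    max_overlap: float
    rank: int  # 0 = first nonzero mode
    collectivity: float
    variance_fraction: float


def best_mode(modes: ModeSet, displacement) -> BestModeRecord:
    """Highest-overlap nonzero mode; ties break toward the lower rank."""
    o = overlaps(modes, displacement)
    rank = int(np.argmax(o))  # argmax takes the first maximum
    fractions, _ = variance_fractions(modes)
    return BestModeRecord(
        max_overlap=float(o[rank]),
        rank=rank,
        collectivity=collectivity(modes.mode(rank)),
        variance_fraction=float(fractions[rank]),
    )


def modes_to_reach(modes: ModeSet, displacement,
                   thresholds=(0.7, 0.8, 0.9)) -> dict[float, float]:
    """Smallest k with CO(k) ≥ threshold, per threshold (inf when never)."""
    o = overlaps(modes, displacement)
    co = np.sqrt(np.cumsum(o**2))
    out = {}
    for t in thresholds:
        hit = np.nonzero(co >= t)[0]
        out[t] = int(hit[0]) + 1 if len(hit) else UNREACHED
    return out


def fluctuation_profile(modes: ModeSet, k: int) -> np.ndarray:
    """Per-residue mean-square fluctuation from the first k nonzero modes:
    MSF_i = Σ_j≤k (1/λ_j)·|mode_j at residue i|²."""
    lam = modes.nonzero_eigenvalues[:k]
    m = modes.nonzero_modes[:, :k]
    per_res = (m.reshape(-1, 3, len(lam)) ** 2).sum(axis=1)  # (N, k)
    return per_res @ (1.0 / lam)


def correlate(profile, reference) -> float:
    """Pearson correlation after least-squares scaling of the profile onto
    the reference (scaling is reported for plots; the coefficient itself is
    affine-invariant)."""
    p = _as_flat(profile)
    r = _as_flat(reference)
    if len(p) != len(r):
        raise ValueError("length mismatch")
    scale = (p @ r) / (p @ p) if p @ p > 0 else 1.0
    p = scale * p
    if np.std(p) == 0 or np.std(r) == 0:
        raise ValueError("constant profile: correlation undefined")
    return float(np.corrcoef(p, r)[0, 1])


def rmsip(u: np.ndarray, v: np.ndarray, k: int = 10) -> float:
    """Root mean square inner product of two k-dimensional subspaces.

    ``u`` and ``v`` hold mode vectors as columns; value in [0, 1].
    """
    uu = np.asarray(u, float)[:, :k]
    vv = np.asarray(v, float)[:, :k]
    return float(np.sqrt(np.sum((uu.T @ vv) ** 2) / k))


def rwsip(u: np.ndarray, u_weights, v: np.ndarray, v_weights) -> float:
    """Root weighted square inner product over the full non-trivial spaces.

    Weights are amplitude variances (for ENM mode sets pass 1/λ so that
    they are comparable to PCA variances); value in [0, 1], 1 iff spaces
    and weight spectra coincide.
    """
    uu = np.asarray(u, float)
    vv = np.asarray(v, float)
    wu = _as_flat(u_weights)
    wv = _as_flat(v_weights)
    inner2 = (uu.T @ vv) ** 2
    num = wu @ inner2 @ wv
    k = min(len(wu), len(wv))
    den = float(np.sum(np.sort(wu)[::-1][:k] * np.sort(wv)[::-1][:k]))
    return float(np.sqrt(num / den))


def ensemble_pca(ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Essential dynamics of a pre-superposed conformational ensemble.

    ``ensemble`` is a sequence of (N, 3) coordinate sets over a common
    residue set.  Returns unit principal directions (3N per column) and
    their variances in descending order.
    """
    x = np.array([np.asarray(c, float).reshape(-1) for c in ensemble])
    if x.shape[0] < 3:
        raise ValueError("need at least three conformers")
    x = x - x.mean(axis=0)
    # SVD of the centered data matrix == eigen-decomposition of the covariance
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    variances = s**2 / x.shape[0]
    return vt.T, variances
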