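"""Elastic-network construction, stabilization, surgery, and normal modes.

The network potential is harmonic over all springs,

    V = Σ_(i<j) k_ij/2 · (d_ij − d⁰_ij)²,

with per-pair stiffness k_ij set by one of four schemes: a uniform cutoff
model, the HCA distance-dependent model, an essential-dynamics-fitted hybrid
(edENM) with sequence-neighbor springs and a size-dependent cutoff, and a
secondary-structure-aware stiffness-scaled cutoff model (OFC).  Normal modes
come from the eigen-decomposition of the 3N×3N Hessian with unit masses; a
stable network has exactly six zero eigenvalues (rigid-body motions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from lmcenm.structure import Structure

log = logging.getLogger(__name__)

DEFAULT_MIN_DEGREE = 4
DEFAULT_ZERO_TOL = 1e-8

NATIVE, STABILIZER, ADDED_FORMING = "native", "stabilizer", "added_forming"


# --- spring schemes ----------------------------------------------------------

@dataclass(frozen=True)
class UniformCutoff:
    """Classic ANM: k_ij = γ for d_ij ≤ cutoff, else 0."""

    gamma: float = 1.0
    cutoff: float = 10.0
    name: str = "uniform_cutoff"
    stabilize_default: bool = True

    def stiffness(self, d, s, n_residues, sse_pair=None) -> float:
        return self.gamma if d <= self.cutoff else 0.0


@dataclass(frozen=True)
class HCA:
    """Cutoff-free stiffness decaying with distance.

    Linear branch a·d − b below 4 Å, power-law c·d^−d_exp beyond.  The linear
    branch turns negative below b/a ≈ 2.78 Å; stiffness is clamped at zero
    there (such Cα distances are physically impossible anyway).
    """

    a: float = 205.5
    b: float = 571.2
    c: float = 3.059e5
    d_exp: float = 6.0
    cutoff: float = 4.0
    gamma: float = 1.0
    name: str = "hca"
    stabilize_default: bool = False

    def stiffness(self, d, s, n_residues, sse_pair=None) -> float:
        if d < self.cutoff:
            k = self.a * d - self.b
            if k < 0:
                log.debug("HCA stiffness clamped at 0 for d=%.2f", d)
                return 0.0
            return k
        return self.c * d ** (-self.d_exp)


@dataclass(frozen=True)
class EdENM:
    """Hybrid scheme: sequence springs a/s² for s ≤ 3, distance springs
    (c/d)⁶ within a size-dependent cutoff r_c(N) = 2.9·ln(N) − 2.9."""

    a: float = 60.0
    b: float = 2.0
    c: float = 6.0
    d_exp: float = 6.0
    gamma: float = 1.0
    name: str = "edenm"
    stabilize_default: bool = False

    @staticmethod
    def size_cutoff(n_residues: int) -> float:
        return 2.9 * math.log(n_residues) - 2.9

    def stiffness(self, d, s, n_residues, sse_pair=None) -> float:
        if s <= 3:
            return self.a / s ** self.b
        if d <= self.size_cutoff(n_residues):
            return (self.c / d) ** self.d_exp
        return 0.0


def default_ofc_table() -> dict:
    """Stiffness multipliers keyed by (SSE pair class, sequence-distance class).

    Shipped default: helix–helix pairs close in sequence are stiffened 3×,
    strand–strand pairs (sheet partners, sequence-distant) 2×, everything
    else 1×.  The table is configuration-replaceable.
    """
    return {("HH", "short"): 3.0, ("EE", "long"): 2.0}


@dataclass(frozen=True)
class OFC:
    """Cutoff model with stiffness scaled by secondary structure and
    sequence distance, via a lookup table of multipliers on γ."""

    gamma: float = 1.0
    cutoff: float = 10.0
    seq_short: int = 4  # s ≤ seq_short counts as "short"
    table: dict = field(default_factory=default_ofc_table)
    name: str = "ofc"
    stabilize_default: bool = True

    def stiffness(self, d, s, n_residues, sse_pair=None) -> float:
        if d > self.cutoff:
            return 0.0
        mult = 1.0
        if sse_pair is not None:
            key = "".join(sorted(sse_pair))
            seq_class = "short" if s <= self.seq_short else "long"
            mult = self.table.get((key, seq_class), 1.0)
        return self.gamma * mult


SCHEMES = {"uniform_cutoff": UniformCutoff, "hca": HCA, "edenm": EdENM, "ofc": OFC}


def make_scheme(name: str, **kwargs):
    try:
        return SCHEMES[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown scheme: {name!r}") from None


def spring_constant(scheme, d_ij: float, s_ij: int, n_residues: int,
                    sse_pair=None) -> float:
    """Stiffness of one spring under the given scheme (0 means no spring)."""
    if d_ij <= 0:
        raise ValueError("distance must be positive")
    if s_ij < 1:
        raise ValueError("sequence separation must be ≥ 1")
    return float(scheme.stiffness(d_ij, s_ij, n_residues, sse_pair))


# --- network -----------------------------------------------------------------

@dataclass
class ElasticNetwork:
    """Weighted spring graph over Cα nodes.

    ``edges`` maps (i, j) with i < j to (stiffness, origin); origin is one of
    ``native``, ``stabilizer``, ``added_forming``.
    """

    coords: np.ndarray
    edges: dict[tuple[int, int], tuple[float, str]]
    scheme: object = None

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def copy(self) -> "ElasticNetwork":
        return ElasticNetwork(
            coords=np.array(self.coords, copy=True),
            edges=dict(self.edges),
            scheme=self.scheme,
        )

    def to_edge_list(self) -> pd.DataFrame:
        rows = [(i, j, k, origin) for (i, j), (k, origin) in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["i", "j", "k", "origin"])


def _gamma_of(scheme) -> float:
    return getattr(scheme, "gamma", 1.0)


def build_network(
    structure, scheme=None, stabilize: bool | None = None,
    min_degree: int = DEFAULT_MIN_DEGREE,
) -> ElasticNetwork:
    """Create springs wherever the scheme yields positive stiffness.

    With ``stabilize`` (default: scheme-dependent, on for the cutoff
    schemes), any node with degree < ``min_degree`` is connected to its
    closest not-yet-connected sequence neighbor — irrespective of spatial
    distance — until the degree criterion holds.  Stabilizer springs carry
    stiffness γ.
    """
    if isinstance(structure, Structure):
        coords = structure.coords
        sse = structure.sse
    else:
        coords = np.asarray(structure, float)
        sse = None
    n = coords.shape[0]
    if n < 3:
        raise ValueError("network too small (need ≥ 3 residues)")
    if scheme is None:
        scheme = UniformCutoff()
    if stabilize is None:
        stabilize = scheme.stabilize_default
    d = squareform(pdist(coords))
    edges: dict[tuple[int, int], tuple[float, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sse_pair = (sse[i], sse[j]) if sse is not None else None
            k = scheme.stiffness(d[i, j], j - i, n, sse_pair)
            if k > 0:
                edges[(i, j)] = (float(k), NATIVE)
    network = ElasticNetwork(coords=np.array(coords, copy=True), edges=edges,
                             scheme=scheme)
    if stabilize:
        _stabilize(network, min_degree, _gamma_of(scheme))
    return network


def _stabilize(network: ElasticNetwork, min_degree: int, gamma: float) -> None:
    """Connect under-constrained nodes to sequence neighbors (closest first,
    ties toward the lower index) until every node has degree ≥ min_degree."""
    n = network.n_nodes
    deg = network.degrees()
    for node in range(n):
        while deg[node] < min_degree:
            candidates = sorted(
                (abs(node - other), other)
                for other in range(n)
                if other != node
                and (min(node, other), max(node, other)) not in network.edges
            )
            if not candidates:
                break
            _, other = candidates[0]
            key = (min(node, other), max(node, other))
            network.edges[key] = (gamma, STABILIZER)
            deg[node] += 1
            deg[other] += 1


def modify_network(
    network: ElasticNetwork,
    remove=(),
    add=(),
    min_sep: int = 4,
    min_degree: int = DEFAULT_MIN_DEGREE,
) -> ElasticNetwork:
    """Network surgery: remove native springs, optionally add forming ones.

    Removals apply only to native springs joining residues at least
    ``min_sep`` sequence positions apart; stabilizer springs are never
    removed, and a removal that would drop either endpoint below degree
    ``min_degree`` is skipped with a warning (stability first).  Added
    springs carry stiffness γ and origin ``added_forming``.
    """
    out = network.copy()
    deg = out.degrees()
    for i, j in remove:
        key = (min(i, j), max(i, j))
        if key not in out.edges:
            continue
        if abs(i - j) < min_sep:
            continue
        k, origin = out.edges[key]
        if origin == STABILIZER:
            continue
        if deg[key[0]] - 1 < min_degree or deg[key[1]] - 1 < min_degree:
            log.warning("removal of %s skipped: would drop a node below degree %d",
                        key, min_degree)
            continue
        del out.edges[key]
        deg[key[0]] -= 1
        deg[key[1]] -= 1
    gamma = _gamma_of(out.scheme)
    for i, j in add:
        key = (min(i, j), max(i, j))
        if key[0] == key[1] or key in out.edges:
            continue
        out.edges[key] = (gamma, ADDED_FORMING)
        deg[key[0]] += 1
        deg[key[1]] += 1
    return out


# --- Hessian and modes -------------------------------------------------------

def potential_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Harmonic network energy of a deformed configuration."""
    coords = np.asarray(coords, float).reshape(network.n_nodes, 3)
    e = 0.0
    for (i, j), (k, _) in network.edges.items():
        d0 = np.linalg.norm(network.coords[j] - network.coords[i])
        d = np.linalg.norm(coords[j] - coords[i])
        e += 0.5 * k * (d - d0) ** 2
    return e


def hessian(network: ElasticNetwork) -> np.ndarray:
    """3N×3N ANM Hessian (unit masses): super-element assembly with
    off-diagonal blocks −k_ij·r̂r̂ᵀ along each spring's equilibrium direction."""
    n = network.n_nodes
    h = np.zeros((3 * n, 3 * n))
    for (i, j), (k, _) in network.edges.items():
        r = network.coords[j] - network.coords[i]
        d = np.linalg.norm(r)
        block = k * np.outer(r, r) / (d * d)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[sl_i, sl_j] -= block
        h[sl_j, sl_i] -= block
        h[sl_i, sl_i] += block
        h[sl_j, sl_j] += block
    return h


@dataclass
class ModeSet:
    """Eigen-decomposition of a network Hessian.

    ``eigenvalues`` ascending, ``eigenvectors`` as columns (3N each,
    orthonormal).  The first ``n_zero`` eigenvalues are numerically zero
    (rigid-body motions); mode ranks count from the first nonzero mode
    (rank 0 = first nonzero mode).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    zero_tol: float

    @property
    def n_coords(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero

    @property
    def is_stable(self) -> bool:
        return self.n_zero == 6

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]

    @property
    def nonzero_modes(self) -> np.ndarray:
        """Columns are the modes ranked by ascending nonzero eigenvalue."""
        return self.eigenvectors[:, self.n_zero:]

    def mode(self, rank: int) -> np.ndarray:
        """Mode vector at the given rank (0 = first nonzero mode)."""
        return self.eigenvectors[:, self.n_zero + rank]

    def to_nmd(self, path, k: int = 20) -> None:
        """Plain-column text export of the first k nonzero modes."""
        with open(path, "w") as fh:
            for rank in range(min(k, self.n_nonzero)):
                vals = " ".join(f"{x:.6f}" for x in self.mode(rank))
                fh.write(f"mode {rank} {self.nonzero_eigenvalues[rank]:.6g} {vals}\n")


def normal_modes(network_or_hessian, zero_tol: float = DEFAULT_ZERO_TOL) -> ModeSet:
    """Full eigen-decomposition; eigenvalues below zero_tol·max(λ) count as zero."""
    if isinstance(network_or_hessian, ElasticNetwork):
        h = hessian(network_or_hessian)
    else:
        h = np.asarray(network_or_hessian, float)
    if h.shape[0] != h.shape[1] or not np.allclose(h, h.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    try:
        evals, evecs = np.linalg.eigh(h)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("NMA failed") from exc
    tol = zero_tol * max(float(evals[-1]), 1e-12)
    n_zero = int(np.sum(evals < tol))
    return ModeSet(eigenvalues=evals, eigenvectors=evecs, n_zero=n_zero,
                   zero_tol=zero_tol)
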