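"""Cα-level structure handling: PDB reading, chain breaks, pairing, superposition.

All analysis downstream works on a single chain reduced to its Cα trace.
Residues are indexed 0..N-1 internally; author numbering (with insertion
codes) is retained only for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from scipy.spatial.transform import Rotation

log = logging.getLogger(__name__)

#: consecutive-Cα distance above which the chain is considered broken (Å)
CHAIN_BREAK_DISTANCE = 4.2

SSE_LABELS = ("H", "E", "C")


@dataclass
class Structure:
    """One chain's Cα trace.

    coords are an (N, 3) array in Å; ``author_numbers`` keep the file's
    residue numbering (insertion codes appended, e.g. ``"45A"``).
    ``annotations`` holds optional per-residue tables keyed by name
    (conservation, depth, symmetry, ...), each an array of length N.
    """

    chain_id: str
    res_names: list[str]
    author_numbers: list[str]
    coords: np.ndarray
    b_factors: np.ndarray
    sse: list[str] | None = None
    annotations: dict[str, np.ndarray] = field(default_factory=dict)
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.sse is not None:
            if len(self.sse) != len(self):
                raise ValueError("sse length mismatch")
            bad = set(self.sse) - set(SSE_LABELS)
            if bad:
                raise ValueError(f"invalid sse labels: {bad}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self)

    def sequence(self) -> str:
        """1-letter sequence; unknown residue types map to X."""
        return "".join(seq1(n, undef_code="X") for n in self.res_names)

    def subset(self, indices: np.ndarray) -> "Structure":
        """New Structure restricted to the given residue indices (in order)."""
        idx = np.asarray(indices, dtype=int)
        return Structure(
            chain_id=self.chain_id,
            res_names=[self.res_names[i] for i in idx],
            author_numbers=[self.author_numbers[i] for i in idx],
            coords=self.coords[idx],
            b_factors=self.b_factors[idx],
            sse=None if self.sse is None else [self.sse[i] for i in idx],
            annotations={k: np.asarray(v)[idx] for k, v in self.annotations.items()},
            resolution=self.resolution,
        )


@dataclass
class ConformationPair:
    """Start (unbound) and end (bound) conformations of one transition.

    ``correspondence`` lists matched residue index pairs (iS, iE), strictly
    increasing in both coordinates.  ``displacement`` holds the per-matched-
    residue vectors Δr_i = r_i^S − r_i^E (Å) after least-squares superposition
    of the end conformation onto the start.
    """

    start: Structure
    end: Structure
    correspondence: list[tuple[int, int]]
    rmsd: float
    displacement: np.ndarray
    end_superposed: np.ndarray
    resolution_start: float | None = None
    resolution_end: float | None = None

    @property
    def matched_start(self) -> np.ndarray:
        return np.array([i for i, _ in self.correspondence], dtype=int)

    @property
    def matched_end(self) -> np.ndarray:
        return np.array([j for _, j in self.correspondence], dtype=int)

    @property
    def n_matched(self) -> int:
        return len(self.correspondence)

    def displacement_vector(self) -> np.ndarray:
        """Displacement flattened to 3M (M = number of matched residues)."""
        return self.displacement.reshape(-1)


def read_ca_structure(path, chain: str) -> Structure:
    """Read one chain's Cα trace from a PDB file.

    Only ATOM records with a Cα are kept; alternate locations resolve to the
    highest-occupancy conformer (ties by altloc letter).  B-factors come from
    the Cα atom; REMARK 2 resolution is captured when present.
    """
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    if chain not in [c.id for c in model]:
        raise KeyError(f"chain not found: {chain!r}")
    names, numbers, coords, bfac = [], [], [], []
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # HETATM / water
        ca = None
        for atom in res.get_unpacked_list():
            if atom.get_name() == "CA":
                if ca is None:
                    ca = atom
                else:
                    # altloc: highest occupancy wins, ties by altloc letter
                    occ_new = atom.get_occupancy() or 0.0
                    occ_old = ca.get_occupancy() or 0.0
                    if occ_new > occ_old or (
                        occ_new == occ_old and atom.get_altloc() < ca.get_altloc()
                    ):
                        ca = atom
        if ca is None:
            log.debug("residue %s%s lacks a CA atom; dropped", resseq, icode.strip())
            continue
        names.append(res.get_resname())
        numbers.append(f"{resseq}{icode.strip()}")
        coords.append(ca.get_coord())
        bfac.append(ca.get_bfactor() or 0.0)
    if not coords:
        raise ValueError("empty structure: no Cα atoms in chain")
    resolution = _read_resolution(path)
    return Structure(
        chain_id=chain,
        res_names=names,
        author_numbers=numbers,
        coords=np.array(coords, dtype=float),
        b_factors=np.array(bfac, dtype=float),
        resolution=resolution,
    )


def _read_resolution(path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK   2 RESOLUTION"):
                for tok in line.split()[3:]:  # skip "REMARK 2 RESOLUTION."
                    try:
                        return float(tok)
                    except ValueError:
                        continue
    return None


def write_ca_structure(structure: Structure, path) -> None:
    """Write a minimal Cα-only PDB file (fixture dialect, read/write stable)."""
    with open(path, "w") as fh:
        if structure.resolution is not None:
            fh.write(
                f"REMARK   2 RESOLUTION. {structure.resolution:6.2f} ANGSTROMS.\n"
            )
        for i in range(len(structure)):
            num = structure.author_numbers[i]
            icode = " "
            if num and num[-1].isalpha():
                icode = num[-1]
                num = num[:-1]
            x, y, z = structure.coords[i]
            fh.write(
                f"ATOM  {i + 1:5d}  CA  {structure.res_names[i]:<3s} "
                f"{structure.chain_id}{int(num):4d}{icode}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{structure.b_factors[i]:6.2f}"
                f"           C  \n"
            )
        fh.write("END\n")


def detect_chain_breaks(
    structure: Structure, threshold: float = CHAIN_BREAK_DISTANCE
) -> list[int]:
    """Indices i where the i→i+1 Cα distance strictly exceeds ``threshold`` Å."""
    if len(structure) < 2:
        raise ValueError("need at least two residues")
    d = np.linalg.norm(np.diff(structure.coords, axis=0), axis=1)
    return [int(i) for i in np.nonzero(d > threshold)[0]]


def _align_sequences(sa: str, sb: str) -> list[tuple[int, int]]:
    """Global alignment with identity scoring (match +1, mismatch −1, gap −2)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    aln = aligner.align(sa, sb)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates and the RMSD (Å).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    moved = rot.apply(mobile - cm) + ct
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return moved, rmsd


def build_pair(start: Structure, end: Structure) -> ConformationPair:
    """Pair two conformations: align sequences, superpose, store Δr_i.

    The residue correspondence comes from a global sequence alignment; the
    end conformation is rigid-body superposed onto the start over all matched
    Cα pairs and the displacement field Δr_i = r_i^S − r_i^E is stored for
    matched residues only.
    """
    if len(start) == 0 or len(end) == 0:
        raise ValueError("empty structure")
    pairs = _align_sequences(start.sequence(), end.sequence())
    if len(pairs) < 2:
        raise ValueError("no correspondence between conformations")
    i_s = np.array([p[0] for p in pairs])
    i_e = np.array([p[1] for p in pairs])
    cm = end.coords[i_e].mean(axis=0)
    ct = start.coords[i_s].mean(axis=0)
    rot, _ = Rotation.align_vectors(start.coords[i_s] - ct, end.coords[i_e] - cm)
    end_full = rot.apply(end.coords - cm) + ct
    moved = end_full[i_e]
    rmsd = float(np.sqrt(np.mean(np.sum((moved - start.coords[i_s]) ** 2, axis=1))))
    displacement = start.coords[i_s] - moved
    return ConformationPair(
        start=start,
        end=end,
        correspondence=pairs,
        rmsd=rmsd,
        displacement=displacement,
        end_superposed=end_full,
        resolution_start=start.resolution,
        resolution_end=end.resolution,
    )


# --- secondary structure -----------------------------------------------------

# Cα-geometry windows for the fallback assignment.  An ideal α-helix has
# d(i,i+3) ≈ 5.1 Å and d(i,i+4) ≈ 6.2 Å; extended strands have d(i,i+2) ≈ 6.7 Å
# or more and large i→i+4 spans.
_HELIX_D13 = (4.5, 6.0)
_HELIX_D14 = (4.8, 7.2)
_STRAND_D12 = 6.4
MIN_SSE_LENGTH = 3


def _geometric_sse(coords: np.ndarray) -> list[str]:
    n = len(coords)
    labels = np.array(["C"] * n, dtype=object)
    d = lambda i, j: float(np.linalg.norm(coords[j] - coords[i]))
    for i in range(n - 4):
        d13, d14 = d(i, i + 3), d(i, i + 4)
        if _HELIX_D13[0] <= d13 <= _HELIX_D13[1] and _HELIX_D14[0] <= d14 <= _HELIX_D14[1]:
            labels[i : i + 5] = "H"
    for i in range(n - 2):
        if labels[i] == "C" and labels[i + 2] == "C" and d(i, i + 2) >= _STRAND_D12:
            # near-fully-extended local geometry
            if np.all(labels[i : i + 3] == "C"):
                labels[i : i + 3] = "E"
    return enforce_min_sse_length(list(labels))


def enforce_min_sse_length(labels: list[str], min_len: int = MIN_SSE_LENGTH) -> list[str]:
    """Relabel H/E runs shorter than ``min_len`` to coil."""
    out = list(labels)
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if out[i] in ("H", "E") and j - i < min_len:
            for k in range(i, j):
                out[k] = "C"
        i = j
    return out


def assign_sse(structure: Structure, backend=None) -> Structure:
    """Fill per-residue secondary-structure labels {H, E, C}.

    ``backend`` may be a callable mapping the structure to a label list
    (e.g. parsed DSSP output collapsed to three states); on any backend
    failure the internal Cα-geometry fallback is used with a warning.
    """
    labels = None
    if backend is not None:
        try:
            labels = list(backend(structure))
            if len(labels) != len(structure) or set(labels) - set(SSE_LABELS):
                raise ValueError("backend returned invalid labels")
        except Exception as exc:  # fall back, never abort
            warnings.warn(f"SSE backend failed ({exc}); using geometric fallback")
            labels = None
    if labels is None:
        labels = _geometric_sse(structure.coords)
    labels = enforce_min_sse_length(labels)
    return replace(structure, sse=labels)
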