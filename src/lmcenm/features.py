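"""Per-contact feature extraction for breaking-contact prediction.

Every scored contact (i, j) is described by a 170-entry numeric vector in
seven fixed blocks:

    pairwise (63) · graph topology (10) · graph spectrum (5) ·
    single node (12) · node label statistics (57) ·
    edge label statistics (13) · whole protein (10)

The topology/spectrum blocks describe the contact's *immediate neighborhood
graph* — residues i, j, their sequence neighbors i±1/j±1 (plus i±4/j±4 when
the residue is helical, one helix turn away), and every residue in contact
with i or j, with contacts among that node set as edges.  Pairwise features
describe the contact itself and the secondary-structure elements (SSEs) it
joins.  Label statistics summarize residue attributes over the neighborhood.

Features whose source data is not derivable from a Cα trace (conservation,
mutual information, pockets, residue depth, half-sphere exposure, symmetry,
hydrogen bonds, side-chain contacts) are fed by optional annotation plugins;
an availability mask records which entries are real.  Masked entries are set
to the neutral value 0 after standardization.  Solvent accessibility uses a
Cα neighbor-count burial surrogate unless an annotation supplies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from lmcenm.contacts import ContactMap
from lmcenm.structure import Structure

BLOCK_SIZES = {
    "pairwise": 63,
    "graph_topology": 10,
    "graph_spectrum": 5,
    "single_node": 12,
    "node_label_stats": 57,
    "edge_label_stats": 13,
    "whole_protein": 10,
}
N_FEATURES = 170

# chemical classes of the 20 standard residue types
CHEM_CLASSES = ("aliphatic", "aromatic", "polar", "positive", "negative",
                "cysteine", "glycine", "proline")
_CHEM_OF = {
    "ALA": "aliphatic", "VAL": "aliphatic", "LEU": "aliphatic",
    "ILE": "aliphatic", "MET": "aliphatic",
    "PHE": "aromatic", "TRP": "aromatic", "TYR": "aromatic",
    "SER": "polar", "THR": "polar", "ASN": "polar", "GLN": "polar",
    "LYS": "positive", "ARG": "positive", "HIS": "positive",
    "ASP": "negative", "GLU": "negative",
    "CYS": "cysteine", "GLY": "glycine", "PRO": "proline",
}
AA20 = sorted(_CHEM_OF)

# consensus hydrophobicity scale used as per-residue solvation-energy proxy
_HYDROPHOBICITY = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}

#: optional per-residue annotation keys (arrays of length N on Structure)
RESIDUE_ANNOTATIONS = ("conservation", "depth", "symmetry", "accessibility",
                      "hse_up", "hse_down")
#: optional per-pair annotation keys (dict[(i, j)] -> value)
PAIR_ANNOTATIONS = ("hbond", "mutual_information", "sidechain_contact")


# --- neighborhood graph ------------------------------------------------------

def neighborhood_graph(contact, cmap: ContactMap, structure: Structure) -> nx.Graph:
    """Immediate neighborhood graph of a contact.

    Nodes: i, j, their sequence neighbors i±1/j±1, every residue in contact
    with i or j, and i±4/j±4 when the residue is helical (the closest
    residues one helix turn away).  Edges: contacts among the node set.
    Indices falling outside the chain are simply omitted.
    """
    i, j = contact
    if not cmap.contacts[i, j]:
        raise ValueError(f"({i}, {j}) is not a contact")
    n = cmap.n_residues
    nodes = {i, j}
    for center in (i, j):
        nodes.update({center - 1, center + 1})
        nodes.update(np.nonzero(cmap.contacts[center])[0].tolist())
        if structure.sse is not None and structure.sse[center] == "H":
            nodes.update({center - 4, center + 4})
    nodes = sorted(k for k in nodes if 0 <= k < n)
    g = nx.Graph(contact=(i, j))
    g.add_nodes_from(nodes)
    for a_idx, a in enumerate(nodes):
        for b in nodes[a_idx + 1:]:
            if cmap.contacts[a, b]:
                g.add_edge(a, b)
    return g


# --- SSE graph ---------------------------------------------------------------

@dataclass
class SSEGraph:
    """Secondary-structure-element segmentation and contact graph.

    ``segments`` are maximal runs (type, start, end-inclusive) partitioning
    the chain; H/E runs shorter than three residues are relabeled coil.
    ``graph`` joins two segments when they share at least one residue
    contact; edge attribute ``contacts`` counts shared residue contacts.
    """

    segments: list[tuple[str, int, int]]
    segment_of: np.ndarray
    graph: nx.Graph

    def is_intra(self, i: int, j: int) -> bool:
        return self.segment_of[i] == self.segment_of[j]


def sse_graph(structure: Structure, cmap: ContactMap) -> SSEGraph:
    if structure.sse is None:
        raise ValueError("structure has no SSE labels; run assign_sse first")
    labels = list(structure.sse)
    # short H/E runs become coil, then merge adjacent equal runs
    from lmcenm.structure import enforce_min_sse_length

    labels = enforce_min_sse_length(labels)
    segments = []
    seg_of = np.zeros(len(labels), dtype=int)
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        seg_of[i:j] = len(segments)
        segments.append((labels[i], i, j - 1))
        i = j
    g = nx.Graph()
    g.add_nodes_from(range(len(segments)))
    ii, jj = np.nonzero(np.triu(cmap.contacts, k=1))
    for a, b in zip(ii, jj):
        sa, sb = int(seg_of[a]), int(seg_of[b])
        if sa == sb:
            continue
        if g.has_edge(sa, sb):
            g[sa][sb]["contacts"] += 1
        else:
            g.add_edge(sa, sb, contacts=1)
    return SSEGraph(segments=segments, segment_of=seg_of, graph=g)


# --- graph descriptor blocks -------------------------------------------------

def graph_features(g: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Topology (10) and adjacency-spectrum (5) descriptors of the
    unlabeled neighborhood graph.

    Radius, diameter and eccentricity are taken on the connected component
    containing the focal contact when the graph is disconnected.
    """
    n = g.number_of_nodes()
    degrees = dict(g.degree())
    closeness = nx.closeness_centrality(g)
    betweenness = nx.betweenness_centrality(g)
    focus = g.graph.get("contact", (next(iter(g.nodes)),))[0]
    comp = g.subgraph(nx.node_connected_component(g, focus))
    ecc = nx.eccentricity(comp)
    topology = np.array([
        n,
        g.number_of_edges(),
        float(np.mean([d / max(n - 1, 1) for d in degrees.values()])),
        float(np.mean(list(closeness.values()))),
        float(np.mean(list(betweenness.values()))),
        nx.radius(comp, e=ecc),
        nx.diameter(comp, e=ecc),
        float(np.mean(list(ecc.values()))),
        sum(1 for d in degrees.values() if d == 1),
        float(nx.average_clustering(g)) if n > 0 else 0.0,
    ])
    adj = nx.to_numpy_array(g)
    evals = np.sort(np.linalg.eigvalsh(adj))[::-1]
    spectrum = np.array([
        evals[0] if len(evals) else 0.0,
        evals[1] if len(evals) > 1 else 0.0,
        len(np.unique(np.round(evals, 6))),
        float(evals.sum()),
        float(np.abs(evals).sum()),  # graph energy
    ])
    return topology, spectrum


# --- feature vector ----------------------------------------------------------

@dataclass
class FeatureVector:
    values: np.ndarray
    available: np.ndarray
    names: list[str]

    def __len__(self) -> int:
        return len(self.values)


def _segment_centroid(structure, seg):
    _, a, b = seg
    return structure.coords[a : b + 1].mean(axis=0)


def _segment_axis(structure, seg):
    _, a, b = seg
    pts = structure.coords[a : b + 1]
    if len(pts) < 2:
        return None
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _entropy(fractions) -> float:
    f = np.asarray(fractions, float)
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())


def _one_hot(value, categories):
    return [1.0 if value == c else 0.0 for c in categories]


def _bin_fractions(values, edges):
    """Fractions of values per bin; ``edges`` are the inner bin boundaries."""
    values = np.asarray(values, float)
    if len(values) == 0:
        return [0.0] * (len(edges) + 1)
    idx = np.searchsorted(edges, values, side="right")
    return [float(np.mean(idx == b)) for b in range(len(edges) + 1)]


_SSE_PAIR_CLASSES = ("HH", "HE", "HC", "EE", "EC", "CC")
_SEQ_SEP_EDGES = (8, 16, 32)  # 4-bin classes: [4,8) [8,16) [16,32) [32,∞)
_DEPTH_EDGES = (2.0, 4.0, 6.0)  # Å, 4-bin contact-depth classes
_MI_EDGES = (0.2, 0.4, 0.6, 0.8)  # 5-bin mutual-information histogram
_SOLV_EDGES = (-1.0, 0.0, 0.5)  # 4-bin hydrophobicity histogram
_CONNECTIVITY_EDGES = (6.0, 8.0, 10.0, 12.0)  # mean contacts per residue


def feature_names() -> list[str]:
    """The 170 column names in block order."""
    names = []
    # pairwise (63)
    names += ["seq_separation", "contact_distance"]
    names += [f"sse_i_{s}" for s in "HEC"] + [f"sse_j_{s}" for s in "HEC"]
    names += [f"sse_pair_{c}" for c in _SSE_PAIR_CLASSES]
    names += [
        "intra_sse", "sse_seq_separation", "sse_centroid_distance",
        "sse_len_i", "sse_len_j", "rel_pos_in_sse_i", "rel_pos_in_sse_j",
        "terminal_sse_i", "terminal_sse_j",
        "inter_sse_contact_count", "inter_sse_contact_fraction",
        "inter_sse_min_distance", "intra_sse_contacts_i",
        "intra_sse_contacts_j", "sse_axis_angle",
        "degree_i", "degree_j", "common_neighbors", "neighbor_jaccard",
    ]
    names += [f"seq_sep_class_{k}" for k in range(4)]
    names += ["min_terminus_separation", "midpoint_centroid_distance",
              "bfactor_mean_ij"]
    names += [
        "hbond", "sidechain_contact",
        "pocket_contact", "pocket_atom_contacts", "pocket_polarity",
        "pocket_hydrophobicity", "pocket_volume", "pocket_drug_score",
        "symmetric_i", "symmetric_j", "both_symmetric",
        "symmetry_plane_distance", "sse_symmetry_coverage_i",
        "sse_symmetry_coverage_j",
    ]
    names += [f"contact_depth_class_{k}" for k in range(4)]
    names += [f"depth_difference_class_{k}" for k in range(4)]
    names += ["mutual_information"]
    # graph topology (10)
    names += ["in_n_nodes", "in_n_edges", "in_avg_degree_centrality",
              "in_avg_closeness", "in_avg_betweenness", "in_radius",
              "in_diameter", "in_avg_eccentricity", "in_n_endpoints",
              "in_avg_clustering"]
    # graph spectrum (5)
    names += ["in_eig_1", "in_eig_2", "in_n_distinct_eigs", "in_eig_sum",
              "in_graph_energy"]
    # single node (12)
    for r in ("i", "j"):
        names += [f"node_degree_{r}", f"node_closeness_{r}",
                  f"node_betweenness_{r}", f"node_terminus_separation_{r}",
                  f"node_conservation_{r}", f"node_nbhd_conservation_{r}"]
    # node label statistics (57)
    names += [f"nl_aa_{aa}" for aa in AA20]
    names += [f"nl_chem_{c}" for c in CHEM_CLASSES]
    names += [f"nl_sse_{s}" for s in "HEC"]
    names += ["nl_chem_entropy", "nl_sse_entropy", "nl_impurity",
              "nl_centroid_distance",
              "nl_access_mean", "nl_access_std", "nl_buried_frac",
              "nl_exposed_frac", "nl_hbond_mean", "nl_solvation_mean"]
    names += [f"nl_solvation_bin_{k}" for k in range(4)]
    names += ["nl_depth_mean"] + [f"nl_depth_bin_{k}" for k in range(5)]
    names += ["nl_hse_up_mean", "nl_hse_down_mean",
              "nl_symmetry_coverage", "nl_symmetry_degree",
              "nl_conservation_mean", "nl_nbhd_conservation_mean"]
    # edge label statistics (13)
    names += ["el_link_impurity", "el_hbond_fraction"]
    names += [f"el_mi_bin_{k}" for k in range(5)]
    names += ["el_mi_cumulative", "el_mi_mean", "el_mi_max", "el_mi_min",
              "el_mi_std", "el_mi_median"]
    # whole protein (10)
    names += ["wp_frac_H", "wp_frac_E", "wp_frac_C"]
    names += [f"wp_connectivity_class_{k}" for k in range(5)]
    names += ["wp_symmetry_coverage", "wp_log_length"]
    assert len(names) == N_FEATURES
    return names


FEATURE_NAMES = feature_names()
_offsets = np.cumsum([0] + list(BLOCK_SIZES.values()))
BLOCK_OFFSETS = dict(zip(BLOCK_SIZES, zip(_offsets[:-1], _offsets[1:])))


def _pair_annotation(annotations, key, i, j):
    table = (annotations or {}).get(key)
    if table is None:
        return None
    return table.get((min(i, j), max(i, j)))


def feature_vector(
    contact,
    structure: Structure,
    cmap: ContactMap,
    sgraph: SSEGraph,
    pair_annotations: dict | None = None,
) -> FeatureVector:
    """170-entry description of one contact with availability mask.

    Per-residue annotations ride on ``structure.annotations``; per-pair
    tables (hydrogen bonds, mutual information, side-chain contacts) come in
    through ``pair_annotations`` as ``{key: {(i, j): value}}``.
    """
    i, j = contact
    if i > j:
        i, j = j, i
    n = len(structure)
    ann = structure.annotations
    values = np.zeros(N_FEATURES)
    avail = np.ones(N_FEATURES, dtype=bool)
    pos = 0

    def put(block_vals, block_avail=True):
        nonlocal pos
        block_vals = np.atleast_1d(np.asarray(block_vals, float))
        values[pos : pos + len(block_vals)] = np.nan_to_num(block_vals)
        if block_avail is not True:
            avail[pos : pos + len(block_vals)] = block_avail
        pos += len(block_vals)

    # ---- pairwise ----
    seg_i = sgraph.segments[sgraph.segment_of[i]]
    seg_j = sgraph.segments[sgraph.segment_of[j]]
    put([abs(j - i), cmap.distances[i, j]])
    put(_one_hot(structure.sse[i], "HEC"))
    put(_one_hot(structure.sse[j], "HEC"))
    pair_class = "".join(sorted(structure.sse[i] + structure.sse[j]))
    put(_one_hot(pair_class, _SSE_PAIR_CLASSES))
    intra = sgraph.is_intra(i, j)
    sse_sep = abs(int(sgraph.segment_of[j]) - int(sgraph.segment_of[i]))
    cent_i, cent_j = _segment_centroid(structure, seg_i), _segment_centroid(structure, seg_j)
    len_i = seg_i[2] - seg_i[1] + 1
    len_j = seg_j[2] - seg_j[1] + 1
    res_i = structure.coords[seg_i[1] : seg_i[2] + 1]
    res_j = structure.coords[seg_j[1] : seg_j[2] + 1]
    if intra:
        inter_count, inter_min = 0.0, 0.0
    else:
        block = cmap.contacts[seg_i[1] : seg_i[2] + 1, seg_j[1] : seg_j[2] + 1]
        inter_count = float(block.sum())
        inter_min = float(
            np.min(np.linalg.norm(res_i[:, None] - res_j[None], axis=2))
        )
    intra_i = float(np.triu(
        cmap.contacts[seg_i[1] : seg_i[2] + 1, seg_i[1] : seg_i[2] + 1], k=1).sum())
    intra_j = float(np.triu(
        cmap.contacts[seg_j[1] : seg_j[2] + 1, seg_j[1] : seg_j[2] + 1], k=1).sum())
    ax_i, ax_j = _segment_axis(structure, seg_i), _segment_axis(structure, seg_j)
    if ax_i is None or ax_j is None:
        angle = 0.0
    else:
        angle = math.degrees(math.acos(min(1.0, abs(float(ax_i @ ax_j)))))
    nb_i = set(np.nonzero(cmap.contacts[i])[0].tolist())
    nb_j = set(np.nonzero(cmap.contacts[j])[0].tolist())
    union = nb_i | nb_j
    put([
        float(intra), sse_sep, float(np.linalg.norm(cent_j - cent_i)),
        len_i, len_j,
        (i - seg_i[1]) / max(len_i - 1, 1), (j - seg_j[1]) / max(len_j - 1, 1),
        float(sgraph.segment_of[i] in (0, len(sgraph.segments) - 1)),
        float(sgraph.segment_of[j] in (0, len(sgraph.segments) - 1)),
        inter_count,
        inter_count / max(len_i * len_j, 1),
        inter_min, intra_i, intra_j, angle,
        len(nb_i), len(nb_j), len(nb_i & nb_j),
        len(nb_i & nb_j) / len(union) if union else 0.0,
    ])
    sep_bin = int(np.searchsorted(_SEQ_SEP_EDGES, abs(j - i), side="right"))
    put(_one_hot(sep_bin, range(4)))
    centroid = structure.coords.mean(axis=0)
    midpoint = 0.5 * (structure.coords[i] + structure.coords[j])
    put([
        min(i, j, n - 1 - i, n - 1 - j),
        float(np.linalg.norm(midpoint - centroid)),
        0.5 * (structure.b_factors[i] + structure.b_factors[j]),
    ])
    hb = _pair_annotation(pair_annotations, "hbond", i, j)
    put([0.0 if hb is None else float(hb)], hb is not None)
    sc = _pair_annotation(pair_annotations, "sidechain_contact", i, j)
    put([0.0 if sc is None else float(sc)], sc is not None)
    # pocket descriptors require an external pocket finder; always masked here
    put(np.zeros(6), False)
    if "symmetry" in ann:
        sym = np.asarray(ann["symmetry"], float)
        si, sj = sym[i] > 0, sym[j] > 0
        cov_i = float(np.mean(sym[seg_i[1] : seg_i[2] + 1] > 0))
        cov_j = float(np.mean(sym[seg_j[1] : seg_j[2] + 1] > 0))
        put([float(si), float(sj), float(si and sj), 0.0, cov_i, cov_j],
            np.array([True, True, True, False, True, True]))
    else:
        put(np.zeros(6), False)
    if "depth" in ann:
        depth = np.asarray(ann["depth"], float)
        mean_depth = 0.5 * (depth[i] + depth[j])
        put(_one_hot(int(np.searchsorted(_DEPTH_EDGES, mean_depth)), range(4)))
        diff = abs(depth[i] - depth[j])
        put(_one_hot(int(np.searchsorted(_DEPTH_EDGES, diff)), range(4)))
    else:
        put(np.zeros(8), False)
    mi = _pair_annotation(pair_annotations, "mutual_information", i, j)
    put([0.0 if mi is None else float(mi)], mi is not None)

    # ---- neighborhood graph blocks ----
    g = neighborhood_graph((i, j), cmap, structure)
    topology, spectrum = graph_features(g)
    put(topology)
    put(spectrum)

    # ---- single node ----
    closeness = nx.closeness_centrality(g)
    betweenness = nx.betweenness_centrality(g)
    cons = np.asarray(ann["conservation"], float) if "conservation" in ann else None
    for r in (i, j):
        put([g.degree(r), closeness[r], betweenness[r], min(r, n - 1 - r)])
        if cons is not None:
            window = cons[max(r - 2, 0) : r + 3]
            put([cons[r], float(window.mean())])
        else:
            put(np.zeros(2), False)

    # ---- node label statistics ----
    nodes = sorted(g.nodes)
    node_names = [structure.res_names[k] for k in nodes]
    aa_frac = [float(np.mean([nm == aa for nm in node_names])) for aa in AA20]
    chem = [_CHEM_OF.get(nm) for nm in node_names]
    chem_frac = [float(np.mean([c == cc for c in chem])) for cc in CHEM_CLASSES]
    sse_frac = [float(np.mean([structure.sse[k] == s for k in nodes])) for s in "HEC"]
    put(aa_frac)
    put(chem_frac)
    put(sse_frac)
    impurity = []
    chem_of_node = dict(zip(nodes, chem))
    for k in nodes:
        nbrs = list(g.neighbors(k))
        if nbrs:
            impurity.append(
                float(np.mean([chem_of_node[b] != chem_of_node[k] for b in nbrs]))
            )
    cent_dist = [float(np.linalg.norm(structure.coords[k] - centroid)) for k in nodes]
    put([_entropy(chem_frac), _entropy(sse_frac),
         float(np.mean(impurity)) if impurity else 0.0,
         float(np.mean(cent_dist))])
    if "accessibility" in ann:
        acc = np.asarray(ann["accessibility"], float)[nodes]
    else:
        # burial surrogate: residues with many Cα neighbors are buried
        counts = cmap.contacts[nodes].sum(axis=1)
        acc = 1.0 - counts / max(float(cmap.contacts.sum(axis=1).max()), 1.0)
    put([float(acc.mean()), float(acc.std()),
         float(np.mean(acc < 0.3)), float(np.mean(acc > 0.7))])
    hb_table = (pair_annotations or {}).get("hbond")
    if hb_table is not None:
        per_node = [
            sum(v for (a, b), v in hb_table.items() if a == k or b == k)
            for k in nodes
        ]
        put([float(np.mean(per_node))])
    else:
        put([0.0], False)
    solv = [_HYDROPHOBICITY.get(nm, 0.0) for nm in node_names]
    put([float(np.mean(solv))])
    put(_bin_fractions(solv, _SOLV_EDGES))
    if "depth" in ann:
        dvals = np.asarray(ann["depth"], float)[nodes]
        put([float(dvals.mean())])
        put(_bin_fractions(dvals, (1.5, 3.0, 4.5, 6.0)))
    else:
        put(np.zeros(6), False)
    for key in ("hse_up", "hse_down"):
        if key in ann:
            put([float(np.asarray(ann[key], float)[nodes].mean())])
        else:
            put([0.0], False)
    if "symmetry" in ann:
        sym = np.asarray(ann["symmetry"], float)[nodes]
        put([float(np.mean(sym > 0)), float(sym.mean())])
    else:
        put(np.zeros(2), False)
    if cons is not None:
        nbhd = [
            float(cons[max(k - 2, 0) : k + 3].mean()) for k in nodes
        ]
        put([float(cons[nodes].mean()), float(np.mean(nbhd))])
    else:
        put(np.zeros(2), False)

    # ---- edge label statistics ----
    edges = list(g.edges)
    if edges:
        link_imp = float(np.mean(
            [chem_of_node[a] != chem_of_node[b] for a, b in edges]))
    else:
        link_imp = 0.0
    put([link_imp])
    if hb_table is not None:
        flags = [
            float(bool(hb_table.get((min(a, b), max(a, b)), 0))) for a, b in edges
        ]
        put([float(np.mean(flags)) if flags else 0.0])
    else:
        put([0.0], False)
    mi_table = (pair_annotations or {}).get("mutual_information")
    if mi_table is not None and edges:
        mi_vals = np.array([
            float(mi_table.get((min(a, b), max(a, b)), 0.0)) for a, b in edges
        ])
        put(_bin_fractions(mi_vals, _MI_EDGES))
        put([float(mi_vals.sum()), float(mi_vals.mean()), float(mi_vals.max()),
             float(mi_vals.min()), float(mi_vals.std()),
             float(np.median(mi_vals))])
    else:
        put(np.zeros(11), False)

    # ---- whole protein ----
    put([float(np.mean([s == c for s in structure.sse])) for c in "HEC"])
    mean_deg = float(cmap.contacts.sum()) / n
    put(_one_hot(int(np.searchsorted(_CONNECTIVITY_EDGES, mean_deg)), range(5)))
    if "symmetry" in ann:
        put([float(np.mean(np.asarray(ann["symmetry"], float) > 0))])
    else:
        put([0.0], False)
    put([math.log(n)])

    assert pos == N_FEATURES
    return FeatureVector(values=values, available=avail, names=FEATURE_NAMES)


def feature_matrix(
    structure: Structure,
    cmap: ContactMap,
    min_sep: int = 4,
    pair_annotations: dict | None = None,
    sgraph: SSEGraph | None = None,
):
    """Feature vectors for every contact with |i−j| ≥ min_sep.

    Returns (pairs, values (n×170), availability (n×170)).
    """
    if sgraph is None:
        sgraph = sse_graph(structure, cmap)
    pairs = cmap.pairs(min_sep=min_sep)
    vals = np.zeros((len(pairs), N_FEATURES))
    avail = np.zeros((len(pairs), N_FEATURES), dtype=bool)
    for row, pair in enumerate(pairs):
        fv = feature_vector(pair, structure, cmap, sgraph, pair_annotations)
        vals[row] = fv.values
        avail[row] = fv.available
    return pairs, vals, avail


def to_frame(pairs, values) -> pd.DataFrame:
    """Dense TSV-ready table with one named column per feature."""
    df = pd.DataFrame(values, columns=FEATURE_NAMES)
    df.insert(0, "j", [p[1] for p in pairs])
    df.insert(0, "i", [p[0] for p in pairs])
    return df


def read_residue_annotation(path) -> np.ndarray:
    """Per-residue TSV (index, value) → dense array."""
    df = pd.read_csv(path, sep="\t", header=None, names=["index", "value"])
    out = np.zeros(int(df["index"].max()) + 1)
    out[df["index"].to_numpy(int)] = df["value"].to_numpy(float)
    return out


def read_pair_annotation(path) -> dict:
    """Per-pair TSV (i, j, value) → {(i, j): value} with i < j."""
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "value"])
    return {
        (min(int(r.i), int(r.j)), max(int(r.i), int(r.j))): float(r.value)
        for r in df.itertuples()
    }
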