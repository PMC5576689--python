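"""Orchestration: curation filters, variant evaluation, prediction, scans.

``analyze_pair`` builds each configured network variant on the *start*
(unbound) conformation restricted to matched residues — normal modes of the
more open conformation capture more of a transition than the compact bound
form — and evaluates the full metric suite against the observed displacement
field.  ``predict_and_build`` composes classifier ranking, removal selection
and network surgery into the learned-maintained-contacts network (lmcENM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from lmcenm import classifier as clf
from lmcenm import features as feat
from lmcenm import metrics
from lmcenm.contacts import build_contact_map, classify_transitions
from lmcenm.enm import (
    EdENM, HCA, OFC, UniformCutoff, build_network, modify_network, normal_modes,
)
from lmcenm.structure import ConformationPair, Structure, assign_sse, detect_chain_breaks

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "cutoff": 10.0,            # Å, contact / spring cutoff r_c
    "strain_threshold": 0.09,  # e_c, breaking-contact strain bound
    "min_degree": 4,           # stabilization degree criterion
    "min_sep": 4,              # sequence separation for scored/removed contacts
    "zero_tol": 1e-8,
    "gamma": 1.0,
    "selection_strategy": "relative",
    "selection_param": 0.16,
    "svm_cost": 100.0,
    "svm_gamma": 1e-5,
    "undersample_ratio": 3.0,
    "rmsd_min": 1.0,           # curation (a)
    "alignment_min": 70,       # curation (b)
    "resolution_max": 2.5,     # curation (c)
    "bound_peptide": False,    # curation (e), advisory flag
    "extended_or_disordered": False,  # curation (f), advisory flag
    "variants": ["ENM", "HCA", "edENM", "OFC", "mcENM"],
}


def load_config(path=None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            config.update(yaml.safe_load(fh) or {})
    return config


@dataclass
class CurationResult:
    """Per-filter verdicts; (e)/(f) are advisory flags supplied by the
    configuration because a Cα-only model cannot see ligand atoms or judge
    overall shape."""

    verdicts: dict[str, bool]
    details: dict[str, object] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.verdicts.values())


def curate_pair(pair: ConformationPair, config: dict | None = None) -> CurationResult:
    """Apply the data-set filters to one conformation pair.

    (a) significant motion (RMSD > 1 Å), (b) alignment length ≥ 70 matched
    positions, (c) resolution ≤ 2.5 Å where known, (d) no chain breaks,
    (e) no bound peptide, (f) not largely extended/disordered.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    verdicts, details = {}, {}
    verdicts["a_significant_motion"] = pair.rmsd > config["rmsd_min"]
    details["rmsd"] = pair.rmsd
    verdicts["b_alignment_length"] = pair.n_matched >= config["alignment_min"]
    details["alignment_length"] = pair.n_matched
    res = [r for r in (pair.resolution_start, pair.resolution_end) if r is not None]
    verdicts["c_resolution"] = all(r <= config["resolution_max"] for r in res)
    details["resolutions"] = res
    breaks = detect_chain_breaks(pair.start) + detect_chain_breaks(pair.end)
    verdicts["d_no_chain_break"] = not breaks
    details["chain_breaks"] = breaks
    verdicts["e_no_bound_peptide"] = not config["bound_peptide"]
    verdicts["f_not_extended_disordered"] = not config["extended_or_disordered"]
    return CurationResult(verdicts=verdicts, details=details)


def _matched_start(pair: ConformationPair) -> Structure:
    sub = pair.start.subset(pair.matched_start)
    if sub.sse is None:
        sub = assign_sse(sub)
    return sub


def _variant_network(name: str, structure: Structure, tmap, config: dict):
    cutoff = config["cutoff"]
    gamma = config["gamma"]
    min_sep = config["min_sep"]
    if name == "ENM":
        return build_network(structure, UniformCutoff(gamma=gamma, cutoff=cutoff))
    if name == "HCA":
        return build_network(structure, HCA())
    if name == "edENM":
        return build_network(structure, EdENM())
    if name == "OFC":
        return build_network(structure, OFC(gamma=gamma, cutoff=cutoff))
    base = build_network(structure, UniformCutoff(gamma=gamma, cutoff=cutoff))
    if name == "mcENM":
        return modify_network(base, remove=tmap.breaking_pairs(min_sep),
                              min_sep=min_sep)
    if name == "mfcENM":
        return modify_network(base, remove=tmap.breaking_pairs(min_sep),
                              add=tmap.forming_pairs(min_sep), min_sep=min_sep)
    raise ValueError(f"unknown variant: {name!r}")


def evaluate_network(network, displacement, b_factors=None, k: int = 10) -> dict:
    """Full metric bundle of one network against one displacement field."""
    modes = normal_modes(network)
    k_eff = min(k, modes.n_nonzero)
    disp = np.asarray(displacement, float).reshape(-1)
    record = {
        "n_zero_modes": modes.n_zero,
        "co10": metrics.cumulative_overlap(modes, disp, k_eff),
        "cfv10": metrics.variance_fractions(modes, k_eff)[1],
    }
    best = metrics.best_mode(modes, disp)
    record.update({
        "max_overlap": best.max_overlap,
        "best_rank": best.rank,
        "best_collectivity": best.collectivity,
        "best_variance_fraction": best.variance_fraction,
    })
    reach = metrics.modes_to_reach(modes, disp)
    record.update({
        "modes_to_70": reach[0.7], "modes_to_80": reach[0.8],
        "modes_to_90": reach[0.9],
    })
    profile = metrics.fluctuation_profile(modes, k_eff)
    disp_mag = np.linalg.norm(disp.reshape(-1, 3), axis=1) ** 2
    try:
        record["fluctuation_correlation"] = metrics.correlate(profile, disp_mag)
    except ValueError:
        record["fluctuation_correlation"] = math.nan
    if b_factors is not None and np.std(b_factors) > 0:
        record["bfactor_correlation"] = metrics.correlate(profile, b_factors)
    else:
        record["bfactor_correlation"] = math.nan
    return record


def analyze_pair(pair: ConformationPair, config: dict | None = None,
                 variants=None, model=None) -> pd.DataFrame:
    """Evaluation report: one metric row per configured network variant.

    Networks are built on the start conformation's matched residues; the
    lmcENM row requires a trained classifier ``model``.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    variants = list(variants or config["variants"])
    structure = _matched_start(pair)
    cmap = build_contact_map(structure, config["cutoff"])
    # transitions re-indexed to the matched subset
    sub_pair = _subset_pair(pair)
    tmap = classify_transitions(sub_pair, config["cutoff"],
                                config["strain_threshold"])
    disp = pair.displacement_vector()
    rows = []
    for name in variants:
        if name == "lmcENM":
            if model is None:
                log.warning("lmcENM requested without a model; skipped")
                continue
            network, _ = predict_and_build(structure, model, config)
        else:
            network = _variant_network(name, structure, tmap, config)
        record = evaluate_network(network, disp, b_factors=structure.b_factors)
        record["variant"] = name
        record["n_edges"] = network.n_edges
        rows.append(record)
    df = pd.DataFrame(rows)
    return df.set_index("variant")


def _subset_pair(pair: ConformationPair) -> ConformationPair:
    """Re-index a pair so matched residues are 0..M−1 in both conformations."""
    start = pair.start.subset(pair.matched_start)
    end_coords = pair.end_superposed[pair.matched_end]
    m = len(start)
    return ConformationPair(
        start=start,
        end=None,
        correspondence=[(k, k) for k in range(m)],
        rmsd=pair.rmsd,
        displacement=pair.displacement,
        end_superposed=end_coords,
        resolution_start=pair.resolution_start,
        resolution_end=pair.resolution_end,
    )


def predict_and_build(structure: Structure, model, config: dict | None = None,
                      pair_annotations=None):
    """Rank contacts, select removals, carve the network: the lmcENM recipe."""
    config = {**DEFAULT_CONFIG, **(config or {})}
    if structure.sse is None:
        structure = assign_sse(structure)
    cmap = build_contact_map(structure, config["cutoff"])
    pairs, values, avail = feat.feature_matrix(
        structure, cmap, min_sep=config["min_sep"],
        pair_annotations=pair_annotations)
    ranked = clf.rank_contacts(model, pairs, values, avail)
    removals = clf.select_removals(ranked, config["selection_strategy"],
                                   config["selection_param"])
    base = build_network(structure, UniformCutoff(gamma=config["gamma"],
                                                  cutoff=config["cutoff"]))
    network = modify_network(base, remove=removals, min_sep=config["min_sep"])
    return network, ranked


def sensitivity_scan(structure: Structure, displacement, ranked,
                     fractions=None, config: dict | None = None) -> pd.DataFrame:
    """CO(10) as a function of the removed top-fraction of ranked contacts."""
    config = {**DEFAULT_CONFIG, **(config or {})}
    if fractions is None:
        fractions = [k / 100 for k in range(0, 51, 5)]
    base = build_network(structure, UniformCutoff(gamma=config["gamma"],
                                                  cutoff=config["cutoff"]))
    rows = []
    for frac in fractions:
        n = int(frac * len(ranked))
        network = modify_network(base, remove=list(ranked.pairs[:n]),
                                 min_sep=config["min_sep"])
        modes = normal_modes(network)
        co = metrics.cumulative_overlap(modes, displacement,
                                        min(10, modes.n_nonzero))
        rows.append({"fraction": frac, "n_removed": base.n_edges - network.n_edges,
                     "co10": co, "n_zero_modes": modes.n_zero})
    return pd.DataFrame(rows)
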