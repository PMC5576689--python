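# lmcenm

Elastic network models (ENMs) predict a protein's intrinsic motions from a
single structure by normal mode analysis of a Cα-level spring network.
Their weakness is well known: localized, weakly collective functional
transitions — a loop folding over a ligand, a lid opening — are poorly
captured because the contacts that must *break* during the motion rigidify
the network. `lmcenm` implements a contact-topology-aware family of ENMs
for structural bioinformaticians who want single-structure motion
predictions that also work for local movers:

- **ENM** — the stabilized baseline anisotropic network model (cutoff
  r_c = 10 Å, every node degree ≥ 4, exactly six zero modes);
- **mcENM** — the network of observed *maintained* contacts: the baseline
  minus contacts seen to break between two known conformations (the
  theoretical upper bound);
- **lmcENM** — the network of *learned* maintained contacts: the baseline
  minus contacts an SVM classifier predicts to break from the unbound
  structure alone;
- **HCA, edENM, OFC** — distance-dependent, hybrid, and
  secondary-structure-scaled spring schemes for comparison.

## The model

Residues i, j are in contact when their Cα distance satisfies d_ij ≤ r_c.
Between a start (unbound) and end (bound) conformation every
start contact is labeled by its strain

    e_ij = |d_ij^S − d_ij^E| / d_ij^S,

*maintained* if e_ij ≤ e_c (default 0.09) and *breaking* otherwise; pairs in
contact only at the end are *forming*. The network potential is harmonic,
V = Σ_(i<j) k_ij/2 (d_ij − d⁰_ij)², and motion is read from the
eigen-decomposition of its 3N×3N Hessian. Agreement with an observed
transition Δr is scored by per-mode overlap O_j = |M_j·Δr|/(|M_j||Δr|), its
cumulative form CO(k) = (Σ_{j≤k} O_j²)^{1/2} (CO(10) is the headline
number), variance fractions CFV(k), the entropy-based degree of
collectivity κ ∈ [1/N, 1], modes-to-X% counts, fluctuation and B-factor
correlations, and the subspace similarities RMSIP/RWSIP against
essential-dynamics PCA.

The classifier describes every long-range contact (|i−j| ≥ 4) by a
170-entry feature vector built from its immediate neighborhood graph and
the secondary-structure-element graph, undersamples maintained contacts 3:1,
trains an RBF-kernel SVM (c = 100, γ = 10⁻⁵) with inverse-class-frequency
weights and Platt-scaled probabilities, and removes the top-16% ranked
contacts (relative-cutoff strategy) to build lmcENM.

## Worked example

```python
from lmcenm import pipeline
from lmcenm.synthetic import SyntheticSpec, make_loop_pair

pair, truth, loop = make_loop_pair(
    SyntheticSpec(n_residues=60, motion="loop_shift", seed=3))
report = pipeline.analyze_pair(pair, variants=["ENM", "edENM", "mcENM"])
print(report[["co10", "best_rank", "modes_to_70"]])
```

prints

```
             co10  best_rank  modes_to_70
variant
ENM      0.330724         10           40
edENM    0.441423         15           27
mcENM    0.915257          8            5
```

The baseline network explains only 33% of the loop motion with its ten
lowest-frequency modes and needs 40 modes to reach 70% cumulative overlap;
after removing the observed breaking contacts the same ten modes capture
92% and five modes suffice for 70% — the mechanism the learned variant
approximates without seeing the second conformation.

A command-line interface mirrors the library
(`lmcenm fixtures`, `contacts`, `build-enm`, `nma`, `evaluate-pair`,
`train`, `predict`, `build-lmcenm`, `scan`, `tune`, `curate`); run
`lmcenm --help`.

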