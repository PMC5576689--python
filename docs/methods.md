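# Methods

## Model and procedure

`lmcenm` treats a protein chain as N point masses at its Cα positions joined
by harmonic springs, V = Σ_(i<j) k_ij/2 (d_ij − d⁰_ij)² with unit masses.
The 3N×3N Hessian is assembled from the standard anisotropic-network
super-elements (off-diagonal 3×3 block −k_ij·r̂r̂ᵀ along each spring's
equilibrium direction) and fully diagonalized; a mechanically stable network
has exactly six numerically zero eigenvalues, the rigid-body motions. Mode
ranks count from the first nonzero mode (rank 0).

Contact transitions between two conformations are labeled from the strain
e_ij = |d_ij^S − d_ij^E| / d_ij^S of every start contact (d ≤ r_c, boundary
inclusive): maintained when e_ij ≤ e_c, breaking otherwise — compression
and stretch both count, and a contact whose end distance leaves the cutoff
while its strain stays small remains maintained, because the strain rule is
applied literally. Pairs in contact only at the end are forming. Distances
are computed only over residues matched by the sequence alignment; pairs
involving unmatched residues carry no label and are excluded from all
denominators.

Network surgery removes listed native springs joining residues ≥ 4 sequence
positions apart (shorter-range removals destabilized maintained-contact
networks), never removes stabilizer springs, and skips any removal that
would drop an endpoint below degree 4. mcENM removes observed breaking
contacts; lmcENM removes the classifier's top-ranked 16% (relative-cutoff
strategy; constant-n and score-threshold strategies are provided); mfcENM
additionally adds forming contacts with stiffness γ (kept for the negative
control it is — it constrains the network further and hurts accuracy).

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| r_c (uniform/OFC cutoff) | 10 | Å | lowest cutoff at which degree-4 stabilization yields six zero modes while keeping localized motions accessible |
| e_c (strain threshold) | 0.09 | — | dataset-optimal separation of breaking from maintained contacts |
| min_degree | 4 | — | stability criterion; under-constrained nodes connect to their nearest not-yet-connected sequence neighbors, ties toward the lower index |
| min_sep | 4 | residues | contacts scored/removed only at |i−j| ≥ 4 |
| SVM cost c / kernel γ | 100 / 1e−5 | — | leave-one-protein-out optimum of top-⌊L/5⌋ precision |
| undersampling ratio | 3 | — | maintained:breaking per protein, capped at availability |
| selection | relative 16% | — | best-performing removal strategy overall |
| zero_tol | 1e−8 | relative | eigenvalue λ < zero_tol·max(λ) counts as zero |
| HCA a, b, c, d; r_c | 205.5, 571.2, 3.059e5, 6; 4.0 Å | mixed | published distance-dependent stiffness; the linear branch is clamped at 0 below b/a ≈ 2.78 Å |
| edENM a, b, c, d | 60, 2, 6, 6 | mixed | published hybrid scheme; size cutoff r_c(N) = 2.9·ln N − 2.9 |

The OFC stiffness table (multipliers on γ by secondary-structure pair and
sequence-distance class: 3× helix–helix short-range, 2× strand–strand
long-range, 1× otherwise) is a configuration-replaceable default chosen to
express the scheme's structure; the published calibration lives in external
software and can be supplied as a table.

## Metric conventions

Mode "variance" is 1/λ with unit stiffness; thermal prefactors cancel in
every fraction and correlation reported. Overlaps are computed against the
displacement after least-squares superposition of the end onto the start
conformation (overlap is frame-dependent; the convention is fixed here).
Fluctuation and B-factor correlations least-squares-scale the predicted
profile before the product-moment coefficient (the coefficient itself is
affine-invariant; the scale matters only for plots). RWSIP weights are
amplitude variances — pass 1/λ for mode sets — and its denominator pairs
both weight spectra in descending order, making 1 attainable exactly when
spaces and spectra coincide. Per-mode metrics on exactly degenerate
eigenvalue pairs depend on the eigensolver's basis choice within the
degenerate subspace; tests use subspace metrics (RMSIP/RWSIP/CO) where that
matters.

## Feature vector

Each scored contact yields 170 entries in seven blocks (pairwise 63, graph
topology 10, graph spectrum 5, single node 12, node label statistics 57,
edge label statistics 13, whole protein 10). Topology and spectrum describe
the contact's immediate neighborhood graph: i, j, their sequence neighbors
i±1/j±1 (plus i±4/j±4 for helical residues — one turn away), and every
residue in contact with i or j. Column-level definitions are the package's
own documented realization of the block structure (see the registry in
`features.py`): annotation-dependent columns (conservation, mutual
information, pockets, residue depth, half-sphere exposure, symmetry,
hydrogen bonds, side-chain contacts) are fed by optional per-residue or
per-pair TSV plugins, recorded in a per-entry availability mask, and set to
the neutral value 0 after standardization when absent. Solvent accessibility
falls back to a Cα neighbor-count burial surrogate. Standardization
statistics are fit on the training corpus only (masked entries excluded)
and serialized with the model.

## Classifier

Per protein, all breaking contacts at |i−j| ≥ 4 are positives and three
times as many maintained contacts are drawn without replacement (per-protein
sub-seeds derive from the corpus seed by hashing the protein id, so corpus
composition changes do not reshuffle unrelated proteins). The RBF-kernel
maximum-margin classifier uses inverse-class-frequency weights; Platt
scaling with 3 internal cross-validation folds calibrates probabilities.
Ranking ties break toward the lexicographically smaller pair; selection
truncates strictly at the computed count. Hyperparameter tuning is
leave-one-protein-out on mean top-⌊L/5⌋ precision with ties toward smaller
cost, then smaller γ. Linear feature weights come from a linear
maximum-margin fit on the standardized features with never-available
columns excluded.

## Synthetic study conditions

The generator emulates the two motion classes the method targets, at toy
scale. A *globule* is a self-avoiding biased random walk (bond 3.8 ± 0.1 Å,
non-bonded exclusion 4 Å) confined to a sphere sized for a radius of
gyration ≈ 3·N^{1/3} Å. A *hinge pair* splits a 60-residue globule at its
midpoint and rotates the second half (30–60°, default 45°) about an interior
pivot on an axis chosen so the halves swing apart: breaking contacts
concentrate at the inter-domain interface, intra-domain contacts survive. A
*loop-shift pair* displaces the most surface-exposed 8-residue window
outward by 6 Å under a half-sine taper. Ground-truth labels are produced by
running the transition classification on the generated coordinates, so
generators and analysis are self-consistent by construction.

Default conditions — 60-residue proteins, 20-protein corpora, strain
threshold 0.09, cutoff 10 Å — were fixed once as the study conditions; the
classifier corpus is hinge-only (a single coherent breaking-contact
signature; the two toy motion classes have opposing signatures that a
near-linear kernel cannot reconcile, and mixed corpora are exposed via
`motions=`). These toys caricature domain vs. local motion: they validate
machinery (label bookkeeping, surgery, mode arithmetic, learnability of a
consistent signature), not biology. Passing them does not show the
classifier transfers to real proteins, whose breaking-contact signatures
are richer and noisier; nor do the toys model side chains, realistic
secondary-structure packing, crystallographic noise, or B-factors.

## Numerical choices and degenerate inputs

Eigen-decomposition uses the symmetric solver on the dense Hessian
(deterministic for fixed input). Collinear bodies legitimately have more
than six zero modes (a dimer has five); stabilization is defined for chains
of ≥ 3 residues. Contact boundary is inclusive (d ≤ r_c); chain-break
detection is strict (d > 4.2 Å). Alternate locations resolve to the highest
occupancy, ties by altloc letter. Residues lacking a Cα are dropped with a
log line. The curation filters (e) bound peptide and (f) extended/disordered
are advisory configuration flags: a Cα-only model cannot see ligand atoms
or judge overall shape, and failing open with an explicit flag beats
silently skipping the check.

## Known limitations

Single chains only; no mmCIF; no side-chain contact definitions; no
rotational-translational block coarse-graining or anharmonic potentials.
The classifier does not reproduce any externally trained model, and
annotation plugins (conservation, pockets, symmetry, depth, hydrogen bonds)
must be computed by external tools and supplied as tables. Problem sizes in
the test suite (20–60 residues, 20-protein corpora, 20 seeds) were chosen
as the smallest at which the studied signatures are stable.
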