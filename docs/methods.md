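# Methods

## Model and procedure

`emtspectrum` treats EMT state as a continuum. The analysis places cells on
that continuum in three steps: diffusion smoothing of signature-gene
expression, graph clustering, and a per-cluster E/M score with fixed class
cutoffs.

**Scaled data.** Counts are depth-normalised to a common target sum
(default 10,000), log1p-transformed, and z-scored per gene. Zero-variance
genes map to all-zero columns. The sign of a scaled value — above or below
the population mean for that gene — is what the downstream score consumes,
so the normalisation's only job is to make that sign meaningful; a
variance-stabilising regression normalisation would serve equally and is
deliberately not required.

**QC semantics.** Detected-gene bounds are inclusive (a cell detecting
exactly `min_genes` = 200 or `max_genes` = 5000 genes is retained; the
upper default sits inside the conventional 4000–7000 range and is
configurable). The mitochondrial rule is strict: cells with *more than*
10% mitochondrial counts are removed, so exactly 10.0% is retained.
Mitochondrial genes are recognised by flag or by a configurable prefix
("MT-"/"mt-").

**Cancer-cell selection.** A cell is selected when its mean scaled
expression over the epithelial marker set reaches a threshold (default 0)
OR its lineage flag is true. The lineage flag models an engineered
reporter (e.g. YFP) recorded upstream of sequencing. Mesenchymal cancer
cells genuinely lack epithelial-marker expression, so marker-only
selection is reliable only for epithelial-skewed populations; the lineage
flag exists precisely to rescue the mesenchymal end.

**Diffusion smoothing.** Markov-affinity imputation on the signature
genes: Euclidean kNN distances pass through an adaptive kernel
exp(−(d/σ_i)^decay) with σ_i the distance to the k-th neighbour; the
diagonal is set to 1, the matrix symmetrised as (A + Aᵀ)/2 and
row-normalised; smoothing is t successive multiplications of the
transition matrix into the expression matrix. Defaults k = 15, decay = 2,
t = 3 — the commonly used values for this family of algorithms; all are
exposed. Duplicate cells (zero k-th-neighbour distance) take σ_i from
their first strictly positive neighbour distance; a dataset of fully
identical cells is rejected. Smoothing is restricted to signature genes
because they are the clustering substrate; the operator accepts any
matrix if full-transcriptome smoothing is wanted.

**Clustering.** A shared-nearest-neighbour graph (Jaccard weights over
kNN sets, k = 15) is partitioned by Leiden modularity optimisation at a
given resolution, deterministically for a fixed seed. Clustering quality
is the mean within-cluster pairwise Pearson correlation of the cells'
signature vectors, computed in closed form from standardised rows;
`select_resolution` returns the smallest grid resolution whose quality
exceeds a floor, falling back to the quality maximum when no floor is
given. No target cluster count is hard-coded.

**E/M score and classes.** For a cluster, EPI (MES) is the fraction of
strictly positive scaled entries pooled over the cluster's cells and the
epithelial (mesenchymal) arm; the score is log2((EPI + ε)/(MES + ε)) with
ε = 1e-6 guarding empty fractions (an all-epithelial cluster gets a large
finite score). "Positive" means strictly > 0: on signed z-scored values
this is the only well-defined reading of a positive-gene percentage.
Pooling entries rather than averaging per-gene indicators is a
convention; the two coincide for single cells. Class boundaries are
inclusive: score ≥ 1.5 epithelial, ≤ −1.5 mesenchymal, otherwise
partial-EMT. Clusters are relabelled in strictly decreasing score order
(ties: larger cluster first, then original label).

**Samples.** The default per-sample call pools the sample's cells and
applies the same fractions → score → cutoffs path; a plurality-of-cell-
classes rule is available behind a flag (ties resolve toward pEMT, the
middle of the spectrum). Both readings of a "predominant" sample
phenotype are defensible; neither is asserted as canonical, and the rule
used is recorded in the output.

**Pathology score.** Specimen composition percentages over six categories
(normal, PanIN, well-/moderately-/poorly-differentiated PDAC, necrosis)
are scored by fixed threshold rules, all strict: normal > 5% → +1,
PanIN > 30% → +2, well+moderate PDAC > 30% → +4, poor PDAC > 5% → +5,
necrosis > 5% → +6 (maximum 18). Whether poorly-differentiated PDAC also
counts toward the PDAC > 30% aggregate is ambiguous; the default excludes
it because that category carries its own rule, and a flag includes it.

**Spatial statistics.** The bivariate Ripley estimate is
K̂(r) = |W|/(n_from·n_to) Σ_ij w_ij 1[d_ij ≤ r] with w_ij = 1 (default) or
the Ohser–Stoyan translation weight; L(r) = √(K(r)/π); the infiltration
statistic is the trapezoidal AUC of L over a uniform 40-point grid in
(0, r_max], r_max = 20 μm by default (cell–cell contact distance).
Coordinates are micrometres; readers reject unlabeled coordinate columns.
The exact edge correction behind published L-function analyses varies, so
it is configurable and logged, never guessed.

## The synthetic generator

The generator emulates exactly the structure the pipeline is designed to
recover. Each cell has a latent coordinate z ∈ [0, 1]; classes occupy
disjoint bands — epithelial z ~ U(0, 0.25), partial-EMT z ~ U(0.35, 0.65),
mesenchymal z ~ U(0.75, 1) — so ground truth is unambiguous. Counts are
gamma-Poisson (negative binomial, dispersion 2) at an expected depth of
2000 per cell, with 30% Bernoulli zero-inflation applied per entry after
sampling; the simple dropout mechanism is what makes diffusion imputation
demonstrably useful. Mitochondrial genes are constant-rate background
genes with a configurable prefix, so the QC mito-fraction is controllable.

**Gene response model.** Each signature gene carries its own sigmoidal
switch point, spread evenly along the latent axis (width 0.05), with a
near-silent off state (off/on rate ratio 0.02/5). This was a genuinely
open design choice, and the naive alternative — one shared response curve
per arm — fails structurally: if all epithelial genes rise and fall
together, a cell sits above or below the population mean for the whole
arm at once, positive fractions saturate at 0 or 1, and the E/M score
degenerates into a step function with no intermediate pEMT regime.
Staggered switch points are also the more faithful picture of an EMT
program, where genes activate at different positions on the continuum.
With switch points uniform on (0, 1), the fraction of positive
epithelial entries falls as ≈ 1 − z and the mesenchymal fraction rises as
≈ z, so the score behaves as log2((1 − z)/z) and crosses +1.5 and −1.5 at
z ≈ 0.26 and 0.74 — inside the empty gaps between the latent bands. The
off state must be near-silent for this to hold: a half-expressed off
state lets the class mixture drag per-gene means, and with it the
positivity thresholds, away from the switch points.

**Panel size.** Defaults are 60 + 60 signature genes, 300 background
genes and 20 mitochondrial genes, so a typical cell detects ~270 genes —
inside the QC window — with a mitochondrial fraction around 3–5%.

**Point patterns.** `csr` draws both phenotypes independently uniformly;
`attraction` places T cells at Gaussian offsets (SD = interaction scale)
from random cancer parents, Thomas-process style, resampling offsets that
leave the window; `exclusion` rejects and resamples T-cell candidates
within the interaction scale of any cancer cell and fails explicitly when
the window is too dense for the requested radius.

**What the generator does not emulate:** realistic transcriptome breadth,
batch effects, doublets, cell-cycle structure, ambient RNA, or spatial
inhomogeneity of tissue. Passing tests therefore demonstrate that the
pipeline's logic is correct and self-consistent under a faithful noise
model — not that any particular biological dataset would yield a
particular cluster count or phenotype split.

## Numerical choices

- Pseudocount 1e-6 in the score; boundaries ≥ 1.5 / ≤ −1.5 inclusive.
- Transition-matrix rows sum to 1 within 1e-9 (validated on
  construction); smoothing uses t explicit multiplications, never an
  eigendecomposition, so t = 0 is exactly the identity.
- Zero-variance genes scale to zero columns rather than NaN.
- Dense affinity/transition matrices: the intended scale is 10³–10⁴
  cells, where dense BLAS beats sparse bookkeeping.
- Cluster labels are made contiguous 1..K in order of first appearance
  before scoring, and remapped to spectrum order afterwards.
- Test problem sizes: recovery runs use 3000 cells × 440 genes over five
  seeds; imputation-utility checks 600 cells over ten seeds; spatial
  calibration 100 CSR simulations of 50+50 points. These sizes give
  stable Monte-Carlo margins for every asserted bound.
- The CSR calibration of L(r) − r is asserted with the translation edge
  correction (unbiased for K under CSR; the uncorrected estimator is
  biased low near the boundary) on radii ≥ 4 μm: below that, the expected
  cross-pair count is well under one and the concavity of the square root
  biases L itself regardless of correction.

## Known limitations

- sctransform-style regression normalisation is not implemented; scaled
  data comes from depth-normalise → log1p → z-score.
- The PCA-based validation variant of the smoothing algorithm is out of
  numerical scope (an embedding for visual checks only).
- Trajectory/pseudotime analysis, differential-expression marker finding
  and survival statistics are out of scope.
- Marker-only cancer-cell selection under-recovers deep-pEMT and
  mesenchymal cells (by construction); use lineage flags where available.
- The L-function estimator offers "none" and "translation" corrections
  only; isotropic (Ripley) correction is not implemented.
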