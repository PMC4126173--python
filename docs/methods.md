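# Methods

## The problem and the data model

A cell's ILD sensitivity function is its mean spike count per stimulus at 13
interaural level differences from −30 to +30 dB in 5 dB steps, positive
meaning the contralateral ear is louder. A survey is an N×13 non-negative
matrix tied to that axis. The package derives, from such a matrix alone, a
small set of template functions and an assignment of every cell to one of
them, via normalization → PCA → hierarchical clustering.

## Normalization and the test bench

Seven rescalings are implemented (ids 1–7): mean correction, division by the
matrix-global maximum, division by the vector maximum, division by the vector
SD, log2 relative to the vector mean, unit total probability mass (UTPM,
`V = X·μₙ/ΣX`), and the per-vector z-score. All per-vector statistics (μₙ,
σₙ, sums, maxima) are computed over one cell's 13 values; only method 2 uses
a matrix-global statistic. Vector SDs use the unbiased (ddof = 1) estimator.
With the per-vector reading, UTPM reduces algebraically to division by
L = 13: a single uniform rescaling of the whole matrix. A variant using the
grand mean instead of μₙ is available (`utpm_mean="grand"`) but is not the
default, because only the per-vector form is shape-preserving in the strict
sense below.

Degenerate inputs are hard errors that name the offending cell: zero vector
SD (methods 4, 7), non-positive counts (method 5), zero vector sum
(method 6). The bench therefore perturbs prototypes with a positive floor
(0.1 spikes) so the log method can participate.

**Bench.** Nine panels of idealized shapes are generated on a 0–100
spikes/stimulus scale — sigmoids varying amplitude / midpoint / slope,
Gaussian peaks varying amplitude / position / position-and-width, a
peak-to-sigmoid and a peak-to-flat blend, and constants — then perturbed by
13 independent uniform draws in ±6% of the curve's amplitude (one draw per
ILD level). The per-panel parameter grids (amplitudes 25/50/75/100
spikes, midpoints −10/0/+10 dB, slopes 2.5/5/10 dB, Gaussian widths 5–12 dB,
blend weights 0.35/0.65) are package defaults chosen to span the
qualitative variation each panel represents; only the varied feature per
panel is fixed by the problem, not the exact grid. The ±6% half-range is the
scale at which the idealized shapes stop looking artificial without becoming
mutually confusable.

**Selection rule.** A method survives stage (a) if it produces no degenerate
failure and its pooled Pearson correlation with the raw values — across
every curve of every panel jointly — is ≥ 0.999. Pooling is the point:
per-vector rescalings (methods 1, 3, 4, 5, 7) keep each curve's shape but
destroy the between-cell amplitude structure, so they fail the pooled test
even though each row correlates perfectly. Stage (b) prefers methods
computable from one cell alone, which eliminates global-max division: a
normalization whose output for one cell changes whenever any other cell
changes does not transfer across surveys. Stage (c) takes the smallest
normalized maximum (strongest range compression) and stage (d) breaks ties
by lowest id. On the default bench this selects UTPM, which scales a
13-level survey down by exactly 1 − 1/13 ≈ 92.31%.

## PCA

The covariance of the 13 level-variables across the N cells uses 1/N scaling
(not 1/(N−1)); percentages are unaffected, raw eigenvalues are reported as
defined. The decomposition is `numpy.linalg.eigh` on the symmetric 13×13
matrix — never the N×N dual — with eigenvalues sorted descending, values
below 1e−12 of the largest clipped to zero, and each eigenvector's sign
fixed by making its largest-magnitude loading positive so score files are
bit-reproducible. A constant input yields all-zero eigenvalues and a
`degenerate` flag plus warning rather than an error.

Because UTPM is a uniform rescaling, UTPM-normalized and raw data give
identical variance percentages (eigenvalues scale by 1/L²); this is asserted
in the tests and is the cleanest internal consistency check on the pipeline.

Component-count rules:

* `explained_variance` (default, threshold 95%): smallest k whose cumulative
  percentage reaches the threshold. On surveys like these, k = 3.
* `kaiser`: count of eigenvalues above a cutoff. The classical λ > 1 applies
  to correlation-matrix PCA; since this is covariance PCA the default cutoff
  is the mean eigenvalue, with `kaiser_cutoff="one"` exposing the classical
  form.
* `scree_elbow`: the eigenvalue of maximum curvature (second difference) is
  taken as the start of the flat tail, and the components before it are
  kept. Scree reading is inherently ambiguous; this is one defensible
  automation, not the authoritative rule.
* `horn`: parallel analysis against 200 i.i.d. Gaussian null matrices
  matched in shape and per-column variance, 95th percentile, seeded;
  components are retained while their eigenvalue exceeds the null percentile
  and retention stops at the first failure.

## Clustering

Distances: euclidean, standardized euclidean (per-dimension unbiased
variance), minkowski (order p, default 2), mahalanobis (sample covariance;
pseudo-inverse with a warning when singular), cityblock, cosine. Cosine
requires non-zero rows (error names the row) and values are clipped at 0
against floating-point undershoot.

Linkage uses the Lance–Williams updates of `scipy.cluster.hierarchy`. Ward
is deliberately applied to whatever dissimilarity is supplied — including
cosine, which is not Euclidean-consistent — because the pipeline treats the
24 metric×linkage combinations as candidates to be ranked empirically by
CCC, not as theoretically sanctioned pairings.

The CCC grid records all 24 coefficients; failures become NaN entries with
reasons. Ties at the maximum are broken by the documented metric order then
linkage order, with a 1e−9 tolerance: exact ties are structural, since
minkowski(p=2) duplicates euclidean, and on PC scores — which are
decorrelated by construction — seuclidean and mahalanobis produce identical
distances up to rounding.

The inconsistency coefficient of a merge is (height − mean)/SD over the link
heights within `depth` levels below it (inclusive), the classic
statistics-toolbox convention, with the coefficient defined as 0 for
one-link windows or zero SD. Default depth 3. Cutting supports exactly one
of: a fixed cluster count k (undo the last k−1 merges; always yields exactly
k non-empty clusters) or an inconsistency threshold. Cluster labels are
relabelled 1..k in order of first appearance, so output files are
deterministic and invariant (up to relabelling) under row permutation.

By default clustering operates on the k = 3 PC score matrix; a
`cluster_on="normalized"` flag clusters the normalized curves directly for
sensitivity checks.

## Templates and type assignment

Templates are arithmetic means of member curves — with true labels and no
noise this reproduces planted templates exactly. Each template is assigned a
type by scale-free rules (all thresholds configurable):

* **INSENSITIVE** if modulation depth (max−min)/max < 0.25;
* **SIGMOID_IE / SIGMOID_EI** if ≥ 90% of axis steps move in one direction
  (steps within 2% of the range count as consistent with either direction);
  rising curves are IE, falling are EI. The orientation follows the
  excitatory/inhibitory naming: EI = excitatory-ipsilateral /
  inhibitory-contralateral, so an EI cell responds less as the contralateral
  ear gets louder, i.e. its function falls with increasing (contra-positive)
  ILD. Mirroring a curve along the axis swaps EI and IE;
* **PEAKED** if the maximum is interior and the curve drops from it by
  ≥ 30% of its range on both flanks;
* **TRANSITION_PEAK_SIGMOID** if only one flank drops (a peak merging into a
  plateau); **TRANSITION_PEAK_FLAT** if an interior peak rises from an
  elevated baseline on both sides (flanks within the transition margin of
  each other and baseline above the insensitivity depth); otherwise
  **TRANSITION_OTHER**.

These numeric thresholds are package-defined defaults for a judgement that
has historically been visual; they are deliberately exposed in
`ClassRuleParams`. The reported "fraction of cells in non-insensitive
clusters" counts members of clusters whose template is anything but
INSENSITIVE.

## The surrogate survey

`simulate_survey` plants seven templates tracing the sigmoid → peaked →
insensitive continuum (a shallow falling sigmoid, a sigmoid/peak transition,
a steep rising sigmoid, broad and narrow peaks, a peak arising from an
elevated baseline, and a flat curve) with the seven-way composition
61/19/36/25/21/11/35 of 208 cells. Each cell is its template scaled by a
uniform ±10% amplitude jitter plus additive Gaussian noise of SD 6
spikes/stimulus truncated at zero (the same scale as the bench's ±6
perturbation on a 100-spike curve); a Poisson noise model is available. The
generator is bit-reproducible under a fixed seed.

What the surrogate does **not** emulate: real surveys have no ground-truth
templates, unequal and correlated noise across ILD levels, response
amplitudes spanning far more than ±10%, cells genuinely intermediate between
types rather than noisy copies of seven fixed shapes, and cluster structure
that is continuous rather than planted. Passing recovery tests (ARI = 1 at
this noise level) therefore demonstrates the pipeline's correctness and
stability, not that seven is the right number of clusters for any real
survey — on real data the cluster count should come from the inconsistency
criterion and inspection of the dendrogram, and the CCC-selected
metric/linkage pair will generally differ from the surrogate's.

## Numerical and I/O choices

Eigenpair residuals are kept below 1e−8·‖A‖; full-rank reconstruction
recovers the data to 1e−8. Survey files are delimited text with a numeric
ILD-level header (descending headers are flipped on read) and the cell id in
the first column; merge tables are written with `repr` of the heights so the
round trip is bit-exact; dendrograms export to Newick with branch lengths
equal to height differences. Pipeline runs with identical config and seed
produce byte-identical reports.

## Problem sizes

All shipped tests and the acceptance script use the native survey size
(N = 208, L = 13), nine-panel benches (28 curves), brute-force oracles at
N ≤ 9, and ten-survey stability sweeps; the whole suite runs in a few
seconds on one core.
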