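# Methods

## Problem and model

`surfquant` quantifies how well a tagged single-pass membrane protein (the
motivating case: clustered protocadherin isoforms) reaches the cell surface.
Live cells co-express a cytoplasmic transfection marker (FP channel) and are
stained with an antibody against an extracellular epitope tag (Ab channel),
so each cell yields two intensities: `fp_cell`, a proxy for total protein
expression, and `ab_cell`, a proxy for surface abundance. From these the
package computes three per-sample metrics:

- **f+** — the fraction of transfected cells whose `ab_cell` lies strictly
  above a surface-stain threshold. Sensitive to the presence of any
  measurable surface protein, less sensitive to how much.
- **Ab̄** (`ab_mean`) — the mean `ab_cell` over all transfected cells,
  negative values included; proportional to the average surface
  concentration. Strongly expression-dependent, so it is usually reported
  relative to a designated positive-control sample.
- **Esurface** (`e_surface`) — the slope of an ordinary least-squares line
  through `(ln FPbin, ln Abbin)`, where transfected cells are binned by
  `fp_cell` and per-bin arithmetic means are taken. Under an approximately
  power-law dose-response `ab ≈ a·fp^k` the slope estimates the exponent
  `k`, making the metric insensitive to overall expression level and to
  multiplicative rescaling of either channel (slope is also invariant to the
  log base, which is natural here; the intercept is in nats).

## Image quantification

Masks are consumed as integer label images (segmentation is upstream).  Per
individual image — per field of view, per channel — the background is the
median intensity of non-cell (label 0) pixels, configurable to the mean;
subtracting a per-image scalar makes per-cell means invariant to any
constant offset, and values may legitimately go negative.  A cell containing
any pixel at or above the channel's saturation level — defaulting to the
image dtype's maximum, configurable per channel because detector saturation
codes vary — is excluded from everything downstream, regardless of which
channel saturated.

## Thresholds

The transfection threshold on `fp_cell` is the 0.995 empirical quantile of
mock-transfected control cells pooled across all biological replicates; the
surface-stain threshold on `ab_cell` is computed identically from cells
expressing an untagged construct. Quantiles interpolate linearly between
order statistics (`numpy` method `"linear"`); with this convention the
fraction of pooled control cells strictly above the threshold is at most
0.005 whenever the pool exceeds a few hundred cells (a warning fires below
100). Both threshold comparisons are strict (`>`), so a cell exactly at
threshold does not count.

## Binning and the Esurface fit

Bin edges are defined once from the pooled `fp_cell` of all transfected
cells across samples and replicates, and shared by every sample. Two modes:

- `log_spaced` (default): `n_bins` geometric intervals between the pooled
  minimum and maximum;
- `equal_count`: quantile edges so each bin holds an equal share of pooled
  cells (approximately log-spaced for lognormal-like expression).

`n_bins` defaults to 20 and is reported in the output. Bins are half-open
`[e_i, e_{i+1})` with the last bin closed. Cells with `fp_cell ≤ 0` cannot
enter the log-log fit and are excluded from binning only — they still count
toward f+ and Ab̄. Bins whose mean `ab_cell` is ≤ 0 are excluded from the
regression (the log is undefined at 0); fewer than 2 usable bins yields a
missing Esurface with diagnostics rather than a number.

Two numerical caveats, both verified by the test suite:

- *Jensen bias.* The regression uses arithmetic per-bin means, so for a
  noise-free power law with `k ≠ 1` the point `(mean fp, mean fp^k)` lies
  slightly off the curve (`E[fp^k] ≠ E[fp]^k`). At 20 bins over ~3 decades
  the resulting slope bias is below 5×10⁻³; it vanishes identically at
  `k = 1`. Recovery is exact (1e-9) only in the linear case.
- *Null-sample selection bias.* For a sample with no true surface signal and
  zero-mean background noise, excluding non-positive bins keeps only
  positive noise whose magnitude shrinks with the per-bin cell count; since
  counts trend with expression, the surviving points acquire a small
  positive residual slope (≈0.2 on the default generator, versus ≈0.8+ for
  trafficking-like samples). "Esurface ≈ 0" for null samples is therefore a
  statement about scale relative to trafficking constructs, not a value that
  converges to zero with more cells.

## Logicle display transform

Histograms of `fp_cell`/`ab_cell` are displayed on a logicle
(biexponential) scale, which is linear around zero — keeping the partly
negative background-subtracted intensities visible — and logarithmic at
scale. The implementation inverts the standard biexponential
`S(x) = a·e^{bx} − c·e^{−dx} − f` with constants fixed by the full-scale
value `T` (default: data maximum), linearization width `W` (default:
estimated from the 5th percentile of negative values as
`(M − log10(T/|r|))/2`), `M = 4.5` decades and `A = 0` additional negative
decades. Forward transformation uses bisection-safeguarded Newton iteration
(~1e-12 relative accuracy). The transform is display-only; no metric is
computed on the logicle scale.

## Flow cytometry path

FCS 3.0/3.1 event files are read by a minimal in-package parser (list-mode,
float or unsigned-integer data, both byte orders) and mapped onto the same
per-cell table; channel names must be stated explicitly in the
configuration. Flow intensities enter the thresholds and metrics as-is: no
background subtraction analogous to images is applied, and no
compensation or additional gating is performed.

## Statistics

Replicate-level metric values (one per biological replicate) are compared
with: Welch's unequal-variance t-test (Welch–Satterthwaite degrees of
freedom), Dunnett's many-to-one test (pooled-variance one-way layout;
adjusted p-values from the equicoordinate multivariate t; with a single
treatment the 1-D reduction is evaluated exactly as a pooled Student t),
Tukey's all-pairs studentized-range test, and the Pearson correlation with
its two-tailed t-transform p-value. Tail direction is always an explicit
argument, never inferred from the data. The multivariate-t quadrature
underlying Dunnett for k ≥ 2 is randomized; its stream is pinned so reruns
are byte-identical. Calibration under a simulated null (type-I error at
α = 0.05, family-wise for the multiple-comparison tests) is checked over
2,000 datasets in the test suite.

## Differential conservation

An aligned set of isoform extracellular sequences is split into two
functional groups (surface-trafficking vs non-trafficking; membership is an
input). Per column and group, amino-acid frequencies are computed over the
20-letter alphabet; gaps (and unrecognized symbols) are excluded and the
distribution renormalized. A pseudocount ε (default `1/n_group`, a
scale-aware Laplace-like choice whose effect shrinks as `1/n²`) keeps both
distributions strictly positive — without smoothing the divergence is
infinite at any fully disjoint column. Each column is scored with the
Kullback-Leibler divergence in nats; the default direction is
KL(non-trafficking ‖ trafficking), configurable, with a Jensen-Shannon
symmetrized option; the direction used is recorded in the output. Columns
that are conserved within each group but differ between groups score
highest; columns variable in either group or identically conserved score
near zero. Columns with > 50 % gaps in either group are flagged; all-gap
columns get a missing score. Reports are 1-based in alignment coordinates,
optionally with residue numbers of a chosen reference sequence by
ungapped-position counting.

## Synthetic data

The generator provides the ground truth against which everything is
validated:

- **Cell tables.** A `transfected_fraction` (default 0.4, typical of
  transient transfection) of cells draw `fp_cell` from a lognormal
  (median 500 a.u., σ_log = 1.0 → ~3 decades of expression); the rest get
  zero-mean Gaussian background (σ = 5 a.u.), as background-subtracted
  intensities of untransfected cells would. Among transfected cells a
  `stained_fraction` (default 0.7) follows `ab = a·fp^k·e^{σz}` (defaults
  `a = 1`, `k = 0.8`, σ = 0.3); the remainder — the
  transfected-but-unstained subpopulation — and all untransfected cells get
  zero-mean Gaussian `ab_cell`. The exponent `k` is the single recoverable
  dose-response parameter.
- **Controls.** Mock-transfected (no expression in either channel) and
  untagged (expression without stain) tables mirror the two threshold
  sources.
- **Image fields.** Non-overlapping constant-intensity disks on a uniform
  additive background, with optionally planted saturated pixels; per-cell
  means are recovered exactly, which is what makes the brute-force oracle
  tests exact.
- **Toy alignments.** Columns planted in four conservation classes
  (conserved-same, conserved-different, one-conserved, both-variable) with
  known labels.

Everything is deterministic under a fixed seed. What the generator does
*not* emulate: spatial noise and PSF physics, cell-shape variability,
autofluorescence structure, junction enrichment, or any nonspecific
staining floor — so passing tests demonstrate correctness of the
estimators under the stated statistical model, not robustness to every
real-microscope artifact. In particular the zero-mean background model is
the harshest case for the null-sample Esurface (see selection bias above);
real null samples with a small positive nonspecific-stain floor behave more
benignly.

## Problem sizes in the validation suite

Parameter-recovery checks use 5,000 transfected cells per table, 20 seeds
per exponent, and exponents {0.5, 1.0, 1.5}; threshold checks use pools of
10,000 control cells; oracle-equivalence checks use 20 random 64×64 fields;
statistical calibration uses 2,000 simulated null datasets per test and
10⁶-draw Monte Carlo oracles for the multiple-comparison distributions.
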