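# Methods

## Eigenvector centrality of the voxel-wise connectome

For an in-mask data matrix `M` (n_voxels x T, row z-scored with ddof = 1)
the voxel-by-voxel Pearson correlation matrix is `C = M Mᵀ / (T − 1)`.
Eigenvector centrality (EC) scores each voxel by the leading eigenvector of
a connectivity matrix: a voxel is central when it is strongly connected to
other central voxels.  Raw correlations can be negative, so we use the
transform

    A = (C + 1) / 2,

the convention of the fastECM toolbox this implementation follows.  `A` is
entrywise positive, hence (Perron–Frobenius) its leading eigenvector is
unique and can be chosen entrywise nonnegative.  Power iteration from the
uniform positive vector `1/√n` converges to it; each product `A·v` is
evaluated matrix-free as

    A v = ( M (Mᵀ v) / (T − 1) + 1⃗ · Σᵢvᵢ ) / 2,

so the n × n matrix is never formed (at 4 mm resolution a grey-matter
connectome has ~5·10⁴ voxels; dense storage would be ~20 GB).  Iterates are
renormalized to unit Euclidean norm; convergence is declared when the L2
difference of successive iterates falls below `tol` (default 1e−9, max 1000
iterations).  Because the `+1` offset makes the leading eigenvalue ≈ n/2
and the spectral gap large, convergence typically takes a few dozen
iterations.  A dense eigendecomposition oracle (`dense_ecm_oracle`,
memory-guarded to ≤ 3000 voxels) provides the independent cross-check used
by the test suite; the two routes agree to < 1e−6 in max-norm over random
problems up to n = 500.

Numerical conventions: output is unit-L2-normalized (not rescaled to
[0, 1]); constant voxels cannot be z-scored and are kept as all-zero rows —
they still receive centrality through the `+1` offset — and flagged; a
series in which *every* voxel is constant is an error.

## Static and dynamic ECM

Static EC uses the whole series.  Dynamic EC segments the series into
`n_windows` partially overlapping windows of `length` volumes (reference
configuration: 100 windows of 100 volumes in a 200-volume, TR = 2 s
acquisition) and runs ECM per window after re-z-scoring *within* the
window, so each window's implied connectivity is that window's true
correlation matrix.  Window starts are `round(linspace(0, T − length,
n_windows))`: the even grid reproduces any printed (T, length, n) triple
deterministically; with at least `n_windows` distinct start positions the
rounding provably never collides, and when fewer positions exist duplicates
are kept with a warning.  Windows shorter than 100 s of acquisition warn:
below the slowest BOLD wavelength, window-to-window EC fluctuation is
likely spurious.  A single full-length window reduces exactly to static
ECM.

## Dual regression and temporal variability

Stage 1 regresses each window's EC map on all K network template maps
simultaneously (intercept included, templates demeaned), giving one EC
loading per network per window.  Stage 2 regresses each voxel's EC series
on all K stage-1 time courses (intercept included; time courses demeaned
and variance-normalized by default so map magnitudes are comparable across
networks), giving subject-specific spatial maps.  Rank-deficient designs
are rejected with the offending columns named.

Temporal variability of a network is the sample SD (ddof = 1) and max−min
range of its stage-1 time course across windows.  Whether the per-network
variability should derive from stage-1 loadings or from the mean dynamic
EC inside a binarized template is genuinely open; stage-1 is the default
and `template_mean_timecourses` (binarization at 50% of the template
maximum) implements the alternative, selectable in the pipeline via
`variability_source="mask-mean"`.  Cluster ROIs use the unweighted
within-cluster mean EC per window and the same SD/range definitions
(shared code path).

## Group inference

Voxel-wise group differences use per-voxel OLS (group + age + sex), the
contrast t statistic, threshold-free cluster enhancement, and
family-wise-error correction by the permutation distribution of the
image-wide maximum TFCE score:

* **TFCE**: `∫ e(h)^E h^H dh` discretized at `h = dh, 2dh, …` with
  `E = 0.5, H = 2, dh = max/100` (the published defaults of the standard
  tool), 26-connected components, negative contrasts enhanced on the
  negated map.  The implementation sorts voxels by height and sweeps the
  threshold downward with an incremental union-find (numba-compiled):
  components only merge as h decreases, so no per-threshold relabelling is
  needed — ~3 ms per 20³ map, which is what makes 10⁵ permutation maps in
  the calibration study affordable.  A brute-force per-threshold labelling
  oracle in the test suite matches it to machine precision.
* **Permutations**: Freedman–Lane — data are residualized against the
  nuisance-only (contrast-zero) columns, residuals are permuted, the
  nuisance fit is added back, and the full-model TFCE map is recomputed
  with the *same* dh as the observed map.  `fwe_p = (1 + #{perm max ≥
  observed}) / (B + 1)`, bounded in `[1/(B+1), 1]`.  B defaults to 500; the
  two one-sided contrasts (A+ > A−, A− > A+) are each corrected at
  α = 0.05.
* **Clusters**: voxels with corrected p < α, 26-connected components,
  components of ≤ 10 voxels discarded, relabelled by decreasing size.

Scalar models (statsmodels OLS) z-score the outcome, leave binary
predictors 0/1 and z-score continuous cognitive scores, so coefficients are
standardized effects.  The variability model is `z(outcome) ~ group + age +
sex`, with the AT version a three-level factor against the A−T− reference.
The cognition model is `z(outcome) ~ z(score) × amyloid + age + sex +
education`; per-group simple slopes are reported with delta-method
standard errors.  Missing values are dropped per model (complete case).

## Biomarker classification and QC

A+ iff CSF Aβ1–42 < 1000 pg/mL (strict); T+ iff CSF p-tau > 27 pg/mL
(strict); boundary values are negative.  A−T+ (suspected non-AD pathology)
is flagged and excluded from AT contrasts and, by default, from the A+/A−
contrast (`include_at_plus=True` retains it).  Motion QC excludes subjects
with mean framewise displacement above the cohort mean + 2 SD, computed on
the full cohort in a single pass before exclusion, one-sided (only
excessive motion fails).

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes at desk
scale: a 20×20×20 grid of 4 mm voxels with a radially tapered grey-matter
probability map (~2 900 voxels above the 0.2 threshold), 200 volumes at
TR = 2 s, K = 4 network templates (10 optional), and phenotypes with the
target marginals (33.1% A+, age ~ N(64.6, 7.01), 58.3% female, education
~ N(14.69, 3.79), MMSE ~ N(28.7, 1.53) capped at 30, RBANS indices mean
100/SD 15 loading on one latent cognitive factor, log-normal framewise
displacement).  CSF values are drawn clear of the 1000/27 thresholds so
classification is unambiguous; boundary behaviour is tested with crafted
records instead.

Per subject, voxel signals are

    x_v(t) = Σ_k m_k(v) a_k(t) s_k(t) + w_v g(t) + σ ε_v(t)

with smooth Gaussian-blob templates `m_k`, band-limited network latents
`s_k`, amplitude envelopes `a_k(t) = 1 + d_k sin(2π t/P_k + φ_k)`, a global
latent `g` whose coupling `w_v` creates hubs, and white noise.  Planted
effects: A+ reduces posterior hub coupling and raises frontal hub coupling
(static EC effects); A+ reduces the first ("DMN-like") network's modulation
depth by `dyn_sd_reduction` in cohort depth-SD units and, within A+, adds
a per-SD-of-cognition slope `cognition_interaction_slope` (negative: A+
with good cognition have the lowest variability).  Setting all four
effects to zero makes groups exchangeable — the null configuration used
for calibration.

**Design for faithful transfer.**  The quantity the variability analysis
estimates — the SD of a network's EC loading across windows — is a noisy,
nonlinear functional of the data.  For recovery tests to be meaningful the
planted depth must dominate that statistic, so several generator choices
trade surface realism for controllability, deliberately:

* latents are sums of six log-spaced sinusoids (15–60 s periods) with
  golden-ratio phases — *deterministic* study-level fixtures shared by all
  subjects, as in a shared-paradigm design.  Filtered-noise latents would
  add χ²-distributed window-variance luck per subject, and seed-dependent
  phases were observed to change the depth→SD gain several-fold;
* the DMN-like modulation waveform is time-locked (fixed 500 s period and
  phase) so depth, not phase luck, drives window-to-window variability;
  other networks use fixed distinct periods (150/180/210 s) with random
  phases and low depth (0.15) to limit leakage through the EC unit-norm
  coupling;
* template centers sit on a deterministic Fibonacci-lattice ring kept
  clear of the hub regions, so static coupling effects cannot leak into
  network variability outcomes; template width shrinks automatically when
  K is large so pairwise template correlations stay below 0.3;
* signal scaling (template amplitude 1.8, noise SD 2.4, depth base 0.7,
  depth spread 0.35) was calibrated during design so that the planted
  depth explains ≈ 0.98 of the between-subject variance in the measured
  network SD, making the depth→outcome mapping effectively linear.

Because depth effects are expressed in depth-SD units, their population
standardized effect on the (approximately linear) SD outcome equals the
nominal parameter.  The truth record stores both the nominal effects and
the *realized* standardized effects — OLS of the z-scored drawn depths on
the analysis covariates over the exact analysis subset, computed from
generator internals only.  Recovery tests compare pipeline estimates to the
realized values: at n = 200 the sampling error of a standardized group
difference is ~0.15 SD, so comparison to the nominal value would measure
cohort luck, whereas comparison to the realized value isolates the
pipeline's own error.

Effect magnitudes (0.3 fractional coupling change; 0.35 SD depth
reduction; −0.45 per-SD cognition slope) sit at the upper end of the
0.2–0.45 standardized-effect range typical of preclinical-amyloid cohort
reports, chosen once so that an n = 200 desk-scale cohort has adequate
power.

**What passing tests do and do not show.**  The generator has no
hemodynamics, physiological noise, motion artefacts, atrophy confounds, or
subject-specific functional topography; its latent waveforms are shared
across subjects and its networks are compact blobs.  Green recovery tests
therefore demonstrate that the *pipeline* is correct and calibrated — not
that effects of this size are detectable in real cohorts, where
between-subject variability is far richer.

## Problem sizes used by the validation suite

Chosen as the package's own desk-scale study conditions: ECM oracle
agreement on 50 random problems (n ≤ 500, T ≤ 200); TFCE oracle agreement
on 20 random 10³ maps; null calibration over 200 replicate cohorts of
n = 40 with B = 500 permutations (the binomial 95% interval around a 5%
family-wise rate); planted-effect recovery on one n = 200 cohort with
B = 500; scalar-model null uniformity over 500 replicates.  The acceptance
script repeats the planted study and a 100-replicate calibration with
seed-derived randomness.

## Known limitations

* The overlap step of the original sliding-window implementation is not
  printed anywhere authoritative; the rounded even grid is this package's
  documented convention.
* TFCE uses a discrete threshold sum; results depend (weakly) on dh, and
  permutation p-values are only exchangeable when observed and permuted
  maps share the same dh (enforced).
* The A = (C+1)/2 transform is one of several conventions for signed
  correlations; alternatives (e.g. positive-only) are out of scope.
* Freedman–Lane partitions nuisance by the zero pattern of the contrast
  vector; contrasts mixing interest and nuisance weights in one column are
  not supported.
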