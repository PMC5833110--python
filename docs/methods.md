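# Methods

## Model

A woman-year observation is a woman alive in a census year, with age $a$
(years, at midyear), a continuous household SES index $s$ (~1–4), the
census year $t$, and a binary live-birth indicator $Y$.  The annual birth
probability is modelled as a Gamma density in age,

$$p(a; \mathbf{x}) = \mathrm{Gamma}(a \mid \alpha(\mathbf{x}),
\beta(\mathbf{x})) = \frac{a^{\alpha-1} e^{-a/\beta}}{\Gamma(\alpha)
\beta^{\alpha}}, \qquad \mathbf{x} = (s, t),$$

which produces the skewed single-peak age-pattern characteristic of
fertility schedules; the peak sits at $(\alpha-1)\beta$ for $\alpha>1$.
A density is not a probability: values are clamped to $[0, 1-10^{-9}]$
before use (the clamp is logged; for all defaults it never binds in the
fertile age range).

The covariate dependence of $\alpha$ and $\beta$ is left nonparametric.
The pipeline is:

1. **Quantile binning** (`fertgp.binning`).  Age and SES are split into
   empirical quantiles (linear interpolation between order statistics;
   pooled across years by default, per-year optional) and each observation
   takes the midpoint of its interval.  Intervals are half-open except the
   last; duplicate edges from ties are merged with a warning.  Year is a
   discrete stratifier, never binned.  Reference resolution for
   study-scale (~2×10⁵ rows) data: 125 age and 25 SES quantiles.
2. **Per-slice Gamma fits** (`fertgp.gamma_age`).  Within each (SES bin ×
   year) slice, $(\alpha, \beta)$ maximise the binomial log-likelihood of
   the binned cells, $\sum_c [n_{b,c}\log p_c + (n_c - n_{b,c})\log(1-p_c)]$
   with $p_c$ the clamped Gamma rate at the cell's age midpoint.
   Optimisation is quasi-Newton (L-BFGS, analytic gradients) over
   $(\log\alpha, \log\beta)$, started from method-of-moments on the
   birth-weighted age distribution plus 5 jittered restarts, objective
   tolerance $10^{-8}$.  Slices with fewer than 3 occupied cells, no
   births, fewer than `min_slice_trials` (default 50) woman-years, or a
   non-converged optimiser are excluded from smoothing and logged.
3. **GP smoothing** (`fertgp.gp`).  Two Gaussian processes with
   squared-exponential kernels smooth $\log\hat\alpha$ and $\log\hat\beta$
   over slice midpoints $(s_{\text{mid}}, t)$; the log scale enforces
   positivity of the smoothed parameters.  Hyperparameters maximise the
   log marginal likelihood (MAP with a Gamma(shape 6, scale 0.25) prior on
   the SES lengthscale — mode $1.25$ SES units — guarding against
   overfitting); optimisation is L-BFGS with analytic gradients on
   log-hyperparameters, 10 restarts drawn log-uniformly over
   $[10^{-2}, 10^2]$ times data-driven scales.  Factorisations are
   Cholesky with jitter escalating $10^{-10} \to 10^{-6}$; an explicit
   inverse is never formed.  Prediction is the posterior mean.
4. **Composition** (`fertgp.model`).  $p(a, \mathbf{x})$ evaluates the
   clamped Gamma curve at $\alpha = e^{\mu_\alpha(\mathbf{x})}$,
   $\beta = e^{\mu_\beta(\mathbf{x})}$.  Year enters the GP covariate
   vector as a continuous dimension with its own lengthscale, so per-year
   curves are slices of a single surface.  Stratified analyses (e.g.
   refugee status) refit the full pipeline independently per stratum with
   identical covariates and quantile counts.

## Estimator design choices

These choices were genuinely open; each is the package's own resolution,
selected on synthetic benchmarks (truth-surface recovery at ~10⁵ rows,
bootstrap band coverage at ~2×10⁴ rows).

**Shared smoothing weights** (`share_gp_hyperparams=True`, default).  The
slice likelihood pins the curve's peak location $\hat\alpha\hat\beta$
tightly while the shape is noisy, so the errors of $\log\hat\alpha$ and
$\log\hat\beta$ are almost perfectly anti-correlated (measured $r=-0.995$).
If the two GPs smooth with different kernel weights this cancellation is
destroyed in the composed rate.  By default the scale GP reuses the shape
GP's lengthscales and noise/signal ratio (variances rescaled to the scale
targets' spread), making both smoothers apply identical weights; fully
independent hyperparameter fits remain available
(`share_gp_hyperparams=False`).

**Small-sample bias correction** (`bias_correction=True` in
`fit_gamma_slice`).  The Gamma-shape MLE from $N$ births is biased:
$E[\hat\alpha] \approx \alpha(1+3/N)$, and on the log scale (where
smoothing happens) the Jensen term $-\mathrm{var}/2 \approx -1/N$ offsets
part of it, leaving $E[\log\hat\alpha] \approx \log\alpha + 2/N$ (verified
by Monte Carlo at $N$ = 15/35/139: measured bias +0.130/+0.041/+0.015 vs
$2/N$ = 0.134/0.057/0.014).  $\hat\alpha$ is divided by $e^{2/N}$ and
$\hat\beta$ multiplied by it, preserving the well-estimated peak age.  The
correction is negligible for data-rich slices.

**GP mean function** (`gp_mean`).  The pipeline uses the plain zero-mean
process (`"zero"`): with ML hyperparameters the fitted signal variance
absorbs the overall level of the log-parameter targets and the smoother's
weights are implicitly constrained to sum to ~1, which stabilised
smoothing on both benchmarks.  A constant mean profiled out of the
marginal likelihood by generalised least squares (`"constant"`, the
default of the standalone `fit_gp`) is the better-behaved choice for
general regression targets and for near-degenerate designs (e.g. only two
distinct SES values), where the zero-mean process can overshoot between
input clusters.

**GP noise** (`gp_noise`).  Noise variance is estimated by maximum
likelihood (`"ml"`, default).  `"slice-asymptotic"` pins it at the known
sampling variance of the targets ($\approx 2/N_\text{births}$ per slice),
which removes degenerate optima in which sampling noise is re-explained as
short-lengthscale signal.  A smoothing prior on the *year* lengthscale was
tried and rejected: the Gamma prior's exponential tail penalises long
lengthscales and blocks the cross-year pooling the data support.

## Model selection and goodness of fit (`fertgp.selection`)

Candidates (quantile counts, covariate sets) are scored by k-fold
cross-validation (default tenfold): woman-years are partitioned uniformly
at random (a `group_by_woman` switch keeps repeated women in one fold,
since woman-years of one woman are not independent), the full pipeline is
refitted per fold, and held-out rows are scored at their unbinned
covariates with the Brier score.  Goodness of fit is a one-sample KS test
comparing the ages of observed births against the model-implied marginal:
predicted probabilities summed over all observed covariate rows on an age
grid and normalised to a density over age.  This marginal construction is
an interpretation — comparing two rate curves is not a textbook KS setting
— and the asymptotic p-value (with $n$ = number of births) is
approximate; its rejection rate under a correct model measures ~0–10% at
the 5% level.  Candidates with $p <$ level/(number of candidates)
(Bonferroni) are rejected; the minimum-Brier survivor is chosen.

## Uncertainty (`fertgp.bootstrap`)

Parametric bootstrap: per replicate, birth indicators are resimulated as
Bernoulli draws of the fitted probabilities at the observed covariates,
the full pipeline (including GP hyperparameter re-optimisation) is
refitted, and the refitted curve is evaluated on the requested grid.
Bands are pointwise percentiles (2.5/25/50/75/97.5) across replicates;
reference replicate count 1000.  A cheaper `gp-draws` mode samples
$(\log\alpha, \log\beta)$ surfaces from the fitted GP posteriors without
refitting; it reflects GP uncertainty only.  Percentile bands capture
sampling variability but not smoothing bias, so single-dataset 95%-band
coverage of the true curve disperses widely at small n (0.59–0.97 across
probe seeds at ~2×10⁴ rows, mean ≈ 0.82–0.92 depending on configuration);
coverage statements in the tests therefore average over replicate
datasets.

## Synthetic data (`fertgp.simulate`)

The generator emulates the structure of HDSS woman-year tables: six census
years (2001–2011, odd), default 37,440 women per year (~224,640 rows,
matching the study scale the package targets), ages uniform on [10, 55],
SES uniform on [1, 4], no longitudinal correlation between years.  The
default truth has constant scale $\beta = 0.6$ and shape
$\alpha(s, t) = 45 + 0.8(s - 2.5) + 0.15(t - 2006)$, giving a peak age
drifting over 25.2–27.6 across the covariate box and a peak annual rate of
~0.10 — the magnitudes reported for rural South African HDSS populations.
An optional refugee stratum draws from a second truth with a shifted shape
(peak age shifted by $0.6$ years per unit shift) mixed at a configurable
fraction (default 0.3).

What the generator does **not** emulate: a realistic population pyramid or
SES distribution (both uniform), woman-level longitudinal dependence,
migration/mortality, measurement error in ages or SES, and any secondary
(premarital) fertility peak.  Passing recovery tests therefore shows the
estimator is consistent and calibrated *under the model's own assumptions*
on data of realistic size and rate magnitude — not that real fertility
follows a Gamma curve.

All module RNG streams derive from (seed, stage-label) spawn keys, so a
single global seed can safely drive simulation, CV folds, bootstrap draws
and optimiser restarts without stream collisions.

## Problem sizes in tests and the acceptance script

Desk-scale runs use cohorts chosen so each (SES bin × year) slice keeps
roughly ≥30 expected births: ~10⁵ rows with 50 age × 10 SES quantiles for
surface recovery, CV calibration and the shape checks; ~2×10⁴ rows with
40 × 5 for bootstrap coverage (B = 100, three replicate datasets); ~3×10⁴
rows for KS calibration (20 replicates).  The CV-vs-irreducible-score
comparison averages nine replicate censuses because a single comparison at
10⁵ rows carries ~2.6% relative binomial noise, larger than the 2%
agreement it verifies (a power calculation: standard error
$2.6\%/\sqrt{k} \le 1\%$ needs $k \ge 7$).

## Known limitations

- The Gamma age-pattern cannot represent a second fertility peak; the
  binomial likelihood treats binned cells as independent.
- The (α, β) parametrisation is ill-conditioned for slices with few
  births; the shared-weights and bias-correction devices mitigate but do
  not remove this.
- The KS p-value treats the model marginal as fixed although it is
  estimated from the same data, making the test conservative-to-
  approximate rather than exactly calibrated.
- Bootstrap percentile bands do not correct for smoothing bias.
- GP fitting is exact (dense Cholesky) and comfortable up to a few
  thousand slices; no sparse approximations are provided.
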