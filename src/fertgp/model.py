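"""The combined fertility model: per-slice Gamma fits smoothed by GPs.

Pipeline: quantile-bin the woman-year observations (age and SES; year is a
discrete stratifier), fit the Gamma age-pattern by binomial maximum
likelihood within each (SES bin, year) slice, then smooth log alpha-hat and
log beta-hat over the covariate vector x = (SES midpoint, year) with two
Gaussian processes (sharing kernel hyperparameters by default, so the two
smoothers apply identical weights and the strongly anti-correlated slice
errors of shape and scale cancel in the composed rate).  Fitting on the log
scale guarantees the smoothed shape/scale stay positive, so predicted rates
are valid probabilities.

Prediction composes the two GP posterior means with the Gamma curve:

    p(a, x) = GammaRate(a; exp(mu_alpha(x)), exp(mu_beta(x))).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import binning, gamma_age, gp
from .gp import GammaPrior, SES_LENGTHSCALE_PRIOR, YEAR_LENGTHSCALE_PRIOR

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one full pipeline fit.

    ``age_quantiles``/``ses_quantiles`` control the binning resolution
    (reference values: 125 and 25).  ``min_slice_trials`` excludes slices
    with too few woman-years from GP training.  ``seed`` drives every
    stochastic step (optimiser restarts); identical config + data give
    bit-identical models.
    """

    age_quantiles: int = 125
    ses_quantiles: int = 25
    covariates: tuple = ("age", "ses")
    level: float = 0.05
    cv_folds: int = 10
    bootstrap_reps: int = 1000
    ses_prior: GammaPrior | None = SES_LENGTHSCALE_PRIOR
    year_prior: GammaPrior | None = None
    gp_noise: str = "ml"                 # or "slice-asymptotic"
    gp_mean: str = "zero"                # or "constant"
    seed: int = 0
    min_slice_trials: int = 50
    min_slice_cells: int = 3
    gamma_restarts: int = 5
    gp_restarts: int = 10
    per_year_quantiles: bool = False
    share_gp_hyperparams: bool = True

    def __post_init__(self) -> None:
        if self.age_quantiles < 1 or self.ses_quantiles < 1:
            raise ValueError("quantile counts must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")


@dataclass
class FertilityModel:
    """Fitted model mapping (age, SES, year) to an annual birth probability."""

    alpha_gp: gp.GPModel
    beta_gp: gp.GPModel
    bin_spec: binning.BinSpec
    slice_fits: list
    config: FitConfig
    years: tuple = ()

    def alpha_beta(self, ses, year) -> tuple[np.ndarray, np.ndarray]:
        """GP-smoothed Gamma shape and scale at covariate points."""
        ses = np.atleast_1d(np.asarray(ses, dtype=float))
        year = np.atleast_1d(np.asarray(year, dtype=float))
        ses, year = np.broadcast_arrays(ses, year)
        Xq = np.column_stack([ses.ravel(), year.ravel()])
        alpha = np.exp(self.alpha_gp.predict(Xq)).reshape(ses.shape)
        beta = np.exp(self.beta_gp.predict(Xq)).reshape(ses.shape)
        return alpha, beta

    def predict(self, age, ses, year):
        """Fertility probability at (age, ses, year); clamped to [0, 1]."""
        age = np.asarray(age, dtype=float)
        ses = np.asarray(ses, dtype=float)
        year = np.asarray(year, dtype=float)
        age_b, ses_b, year_b = np.broadcast_arrays(age, ses, year)
        alpha, beta = self.alpha_beta(ses_b.ravel(), year_b.ravel())
        from scipy import stats
        with np.errstate(divide="ignore"):
            logp = stats.gamma.logpdf(age_b.ravel(), alpha.ravel(),
                                      scale=beta.ravel())
        out = np.clip(np.exp(np.minimum(logp, 0.0)), 0.0, 1.0 - 1e-9)
        out = out.reshape(age_b.shape)
        return float(out) if out.ndim == 0 else out

    def predict_rows(self, obs: pd.DataFrame) -> np.ndarray:
        """Per-row predicted probabilities at unbinned (age, ses, year)."""
        return self.predict(obs["age"].to_numpy(), obs["ses"].to_numpy(),
                            obs["year"].to_numpy())

    def peak_age(self, ses, year):
        """Age of peak fertility (alpha-1)*beta at covariate points."""
        alpha, beta = self.alpha_beta(ses, year)
        return (alpha - 1.0) * beta

    def slice_table(self) -> pd.DataFrame:
        """Per-slice Gamma fits as a tidy table (diagnostics/export)."""
        rows = [{"ses_mid": sid[0], "year": sid[1], "alpha": p.alpha,
                 "beta": p.beta, "n_eff": p.n_eff, "converged": p.converged}
                for p in self.slice_fits for sid in [p.slice_id]]
        return pd.DataFrame(rows)


def _fit_slices(binned: pd.DataFrame, config: FitConfig) -> list:
    """Gamma fits per (SES midpoint, year) slice of the binned dataset."""
    fits, skipped = [], 0
    for (ses_mid, year), sub in binned.groupby(["ses_mid", "year"]):
        sid = (float(ses_mid), int(year))
        if sub["n_trials"].sum() < config.min_slice_trials:
            skipped += 1
            continue
        try:
            p = gamma_age.fit_gamma_slice(
                sub["age_mid"].to_numpy(), sub["n_trials"].to_numpy(),
                sub["n_births"].to_numpy(), slice_id=sid,
                n_restarts=config.gamma_restarts, seed=config.seed,
                min_cells=config.min_slice_cells)
        except ValueError as exc:
            log.warning("slice %s skipped: %s", sid, exc)
            skipped += 1
            continue
        if not p.converged:
            log.warning("slice %s excluded: optimiser did not converge", sid)
            skipped += 1
            continue
        fits.append(p)
    if skipped:
        log.info("slice fitting: %d fitted, %d skipped/excluded",
                 len(fits), skipped)
    return fits


def fit_fertility_model(obs: pd.DataFrame, config: FitConfig) -> FertilityModel:
    """Fit the full combined model to a woman-year observation table.

    Raises ValueError when fewer than 3 slices yield converged Gamma fits
    (the GPs need at least 3 training points).
    """
    spec = binning.build_bin_spec(
        obs, {"age": config.age_quantiles, "ses": config.ses_quantiles})
    binned = binning.empirical_rates(obs, spec)
    fits = _fit_slices(binned, config)
    if len(fits) < 3:
        raise ValueError(
            f"only {len(fits)} converged slices; need at least 3 for GP smoothing")
    X = np.array([[p.slice_id[0], p.slice_id[1]] for p in fits], dtype=float)
    priors = {}
    if config.ses_prior is not None:
        priors[0] = config.ses_prior
    if config.year_prior is not None:
        priors[1] = config.year_prior
    priors = priors or None
    log_a = np.log([p.alpha for p in fits])
    log_b = np.log([p.beta for p in fits])
    if config.gp_noise == "slice-asymptotic":
        # the targets are ML estimates with known sampling variance
        # (~2/N_births for the log shape of a Gamma curve informed by N
        # births); pinning the GP noise there avoids degenerate optima that
        # re-explain sampling noise as short-lengthscale signal
        fixed_noise = float(np.mean([2.0 / max(p.n_births, 1.0) for p in fits]))
    elif config.gp_noise == "ml":
        fixed_noise = None
    else:
        raise ValueError(f"unknown gp_noise mode {config.gp_noise!r}")
    alpha_gp = gp.fit_gp(X, log_a, priors=priors, seed=config.seed,
                         n_restarts=config.gp_restarts,
                         fixed_noise=fixed_noise, mean=config.gp_mean)
    if config.share_gp_hyperparams:
        # The per-slice errors of log alpha-hat and log beta-hat are almost
        # perfectly anti-correlated (the curve's mode is well determined,
        # its shape is not).  Smoothing both with the same kernel weights
        # preserves that cancellation in the composed rate; the beta GP
        # reuses the alpha GP's lengthscales and noise/signal ratio, with
        # variances rescaled to the beta targets' spread.
        s = max(float(np.var(log_b)) / max(float(np.var(log_a)), 1e-12), 1e-6)
        h = alpha_gp.hyperparams
        hb = replace(h, signal_variance=h.signal_variance * s,
                     noise_variance=max(h.noise_variance * s, 1e-10))
        beta_gp = gp.GPModel(
            X=X, y=log_b, hyperparams=hb,
            mean_offset=0.0 if config.gp_mean == "zero" else None)
    else:
        beta_gp = gp.fit_gp(X, log_b, priors=priors, seed=config.seed + 1,
                            n_restarts=config.gp_restarts,
                            fixed_noise=fixed_noise, mean=config.gp_mean)
    years = tuple(sorted(obs["year"].unique().tolist()))
    return FertilityModel(alpha_gp=alpha_gp, beta_gp=beta_gp, bin_spec=spec,
                          slice_fits=fits, config=config, years=years)


def stratified_fit(obs: pd.DataFrame, flag_column: str,
                   config: FitConfig) -> tuple[FertilityModel, FertilityModel]:
    """Fit the model independently on flag==0 and flag==1 sub-tables.

    Both strata use the same covariates and quantile counts (each stratum's
    quantiles are recomputed from its own rows).  Returns
    (model_flag0, model_flag1).
    """
    flags = obs[flag_column]
    if not flags.isin([0, 1]).all():
        raise ValueError(f"{flag_column} must be binary 0/1")
    sub0 = obs[flags == 0]
    sub1 = obs[flags == 1]
    if len(sub0) == 0 or len(sub1) == 0:
        raise ValueError(f"stratum of {flag_column} is empty")
    return (fit_fertility_model(sub0.reset_index(drop=True), config),
            fit_fertility_model(sub1.reset_index(drop=True), config))


__all__ = [
    "FitConfig",
    "FertilityModel",
    "fit_fertility_model",
    "stratified_fit",
]
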