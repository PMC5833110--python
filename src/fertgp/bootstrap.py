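"""Parametric bootstrap confidence bands for fitted fertility curves.

Each replicate simulates new 0/1 birth indicators at the observed covariate
rows from the fitted model's predicted probabilities, refits the full
pipeline with the same configuration (including GP hyperparameter
re-optimisation), and evaluates the refitted curve on an evaluation grid.
Bands are pointwise percentiles (2.5, 25, 50, 75, 97.5) across replicates,
giving 50% and 95% intervals.

A cheaper alternative mode ("gp-draws") skips the refit and instead draws
log alpha / log beta surfaces from the fitted GP posteriors; it reflects
GP uncertainty only, not slice-fit or binning variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ._rng import derived_rng
from .model import FertilityModel, fit_fertility_model

log = logging.getLogger(__name__)

BAND_LEVELS = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass(frozen=True)
class BootstrapBands:
    """Pointwise percentile bands of the fertility curve on a grid.

    ``grid`` is a DataFrame with columns age, ses, year (one row per
    evaluation point); ``quantiles`` maps band level (percent) to an array
    of curve values over the grid.
    """

    grid: pd.DataFrame
    quantiles: dict
    n_replicates: int
    n_dropped: int
    seed: int
    mode: str = "refit"

    def __post_init__(self) -> None:
        qs = sorted(self.quantiles)
        arrs = np.stack([self.quantiles[q] for q in qs])
        if np.any(np.diff(arrs, axis=0) < -1e-12):
            raise ValueError("band quantiles are not ordered at every point")
        if np.any((arrs < 0) | (arrs > 1)):
            raise ValueError("band values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        for q in sorted(self.quantiles):
            out[f"q{q:g}"] = self.quantiles[q]
        return out


def curve_grid(ages, ses_values, years) -> pd.DataFrame:
    """Cartesian evaluation grid as a tidy (age, ses, year) frame."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    ses_values = np.atleast_1d(np.asarray(ses_values, dtype=float))
    years = np.atleast_1d(np.asarray(years))
    a, s, yr = np.meshgrid(ages, ses_values, years, indexing="ij")
    return pd.DataFrame({"age": a.ravel(), "ses": s.ravel(),
                         "year": yr.ravel().astype(float)})


def _eval_on_grid(model: FertilityModel, grid: pd.DataFrame) -> np.ndarray:
    return model.predict(grid["age"].to_numpy(), grid["ses"].to_numpy(),
                         grid["year"].to_numpy())


def parametric_bootstrap(model: FertilityModel, obs: pd.DataFrame,
                         grid: pd.DataFrame, B: int = 1000, seed: int = 0,
                         mode: str = "refit",
                         max_drop_fraction: float = 0.10) -> BootstrapBands:
    """Bootstrap bands for the fitted curve on an evaluation grid.

    ``mode='refit'`` (default): simulate Y* ~ Bernoulli(p_hat) at the
    observed covariates and refit the full pipeline per replicate.
    ``mode='gp-draws'``: draw (log alpha, log beta) surfaces from the GP
    posteriors instead of refitting.

    Replicates whose refit fails are dropped and counted; more than
    ``max_drop_fraction`` dropped raises RuntimeError.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("refit", "gp-draws"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    rng = derived_rng(seed, "bootstrap")
    curves = []
    dropped = 0
    if mode == "refit":
        p_hat = model.predict_rows(obs)
        for b in range(B):
            sim = obs.copy()
            sim["y"] = (rng.random(len(obs)) < p_hat).astype(np.int64)
            try:
                refit = fit_fertility_model(sim, model.config)
            except (ValueError, RuntimeError) as exc:
                dropped += 1
                log.warning("bootstrap replicate %d dropped: %s", b, exc)
                continue
            curves.append(_eval_on_grid(refit, grid))
    else:
        curves = _gp_draw_curves(model, grid, B, rng)
    if dropped > max_drop_fraction * B:
        raise RuntimeError(
            f"{dropped}/{B} bootstrap replicates failed (> {max_drop_fraction:.0%})")
    if not curves:
        raise RuntimeError("no bootstrap replicate succeeded")
    stack = np.stack(curves)
    quantiles = {q: np.percentile(stack, q, axis=0) for q in BAND_LEVELS}
    return BootstrapBands(grid=grid.reset_index(drop=True), quantiles=quantiles,
                          n_replicates=len(curves), n_dropped=dropped,
                          seed=seed, mode=mode)


def _gp_draw_curves(model: FertilityModel, grid: pd.DataFrame, B: int,
                    rng: np.random.Generator) -> list:
    """Curves from joint GP posterior draws of (log alpha, log beta)."""
    pts = grid[["ses", "year"]].drop_duplicates().to_numpy(dtype=float)
    post_a = model.alpha_gp.posterior(pts)
    post_b = model.beta_gp.posterior(pts)

    def _sampler(post):
        cov = post.cov + 1e-10 * np.eye(len(post.mean))
        L = linalg.cholesky(cov, lower=True)
        return lambda: post.mean + L @ rng.standard_normal(len(post.mean))

    draw_a, draw_b = _sampler(post_a), _sampler(post_b)
    key = {tuple(p): i for i, p in enumerate(map(tuple, pts))}
    idx = np.array([key[(s, y)] for s, y in
                    zip(grid["ses"].to_numpy(dtype=float),
                        grid["year"].to_numpy(dtype=float))])
    ages = grid["age"].to_numpy(dtype=float)
    curves = []
    for _ in range(B):
        alpha = np.exp(draw_a())[idx]
        beta = np.exp(draw_b())[idx]
        with np.errstate(divide="ignore"):
            logp = stats.gamma.logpdf(ages, alpha, scale=beta)
        curves.append(np.clip(np.exp(np.minimum(logp, 0.0)), 0.0, 1.0 - 1e-9))
    return curves


__all__ = [
    "BootstrapBands",
    "BAND_LEVELS",
    "curve_grid",
    "parametric_bootstrap",
]
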