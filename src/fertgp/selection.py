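"""Model selection: cross-validated Brier score and KS goodness of fit.

Candidate configurations (quantile counts, covariate sets) are compared by
tenfold cross-validated Brier score

    S_B = (1/N) * sum_i (Y_i - p_i(a, x))^2,

the mean squared difference between the predicted birth probability and the
observed 0/1 indicator, evaluated on held-out woman-years at their unbinned
covariate values.  Goodness of fit uses a Kolmogorov-Smirnov comparison of
the model-implied marginal age distribution of births against the empirical
age distribution of observed births; candidates with KS p-value below a
Bonferroni-corrected threshold (level / number of candidates) are rejected,
and the minimum-Brier non-rejected candidate is chosen.

The KS construction deserves a note: comparing two fitted rate curves is
not a textbook KS setting.  Here the model marginal is built by summing
predicted probabilities over all observed covariate rows on an age grid and
normalising to a density over age, which is then compared (one-sample KS,
asymptotic p-value with n = number of births) to the ages at which births
were actually observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from ._rng import derived_rng
from .model import FertilityModel, FitConfig, fit_fertility_model

log = logging.getLogger(__name__)


def brier_score(predicted, outcomes) -> float:
    """Mean squared difference between probabilities and 0/1 outcomes."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return float(np.mean((y - p) ** 2))


@dataclass(frozen=True)
class CVResult:
    """Per-fold and pooled cross-validated Brier scores."""

    fold_scores: np.ndarray
    fold_sizes: np.ndarray
    mean_score: float          # pooled over all held-out rows
    folds: int
    seed: int
    failed_folds: int = 0


def cross_validate(obs: pd.DataFrame, config: FitConfig, folds: int = 10,
                   seed: int = 0, group_by_woman: bool = False) -> CVResult:
    """K-fold cross-validated Brier score of the full pipeline.

    Rows (woman-years) are partitioned uniformly at random into ``folds``
    folds; with ``group_by_woman`` all of one woman's rows share a fold
    (repeated women violate row independence).  For each fold the pipeline
    is refitted on the complement and scored on the held-out rows at their
    unbinned (age, ses, year).  The pooled mean weights folds by size.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = derived_rng(seed, "cv")
    n = len(obs)
    if group_by_woman:
        women = obs["woman_id"].unique()
        w_fold = dict(zip(women, rng.integers(0, folds, size=len(women))))
        assign = obs["woman_id"].map(w_fold).to_numpy()
    else:
        assign = rng.integers(0, folds, size=n)
    scores, sizes = [], []
    sum_sq, n_test = 0.0, 0
    failed = 0
    for k in range(folds):
        test = obs[assign == k]
        train = obs[assign != k]
        if len(test) == 0:
            continue
        try:
            m = fit_fertility_model(train.reset_index(drop=True), config)
        except (ValueError, RuntimeError) as exc:
            log.warning("fold %d fit failed: %s", k, exc)
            failed += 1
            scores.append(np.nan)
            sizes.append(len(test))
            continue
        p = m.predict_rows(test)
        y = test["y"].to_numpy(dtype=float)
        scores.append(float(np.mean((y - p) ** 2)))
        sizes.append(len(test))
        sum_sq += float(np.sum((y - p) ** 2))
        n_test += len(test)
    if n_test == 0:
        raise RuntimeError("every cross-validation fold failed to fit")
    return CVResult(fold_scores=np.asarray(scores), fold_sizes=np.asarray(sizes),
                    mean_score=sum_sq / n_test, folds=folds, seed=seed,
                    failed_folds=failed)


def ks_age_marginal(model: FertilityModel, obs: pd.DataFrame,
                    grid_size: int = 200) -> tuple[float, float]:
    """KS statistic and p-value for the model's marginal age-pattern.

    Empirical sample: ages of woman-years with an observed birth.  Model
    distribution: predicted birth probability summed over all observed
    covariate rows on an age grid spanning the observed ages, normalised to
    a density over age.  The statistic is the sup distance between the two
    CDFs; the p-value uses the asymptotic one-sample KS distribution with
    n = number of births.
    """
    birth_ages = obs.loc[obs["y"] == 1, "age"].to_numpy(dtype=float)
    n_births = birth_ages.size
    if n_births == 0:
        raise ValueError("no births in the observation table")
    lo, hi = float(obs["age"].min()), float(obs["age"].max())
    grid = np.linspace(lo, hi, grid_size)
    ses = obs["ses"].to_numpy(dtype=float)
    year = obs["year"].to_numpy(dtype=float)
    alpha, beta = model.alpha_beta(ses, year)
    with np.errstate(divide="ignore"):
        logp = stats.gamma.logpdf(grid[:, None], alpha[None, :],
                                  scale=beta[None, :])
    p = np.clip(np.exp(np.minimum(logp, 0.0)), 0.0, 1.0)
    weight = p.sum(axis=1)                         # expected births per age
    cdf_grid = integrate.cumulative_trapezoid(weight, grid, initial=0.0)
    total = cdf_grid[-1]
    if total <= 0:
        raise ValueError("model marginal has zero mass on the age grid")
    cdf_grid /= total
    model_cdf = np.interp(np.sort(birth_ages), grid, cdf_grid)
    ecdf_hi = np.arange(1, n_births + 1) / n_births
    ecdf_lo = np.arange(0, n_births) / n_births
    stat = float(np.max(np.maximum(np.abs(ecdf_hi - model_cdf),
                                   np.abs(model_cdf - ecdf_lo))))
    pval = float(stats.kstwobign.sf(np.sqrt(n_births) * stat))
    return stat, min(max(pval, 0.0), 1.0)


@dataclass(frozen=True)
class CandidateResult:
    config: FitConfig
    mean_brier: float
    fold_scores: np.ndarray
    ks_stat: float
    ks_p: float
    rejected: bool
    error: str | None = None


@dataclass(frozen=True)
class ModelSelectionReport:
    """Full record of a model-selection run."""

    candidates: list
    threshold: float
    level: float
    chosen_index: int | None

    @property
    def chosen(self) -> CandidateResult | None:
        return None if self.chosen_index is None else self.candidates[self.chosen_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.candidates):
            rows.append({
                "candidate": i,
                "age_q": c.config.age_quantiles,
                "ses_q": c.config.ses_quantiles,
                "mean_brier": c.mean_brier,
                "ks_stat": c.ks_stat,
                "ks_p": c.ks_p,
                "rejected": c.rejected,
                "chosen": i == self.chosen_index,
                "error": c.error or "",
            })
        return pd.DataFrame(rows)


def select_model(obs: pd.DataFrame, candidates: list, level: float = 0.05,
                 seed: int = 0, folds: int = 10) -> ModelSelectionReport:
    """Evaluate candidate configs and choose by Brier among non-rejected.

    Every candidate gets a cross-validated Brier score and a KS p-value
    from a fit on the full table.  The Bonferroni threshold is
    ``level / len(candidates)``; a candidate is rejected when its KS p falls
    below it.  The chosen config minimises the pooled Brier among
    non-rejected candidates; a report with ``chosen_index=None`` is returned
    when all are rejected or failed.
    """
    if not candidates:
        raise ValueError("need at least one candidate config")
    threshold = level / len(candidates)
    results = []
    for i, config in enumerate(candidates):
        try:
            cv = cross_validate(obs, config, folds=folds, seed=seed + i)
            full = fit_fertility_model(obs, config)
            stat, pval = ks_age_marginal(full, obs)
            results.append(CandidateResult(
                config=config, mean_brier=cv.mean_score,
                fold_scores=cv.fold_scores, ks_stat=stat, ks_p=pval,
                rejected=bool(pval < threshold)))
        except (ValueError, RuntimeError) as exc:
            log.warning("candidate %d failed: %s", i, exc)
            results.append(CandidateResult(
                config=config, mean_brier=np.inf, fold_scores=np.array([]),
                ks_stat=np.nan, ks_p=np.nan, rejected=True, error=str(exc)))
    viable = [i for i, r in enumerate(results)
              if not r.rejected and np.isfinite(r.mean_brier)]
    chosen = min(viable, key=lambda i: results[i].mean_brier) if viable else None
    if chosen is None:
        log.warning("model selection: all %d candidates rejected or failed",
                    len(candidates))
    return ModelSelectionReport(candidates=results, threshold=threshold,
                                level=level, chosen_index=chosen)


def bayes_brier(true_rates) -> float:
    """The irreducible Brier score (1/N) sum p(1-p) of a known truth."""
    p = np.asarray(true_rates, dtype=float)
    return float(np.mean(p * (1.0 - p)))


__all__ = [
    "brier_score",
    "bayes_brier",
    "cross_validate",
    "CVResult",
    "ks_age_marginal",
    "select_model",
    "CandidateResult",
    "ModelSelectionReport",
]
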