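"""Synthetic woman-year tables from a known ground-truth fertility surface.

Emulates the structure of HDSS census-round data: one row per woman per
census year, with age at midyear, a continuous household socio-economic
status (SES) index, an optional refugee flag, and a binary live-birth
indicator drawn as Bernoulli with success probability given by a Gamma
age-pattern whose shape/scale vary smoothly over (SES, year).

The generator is the test bed for the whole pipeline: every downstream
stage can be checked against the truth surface it was generated from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derived_rng

log = logging.getLogger(__name__)

OBS_COLUMNS = ["woman_id", "year", "age", "ses", "refugee", "education", "y"]

DEFAULT_YEARS = (2001, 2003, 2005, 2007, 2009, 2011)


@dataclass
class GroundTruth:
    """A known fertility surface: alpha(x), beta(x) over (SES, year).

    ``alpha_fn`` and ``beta_fn`` take (ses, year) arrays and return strictly
    positive shape/scale values.  Ages and SES are sampled from the stated
    marginals (uniform by default; the real population pyramid is not
    emulated) independently each year.
    """

    alpha_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    beta_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    age_range: tuple[float, float] = (10.0, 55.0)
    ses_range: tuple[float, float] = (1.0, 4.0)
    years: Sequence[int] = DEFAULT_YEARS
    cohort_sizes: Sequence[int] | int = 5000
    age_sampler: Callable | None = None   # rng, n -> ages
    ses_sampler: Callable | None = None   # rng, n -> ses
    label: str = "truth"

    def cohort_size_list(self) -> list[int]:
        if np.isscalar(self.cohort_sizes):
            return [int(self.cohort_sizes)] * len(self.years)
        sizes = [int(s) for s in self.cohort_sizes]
        if len(sizes) != len(self.years):
            raise ValueError("cohort_sizes length must match years")
        return sizes

    def rate(self, age, ses, year):
        """True fertility probability at (age, ses, year), clamped to [0, 1]."""
        age, ses, year = np.broadcast_arrays(
            np.asarray(age, dtype=float), np.asarray(ses, dtype=float),
            np.asarray(year, dtype=float))
        alpha = np.broadcast_to(
            np.asarray(self.alpha_fn(ses, year), dtype=float), age.shape)
        beta = np.broadcast_to(
            np.asarray(self.beta_fn(ses, year), dtype=float), age.shape)
        out = _clamped_rate_vec(age, alpha, beta)
        return out if out.ndim else float(out)

    def validate(self, n_probe: int = 25) -> None:
        """Probe alpha/beta over the covariate box; reject bad surfaces."""
        ses = np.linspace(*self.ses_range, n_probe)
        for year in self.years:
            yv = np.full(n_probe, float(year))
            a = np.asarray(self.alpha_fn(ses, yv), dtype=float)
            b = np.asarray(self.beta_fn(ses, yv), dtype=float)
            for name, v in (("alpha", a), ("beta", b)):
                if np.any(~np.isfinite(v)) or np.any(v <= 0):
                    raise ValueError(
                        f"{name}_fn returned non-positive/non-finite values "
                        f"for year {year}")


def make_default_truth(cohort_size: int = 37440, refugee_shift: float = 0.0,
                       label: str = "default") -> GroundTruth:
    """Default synthetic fertility surface.

    Calibrated so that the age-pattern peaks between ages 25 and 30 with a
    peak annual birth probability near 0.10, the magnitude seen in rural
    South African HDSS populations, with weak SES dependence and a mild
    upward trend of the shape parameter over calendar time.  ``beta`` is
    held constant; ``alpha`` is linear in SES and year.

    ``refugee_shift`` adds a constant to alpha, shifting the peak age by
    ``0.6 * refugee_shift`` years — used to build distinguishable strata.
    """
    beta0 = 0.6

    def alpha_fn(ses, year):
        ses = np.asarray(ses, dtype=float)
        year = np.asarray(year, dtype=float)
        return 45.0 + 0.8 * (ses - 2.5) + 0.15 * (year - 2006.0) + refugee_shift

    def beta_fn(ses, year):
        ses = np.asarray(ses, dtype=float)
        return np.full_like(ses, beta0)

    return GroundTruth(alpha_fn=alpha_fn, beta_fn=beta_fn,
                       cohort_sizes=cohort_size, label=label)


def simulate_population(truth: GroundTruth, seed: int,
                        refugee_truth: GroundTruth | None = None,
                        refugee_fraction: float = 0.3,
                        id_offset: int = 0) -> pd.DataFrame:
    """Draw a woman-year observation table from a ground-truth surface.

    For each census year, ``cohort_sizes[k]`` women are drawn independently
    (no longitudinal correlation between years — woman-years are treated as
    independent observations).  Ages and SES come from the truth's samplers
    (uniform over the stated ranges by default), and the live-birth
    indicator is Bernoulli with the truth's clamped Gamma rate.

    If ``refugee_truth`` is given, a fraction ``refugee_fraction`` of each
    cohort is drawn from it instead and flagged ``refugee=1``.

    Identical (truth, seed) gives a bit-identical table.
    """
    truth.validate()
    if refugee_truth is not None:
        refugee_truth.validate()
    rng = derived_rng(seed, "simulate")
    frames = []
    next_id = id_offset
    for year, size in zip(truth.years, truth.cohort_size_list()):
        if refugee_truth is not None:
            n_ref = int(round(size * refugee_fraction))
        else:
            n_ref = 0
        parts = [(truth, size - n_ref, 0)]
        if n_ref:
            parts.append((refugee_truth, n_ref, 1))
        for src, n, flag in parts:
            if n <= 0:
                continue
            if src.age_sampler is not None:
                age = np.asarray(src.age_sampler(rng, n), dtype=float)
            else:
                age = rng.uniform(*src.age_range, size=n)
            if src.ses_sampler is not None:
                ses = np.asarray(src.ses_sampler(rng, n), dtype=float)
            else:
                ses = rng.uniform(*src.ses_range, size=n)
            yv = np.full(n, float(year))
            alpha = np.asarray(src.alpha_fn(ses, yv), dtype=float)
            beta = np.asarray(src.beta_fn(ses, yv), dtype=float)
            p = _clamped_rate_vec(age, alpha, beta)
            y = (rng.random(n) < p).astype(np.int64)
            frames.append(pd.DataFrame({
                "woman_id": np.arange(next_id, next_id + n, dtype=np.int64),
                "year": np.full(n, int(year), dtype=np.int64),
                "age": age,
                "ses": ses,
                "refugee": np.full(n, flag, dtype=np.int64),
                "education": np.full(n, np.nan),
                "y": y,
            }))
            next_id += n
    obs = pd.concat(frames, ignore_index=True)
    log.info("simulated %d woman-years over %d census years",
             len(obs), len(truth.years))
    return obs


def _clamped_rate_vec(age: np.ndarray, alpha: np.ndarray,
                      beta: np.ndarray) -> np.ndarray:
    """Vectorised clamped Gamma rate (log-space, clamp below 1)."""
    with np.errstate(divide="ignore"):
        logp = stats.gamma.logpdf(age, alpha, scale=beta)
    n_over = int(np.count_nonzero(logp > 0))
    if n_over:
        log.warning("rate clamp applied to %d draw(s) with density > 1", n_over)
    return np.clip(np.exp(np.minimum(logp, 0.0)), 0.0, 1.0 - 1e-9)


def validate_observations(obs: pd.DataFrame) -> None:
    """Check the observation-table invariants; raise ValueError on failure."""
    missing = [c for c in ("woman_id", "year", "age", "ses", "y")
               if c not in obs.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for c in ("age", "ses", "y"):
        if obs[c].isna().any():
            raise ValueError(f"column {c} contains missing values")
    if (obs["age"] < 0).any() or ~np.isfinite(obs["age"]).all():
        raise ValueError("ages must be finite and non-negative")
    if not obs["y"].isin([0, 1]).all():
        raise ValueError("y must be binary")
    if obs.duplicated(subset=["woman_id", "year"]).any():
        raise ValueError("duplicate (woman_id, year) rows")


def write_observations(obs: pd.DataFrame, path, header_lines=()) -> None:
    """Write a headered CSV observation table (columns in canonical order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        obs.loc[:, OBS_COLUMNS].to_csv(fh, index=False)


def read_observations(path) -> pd.DataFrame:
    """Read a CSV observation table, skipping '#' header lines."""
    obs = pd.read_csv(path, comment="#")
    validate_observations(obs)
    return obs


__all__ = [
    "GroundTruth",
    "make_default_truth",
    "simulate_population",
    "validate_observations",
    "write_observations",
    "read_observations",
    "OBS_COLUMNS",
    "DEFAULT_YEARS",
]
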