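"""Quantile binning of covariates and empirical per-cell fertility rates.

To turn the 0/1 birth indicators into a regression target, observations are
binned by empirical quantiles of each continuous covariate (age, SES; year
is a discrete stratifier and is never binned).  Each observation's covariate
value is replaced by the midpoint of its quantile interval, and the
empirical fertility rate of a cell is the fraction of its woman-years with
a live birth.

Quantiles use linear interpolation between order statistics.  Intervals are
half-open [lower, upper) except the last, which is closed.  Heavy ties can
produce duplicate quantile edges; affected bins are merged with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BINNED_COLUMNS = ["age_mid", "ses_mid", "year", "n_trials", "n_births", "rate"]


@dataclass(frozen=True)
class CovariateBins:
    """Quantile bins for one covariate: edges and interval midpoints."""

    name: str
    q: int
    edges: np.ndarray        # length nbins+1, strictly increasing
    midpoints: np.ndarray    # length nbins

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("edges must be a 1-d array of length >= 2")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing after merging")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "midpoints",
                           np.asarray(self.midpoints, dtype=float))

    @property
    def nbins(self) -> int:
        return self.edges.size - 1

    def assign(self, values) -> np.ndarray:
        """Map values to their bin midpoints.

        Values outside [edges[0], edges[-1]] are clipped into the outer bins
        so that every observation maps to exactly one bin.
        """
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.edges, v, side="right") - 1
        idx = np.clip(idx, 0, self.nbins - 1)
        return self.midpoints[idx]


@dataclass(frozen=True)
class BinSpec:
    """Per-covariate quantile bins used to build the regression dataset."""

    covariates: dict = field(default_factory=dict)  # name -> CovariateBins

    def __getitem__(self, name: str) -> CovariateBins:
        return self.covariates[name]

    @property
    def quantile_counts(self) -> dict:
        return {k: v.q for k, v in self.covariates.items()}


def quantile_bin(values, q: int, name: str = "x") -> CovariateBins:
    """Build q-quantile bins for one covariate.

    Edges are the empirical quantiles at probabilities k/q, k = 0..q, with
    linear interpolation.  Duplicate edges (heavy ties) are merged; the
    degenerate all-equal case yields a single bin whose midpoint equals the
    common value.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError(f"cannot bin empty values for covariate {name!r}")
    if q < 1:
        raise ValueError("q must be >= 1")
    probs = np.linspace(0.0, 1.0, q + 1)
    edges = np.quantile(v, probs, method="linear")
    uniq = np.unique(edges)
    if uniq.size < edges.size:
        log.warning("covariate %s: %d duplicate quantile edge(s) merged",
                    name, edges.size - uniq.size)
    if uniq.size == 1:
        # all values identical: a single degenerate bin
        val = float(uniq[0])
        eps = max(abs(val), 1.0) * 1e-9
        return CovariateBins(name=name, q=q,
                             edges=np.array([val - eps, val + eps]),
                             midpoints=np.array([val]))
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    return CovariateBins(name=name, q=q, edges=uniq, midpoints=mids)


def build_bin_spec(obs: pd.DataFrame, quantile_counts: dict,
                   per_year: bool = False) -> BinSpec | dict:
    """Build a BinSpec from observations.

    ``quantile_counts`` maps covariate column names (e.g. ``age``, ``ses``)
    to quantile counts.  With ``per_year=True`` a separate BinSpec is built
    from each census year's rows (returned as {year: BinSpec}); default is
    pooled across years.
    """
    if per_year:
        return {int(yr): build_bin_spec(sub, quantile_counts)
                for yr, sub in obs.groupby("year")}
    cov = {name: quantile_bin(obs[name].to_numpy(), q, name=name)
           for name, q in quantile_counts.items()}
    return BinSpec(covariates=cov)


def empirical_rates(obs: pd.DataFrame, spec: BinSpec) -> pd.DataFrame:
    """Aggregate observations into binned cells with empirical rates.

    One row per occupied (age bin x SES bin x year) cell, with columns
    ``age_mid, ses_mid, year, n_trials, n_births, rate``.  Trials and births
    are conserved: their totals equal the row count and birth count of
    ``obs``.
    """
    work = pd.DataFrame({
        "year": obs["year"].to_numpy(),
        "y": obs["y"].to_numpy(),
    })
    keys = ["year"]
    for name, bins in spec.covariates.items():
        col = f"{name}_mid"
        work[col] = bins.assign(obs[name].to_numpy())
        keys.append(col)
    g = work.groupby(keys, sort=True)["y"].agg(n_trials="size", n_births="sum")
    out = g.reset_index()
    out["rate"] = out["n_births"] / out["n_trials"]
    cols = [f"{n}_mid" for n in spec.covariates] + ["year",
                                                    "n_trials", "n_births", "rate"]
    return out.loc[:, cols]


def write_binned(binned: pd.DataFrame, path, header_lines=()) -> None:
    """Write a binned dataset as headered CSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        binned.to_csv(fh, index=False)


__all__ = [
    "CovariateBins",
    "BinSpec",
    "quantile_bin",
    "build_bin_spec",
    "empirical_rates",
    "write_binned",
    "BINNED_COLUMNS",
]
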