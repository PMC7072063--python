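"""Time-resolved population-heterogeneity statistics.

Works on a *fraction table*: a DataFrame indexed by time (h) with one column
per population holding its share in percent of gated cells.  Provides

* total vs individual population change between a baseline and a final
  window of samples,
* the sum of absolute total changes (a scalar heterogeneity-shift index),
* broken-stick lag + exponential growth fitting of density series,
* assembly of per-sample gating tables and bulk culture measurements into
  one population time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GrowthFit:
    """Result of a broken-stick (lag + exponential) fit on log density.

    ``lag`` is the breakpoint time (h) between the flat segment and the
    exponential segment, ``mu`` the post-lag specific growth rate (h^-1),
    ``level`` the fitted log density of the flat segment, ``rss`` the
    residual sum of squares on log density, ``n_post_lag`` the number of
    points strictly after the breakpoint and ``no_growth`` a flag raised
    when the best fit has a non-positive slope.
    """

    lag: float
    mu: float
    level: float
    rss: float
    n_post_lag: int
    no_growth: bool = False


def population_change(
    series: pd.DataFrame, baseline_n: int = 3, final_n: int = 3
) -> pd.DataFrame:
    """Total (percentage points) and individual (%) change per population.

    The baseline window is the first ``baseline_n`` samples, the final
    window the last ``final_n`` samples; they must not overlap.  The total
    change is ``mean(final) - mean(baseline)`` in percentage points of all
    gated cells; the individual change expresses the same shift relative to
    the population's own baseline share,
    ``100 * total_change / mean(baseline)``.
    """
    if baseline_n < 1 or final_n < 1:
        raise ValueError("windows must contain at least one sample each")
    if baseline_n + final_n > len(series):
        raise ValueError("baseline and final windows overlap")
    base = series.iloc[:baseline_n].mean(axis=0)
    final = series.iloc[-final_n:].mean(axis=0)
    total = final - base
    if (base == 0).any():
        raise ZeroDivisionError("baseline mean fraction is zero for some population")
    individual = 100.0 * total / base
    return pd.DataFrame(
        {
            "baseline_pct": base,
            "total_change_pts": total,
            "individual_change_pct": individual,
        }
    ).rename_axis("population")


def sum_abs_changes(
    series: pd.DataFrame, baseline_n: int = 3, final_n: int = 3
) -> float:
    """Sum over populations of |total change|, in percentage points."""
    if series.shape[1] < 2:
        raise ValueError("needs at least two populations")
    change = population_change(series, baseline_n, final_n)
    return float(change["total_change_pts"].abs().sum())


def fit_lag_exponential(times, densities) -> GrowthFit:
    """Fit a flat-then-exponential (broken-stick) model to a density series.

    On log density the model is a horizontal segment (the lag phase at the
    inoculation level) followed by a straight line of slope ``mu``.  The
    breakpoint is searched over the observed sample times (a discrete grid
    search); for each candidate the level and slope are obtained by linear
    least squares on the basis ``[1, max(0, t - t_b)]``, and the candidate
    with the smallest residual sum of squares wins.  A breakpoint at the
    first sample time corresponds to growth without lag.

    Requires at least 5 time points and strictly positive densities.
    Emits a warning when fewer than 3 points lie after the fitted
    breakpoint; sets ``no_growth`` when the fitted slope is <= 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(densities, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and densities must be 1-D and equally long")
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(y <= 0):
        raise ValueError("densities must be > 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    logy = np.log(y)
    best = None
    # candidates leave >= 2 points strictly after the breakpoint so the
    # slope is identified
    for tb in t[: len(t) - 2]:
        ramp = np.maximum(0.0, t - tb)
        X = np.column_stack([np.ones_like(t), ramp])
        coef, *_ = np.linalg.lstsq(X, logy, rcond=None)
        rss = float(((X @ coef - logy) ** 2).sum())
        if best is None or rss < best[0] - 1e-15:
            best = (rss, tb, coef)
    rss, lag, (level, mu) = best
    n_post = int((t > lag).sum())
    if n_post < 3:
        warnings.warn("fewer than 3 post-lag points; growth-rate fit unreliable")
    return GrowthFit(
        lag=float(lag),
        mu=float(mu),
        level=float(level),
        rss=rss,
        n_post_lag=n_post,
        no_growth=bool(mu <= 0),
    )


def fit_populations(density_table: pd.DataFrame) -> pd.DataFrame:
    """Broken-stick fit per population column of a density table.

    Returns a table (population, lag_h, mu_per_h, rss).
    """
    rows = []
    for pop in density_table.columns:
        fit = fit_lag_exponential(density_table.index.to_numpy(), density_table[pop])
        rows.append(
            {"population": pop, "lag_h": fit.lag, "mu_per_h": fit.mu, "rss": fit.rss}
        )
    return pd.DataFrame(rows)


def assemble_timeseries(
    population_tables: list[pd.DataFrame],
    culture: pd.DataFrame | None = None,
    provenance: str = "offline",
) -> pd.DataFrame:
    """Combine per-sample gating tables into one population time series.

    ``population_tables`` are tables with columns (sample_id, time_h,
    population, fraction_pct) as emitted per sample; ``culture`` optionally
    supplies bulk viable density (columns time_h, X_v_per_ml) so that
    per-population viable densities (``density_per_ml`` = X_v * fraction /
    100) can be attached.  Input order does not matter; duplicate times
    with conflicting fractions raise.

    Returns a tidy DataFrame (time_h, population, fraction_pct
    [, density_per_ml], provenance) sorted by time.
    """
    tidy = pd.concat(population_tables, ignore_index=True)
    required = {"time_h", "population", "fraction_pct"}
    if not required <= set(tidy.columns):
        raise ValueError(f"population tables need columns {sorted(required)}")
    dup = tidy.groupby(["time_h", "population"])["fraction_pct"].nunique()
    if (dup > 1).any():
        raise ValueError("conflicting fractions at the same time point")
    tidy = (
        tidy.drop_duplicates(["time_h", "population"])
        .sort_values(["time_h", "population"])
        .reset_index(drop=True)
    )
    if culture is not None:
        xv = culture.set_index("time_h")["X_v_per_ml"]
        tidy["density_per_ml"] = (
            xv.reindex(tidy["time_h"]).to_numpy() * tidy["fraction_pct"].to_numpy() / 100.0
        )
    tidy["provenance"] = provenance
    return tidy[[c for c in ("time_h", "population", "fraction_pct", "density_per_ml", "provenance") if c in tidy.columns]]


def fraction_table(tidy: pd.DataFrame, value: str = "fraction_pct") -> pd.DataFrame:
    """Pivot a tidy series into a time-by-population table."""
    return tidy.pivot(index="time_h", columns="population", values=value)
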