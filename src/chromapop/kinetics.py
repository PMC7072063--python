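"""Cell-specific rate estimation from two-point concentration differences.

For consecutive sampling times t_i, t_{i+1} the cell-specific rate of an
analyte is the concentration difference per hour, normalized by the
trapezoidal mean viable cell density:

    q = (c_i - c_{i+1}) / (t_{i+1} - t_i) * 2 / (X_v,i + X_v,i+1)   (consumption)
    q = (c_{i+1} - c_i) / (t_{i+1} - t_i) * 2 / (X_v,i + X_v,i+1)   (production)

Internally X_v is in cells per liter and concentrations in mmol/l (mg/l for
antibody), so rates come out in mmol (or mg) per cell per hour, matching the
1e-10 .. 1e-11 magnitudes typical for CHO cultures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: default sign convention per analyte column
ANALYTE_MODES = {
    "c_Glc": "consumption",
    "c_Gln": "consumption",
    "c_Lac": "production",
    "c_Amm": "production",
    "c_Ab": "production",
}


def specific_rate(
    series: pd.DataFrame,
    analyte: str,
    mode: str = "auto",
    passage_times: list[float] | None = None,
    exclude_intervals: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-interval cell-specific rates for one analyte.

    Parameters
    ----------
    series
        Culture time course with columns ``time_h``, ``X_v_per_l`` and the
        analyte column (e.g. ``c_Glc``); times strictly increasing.
    analyte
        Analyte column name.
    mode
        "consumption", "production" or "auto" (sign convention looked up
        from :data:`ANALYTE_MODES`).
    passage_times
        Culture-transfer times (h).  Intervals spanning a passage are
        excluded because the concentration is reset by the medium exchange.
    exclude_intervals
        Additional ``(t_start, t_end)`` intervals to drop (e.g. rates judged
        unreliable and bracketed out of a report).

    Returns
    -------
    DataFrame with columns (t_start_h, t_end_h, t_mid_h, q); q in mmol (or
    mg) per cell per hour.
    """
    if mode == "auto":
        try:
            mode = ANALYTE_MODES[analyte]
        except KeyError:
            raise ValueError(f"no default mode for analyte {analyte!r}") from None
    if mode not in ("consumption", "production"):
        raise ValueError(f"unknown mode {mode!r}")
    for col in ("time_h", "X_v_per_l", analyte):
        if col not in series.columns:
            raise KeyError(f"series missing column {col!r}")
    t = series["time_h"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least two timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    c = series[analyte].to_numpy(float)
    xv = series["X_v_per_l"].to_numpy(float)

    dt = np.diff(t)
    mean_xv = 0.5 * (xv[:-1] + xv[1:])
    if np.any(mean_xv <= 0):
        raise ValueError("mean viable density must be > 0 on every interval")
    dc = c[:-1] - c[1:] if mode == "consumption" else c[1:] - c[:-1]
    q = dc / dt / mean_xv

    out = pd.DataFrame(
        {
            "t_start_h": t[:-1],
            "t_end_h": t[1:],
            "t_mid_h": 0.5 * (t[:-1] + t[1:]),
            "q": q,
        }
    )
    keep = np.ones(len(out), dtype=bool)
    for tp in passage_times or []:
        keep &= ~((out["t_start_h"] < tp) & (out["t_end_h"] > tp))
    for lo, hi in exclude_intervals or []:
        keep &= ~(np.isclose(out["t_start_h"], lo) & np.isclose(out["t_end_h"], hi))
    return out.loc[keep].reset_index(drop=True)


def rate_table(
    series: pd.DataFrame,
    analytes: dict[str, str] | None = None,
    passage_times: list[float] | None = None,
) -> pd.DataFrame:
    """Rates for several analytes on a common interval grid.

    Returns columns (t_mid_h, q_Glc, q_Lac, q_Ab, ...) named ``q_<suffix>``
    from the analyte column names.
    """
    analytes = analytes or {a: "auto" for a in ANALYTE_MODES if a in series.columns}
    out = None
    for analyte, mode in analytes.items():
        r = specific_rate(series, analyte, mode, passage_times=passage_times)
        col = "q_" + analyte.removeprefix("c_")
        r = r[["t_mid_h", "q"]].rename(columns={"q": col})
        out = r if out is None else out.merge(r, on="t_mid_h", how="outer")
    return out


def relative_change(value_start: float, value_end: float, mode: str = "delta") -> float:
    """Relative change between two values, in percent.

    ``mode="delta"`` returns ``100 * (end - start) / start`` (a +20% change
    reads as 20); ``mode="ratio"`` returns ``100 * end / start`` (the "rose
    to 220% of its initial value" convention).
    """
    if value_start == 0:
        raise ZeroDivisionError("relative change undefined for zero start value")
    if mode == "delta":
        return 100.0 * (value_end - value_start) / value_start
    if mode == "ratio":
        return 100.0 * value_end / value_start
    raise ValueError(f"unknown mode {mode!r}")
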