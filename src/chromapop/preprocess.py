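"""Event-level preprocessing: scatter gating, compensation, bounded log normalization.

The processing order is debris exclusion (SSC-A vs FSC-A rectangle) ->
doublet exclusion (FSC-H/FSC-A ratio) -> spillover compensation ->
bounded log normalization onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelConfig, SCATTER_COLUMNS
from .sample import FlowSample


class EmptySampleError(ValueError):
    """All events were excluded by a gate."""


@dataclass(frozen=True)
class ScatterGate:
    """Rectangular debris gate plus a singlet ratio band.

    Events survive when FSC-A and SSC-A fall inside the rectangle and the
    FSC-H / FSC-A ratio lies within ``[ratio_min, ratio_max]`` (doublets
    have roughly doubled FSC-A at unchanged FSC-H, i.e. ratio ~ 0.5).
    """

    fsc_a: tuple[float, float] = (1e5, 4e6)
    ssc_a: tuple[float, float] = (1e4, 4e6)
    ratio_min: float = 0.8
    ratio_max: float = 1.2


def exclude_debris_doublets(
    sample: FlowSample, gate: ScatterGate | None = None
) -> tuple[FlowSample, dict[str, int]]:
    """Remove debris and doublets; return the filtered sample and exclusion counts.

    Raises
    ------
    KeyError
        if a scatter column is missing.
    EmptySampleError
        if no event survives the gates.
    """
    gate = gate or ScatterGate()
    ev = sample.events
    for col in SCATTER_COLUMNS:
        if col not in ev.columns:
            raise KeyError(f"scatter column {col!r} missing from event table")

    fsc_a = ev["FSC-A"].to_numpy(float)
    ssc_a = ev["SSC-A"].to_numpy(float)
    in_rect = (
        (fsc_a >= gate.fsc_a[0])
        & (fsc_a <= gate.fsc_a[1])
        & (ssc_a >= gate.ssc_a[0])
        & (ssc_a <= gate.ssc_a[1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ev["FSC-H"].to_numpy(float) / fsc_a
    singlet = (ratio >= gate.ratio_min) & (ratio <= gate.ratio_max)

    n_debris = int((~in_rect).sum())
    # doublets counted among events that passed the debris rectangle
    n_doublets = int((in_rect & ~singlet).sum())
    keep = in_rect & singlet
    if not keep.any():
        raise EmptySampleError("all events excluded by scatter gates")
    counts = {"debris": n_debris, "doublets": n_doublets, "retained": int(keep.sum())}
    return sample.with_events(ev.loc[keep].reset_index(drop=True)), counts


def apply_spillover(events: pd.DataFrame, panel: PanelConfig) -> pd.DataFrame:
    """Add spillover to true signals (the forward model that compensation undoes).

    Terms are applied in reverse panel order on the *true* source signal, so
    that sequential compensation in panel order inverts the result exactly.
    """
    out = events.copy()
    for target, source, coeff in reversed(panel.spillover):
        out[target] = out[target] + coeff * events[source]
    return out


def compensate(
    sample: FlowSample,
    panel: PanelConfig,
    floor: float = 1.0,
    sequential: bool = True,
) -> FlowSample:
    """Subtract spillover from each target channel.

    With ``sequential=True`` (default) each term uses the source channel as
    already compensated by earlier terms, i.e. the panel's ordered terms form
    a triangular spillover system.  ``sequential=False`` uses raw source
    values throughout.  Results are floored at ``floor`` (raw units, default
    1) so subsequent log transforms remain defined; the floor sits below any
    positivity threshold, so classification is unaffected.

    Raises
    ------
    ValueError
        if the sample is already compensated.
    """
    if sample.compensated:
        raise ValueError("sample is already compensated")
    ev = sample.events.copy()
    raw = sample.events
    for target, source, coeff in panel.spillover:
        src = ev[source] if sequential else raw[source]
        ev[target] = ev[target] - coeff * src
    for ch in {t for t, _, _ in panel.spillover}:
        ev[ch] = ev[ch].clip(lower=floor)
    return sample.with_events(ev, compensated=True)


def normalize_intensity(
    intensity,
    lower: float,
    upper: float,
    ascending: bool = True,
    base: float = 10.0,
    clip: bool = True,
):
    """Bounded log normalization of raw intensity onto [0, 1].

    In ascending mode (default) ``I_lower`` maps to 0 and ``I_upper`` to 1::

        I_norm = (log I - log I_lower) / (log I_upper - log I_lower)

    ``ascending=False`` selects the complementary, descending orientation
    (``I_lower`` -> 1, ``I_upper`` -> 0).  The result is independent of the
    log base.  Values outside the bounds are clipped to [0, 1] unless
    ``clip=False``.

    Raises
    ------
    ValueError
        for invalid bounds or non-positive intensities.
    """
    if not (0 < lower < upper):
        raise ValueError("bounds must satisfy 0 < I_lower < I_upper")
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("intensities must be > 0 (apply flooring first)")
    log = lambda x: np.log(x) / np.log(base)
    norm = (log(arr) - log(lower)) / (log(upper) - log(lower))
    if not ascending:
        norm = 1.0 - norm
    if clip:
        norm = np.clip(norm, 0.0, 1.0)
    if np.isscalar(intensity):
        return float(norm)
    return norm


def normalize_sample(
    sample: FlowSample, panel: PanelConfig, ascending: bool = True
) -> pd.DataFrame:
    """Normalized cube coordinates for every bounded channel of the panel.

    Returns a DataFrame with one column per channel that has bounds
    configured, named ``I_<channel>``; values in [0, 1].
    """
    out = {}
    for ch, (lo, hi) in panel.bounds.items():
        out[f"I_{ch}"] = normalize_intensity(
            sample.events[ch].to_numpy(float), lo, hi, ascending=ascending
        )
    return pd.DataFrame(out, index=sample.events.index)
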