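"""Classify events into marker-defined populations and compute population sizes.

Two gating schemes are implemented:

* octant gating — each of three marker channels is thresholded into a
  positive/negative flag, giving 2^3 = 8 mutually exclusive populations
  (none, R, G, B, RG, GB, BR, RGB);
* nearest-centroid gating — events are assigned to the closest of a set of
  population centroids in log10-intensity space (with a rectangular-gate
  mode as an alternative), used when singly-marked populations separate on
  two filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import OCTANT_LABELS, PanelConfig
from .sample import FlowSample

# canonical label for each set of positive colors (paper order: RG, GB, BR)
_OCTANT_BY_COLORSET = {
    frozenset(): "none",
    frozenset("R"): "R",
    frozenset("G"): "G",
    frozenset("B"): "B",
    frozenset("RG"): "RG",
    frozenset("GB"): "GB",
    frozenset("BR"): "BR",
    frozenset("RGB"): "RGB",
}


def positivity_flags(sample: FlowSample, panel: PanelConfig) -> pd.DataFrame:
    """Per-event boolean positivity per thresholded channel.

    An event is positive in a channel when its compensated intensity is
    strictly above the panel threshold (intensity exactly at the threshold
    counts as negative).  Requires a compensated sample whenever the panel
    defines spillover terms.
    """
    if panel.spillover and not sample.compensated:
        raise ValueError("positivity requires a compensated sample")
    flags = {}
    for ch, thr in panel.thresholds.items():
        if ch not in sample.events.columns:
            raise KeyError(f"unknown channel {ch!r} in event table")
        flags[ch] = sample.events[ch].to_numpy(float) > thr
    return pd.DataFrame(flags, index=sample.events.index)


def classify_octant(r_pos, g_pos, b_pos) -> np.ndarray:
    """Octant label from three positivity flags (vectorized).

    The label is exactly the set of positive colors; the eight labels are
    exhaustive and mutually exclusive.
    """
    r = np.asarray(r_pos, dtype=bool)
    g = np.asarray(g_pos, dtype=bool)
    b = np.asarray(b_pos, dtype=bool)
    lut = np.empty(8, dtype=object)
    for i in range(8):
        colors = frozenset(
            c for c, bit in zip("RGB", (i & 4, i & 2, i & 1)) if bit
        )
        lut[i] = _OCTANT_BY_COLORSET[colors]
    idx = r.astype(int) * 4 + g.astype(int) * 2 + b.astype(int)
    return lut[idx]


def assign_octants(sample: FlowSample, panel: PanelConfig) -> pd.Series:
    """Octant label per event, using the panel's R/G/B channel mapping."""
    if set(panel.color_channels) != set("RGB"):
        raise ValueError("panel does not define R/G/B color channels")
    flags = positivity_flags(sample, panel)
    labels = classify_octant(
        flags[panel.color_channels["R"]],
        flags[panel.color_channels["G"]],
        flags[panel.color_channels["B"]],
    )
    return pd.Series(labels, index=sample.events.index, name="population")


def classify_four_color(
    sample: FlowSample, panel: PanelConfig, method: str = "centroid"
) -> pd.Series:
    """Assign each event to one of the panel's populations (or "unassigned").

    ``method="centroid"`` (default): nearest centroid in log10-intensity
    space over the channels named in the centroids; exact distance ties are
    labelled "unassigned".  ``method="rectangle"``: events are labelled by
    the first rectangular gate (on raw intensity) that contains them;
    events in no gate are "unassigned".
    """
    if method == "centroid":
        if not panel.centroids:
            raise ValueError("panel defines no centroids")
        labels = list(panel.centroids)
        chans = list(next(iter(panel.centroids.values())))
        for ch in chans:
            if ch not in sample.events.columns:
                raise KeyError(f"unknown channel {ch!r} in event table")
        coords = np.log10(np.clip(sample.events[chans].to_numpy(float), 1.0, None))
        cents = np.array([[panel.centroids[l][c] for c in chans] for l in labels])
        d2 = ((coords[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        best = d2.argmin(axis=1)
        out = np.array(labels, dtype=object)[best]
        # distance ties (to numerical precision) -> unassigned
        sorted_d2 = np.sort(d2, axis=1)
        out[np.isclose(sorted_d2[:, 0], sorted_d2[:, 1], rtol=1e-9, atol=1e-12)] = "unassigned"
    elif method == "rectangle":
        if not panel.rect_gates:
            raise ValueError("panel defines no rectangular gates")
        out = np.full(len(sample.events), "unassigned", dtype=object)
        unset = np.ones(len(sample.events), dtype=bool)
        for label, gate in panel.rect_gates.items():
            inside = np.ones(len(sample.events), dtype=bool)
            for ch, (lo, hi) in gate.items():
                vals = sample.events[ch].to_numpy(float)
                inside &= (vals >= lo) & (vals <= hi)
            out[inside & unset] = label
            unset &= ~inside
    else:
        raise ValueError(f"unknown gating method {method!r}")
    return pd.Series(out, index=sample.events.index, name="population")


def population_sizes(
    assignment: pd.Series, populations: list[str] | None = None
) -> pd.DataFrame:
    """Counts and fractions (% of gated events) per population.

    ``populations`` fixes the output rows (missing populations get zero);
    by default the octant label set is used when all labels are octants,
    otherwise the observed labels in sorted order.
    """
    if len(assignment) == 0:
        raise ValueError("empty assignment")
    counts = assignment.value_counts()
    if populations is None:
        if set(counts.index) <= set(OCTANT_LABELS):
            populations = list(OCTANT_LABELS)
        else:
            populations = sorted(counts.index)
    n = len(assignment)
    rows = []
    for pop in populations:
        c = int(counts.get(pop, 0))
        rows.append({"population": pop, "count": c, "fraction_pct": 100.0 * c / n})
    return pd.DataFrame(rows)


def marginal_positive_pct(flags: pd.DataFrame) -> pd.Series:
    """Per-channel positive percentage (marginal gates; may overlap)."""
    if len(flags) == 0:
        raise ValueError("empty sample")
    return 100.0 * flags.mean(axis=0)


def octants_containing(color: str) -> list[str]:
    """The four octant labels whose color set contains ``color``."""
    if color not in "RGB" or len(color) != 1:
        raise ValueError("color must be one of 'R', 'G', 'B'")
    return [lab for s, lab in _OCTANT_BY_COLORSET.items() if color in s]
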