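"""Panel configuration: channels, spillover terms, normalization bounds, gates.

A :class:`PanelConfig` is the single source of truth for how fluorescence
channels are named, which spillover corrections apply, where the bounded-log
normalization boundaries sit, and how events are assigned to populations.
Two factory functions build the panels used by the two experiment designs:

* :func:`case1_panel` — three-color RGB marking (mCherry / Venus / Cerulean)
  with octant gating and the published compensation coefficients.
* :func:`case2_panel` — four singly-marked populations read on two filters
  (450/45 and 585/42) with nearest-centroid gating and no compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SCATTER_COLUMNS = ("FSC-A", "FSC-H", "SSC-A")

# Octant labels in the order they are conventionally reported:
# unstained, singles, doubles, triple.
OCTANT_LABELS = ("none", "R", "G", "B", "RG", "GB", "BR", "RGB")


@dataclass(frozen=True)
class Channel:
    """One fluorescence detector: a name plus laser / filter metadata.

    ``column`` is the on-disk CSV column name, derived from the filter
    (e.g. filter "585/40" -> column "FL_585_40").
    """

    name: str
    laser_nm: int
    filter_spec: str

    @property
    def column(self) -> str:
        return "FL_" + self.filter_spec.replace("/", "_")


@dataclass
class PanelConfig:
    """Channels, spillover coefficients, bounds, thresholds and populations.

    Parameters
    ----------
    channels
        Fluorescence channels, in panel order.
    spillover
        Ordered ``(target_channel, source_channel, coefficient)`` terms.
        Compensation subtracts ``coefficient * source`` from ``target``,
        sequentially in list order.
    bounds
        Per channel ``(I_lower, I_upper)`` raw-intensity bounds for the
        bounded log normalization.
    thresholds
        Per channel positivity threshold (raw intensity units); an event is
        positive in a channel when its compensated intensity is strictly
        above this value.
    color_channels
        For octant gating: mapping of color letter (R/G/B) to channel name.
    centroids
        For centroid gating: mapping of population label to per-channel
        log10-intensity centroid coordinates.
    rect_gates
        Alternative rectangular gates: label -> {channel: (lo, hi)} on raw
        intensity.
    """

    channels: list[Channel]
    spillover: list[tuple[str, str, float]] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    color_channels: dict[str, str] = field(default_factory=dict)
    centroids: dict[str, dict[str, float]] = field(default_factory=dict)
    rect_gates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in panel")
        for tgt, src, coeff in self.spillover:
            if tgt not in names or src not in names:
                raise ValueError(f"spillover term references unknown channel: {tgt!r}/{src!r}")
            if coeff < 0:
                raise ValueError("spillover coefficients must be >= 0")
        for ch, (lo, hi) in self.bounds.items():
            if ch not in names:
                raise ValueError(f"bounds for unknown channel {ch!r}")
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {ch!r} must satisfy 0 < I_lower < I_upper")
        for ch, thr in self.thresholds.items():
            if ch not in names:
                raise ValueError(f"threshold for unknown channel {ch!r}")
            if thr <= 0:
                raise ValueError(f"threshold for {ch!r} must be > 0")
        for color, ch in self.color_channels.items():
            if ch not in names:
                raise ValueError(f"color {color!r} mapped to unknown channel {ch!r}")

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def column_map(self) -> dict[str, str]:
        """Mapping channel name -> CSV column name."""
        return {c.name: c.column for c in self.channels}

    def channel(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"unknown channel {name!r}")


def case1_panel() -> PanelConfig:
    """Three-color RGB panel (mCherry = R, Venus = G, Cerulean = B).

    Compensation: Venus - 0.15*mCherry, then Cerulean - 0.039*Venus
    (sequential, using the already-compensated Venus).  Normalization
    bounds: lower 1e3 for all channels; upper 2e5 (mCherry, Cerulean)
    and 1e7 (Venus).  Positivity threshold equals the lower bound.
    """
    channels = [
        Channel("mCherry", 488, "690/50"),
        Channel("Venus", 488, "585/40"),
        Channel("Cerulean", 405, "525/40"),
    ]
    return PanelConfig(
        channels=channels,
        spillover=[("Venus", "mCherry", 0.15), ("Cerulean", "Venus", 0.039)],
        bounds={
            "mCherry": (1e3, 2e5),
            "Venus": (1e3, 1e7),
            "Cerulean": (1e3, 2e5),
        },
        thresholds={"mCherry": 1e3, "Venus": 1e3, "Cerulean": 1e3},
        color_channels={"R": "mCherry", "G": "Venus", "B": "Cerulean"},
    )


# log10 centroids of the four singly-marked populations in the
# (450/45, 585/42) filter plane.  Cerulean and mTagBFP separate by
# intensity on the 405 nm laser line; mOrange2 and Venus on 488 nm.
_CASE2_CENTROIDS = {
    "Cerulean": {"FL_450_45": 4.2, "FL_585_42": 2.1},
    "mTagBFP": {"FL_450_45": 5.4, "FL_585_42": 2.1},
    "mOrange2": {"FL_450_45": 2.1, "FL_585_42": 4.2},
    "Venus": {"FL_450_45": 2.1, "FL_585_42": 5.5},
}


def case2_panel() -> PanelConfig:
    """Two-filter panel distinguishing four singly-marked populations.

    No compensation is applied; assignment is nearest-centroid in
    log10-intensity space against well-separated cluster centroids.
    """
    channels = [
        Channel("FL_450_45", 405, "450/45"),
        Channel("FL_585_42", 488, "585/42"),
    ]
    return PanelConfig(
        channels=channels,
        centroids={k: dict(v) for k, v in _CASE2_CENTROIDS.items()},
    )
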