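"""Ready-made configurations for the two case-study designs.

The numbers here define the *study conditions* the generator emulates:
published octant compositions, marginal positive fractions, lag times, the
common post-lag growth rate, inoculation densities and sampling schedules.
"""

from __future__ import annotations

import numpy as np

from .panel import OCTANT_LABELS, case1_panel, case2_panel
from .synthetic import (
    ChannelIntensity,
    ClonePopulation,
    SimulationConfig,
    VectorCopyModel,
)

# ---------------------------------------------------------------------------
# clonal-outgrowth design (three-color octants)
# ---------------------------------------------------------------------------

#: measured day-0 octant composition (% of gated events; sums to 100.07
#: because the published per-cluster values are individually rounded)
DAY0_OCTANT_PCT = {
    "none": 13.8,
    "R": 8.56,
    "G": 8.66,
    "B": 7.76,
    "RG": 10.8,
    "BR": 7.19,
    "GB": 20.6,
    "RGB": 22.7,
}

#: measured end-of-study (day 130) marginal positive percentages
DAY130_MARGINAL_PCT = {"mCherry": 4.01, "Venus": 84.3, "Cerulean": 84.8}


def day130_octant_pct(unstained_pct: float = 13.8) -> dict[str, float]:
    """Octant composition consistent with the day-130 marginal positives.

    Only the marginal channel-positive percentages and the qualitative
    picture (one dominant Venus+Cerulean population, unstained share
    unchanged, everything else negligible) are measured at the end of the
    study, so the joint composition is reconstructed: the small remaining
    mCherry-positive share is placed entirely in the triple-positive
    octant, the single-positive G and B octants absorb the excess of each
    marginal, the GB octant carries the dominant population, and the R, RG
    and BR octants are empty.  The construction reproduces the three
    marginals exactly and sums to 100.
    """
    m_r = DAY130_MARGINAL_PCT["mCherry"]
    m_g = DAY130_MARGINAL_PCT["Venus"]
    m_b = DAY130_MARGINAL_PCT["Cerulean"]
    stained = 100.0 - unstained_pct
    # with R = RG = BR = 0:  RGB = m_r;  G + GB = m_g - m_r;  B + GB = m_b - m_r
    gb = (m_g - m_r) + (m_b - m_r) - (stained - m_r)
    comp = {
        "none": unstained_pct,
        "R": 0.0,
        "G": m_g - m_r - gb,
        "B": m_b - m_r - gb,
        "RG": 0.0,
        "BR": 0.0,
        "GB": gb,
        "RGB": m_r,
    }
    if any(v < -1e-9 for v in comp.values()):
        raise ValueError("marginals inconsistent with the requested unstained share")
    return comp


#: broad polyclonal positive-intensity peaks at day 0 (log10 raw units)
DAY0_POSITIVE_LEVELS = {
    "mCherry": ChannelIntensity(4.5, 0.35),
    "Venus": ChannelIntensity(5.3, 0.45),
    "Cerulean": ChannelIntensity(4.2, 0.35),
}

#: narrow variant-clone peaks dominating at day 130 (Venus high at ~1.5e6,
#: Cerulean intermediate at ~1e4)
DAY130_POSITIVE_LEVELS = {
    "mCherry": ChannelIntensity(4.5, 0.30),
    "Venus": ChannelIntensity(6.17, 0.15),
    "Cerulean": ChannelIntensity(4.0, 0.15),
}

_COLOR_CHANNEL = {"R": "mCherry", "G": "Venus", "B": "Cerulean"}


def octant_profiles(
    positive_levels: dict[str, ChannelIntensity] | None = None,
) -> dict[str, dict[str, ChannelIntensity]]:
    """Marker profile per octant label: positive channels get the given levels."""
    levels = positive_levels or DAY0_POSITIVE_LEVELS
    profiles = {}
    for label in OCTANT_LABELS:
        colors = () if label == "none" else tuple(label)
        profiles[label] = {_COLOR_CHANNEL[c]: levels[_COLOR_CHANNEL[c]] for c in colors}
    return profiles


def rgb_copy_model(effective_moi: float = 1.0) -> VectorCopyModel:
    """Poisson transduction model: one vector per color at the given MOI."""
    return VectorCopyModel(
        effective_moi={ch: effective_moi for ch in _COLOR_CHANNEL.values()},
        per_copy={ch: lvl for ch, lvl in DAY0_POSITIVE_LEVELS.items()},
        autofluorescence={},
    )


def case1_populations(
    variant_fraction: float = 1e-3,
    base_mu: float = 0.028,
    variant_mu: float = 0.0315,
    variant_q_ab: float = 4.5e-10,
) -> list[ClonePopulation]:
    """Octant populations plus a faster-growing variant clone.

    The variant carries the narrow high-Venus / intermediate-Cerulean
    signature (a GB-octant sub-clone), starts from a small share already
    present in the inoculum, and has a growth-rate and productivity
    advantage; all other populations grow neutrally.
    """
    total = sum(DAY0_OCTANT_PCT.values())
    day0 = octant_profiles(DAY0_POSITIVE_LEVELS)
    pops = [
        ClonePopulation(
            label=label,
            marker_profile=day0[label],
            mu=base_mu,
            initial_fraction=(1.0 - variant_fraction) * pct / total,
        )
        for label, pct in DAY0_OCTANT_PCT.items()
    ]
    pops.append(
        ClonePopulation(
            label="GB-variant",
            marker_profile={
                "Venus": DAY130_POSITIVE_LEVELS["Venus"],
                "Cerulean": DAY130_POSITIVE_LEVELS["Cerulean"],
            },
            mu=variant_mu,
            q_ab=variant_q_ab,
            initial_fraction=variant_fraction,
        )
    )
    return pops


def case1_config(seed: int = 0, events_per_sample: int = 20_000) -> SimulationConfig:
    """High-passage repeated-batch design: 5-day passages over 130 days."""
    return SimulationConfig(
        populations=case1_populations(),
        panel=case1_panel(),
        schedule_h=np.arange(0.0, 130.0 * 24.0 + 1, 5.0 * 24.0),
        passage_interval_days=5.0,
        passage_seed_density_per_ml=0.3e6,
        events_per_sample=events_per_sample,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# mixed-growth-phase design (four singly-marked populations)
# ---------------------------------------------------------------------------

#: preculture growth phase -> observed lag (h); common post-lag mu = 0.037/h
CASE2_LAGS_H = {
    "Cerulean-EX": 3.0,
    "mOrange2-LE": 13.0,
    "mTagBFP-TP": 15.0,
    "Venus-SP": 18.0,
}
CASE2_MU = 0.037

#: population label -> fluorophore centroid key of the two-filter panel
_CASE2_FLUOR = {
    "Cerulean-EX": "Cerulean",
    "mOrange2-LE": "mOrange2",
    "mTagBFP-TP": "mTagBFP",
    "Venus-SP": "Venus",
}
#: within-cluster log10 SD of the singly-marked populations; at the
#: centroid spacing above this keeps neighboring clusters >= 3 SD apart
#: (clearly distinguishable, as required for centroid gating)
CASE2_CLUSTER_SD = 0.2


def case2_populations(mu: float = CASE2_MU) -> list[ClonePopulation]:
    panel = case2_panel()
    pops = []
    for label, lag in CASE2_LAGS_H.items():
        centroid = panel.centroids[_CASE2_FLUOR[label]]
        profile = {
            ch: ChannelIntensity(log10_mean, CASE2_CLUSTER_SD)
            for ch, log10_mean in centroid.items()
        }
        pops.append(
            ClonePopulation(
                label=label,
                marker_profile=profile,
                mu=mu,
                lag=lag,
                initial_fraction=0.25,
            )
        )
    return pops


def case2_config(
    mode: str = "afc", seed: int = 0, events_per_sample: int = 20_000
) -> SimulationConfig:
    """Mixed-growth-phase design.

    ``mode="afc"``: bioreactor with automated flow cytometry, hourly
    sampling for 48 h.  ``mode="shakeflask"``: twice-daily sampling for
    7 days with a stationary cap.  Both start from 1e6 cells/ml total
    (0.25e6 per population) and 5% measurement noise.
    """
    if mode == "afc":
        schedule = np.arange(0.0, 49.0, 1.0)
        capacity = None
    elif mode == "shakeflask":
        schedule = np.arange(0.0, 169.0, 12.0)
        capacity = 12.8e6
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SimulationConfig(
        populations=case2_populations(),
        panel=case2_panel(),
        schedule_h=schedule,
        inoculum_density_per_ml=1.0e6,
        events_per_sample=events_per_sample,
        noise_cv=0.05,
        capacity_per_ml=capacity,
        rng_seed=seed,
    )
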