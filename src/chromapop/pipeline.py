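"""End-to-end orchestration of the two case-study pipelines.

``simulate -> preprocess -> gate -> track -> rates`` with CSV reporting.
Each stage is a thin call into the corresponding module so that the same
functions serve both simulated and real (CSV) inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, gating, io, kinetics
from .panel import PanelConfig
from .preprocess import ScatterGate, compensate, exclude_debris_doublets, normalize_sample
from .presets import DAY130_POSITIVE_LEVELS, case1_config, case2_config, octant_profiles
from .sample import FlowSample
from .synthetic import (
    SimulationConfig,
    sample_events_from_culture,
    simulate_mixed_culture,
    simulate_repeated_batch,
)

log = logging.getLogger("chromapop")


def gate_sample(
    sample: FlowSample,
    panel: PanelConfig,
    scatter_gate: ScatterGate | None = None,
    method: str | None = None,
):
    """Run one sample through scatter gating, compensation and classification.

    Returns ``(table, extras)`` where ``table`` has columns (sample_id,
    time_h, population, count, fraction_pct) over the retained singlet
    events, and ``extras`` carries the exclusion counts, per-channel
    marginal positive percentages (octant panels) and normalized cube
    coordinates when the panel defines bounds.
    """
    filtered, counts = exclude_debris_doublets(sample, scatter_gate)
    extras: dict = {"exclusions": counts}
    if panel.spillover:
        filtered = compensate(filtered, panel)
    if method is None:
        method = "octant" if panel.color_channels else "centroid"
    if method == "octant":
        assignment = gating.assign_octants(filtered, panel)
        flags = gating.positivity_flags(filtered, panel)
        extras["marginal_positive_pct"] = gating.marginal_positive_pct(flags)
        sizes = gating.population_sizes(assignment)
    else:
        assignment = gating.classify_four_color(filtered, panel, method=method)
        sizes = gating.population_sizes(
            assignment, populations=[*sorted(panel.centroids), "unassigned"]
        )
    if panel.bounds:
        cube = normalize_sample(filtered, panel)
        cube.insert(0, "event_id", np.arange(len(cube)))
        extras["cube_coordinates"] = cube
    table = sizes.assign(sample_id=sample.culture_id, time_h=sample.time_h)[
        ["sample_id", "time_h", "population", "count", "fraction_pct"]
    ]
    return table, extras


def _write(results: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            io.write_table(obj.reset_index() if obj.index.name else obj, out / f"{name}.csv")


def repeated_batch_rates(culture: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Cell-specific rates over repeated-batch passages.

    Measurements are taken just before each transfer, so consecutive samples
    both sit at cycle endpoints and their difference carries no rate
    information.  Instead each passage contributes one interval from its
    *calculated* post-transfer state (seed density, fresh-medium
    concentrations) to the measurement at its end, mirroring how
    concentrations after the cell transfer are reconstructed rather than
    measured.
    """
    T = cfg.passage_interval_days * 24.0
    frames = []
    analytes = [a for a in kinetics.ANALYTE_MODES if a in culture.columns]
    for _, row in culture.iterrows():
        t = row["time_h"]
        if t <= 0:
            continue
        t_start = (np.ceil(t / T) - 1) * T
        if t - t_start <= 0:
            continue
        start = {
            "time_h": t_start,
            "X_v_per_l": cfg.passage_seed_density_per_ml * 1e3,
            **{a: cfg.medium[a] for a in analytes},
        }
        end = {"time_h": t, "X_v_per_l": row["X_v_per_l"], **{a: row[a] for a in analytes}}
        frames.append(kinetics.rate_table(pd.DataFrame([start, end])))
    return pd.concat(frames, ignore_index=True)


def run_case1(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    out_dir=None,
    variant_events: bool = True,
) -> dict:
    """Clonal-outgrowth pipeline: repeated-batch simulation, octant gating,
    fraction trajectories and cell-specific rates.

    Deterministic given the config seed.  Returns a dict of result tables;
    with ``out_dir`` set they are also written as CSV next to a run
    manifest.
    """
    cfg = cfg or case1_config(seed=seed)
    culture, fractions = simulate_repeated_batch(cfg)
    profiles = octant_profiles()
    profiles["GB-variant"] = {
        "Venus": DAY130_POSITIVE_LEVELS["Venus"],
        "Cerulean": DAY130_POSITIVE_LEVELS["Cerulean"],
    }
    rng = np.random.default_rng(cfg.rng_seed)
    tables, marginals = [], []
    for t in cfg.schedule_h:
        frac = fractions.loc[t].to_dict()
        sample = sample_events_from_culture(
            frac,
            profiles,
            cfg.panel,
            cfg.events_per_sample,
            rng,
            debris_rate=cfg.debris_rate,
            doublet_rate=cfg.doublet_rate,
            time_h=float(t),
            culture_id="case1",
        )
        table, extras = gate_sample(sample, cfg.panel)
        tables.append(table)
        marginals.append(
            extras["marginal_positive_pct"].rename_axis("channel").reset_index(name="positive_pct").assign(time_h=float(t))
        )
        log.info("case1 t=%.0f h gated %d events", t, extras["exclusions"]["retained"])

    series = dynamics.assemble_timeseries(tables, culture[["time_h", "X_v_per_ml"]])
    rates = repeated_batch_rates(culture, cfg)
    results = {
        "culture": culture,
        "population_series": series,
        "marginal_positive": pd.concat(marginals, ignore_index=True),
        "rates": rates,
        "true_fractions": fractions.reset_index(),
    }
    if out_dir is not None:
        _write(results, out_dir)
        io.write_manifest(Path(out_dir) / "manifest.json", repr(cfg), cfg.rng_seed, {"mode": "case1"})
    return results


def run_case2(
    cfg: SimulationConfig | None = None,
    mode: str = "afc",
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Mixed-growth-phase pipeline: lag/growth simulation, centroid gating,
    change statistics and broken-stick growth fits."""
    cfg = cfg or case2_config(mode=mode, seed=seed)
    densities, culture = simulate_mixed_culture(cfg)
    profiles = {p.label: p.marker_profile for p in cfg.populations}
    rng = np.random.default_rng(cfg.rng_seed)
    tables = []
    for t in cfg.schedule_h:
        x = densities.loc[t]
        frac = (x / x.sum()).to_dict()
        sample = sample_events_from_culture(
            frac,
            profiles,
            cfg.panel,
            cfg.events_per_sample,
            rng,
            debris_rate=cfg.debris_rate,
            doublet_rate=cfg.doublet_rate,
            time_h=float(t),
            culture_id=f"case2-{mode}",
        )
        table, _ = gate_sample(sample, cfg.panel)
        tables.append(table)

    series = dynamics.assemble_timeseries(
        tables, culture[["time_h", "X_v_per_ml"]], provenance=mode
    )
    frac_table = dynamics.fraction_table(series).drop(columns="unassigned", errors="ignore")
    window = 3 if mode == "afc" else 1
    change = dynamics.population_change(frac_table, window, window)
    change["sum_abs_changes_pts"] = dynamics.sum_abs_changes(frac_table, window, window)
    density_table = dynamics.fraction_table(series, "density_per_ml").drop(
        columns="unassigned", errors="ignore"
    )
    fits = dynamics.fit_populations(density_table)
    results = {
        "culture": culture,
        "population_series": series,
        "change": change.reset_index(),
        "growth_fits": fits,
        "true_densities": densities.reset_index(),
    }
    if out_dir is not None:
        _write(results, out_dir)
        io.write_manifest(Path(out_dir) / "manifest.json", repr(cfg), cfg.rng_seed, {"mode": f"case2-{mode}"})
    return results
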