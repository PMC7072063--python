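"""Synthetic cytometry events and culture time courses with known ground truth.

Emulates the two experiment designs the analysis stack targets:

* **Clonal-outgrowth design** — CHO cells co-transduced with three
  fluorescent-protein vectors (RGB marking) form eight intensity clusters
  (octants).  Cultures are passaged every few days for many weeks; a small
  faster-growing variant clone seeded in the inoculum progressively
  overgrows the rest while bulk metabolites cycle with each passage.
* **Mixed-growth-phase design** — four singly-marked populations are pooled
  at equal density; each resumes exponential growth at a common specific
  growth rate after a population-specific lag phase set by its preculture
  age.

Population composition dynamics follow the exact replicator form
``f_p(t) = f_p(0) e^{mu_p t} / sum_q f_q(0) e^{mu_q t}``; event tables are
multinomial draws from the composition with log-normal per-channel
intensities, optional spillover, and configurable debris/doublet
contamination, so every downstream stage has a closed-form oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .panel import PanelConfig, case1_panel, case2_panel
from .preprocess import apply_spillover
from .sample import FlowSample

ML_PER_L = 1e3


@dataclass(frozen=True)
class ChannelIntensity:
    """Log-normal intensity component: log10 mean and SD in raw units."""

    log10_mean: float
    log10_sd: float

    def __post_init__(self) -> None:
        if self.log10_sd < 0:
            raise ValueError("intensity SD must be >= 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return 10.0 ** rng.normal(self.log10_mean, self.log10_sd, n)


@dataclass
class VectorCopyModel:
    """Poisson copy-number model for stochastic multi-vector transduction.

    Each vector integrates with copy count ~ Poisson(effective MOI),
    independently across vectors.  A cell's channel intensity is its
    autofluorescence plus the sum of one log-normal per integrated copy
    (per-copy signals add on the linear scale).  The effective MOI is the
    functional titer per cell, which need not equal the nominal MOI.
    """

    effective_moi: dict[str, float]
    per_copy: dict[str, ChannelIntensity]
    autofluorescence: dict[str, ChannelIntensity]

    def __post_init__(self) -> None:
        for ch, moi in self.effective_moi.items():
            if moi < 0:
                raise ValueError(f"effective MOI for {ch!r} must be >= 0")
            if ch not in self.per_copy:
                raise ValueError(f"no per-copy intensity for vector {ch!r}")


@dataclass
class ClonePopulation:
    """One tracked population: marker profile, growth and rate parameters.

    ``marker_profile`` maps each *positive* channel to its intensity
    distribution; channels absent from the profile emit autofluorescence
    only.  Rates are cell-specific: mmol (mg for antibody) per cell per
    hour; glucose and glutamine are consumed, lactate, ammonium and
    antibody produced.
    """

    label: str
    marker_profile: dict[str, ChannelIntensity] = field(default_factory=dict)
    mu: float = 0.030  # h^-1
    lag: float = 0.0  # h
    q_glc: float = 5.0e-11
    q_lac: float = 6.8e-11
    q_ab: float = 2.0e-10
    q_gln: float = 6.0e-12
    q_amm: float = 4.0e-12
    initial_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.lag < 0:
            raise ValueError("mu and lag must be >= 0")
        if not (0.0 <= self.initial_fraction <= 1.0):
            raise ValueError("initial_fraction must be in [0, 1]")


#: fresh-medium concentrations (mmol/l; antibody mg/l)
FRESH_MEDIUM = {"c_Glc": 35.0, "c_Gln": 5.0, "c_Lac": 0.0, "c_Amm": 0.0, "c_Ab": 0.0}

#: autofluorescence used for unmarked channels
DEFAULT_AUTOFLUORESCENCE = ChannelIntensity(2.0, 0.3)


@dataclass
class SimulationConfig:
    """Experiment description for the simulators.

    ``schedule_h`` are the sampling times (h, strictly increasing);
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal measurement noise applied to densities and concentrations at
    sampling times only.
    """

    populations: list[ClonePopulation]
    panel: PanelConfig
    schedule_h: np.ndarray
    passage_interval_days: float = 5.0
    passage_seed_density_per_ml: float = 0.3e6
    inoculum_density_per_ml: float = 1.0e6
    events_per_sample: int = 20_000
    noise_cv: float = 0.05
    debris_rate: float = 0.0
    doublet_rate: float = 0.0
    capacity_per_ml: float | None = None
    medium: dict[str, float] = field(default_factory=lambda: dict(FRESH_MEDIUM))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.schedule_h = np.asarray(self.schedule_h, dtype=float)
        if len(self.populations) < 1:
            raise ValueError("need at least one population")
        if self.schedule_h.ndim != 1 or np.any(np.diff(self.schedule_h) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.events_per_sample <= 0:
            raise ValueError("events_per_sample must be > 0")
        if self.passage_interval_days <= 0:
            raise ValueError("passage interval must be > 0")
        total = sum(p.initial_fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial fractions sum to {total}, not 1")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]


# ---------------------------------------------------------------------------
# event-level generators
# ---------------------------------------------------------------------------

def _scatter_columns(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    fsc_a = 10.0 ** rng.normal(5.7, 0.08, n)
    fsc_h = fsc_a * rng.normal(1.0, 0.02, n)
    ssc_a = 10.0 ** rng.normal(5.2, 0.15, n)
    return {"FSC-A": fsc_a, "FSC-H": fsc_h, "SSC-A": ssc_a}


def draw_transduced_events(
    model: VectorCopyModel,
    n_events: int,
    seed: int | np.random.Generator,
    panel: PanelConfig | None = None,
) -> pd.DataFrame:
    """Raw event table from the Poisson copy-number model.

    Per vector (= channel) each event receives copies ~ Poisson(MOI); its
    channel intensity is autofluorescence plus the sum of per-copy
    log-normal signals.  If ``panel`` defines spillover, it is added so the
    compensation stage can undo it.  Scatter columns are included.
    Reproducible under a fixed seed.
    """
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols: dict[str, np.ndarray] = {}
    channels = panel.channel_names if panel is not None else list(model.effective_moi)
    for ch in channels:
        auto = model.autofluorescence.get(ch, DEFAULT_AUTOFLUORESCENCE)
        signal = auto.draw(rng, n_events)
        moi = model.effective_moi.get(ch, 0.0)
        if moi > 0:
            copies = rng.poisson(moi, n_events)
            per_copy = model.per_copy[ch]
            for c in np.unique(copies[copies > 0]):
                idx = np.flatnonzero(copies == c)
                signal[idx] += per_copy.draw(rng, len(idx) * int(c)).reshape(len(idx), int(c)).sum(axis=1)
        cols[ch] = signal
    events = pd.DataFrame(cols)
    if panel is not None and panel.spillover:
        events = apply_spillover(events, panel)
    for k, v in _scatter_columns(rng, n_events).items():
        events[k] = v
    return events


def sample_events_from_culture(
    fractions: dict[str, float],
    profiles: dict[str, dict[str, ChannelIntensity]],
    panel: PanelConfig,
    n_events: int,
    seed: int | np.random.Generator,
    autofluorescence: ChannelIntensity = DEFAULT_AUTOFLUORESCENCE,
    debris_rate: float = 0.0,
    doublet_rate: float = 0.0,
    time_h: float = 0.0,
    culture_id: str = "",
) -> FlowSample:
    """Multinomial event table at the given population composition.

    ``fractions`` maps population label to its share (must sum to 1);
    ``profiles`` maps label to a marker profile (positive channels only).
    Debris events carry aberrantly low forward scatter; doublet events
    carry doubled FSC-A (and doubled fluorescence) at an unchanged
    FSC-H/FSC-A target so the singlet gate removes them.  The ground-truth
    label per event is stored in ``sample.meta["truth"]`` ("debris" /
    "doublet" for contamination events).
    """
    if not panel.channel_names:
        raise ValueError("panel defines no fluorescence channels")
    labels = list(fractions)
    p = np.asarray([fractions[l] for l in labels], dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions sum to {p.sum()}, not 1")
    if debris_rate + doublet_rate > 1.0:
        raise ValueError("debris_rate + doublet_rate must be <= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    membership = rng.choice(len(labels), size=n_events, p=p / p.sum())
    u = rng.random(n_events)
    is_debris = u < debris_rate
    is_doublet = (~is_debris) & (u < debris_rate + doublet_rate)

    cols = {ch: np.empty(n_events) for ch in panel.channel_names}
    for i, label in enumerate(labels):
        idx = np.flatnonzero(membership == i)
        profile = profiles.get(label, {})
        for ch in panel.channel_names:
            dist = profile.get(ch, autofluorescence)
            cols[ch][idx] = dist.draw(rng, len(idx))
    events = pd.DataFrame(cols)
    if panel.spillover:
        events = apply_spillover(events, panel)

    scatter = _scatter_columns(rng, n_events)
    # doublets: two cells in one droplet -- area signals double, height does not
    for ch in panel.channel_names:
        events.loc[is_doublet, ch] *= 2.0
    scatter["FSC-A"][is_doublet] *= 2.0
    # debris: small particles, autofluorescent only, low forward scatter
    n_deb = int(is_debris.sum())
    if n_deb:
        scatter["FSC-A"][is_debris] = 10.0 ** rng.normal(4.3, 0.2, n_deb)
        scatter["FSC-H"][is_debris] = scatter["FSC-A"][is_debris] * rng.normal(1.0, 0.02, n_deb)
        for ch in panel.channel_names:
            events.loc[is_debris, ch] = autofluorescence.draw(rng, n_deb)
    for k, v in scatter.items():
        events[k] = v

    truth = np.array(labels, dtype=object)[membership]
    truth[is_debris] = "debris"
    truth[is_doublet] = "doublet"
    return FlowSample(
        events=events,
        time_h=time_h,
        culture_id=culture_id,
        meta={"truth": truth},
    )


# ---------------------------------------------------------------------------
# population dynamics forward models
# ---------------------------------------------------------------------------

def replicator_fractions(
    populations: list[ClonePopulation], t_h: np.ndarray
) -> pd.DataFrame:
    """Exact composition under exponential growth-rate selection.

    ``f_p(t) = f_p(0) e^{mu_p t} / sum_q f_q(0) e^{mu_q t}``; passaging with
    preserved fractions does not alter this trajectory.  Growth-rate
    exponents are centred before exponentiation for numerical stability.
    """
    t = np.atleast_1d(np.asarray(t_h, dtype=float))
    mus = np.array([p.mu for p in populations])
    f0 = np.array([p.initial_fraction for p in populations])
    expo = np.outer(t, mus - mus.max())
    w = f0[None, :] * np.exp(expo)
    frac = w / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, index=t, columns=[p.label for p in populations]).rename_axis("time_h")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unbiased multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, shape)


def integrate_bulk_kinetics(
    populations: list[ClonePopulation],
    density_fn,
    times_h: np.ndarray,
    initial: dict[str, float] | None = None,
    dt: float = 0.05,
) -> pd.DataFrame:
    """Bulk concentration time courses from per-population cell-specific rates.

    The forward model is ``dc/dt = -sum_p q_cons,p X_p(t)`` for consumed and
    ``+sum_p q_prod,p X_p(t)`` for produced analytes, with ``X_p`` in cells
    per liter given by ``density_fn(t_grid) -> (len(grid), n_pop)`` array.
    Integrated by trapezoidal quadrature on a grid of step ``dt`` (h);
    concentrations are floored at zero.
    """
    if dt <= 0:
        raise ValueError("step size dt must be > 0")
    initial = dict(FRESH_MEDIUM if initial is None else initial)
    if any(v < 0 for v in initial.values()):
        raise ValueError("initial concentrations must be >= 0")
    times = np.asarray(times_h, dtype=float)
    t0, t1 = times.min(), times.max()
    grid = np.linspace(t0, t1, max(2, int(np.ceil((t1 - t0) / dt)) + 1))
    x = np.asarray(density_fn(grid), dtype=float)  # cells per liter

    signs = {"c_Glc": -1.0, "c_Gln": -1.0, "c_Lac": 1.0, "c_Amm": 1.0, "c_Ab": 1.0}
    q_attr = {"c_Glc": "q_glc", "c_Gln": "q_gln", "c_Lac": "q_lac", "c_Amm": "q_amm", "c_Ab": "q_ab"}
    out = {"time_h": times}
    for analyte, c0 in initial.items():
        q = np.array([getattr(p, q_attr[analyte]) for p in populations])
        flux = signs[analyte] * (x * q[None, :]).sum(axis=1)
        cum = np.concatenate([[0.0], cumulative_trapezoid(flux, grid)])
        conc = np.maximum(0.0, c0 + cum)
        out[analyte] = np.interp(times, grid, conc)
    return pd.DataFrame(out)


def simulate_repeated_batch(cfg: SimulationConfig):
    """Repeated-batch (high-passage) culture with growth-rate selection.

    Within each passage every population grows exponentially at its own
    ``mu`` (lag phases are ignored here: cells are transferred mid-
    exponential).  At each passage the total density resets to the seed
    density with fractions preserved and metabolites reset to fresh
    medium.  The composition therefore follows the exact replicator
    trajectory in cumulative culture time.

    Returns ``(culture, fractions)``: a culture table at the sampling
    schedule (time_h, passage, X_v_per_ml, X_v_per_l, viability,
    concentrations; measurement noise applied) and the noise-free fraction
    table (rows sum to 1).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    T = cfg.passage_interval_days * 24.0
    times = cfg.schedule_h
    fractions = replicator_fractions(cfg.populations, times)
    mus = np.array([p.mu for p in cfg.populations])

    rows = []
    for t in times:
        # a sampling time on a passage boundary reads the flask *before* transfer
        passage = 0 if t == 0 else int(np.ceil(t / T)) - 1
        t_start = passage * T
        tau = t - t_start
        f_start = replicator_fractions(cfg.populations, np.array([t_start])).iloc[0].to_numpy()
        x_start = cfg.passage_seed_density_per_ml * f_start  # cells/ml
        x_pops_ml = x_start * np.exp(mus * tau)

        def density_fn(grid, x_start=x_start, t_start=t_start):
            return np.outer(np.ones_like(grid), x_start * ML_PER_L) * np.exp(
                np.outer(grid - t_start, mus)
            )

        conc = integrate_bulk_kinetics(
            cfg.populations, density_fn, np.array([t_start, t]), cfg.medium
        ).iloc[-1]
        xv_ml = x_pops_ml.sum()
        row = {"time_h": t, "passage": passage, "X_v_per_ml": xv_ml}
        for analyte in cfg.medium:
            row[analyte] = conc[analyte]
        rows.append(row)

    culture = pd.DataFrame(rows)
    analytes = list(cfg.medium)
    noise = _lognormal_noise(rng, cfg.noise_cv, (len(culture), 1 + len(analytes)))
    culture["X_v_per_ml"] *= noise[:, 0]
    for j, analyte in enumerate(analytes):
        culture[analyte] *= noise[:, j + 1]
    culture["X_v_per_l"] = culture["X_v_per_ml"] * ML_PER_L
    culture["viability"] = np.clip(rng.normal(0.97, 0.01, len(culture)), 0.0, 1.0)
    return culture, fractions


def mixed_culture_densities(
    populations: list[ClonePopulation],
    x0_per_ml: float,
    t_h: np.ndarray,
    capacity_per_ml: float | None = None,
) -> np.ndarray:
    """Noise-free per-population densities (cells/ml) of a mixed culture.

    Delayed exponential growth: ``X_p(t) = X_p(0)`` during the lag, then
    ``X_p(0) e^{mu_p (t - lag_p)}``.  A total carrying capacity, if set,
    rescales all populations proportionally (composition unaffected).
    """
    t = np.atleast_1d(np.asarray(t_h, dtype=float))
    x = np.empty((len(t), len(populations)))
    for j, p in enumerate(populations):
        grown = np.maximum(0.0, t - p.lag)
        x[:, j] = x0_per_ml * p.initial_fraction * np.exp(p.mu * grown)
    if capacity_per_ml is not None:
        total = x.sum(axis=1)
        over = total > capacity_per_ml
        x[over] *= (capacity_per_ml / total[over])[:, None]
    return x


def simulate_mixed_culture(cfg: SimulationConfig):
    """Mixed-growth-phase culture with per-population lag phases.

    Returns ``(densities, culture)``: a table of per-population viable
    densities (cells/ml) at the sampling schedule with multiplicative
    log-normal measurement noise, and the bulk culture table (total X_v
    plus metabolite concentrations integrated from the lag-aware forward
    model, noise applied at sampling).
    """
    if any(p.lag < 0 for p in cfg.populations):
        raise ValueError("lags must be >= 0")
    rng = np.random.default_rng(cfg.rng_seed)
    times = cfg.schedule_h
    x_true = mixed_culture_densities(
        cfg.populations, cfg.inoculum_density_per_ml, times, cfg.capacity_per_ml
    )
    noise = _lognormal_noise(rng, cfg.noise_cv, x_true.shape)
    densities = pd.DataFrame(
        x_true * noise, index=pd.Index(times, name="time_h"), columns=cfg.labels
    )

    def density_fn(grid):
        return (
            mixed_culture_densities(
                cfg.populations, cfg.inoculum_density_per_ml, grid, cfg.capacity_per_ml
            )
            * ML_PER_L
        )

    culture = integrate_bulk_kinetics(cfg.populations, density_fn, times, cfg.medium)
    analytes = list(cfg.medium)
    cnoise = _lognormal_noise(rng, cfg.noise_cv, (len(culture), 1 + len(analytes)))
    culture["X_v_per_ml"] = x_true.sum(axis=1) * cnoise[:, 0]
    for j, analyte in enumerate(analytes):
        culture[analyte] *= cnoise[:, j + 1]
    culture["X_v_per_l"] = culture["X_v_per_ml"] * ML_PER_L
    culture["viability"] = np.clip(rng.normal(0.97, 0.01, len(culture)), 0.0, 1.0)
    return densities, culture
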