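"""Ground-truth structure of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from chromapop import dynamics, kinetics
from chromapop.panel import case1_panel
from chromapop.presets import (
    DAY130_MARGINAL_PCT,
    case1_config,
    case2_config,
    day130_octant_pct,
    octant_profiles,
    rgb_copy_model,
)
from chromapop.synthetic import (
    ClonePopulation,
    SimulationConfig,
    VectorCopyModel,
    draw_transduced_events,
    integrate_bulk_kinetics,
    mixed_culture_densities,
    replicator_fractions,
    sample_events_from_culture,
    simulate_mixed_culture,
    simulate_repeated_batch,
)


class TestVectorCopyModel:
    def test_poisson_zero_class_at_moi_one_per_vector(self, panel1):
        # P(no copies of any of 3 vectors) = e^-3 ~ 0.0498
        n = 100_000
        events = draw_transduced_events(rgb_copy_model(1.0), n, seed=4, panel=panel1)
        from chromapop.pipeline import gate_sample
        from chromapop.sample import FlowSample

        table, _ = gate_sample(FlowSample(events=events), panel1)
        p = np.exp(-3.0)
        se = np.sqrt(p * (1 - p) / n)
        got = table.set_index("population").loc["none", "fraction_pct"] / 100
        assert got == pytest.approx(p, abs=3 * se)

    def test_zero_moi_all_autofluorescent(self, panel1):
        events = draw_transduced_events(rgb_copy_model(0.0), 5_000, seed=4, panel=panel1)
        from chromapop.pipeline import gate_sample
        from chromapop.sample import FlowSample

        table, _ = gate_sample(FlowSample(events=events), panel1)
        got = table.set_index("population")["fraction_pct"]
        assert got["none"] > 99.5  # only autofluorescence tails escape

    def test_negative_moi_rejected(self):
        with pytest.raises(ValueError):
            VectorCopyModel(effective_moi={"Venus": -1.0}, per_copy={}, autofluorescence={})

    def test_fixed_seed_bit_identical(self, panel1):
        a = draw_transduced_events(rgb_copy_model(), 1_000, seed=12, panel=panel1)
        b = draw_transduced_events(rgb_copy_model(), 1_000, seed=12, panel=panel1)
        pd.testing.assert_frame_equal(a, b)


class TestReplicatorDynamics:
    def test_single_population_fraction_is_one(self):
        pops = [ClonePopulation("only", initial_fraction=1.0, mu=0.03)]
        f = replicator_fractions(pops, np.arange(0, 3000, 120.0))
        assert np.allclose(f["only"], 1.0)

    def test_two_clone_closed_form(self):
        mu1, mu2, f0 = 0.030, 0.035, 0.01
        pops = [
            ClonePopulation("wt", mu=mu1, initial_fraction=1 - f0),
            ClonePopulation("var", mu=mu2, initial_fraction=f0),
        ]
        t = np.array([0.0, 500.0, 1500.0, 3120.0])
        f = replicator_fractions(pops, t)
        expected = f0 * np.exp(mu2 * t) / (f0 * np.exp(mu2 * t) + (1 - f0) * np.exp(mu1 * t))
        assert np.allclose(f["var"].to_numpy(), expected, atol=1e-9)

    def test_neutrality_equal_mu(self):
        pops = [
            ClonePopulation(l, mu=0.03, initial_fraction=x)
            for l, x in zip("abc", (0.2, 0.3, 0.5))
        ]
        f = replicator_fractions(pops, np.arange(0.0, 130 * 24, 120.0))
        assert np.allclose(f.to_numpy(), [[0.2, 0.3, 0.5]] * len(f), atol=1e-12)

    def test_repeated_batch_fractions_sum_to_one(self):
        _, fr = simulate_repeated_batch(case1_config(seed=0))
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_three_clone_replicator_matches_simulation(self):
        pops = [
            ClonePopulation("a", mu=0.028, initial_fraction=0.5),
            ClonePopulation("b", mu=0.031, initial_fraction=0.3),
            ClonePopulation("c", mu=0.034, initial_fraction=0.2),
        ]
        cfg = case1_config(seed=1)
        cfg = SimulationConfig(
            populations=pops,
            panel=cfg.panel,
            schedule_h=cfg.schedule_h,
            rng_seed=1,
        )
        _, fr = simulate_repeated_batch(cfg)
        t = fr.index.to_numpy()
        w = np.array([[p.initial_fraction * np.exp(p.mu * ti) for p in pops] for ti in t])
        expected = w / w.sum(axis=1, keepdims=True)
        assert np.allclose(fr.to_numpy(), expected, atol=1e-9)


class TestMixedCulture:
    def test_delayed_exponential_hand_value(self):
        # lag 18 h, mu 0.037/h, X0 0.25e6/ml: X(48) = 0.25e6 * e^(0.037*30)
        pop = ClonePopulation("v", mu=0.037, lag=18.0, initial_fraction=1.0)
        x = mixed_culture_densities([pop], 0.25e6, np.array([48.0]))
        assert x[0, 0] == pytest.approx(0.25e6 * np.exp(0.037 * 30.0), rel=1e-12)
        assert x[0, 0] == pytest.approx(7.58e5, rel=1e-3)

    def test_flat_during_lag_and_zero_mu(self):
        pop = ClonePopulation("v", mu=0.0, lag=0.0, initial_fraction=1.0)
        x = mixed_culture_densities([pop], 1e6, np.arange(0.0, 48.0))
        assert np.allclose(x, 1e6)
        lagpop = ClonePopulation("v", mu=0.05, lag=10.0, initial_fraction=1.0)
        x = mixed_culture_densities([lagpop], 1e6, np.arange(0.0, 10.5, 0.5))
        assert np.allclose(x, 1e6)

    def test_noiseless_roundtrip_through_growth_fit(self):
        cfg = case2_config("afc", seed=0)
        cfg.noise_cv = 0.0
        dens, _ = simulate_mixed_culture(cfg)
        fits = dynamics.fit_populations(dens).set_index("population")
        for pop in cfg.populations:
            assert fits.loc[pop.label, "lag_h"] == pytest.approx(pop.lag, abs=1e-6)
            assert fits.loc[pop.label, "mu_per_h"] == pytest.approx(pop.mu, rel=1e-6)

    def test_capacity_cap_preserves_composition(self):
        pops = [
            ClonePopulation("a", mu=0.04, lag=0.0, initial_fraction=0.5),
            ClonePopulation("b", mu=0.04, lag=0.0, initial_fraction=0.5),
        ]
        x = mixed_culture_densities([*pops], 1e6, np.arange(0.0, 200.0, 10.0), capacity_per_ml=5e6)
        assert x.sum(axis=1).max() <= 5e6 * (1 + 1e-12)
        frac = x / x.sum(axis=1, keepdims=True)
        assert np.allclose(frac, 0.5)


class TestBulkKinetics:
    def test_zero_rate_keeps_concentration_constant(self):
        pop = ClonePopulation("a", mu=0.03, q_glc=0.0, initial_fraction=1.0)
        out = integrate_bulk_kinetics(
            [pop], lambda g: np.full((len(g), 1), 5e9), np.array([0.0, 24.0]), {"c_Glc": 30.0}
        )
        assert np.allclose(out["c_Glc"], 30.0)

    def test_constant_density_linear_solution(self):
        # X_v 5e9 cells/l at q_Glc 5.00e-11 mmol/cell/h for 24 h: dc = 6.0 mmol/l
        pop = ClonePopulation("a", q_glc=5.00e-11, initial_fraction=1.0)
        out = integrate_bulk_kinetics(
            [pop], lambda g: np.full((len(g), 1), 5e9), np.array([0.0, 24.0]), {"c_Glc": 35.0}
        )
        assert out["c_Glc"].iloc[-1] == pytest.approx(35.0 - 6.0, abs=1e-8)

    def test_concentrations_floored_at_zero(self):
        pop = ClonePopulation("a", q_glc=5e-11, initial_fraction=1.0)
        out = integrate_bulk_kinetics(
            [pop], lambda g: np.full((len(g), 1), 5e10), np.array([0.0, 120.0]), {"c_Glc": 10.0}
        )
        assert out["c_Glc"].iloc[-1] == 0.0

    def test_invalid_step_size_rejected(self):
        pop = ClonePopulation("a", initial_fraction=1.0)
        with pytest.raises(ValueError):
            integrate_bulk_kinetics([pop], lambda g: np.ones((len(g), 1)), [0.0, 1.0], dt=0.0)

    def test_rate_roundtrip_slowly_varying_density(self):
        # forward-simulated concentrations fed to the two-point estimator
        # return the configured q within 2% when X_v varies slowly
        q, mu = 5.0e-11, 0.002
        pop = ClonePopulation("a", mu=mu, q_glc=q, initial_fraction=1.0)
        t = np.arange(0.0, 49.0, 1.0)
        fn = lambda g: (2e9 * np.exp(mu * np.asarray(g)))[:, None]
        conc = integrate_bulk_kinetics([pop], fn, t, {"c_Glc": 35.0})
        series = pd.DataFrame({"time_h": t, "X_v_per_l": fn(t)[:, 0], "c_Glc": conc["c_Glc"]})
        est = kinetics.specific_rate(series, "c_Glc", "consumption")["q"]
        assert np.allclose(est, q, rtol=0.02)


class TestEventSampling:
    def test_degenerate_fractions_single_population(self, panel1):
        profiles = octant_profiles()
        s = sample_events_from_culture(
            {"R": 1.0, "G": 0.0, "B": 0.0, "none": 0.0}, profiles, panel1, 3000, seed=5
        )
        assert (s.meta["truth"] == "R").all()

    def test_multinomial_fractions_recovered(self, panel1):
        n = 100_000
        fr = {"R": 0.25, "G": 0.25, "B": 0.25, "none": 0.25}
        s = sample_events_from_culture(fr, octant_profiles(), panel1, n, seed=6)
        for lab, p in fr.items():
            got = (s.meta["truth"] == lab).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert got == pytest.approx(p, abs=3 * se)

    def test_fractions_must_sum_to_one(self, panel1):
        with pytest.raises(ValueError, match="sum"):
            sample_events_from_culture({"R": 0.6, "G": 0.6}, octant_profiles(), panel1, 10, seed=0)

    def test_day130_composition_reproduces_marginals(self):
        comp = day130_octant_pct()
        assert sum(comp.values()) == pytest.approx(100.0, abs=1e-9)
        assert comp["R"] + comp["RG"] + comp["BR"] + comp["RGB"] == pytest.approx(
            DAY130_MARGINAL_PCT["mCherry"]
        )
        assert comp["G"] + comp["RG"] + comp["GB"] + comp["RGB"] == pytest.approx(
            DAY130_MARGINAL_PCT["Venus"]
        )
        assert comp["B"] + comp["BR"] + comp["GB"] + comp["RGB"] == pytest.approx(
            DAY130_MARGINAL_PCT["Cerulean"]
        )

    def test_config_validation(self, panel1):
        pops = [ClonePopulation("a", initial_fraction=0.6)]
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(populations=pops, panel=panel1, schedule_h=[0.0, 1.0])
        good = [ClonePopulation("a", initial_fraction=1.0)]
        with pytest.raises(ValueError, match="increasing"):
            SimulationConfig(populations=good, panel=panel1, schedule_h=[1.0, 1.0])
        with pytest.raises(ValueError, match="events"):
            SimulationConfig(
                populations=good, panel=panel1, schedule_h=[0.0, 1.0], events_per_sample=0
            )
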