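"""Population-change statistics and broken-stick growth fitting."""

import numpy as np
import pandas as pd
import pytest

from chromapop.dynamics import (
    assemble_timeseries,
    fit_lag_exponential,
    fraction_table,
    population_change,
    sum_abs_changes,
)


def series_from(rows, pops):
    return pd.DataFrame(rows, columns=pops, index=pd.Index(range(len(rows)), name="time_h"))


class TestPopulationChange:
    def test_constant_series_has_zero_change(self):
        s = series_from([[25, 75]] * 6, ["a", "b"])
        out = population_change(s)
        assert (out["total_change_pts"] == 0).all()
        assert (out["individual_change_pct"] == 0).all()

    @pytest.mark.parametrize(
        "total,expected_individual",
        [(-5.01, -20.04), (-1.77, -7.08), (6.30, 25.2)],
    )
    def test_individual_change_on_quarter_baseline(self, total, expected_individual):
        # a population starting at a 25% share: individual = 100 * total / 25
        s = series_from([[25.0, 75.0], [25.0 + total, 75.0 - total]], ["x", "rest"])
        out = population_change(s, baseline_n=1, final_n=1)
        assert out.loc["x", "total_change_pts"] == pytest.approx(total)
        assert out.loc["x", "individual_change_pct"] == pytest.approx(expected_individual)

    def test_linearity_in_fractions(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(5, 40, size=(8, 3))
        s = series_from(vals, ["a", "b", "c"])
        one = population_change(s)
        two = population_change(2 * s)
        assert np.allclose(two["total_change_pts"], 2 * one["total_change_pts"])
        assert np.allclose(two["individual_change_pct"], one["individual_change_pct"])

    def test_overlapping_windows_rejected(self):
        s = series_from([[50, 50]] * 4, ["a", "b"])
        with pytest.raises(ValueError):
            population_change(s, baseline_n=3, final_n=3)

    def test_zero_baseline_rejected(self):
        s = series_from([[0, 100], [5, 95]], ["a", "b"])
        with pytest.raises(ZeroDivisionError):
            population_change(s, baseline_n=1, final_n=1)


class TestSumAbsChanges:
    def test_constant_series_is_zero(self):
        s = series_from([[25, 25, 25, 25]] * 6, list("abcd"))
        assert sum_abs_changes(s) == 0.0

    def test_reported_component_sum(self):
        # per-population total changes +7.95, +2.05, -0.41, -9.59 add to 20.00
        start = np.array([24.0, 25.0, 25.5, 25.5])
        change = np.array([7.95, 2.05, -0.41, -9.59])
        s = series_from([start, start + change], list("abcd"))
        assert sum_abs_changes(s, 1, 1) == pytest.approx(20.00)

    def test_population_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(5, 40, size=(8, 4))
        s = series_from(vals, list("abcd"))
        shuffled = s[["c", "a", "d", "b"]]
        assert sum_abs_changes(s) == pytest.approx(sum_abs_changes(shuffled))

    def test_needs_two_populations(self):
        s = series_from([[100.0]] * 6, ["only"])
        with pytest.raises(ValueError):
            sum_abs_changes(s)


def brute_force_broken_stick(t, y):
    """Independent oracle: closed-form least squares per breakpoint.

    For fixed breakpoint tb the model y ~ a + mu*max(0, t-tb) is ordinary
    two-parameter linear regression on the ramp covariate; solve it with
    the textbook covariance formula instead of the packaged lstsq path.
    """
    logy = np.log(y)
    best = None
    for tb in t[:-2]:
        x = np.maximum(0.0, t - tb)
        mu = np.cov(x, logy, bias=True)[0, 1] / np.var(x)
        a = logy.mean() - mu * x.mean()
        rss = ((a + mu * x - logy) ** 2).sum()
        if best is None or rss < best[0] - 1e-15:
            best = (rss, tb, mu)
    return best[1], best[2]


class TestLagExponentialFit:
    def test_noiseless_roundtrip_recovers_lag_and_mu(self):
        t = np.arange(0.0, 49.0)
        lag, mu, x0 = 18.0, 0.037, 0.25e6
        y = x0 * np.exp(mu * np.maximum(0.0, t - lag))
        fit = fit_lag_exponential(t, y)
        assert fit.lag == pytest.approx(lag, abs=1e-9)
        assert fit.mu == pytest.approx(mu, rel=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_zero_lag_pure_exponential(self):
        t = np.arange(0.0, 25.0)
        y = 1e6 * np.exp(0.03 * t)
        fit = fit_lag_exponential(t, y)
        assert fit.lag == 0.0
        assert fit.mu == pytest.approx(0.03, rel=1e-9)
        assert not fit.no_growth

    def test_decreasing_series_flags_no_growth(self):
        t = np.arange(0.0, 10.0)
        fit = fit_lag_exponential(t, 1e6 * np.exp(-0.02 * t))
        assert fit.no_growth

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 30.0, 2.0)
        y = 2e5 * np.exp(0.04 * np.maximum(0.0, t - 8.0)) * np.exp(rng.normal(0, 0.05, len(t)))
        fit = fit_lag_exponential(t, y)
        lag_o, mu_o = brute_force_broken_stick(t, y)
        assert fit.lag == lag_o
        assert fit.mu == pytest.approx(mu_o, rel=1e-9)

    def test_noisy_mu_recovered_within_10pct(self):
        # 5% log-normal noise, 20 replicates: median fitted slope near truth
        t = np.arange(0.0, 49.0)
        mu, lag = 0.037, 15.0
        mus = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 0.25e6 * np.exp(mu * np.maximum(0.0, t - lag)) * rng.lognormal(0, 0.05, len(t))
            mus.append(fit_lag_exponential(t, y).mu)
        assert np.median(mus) == pytest.approx(mu, rel=0.10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_lag_exponential([0, 1, 2, 3], [1, 2, 3, 4])  # too short
        with pytest.raises(ValueError):
            fit_lag_exponential([0, 1, 2, 3, 4], [1, 2, 0, 4, 5])  # nonpositive
        with pytest.warns(UserWarning):
            # breakpoint near the end leaves < 3 post-lag points
            t = np.arange(0.0, 7.0)
            y = np.array([1, 1, 1, 1, 1, 2.0, 4.0]) * 1e5
            fit_lag_exponential(t, y)


class TestAssembleTimeseries:
    @staticmethod
    def tables():
        rows = []
        for t, fr in [(0.0, (25.0, 75.0)), (24.0, (30.0, 70.0))]:
            for pop, f in zip(["a", "b"], fr):
                rows.append({"sample_id": "c", "time_h": t, "population": pop, "fraction_pct": f})
        return [pd.DataFrame(rows[:2]), pd.DataFrame(rows[2:])]

    def test_density_arithmetic(self):
        culture = pd.DataFrame({"time_h": [0.0, 24.0], "X_v_per_ml": [4e6, 8e6]})
        tidy = assemble_timeseries(self.tables(), culture)
        row = tidy.query("time_h == 0 and population == 'a'").iloc[0]
        assert row["density_per_ml"] == pytest.approx(1e6)

    def test_input_order_invariance(self):
        t = self.tables()
        a = assemble_timeseries(t)
        b = assemble_timeseries(t[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_conflicting_duplicate_times_rejected(self):
        t = self.tables()
        bad = t[0].copy()
        bad["fraction_pct"] += 1.0
        with pytest.raises(ValueError, match="conflicting"):
            assemble_timeseries(t + [bad])

    def test_fraction_table_pivot(self):
        tidy = assemble_timeseries(self.tables())
        wide = fraction_table(tidy)
        assert wide.loc[24.0, "a"] == 30.0
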