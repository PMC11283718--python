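"""Rate fitting, max-rate windows, treatment comparison and correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soasr import simulate
from soasr.kinetics import (
    compare_treatments,
    correlate_potential,
    fit_linear_rate,
    max_rate,
    rate_ratio,
)

from conftest import make_series


class TestFitLinearRate:
    def test_exact_line_recovers_slope_with_zero_stderr(self):
        t = np.arange(0, 7, dtype=float)
        s = make_series(t, 5 + 26 * t)
        est = fit_linear_rate(s, "As(III)")
        assert est.rate == pytest.approx(26.0)
        assert est.stderr == pytest.approx(0.0, abs=1e-10)

    def test_constant_series_gives_zero_rate(self):
        s = make_series([0, 1, 2, 3], [7.0, 7.0, 7.0, 7.0])
        assert fit_linear_rate(s, "As(III)").rate == pytest.approx(0.0)

    def test_pooled_replicates(self):
        t = [0.0, 1.0, 2.0]
        reps = [
            make_series(t, [0.0, 10.0, 20.0], replicate="r1"),
            make_series(t, [2.0, 12.0, 22.0], replicate="r2"),
        ]
        est = fit_linear_rate(reps, "As(III)")
        assert est.rate == pytest.approx(10.0)
        assert est.n_replicates == 2

    def test_monte_carlo_recovery_at_transfer_rate(self, rng):
        """Mean fitted rate over noisy triplicate sims stays within 2% of 26."""
        cfg = simulate.transfer_culture_config()
        rates = []
        for _ in range(200):
            series = simulate.simulate_incubation(cfg, rng)
            rates.append(fit_linear_rate(series, "As(III)").rate)
        assert 25.5 <= np.mean(rates) <= 26.5

    def test_too_few_points_raises(self):
        s = make_series([0, 1], [0.0, 1.0])
        with pytest.raises(ValueError):
            fit_linear_rate(s, "As(III)", window=(0, 0))

    def test_unknown_analyte_lists_valid_names(self):
        s = make_series([0, 1], [0.0, 1.0])
        with pytest.raises(KeyError, match="As\\(III\\)"):
            fit_linear_rate(s, "nope")

    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
    @settings(max_examples=40, deadline=None)
    def test_time_shift_invariance_and_unit_equivariance(self, shift, scale):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        c = np.array([1.0, 4.0, 6.0, 10.0])
        base = fit_linear_rate(make_series(t, c), "As(III)").rate
        shifted = fit_linear_rate(
            make_series(t + abs(shift), c), "As(III)"
        ).rate
        scaled = fit_linear_rate(make_series(t, c * scale), "As(III)").rate
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestMaxRate:
    def test_piecewise_flat_then_decline(self):
        t = np.arange(0, 8, dtype=float)
        c = np.where(t < 3, 500.0, 500.0 - 38.0 * (t - 3))
        s = make_series(t, c, analyte="As(V)", basis="dry_weight")
        est = max_rate(s, "As(V)", window_size=3, direction="consumption")
        assert est.rate == pytest.approx(38.0)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_monotone_line_gives_slope_regardless_of_window(self, k):
        t = np.arange(0, 6, dtype=float)
        s = make_series(t, 100 - 7 * t, analyte="As(V)")
        assert max_rate(s, "As(V)", window_size=k, direction="consumption").rate == pytest.approx(7.0)

    def test_diff_quotient_mode(self):
        s = make_series([0.0, 1.0, 2.0], [10.0, 8.0, 2.0], analyte="As(V)")
        est = max_rate(s, "As(V)", direction="consumption", mode="diff")
        assert est.rate == pytest.approx(6.0)

    def test_window_too_large_raises(self):
        s = make_series([0, 1, 2], [3.0, 2.0, 1.0], analyte="As(V)")
        with pytest.raises(ValueError):
            max_rate(s, "As(V)", window_size=4)

    def test_no_donor_control_recovery(self, rng):
        """Slow control slope (1.4 μM/g dw/d) recovered within noise envelope."""
        cfg = simulate.donor_comparison_config()
        rates = []
        for _ in range(100):
            series = [
                s for s in simulate.simulate_incubation(cfg, rng) if s.treatment == "no_donor"
            ]
            rates.append(-fit_linear_rate(series, "As(V)").rate)
        assert np.mean(rates) == pytest.approx(1.4, rel=0.05)


class TestRateRatio:
    def test_paper_operating_point(self):
        t = np.arange(0, 5, dtype=float)
        a = fit_linear_rate(make_series(t, 26 * t), "As(III)")
        b = fit_linear_rate(make_series(t, 13 * t, analyte="SO4"), "SO4")
        assert rate_ratio(a, b) == pytest.approx(2.0)

    def test_identical_estimates_give_one(self):
        t = np.arange(0, 5, dtype=float)
        a = fit_linear_rate(make_series(t, 9 * t), "As(III)")
        assert rate_ratio(a, a) == 1.0

    def test_noise_free_stoichiometric_simulation_is_exactly_two(self):
        cfg = simulate.transfer_culture_config(noise_sd={})
        series = simulate.simulate_incubation(cfg, 0)
        a = fit_linear_rate(series, "As(III)")
        b = fit_linear_rate(series, "SO4")
        assert rate_ratio(a, b) == pytest.approx(2.0, rel=1e-12)

    def test_zero_denominator_raises(self):
        t = np.arange(0, 5, dtype=float)
        a = fit_linear_rate(make_series(t, 2 * t), "As(III)")
        b = fit_linear_rate(make_series(t, 0 * t, analyte="SO4"), "SO4")
        with pytest.raises(ZeroDivisionError):
            rate_ratio(a, b)


class TestMassClosure:
    def test_noise_free_arsenic_is_conserved_at_every_timepoint(self):
        cfg = simulate.transfer_culture_config(noise_sd={})
        for s in simulate.simulate_incubation(cfg, 0):
            total = s.concentrations["As(V)"] + s.concentrations["As(III)"]
            assert np.allclose(total, total[0])


class TestCompareTreatments:
    def _groups(self, rate_a, rate_b, sd, rng, reps=3):
        t = np.arange(0, 8, dtype=float)
        out = []
        for treatment, rate in (("A", rate_a), ("B", rate_b)):
            for r in range(reps):
                noise = rng.normal(0, sd, size=t.shape) if sd else 0.0
                out.append(
                    make_series(t, np.maximum(rate * t + noise, 0), treatment=treatment,
                                replicate=f"r{r}")
                )
        return out

    def test_identical_groups_not_significant(self, rng):
        series = []
        t = np.arange(0, 8, dtype=float)
        vals = rng.normal(0, 1, size=t.shape) + 5 * t
        for treatment in ("A", "B"):
            for r in range(3):
                series.append(make_series(t, np.maximum(vals, 0), treatment=treatment,
                                          replicate=f"r{r}"))
        _, tests = compare_treatments(series, "As(III)")
        assert tests["p"].iloc[0] > 0.99

    def test_separated_groups_significant(self, rng):
        series = self._groups(45.0, 1.4, 0.5, rng)
        _, tests = compare_treatments(series, "As(III)")
        assert tests["p"].iloc[0] < 0.01

    def test_three_treatments_three_pairwise_tests(self, rng):
        series = self._groups(10.0, 5.0, 0.5, rng) + [
            make_series(np.arange(0, 8, dtype=float), np.arange(0, 8) * 2.0,
                        treatment="C", replicate=f"r{r}")
            for r in range(3)
        ]
        estimates, tests = compare_treatments(series, "As(III)")
        assert len(estimates) == 3
        assert len(tests) == 3

    def test_single_replicate_tests_unavailable(self):
        t = np.arange(0, 5, dtype=float)
        series = [
            make_series(t, 2 * t, treatment="A", replicate="r1"),
            make_series(t, 3 * t, treatment="B", replicate="r1"),
        ]
        estimates, tests = compare_treatments(series, "As(III)")
        assert len(estimates) == 2
        assert not tests["available"].iloc[0]


class TestCorrelatePotential:
    def test_perfect_linear_relation(self):
        sites = [f"s{i}" for i in range(6)]
        x = np.arange(6, dtype=float)
        geo = pd.DataFrame({"site": sites, "parameter": "WSRS", "value": x})
        res = correlate_potential({s: 2 * v for s, v in zip(sites, x)}, geo)
        assert res[0].r == pytest.approx(1.0)
        assert res[0].p < 1e-6

    def test_independent_data_near_zero(self, rng):
        n = 400
        sites = [f"s{i}" for i in range(n)]
        geo = pd.DataFrame({"site": sites, "parameter": "TOC", "value": rng.normal(size=n)})
        res = correlate_potential({s: v for s, v in zip(sites, rng.normal(size=n))}, geo)
        assert abs(res[0].r) < 0.15

    def test_zero_variance_flagged_undefined(self):
        sites = ["a", "b", "c", "d"]
        geo = pd.DataFrame({"site": sites, "parameter": "pH", "value": [7.0] * 4})
        res = correlate_potential({s: float(i) for i, s in enumerate(sites)}, geo)
        assert res[0].undefined
        assert math.isnan(res[0].r)

    def test_simulated_correlation_recovery(self, rng):
        """Mean r over 500 draws of n=12 sites at true ρ=0.9 lands near 0.9."""
        rho, n = 0.9, 12
        rs = []
        for _ in range(500):
            x = rng.normal(size=n)
            y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
            sites = [f"s{i}" for i in range(n)]
            geo = pd.DataFrame({"site": sites, "parameter": "WSOC", "value": x})
            res = correlate_potential(dict(zip(sites, y)), geo)
            rs.append(res[0].r)
        # finite-sample Pearson r is slightly biased toward 0; ±0.05 band
        assert abs(np.mean(rs) - rho) < 0.05

    def test_missing_sites_dropped_pairwise(self):
        geo = pd.DataFrame(
            {"site": ["a", "b", "c", "zz"], "parameter": "As", "value": [1.0, 2.0, 3.0, 4.0]}
        )
        res = correlate_potential({"a": 1.0, "b": 2.0, "c": 2.5}, geo)
        assert res[0].n == 3
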