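"""Closed forms and Monte-Carlo agreement of the FP/FN error model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from aohu import (
    PopulationModel,
    error_curves,
    fn_rate,
    fn_rate_dynamic,
    fp_rate_population,
    fp_rate_scan,
    make_plaque_law,
    min_threshold_for_fp,
)
from aohu.error_model import fp_rate_population_mc

ARTERIAL = PopulationModel(M=326.0, S=68.0, sigma_bar=30.0, phase="arterial")
VENOUS = PopulationModel(M=180.0, S=30.0, sigma_bar=30.0, phase="venous")
DELAYED = PopulationModel(M=110.0, S=16.0, sigma_bar=30.0, phase="delayed")


class TestScanFP:
    def test_threshold_at_the_mean_is_half(self):
        assert fp_rate_scan(326, 68, 326) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(
        mean=st.floats(40, 500),
        sd=st.floats(5, 90),
        n=st.floats(0.5, 4.5),
    )
    def test_dynamic_cutoff_depends_only_on_n(self, mean, sd, n):
        assert fp_rate_scan(mean, sd, mean + n * sd) == pytest.approx(float(norm.sf(n)), rel=1e-9)

    def test_three_sd_value(self):
        assert fp_rate_scan(110, 16, 110 + 3 * 16) == pytest.approx(0.001350, abs=5e-7)

    def test_arterial_at_400(self, rng):
        analytic = fp_rate_scan(326, 68, 400)
        assert analytic == pytest.approx(1 - norm.cdf(74 / 68), abs=1e-12)
        assert analytic == pytest.approx(0.138, abs=0.001)
        draws = rng.normal(326, 68, size=10**6)
        emp = (draws >= 400).mean()
        assert emp == pytest.approx(analytic, abs=3 * np.sqrt(analytic * (1 - analytic) / 1e6))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            fp_rate_scan(100, 0.0, 130)


class TestPopulationFP:
    def test_degenerate_population_reduces_to_single_scan(self):
        pop = PopulationModel(M=200.0, S=0.0, sigma_bar=25.0)
        for T in (150, 200, 280):
            assert fp_rate_population(pop, T) == pytest.approx(fp_rate_scan(200, 25, T))

    @pytest.mark.parametrize("T,expected,tol", [(200, 0.955, 0.001), (400, 0.160, 0.001)])
    def test_arterial_closed_form(self, T, expected, tol):
        assert fp_rate_population(ARTERIAL, T) == pytest.approx(expected, abs=tol)

    def test_closed_form_agrees_with_monte_carlo(self, rng):
        for T in (200, 300, 400, 550):
            closed = fp_rate_population(ARTERIAL, T)
            n = 10_000
            mc = fp_rate_population_mc(ARTERIAL, T, n, rng)
            # per-scan tail probs are bounded by 1; their SD is < 0.5
            assert mc == pytest.approx(closed, abs=3 * 0.5 / np.sqrt(n))

    def test_explicit_scan_list_average(self):
        pop = PopulationModel(scans=((100.0, 10.0), (200.0, 20.0)))
        expected = 0.5 * (fp_rate_scan(100, 10, 150) + fp_rate_scan(200, 20, 150))
        assert fp_rate_population(pop, 150) == pytest.approx(expected)

    def test_empty_scan_list_rejected(self):
        with pytest.raises(ValueError):
            PopulationModel(scans=())


class TestFN:
    def test_nothing_below_generating_threshold(self, law):
        assert fn_rate(law, 130.0) == 0.0
        assert fn_rate(law, 100.0) == 0.0

    def test_median_threshold_halves_plaque(self, law):
        assert fn_rate(law, 256.0) == pytest.approx(0.5)

    def test_fn_at_250_near_half(self, law):
        assert fn_rate(law, 250.0) == pytest.approx(0.48, abs=0.005)

    def test_dynamic_fn_ordering_across_phases(self, law, rng):
        rates = [
            fn_rate_dynamic(law, pop, 3.0, n_mc=50_000, rng=rng)
            for pop in (DELAYED, VENOUS, ARTERIAL)
        ]
        assert rates[0] < rates[1] < rates[2]
        assert rates[0] < 0.5 and rates[2] > 0.5  # delayed mild, arterial severe

    def test_dynamic_fn_limits(self, law, rng):
        assert fn_rate_dynamic(law, DELAYED, 60.0, rng=rng) == pytest.approx(1.0, abs=1e-6)
        far_law = make_plaque_law(9000.0, 9500.0, 10_000.0)
        assert fn_rate_dynamic(far_law, ARTERIAL, 5.0, rng=rng) == 0.0

    def test_explicit_scan_list_is_exact(self, law):
        pop = PopulationModel(scans=((110.0, 16.0), (180.0, 30.0)))
        expected = 0.5 * (law.cdf(110 + 3 * 16) + law.cdf(180 + 3 * 30))
        assert fn_rate_dynamic(law, pop, 3.0) == pytest.approx(expected)


class TestCurvesAndInversion:
    def test_curves_shape_and_monotonicity(self, law, rng):
        pops = {"arterial": ARTERIAL, "venous": VENOUS, "delayed": DELAYED}
        curves = error_curves(law, pops, uniform_grid=range(130, 601, 30),
                              dynamic_grid=np.arange(1, 5.1, 0.5), n_mc=20_000, rng=rng)
        uni = curves[curves.scheme == "uniform"]
        dyn = curves[curves.scheme == "dynamic"]
        # dynamic FP identical across phases, uniform FP ordered by M
        for N, grp in dyn.groupby("threshold_or_N"):
            assert grp.fp.nunique() == 1
            assert grp.fp.iloc[0] == pytest.approx(float(norm.sf(N)))
        at_300 = uni[uni.threshold_or_N == 310].set_index("phase").fp
        assert at_300["arterial"] > at_300["venous"] > at_300["delayed"]

    def test_fn_strictly_increasing_on_bin_grid(self, law):
        vals = [fn_rate(law, T) for T in (130, 200, 300, 400)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_uniform_fp_crosses_dynamic_level_near_549(self):
        t549 = min_threshold_for_fp(ARTERIAL, float(norm.sf(3)))
        assert t549 == pytest.approx(326 + 3 * np.hypot(68, 30), abs=1e-9)
        assert t549 == pytest.approx(549, abs=1)
        assert fp_rate_population(ARTERIAL, t549) == pytest.approx(float(norm.sf(3)), rel=1e-9)

    def test_inversion_closed_form_cases(self):
        pop = PopulationModel(M=200.0, S=0.0, sigma_bar=30.0)
        assert min_threshold_for_fp(pop, float(norm.sf(3))) == pytest.approx(200 + 3 * 30)
        assert min_threshold_for_fp(ARTERIAL, 0.5) == pytest.approx(326.0)

    def test_inversion_by_bisection_on_explicit_list(self):
        scans = tuple((m, 30.0) for m in np.linspace(250, 400, 21))
        pop = PopulationModel(scans=scans)
        target = 0.01
        T = min_threshold_for_fp(pop, target)
        assert fp_rate_population(pop, T) == pytest.approx(target, abs=1e-5)

    def test_inversion_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            min_threshold_for_fp(ARTERIAL, 0.0)
        with pytest.raises(ValueError):
            min_threshold_for_fp(ARTERIAL, 1.0)
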