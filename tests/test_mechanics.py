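"""Stress/strain arithmetic, cycle segmentation, and the stiffness and
hysteresis estimators against independent oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbmech import mechanics as mech
from sbmech.synthetic import SpecimenGeometry

from conftest import sine_record


class TestStressStrain:
    def test_zero_load_zero_stress(self, geometry):
        assert mech.compute_stress(np.zeros(5), geometry).max() == 0.0

    def test_unit_area_conversion(self):
        g = SpecimenGeometry(diameter=2.0)  # area = pi mm^2
        s = mech.compute_stress(np.array([np.pi]), g)
        assert s[0] == pytest.approx(1.0, rel=1e-12)

    def test_strain_definition_arithmetic(self):
        assert mech.compute_engineering_strain(np.array([0.1]), 10.0)[0] == pytest.approx(1.0)
        assert mech.compute_engineering_strain(np.array([10.0]), 10.0)[0] == pytest.approx(100.0)
        assert mech.compute_engineering_strain(np.array([0.0]), 10.0)[0] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.1, 10.0), ref=st.floats(1.0, 20.0))
    def test_linearity_properties(self, scale, ref):
        g = SpecimenGeometry(diameter=6.0)
        load = np.array([1.0, 5.0, -2.0])
        assert np.allclose(mech.compute_stress(load * scale, g),
                           scale * mech.compute_stress(load, g))
        disp = np.array([0.01, 0.2, 0.003])
        assert np.allclose(mech.compute_engineering_strain(disp * scale, ref),
                           scale * mech.compute_engineering_strain(disp, ref))

    def test_bad_inputs_rejected(self, geometry):
        with pytest.raises(ValueError):
            mech.compute_engineering_strain(np.array([1.0]), 0.0)


class TestSegmentation:
    def test_protocol_record_yields_100_cycles(self, two_layer_record):
        record, _ = two_layer_record
        cycles = mech.segment_cycles(record, 2.0)
        assert len(cycles) == 100
        # ~250 samples per cycle at 500 Hz / 2 Hz
        n = cycles[50][0].stress.size + cycles[50][1].stress.size - 1
        assert n == pytest.approx(251, abs=2)
        assert cycles[0][0].cycle_index == 1

    def test_three_and_a_half_periods_gives_three_cycles(self, geometry):
        record = sine_record(geometry, periods=3.5)
        assert len(mech.segment_cycles(record, 2.0)) == 3

    def test_constant_signal_gives_empty_with_warning(self, geometry, caplog):
        t = np.arange(0, 2, 1 / 500)
        record = mech.LoadDisplacementRecord(
            t, np.full_like(t, 30.0), np.zeros_like(t), 500.0, geometry, 10.0)
        with caplog.at_level("WARNING"):
            assert mech.segment_cycles(record, 2.0) == []
        assert "constant" in caplog.text

    def test_branch_extrema_are_cycle_boundaries(self, geometry):
        record = sine_record(geometry, periods=3.0)
        for loading, unloading in mech.segment_cycles(record, 2.0):
            assert loading.stress[0] == pytest.approx(loading.stress.min())
            assert loading.stress[-1] == pytest.approx(loading.stress.max())
            assert unloading.stress[0] == pytest.approx(unloading.stress.max())


def _normal_equations_slope(x, y):
    """Brute-force OLS slope via explicit normal equations."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)


class TestStiffness:
    def test_exact_linear_branch(self):
        strain = np.linspace(0.0, 2.0, 100)  # %
        stress = 1000.0 * strain / 100.0
        b = mech.CycleBranch(stress, strain, "loading", 1)
        assert mech.stiffness_middle50(b) == pytest.approx(1000.0, rel=1e-12)

    def test_quadratic_branch_matches_normal_equations_oracle(self):
        eps = np.linspace(0.0, 0.02, 500)
        stress = 5.0e6 * eps**2
        b = mech.CycleBranch(stress, eps * 100, "loading", 1)
        got = mech.stiffness_middle50(b)
        lo = stress.min() + 0.25 * np.ptp(stress)
        hi = stress.min() + 0.75 * np.ptp(stress)
        sel = (stress >= lo) & (stress <= hi)
        assert got == pytest.approx(_normal_equations_slope(eps[sel], stress[sel]), rel=1e-9)

    def test_simulated_cycle_matches_series_formula(self, reversible_record):
        record, truth = reversible_record
        loading, _ = mech.segment_cycles(record, 2.0)[49]
        assert mech.stiffness_middle50(loading) == pytest.approx(
            truth.whole_modulus, rel=0.02)

    def test_resampling_invariance(self):
        # a mildly nonlinear (physiological) branch sampled at two densities:
        # the stress-range window makes the slope sampling-invariant
        def branch(n):
            eps = np.linspace(0, 0.01, n)
            return mech.CycleBranch(3000 * eps + 2.0e4 * eps**2, eps * 100, "loading", 1)
        a = mech.stiffness_middle50(branch(120))
        b = mech.stiffness_middle50(branch(4000))
        assert a == pytest.approx(b, rel=1e-3)

    def test_too_few_samples_rejected_naming_cycle(self):
        b = mech.CycleBranch(np.linspace(0, 1, 6), np.linspace(0, 1, 6), "loading", 7)
        with pytest.raises(ValueError, match="cycle 7"):
            mech.stiffness_middle50(b)

    def test_zero_strain_variance_rejected(self):
        b = mech.CycleBranch(np.linspace(0, 1, 50), np.zeros(50), "loading", 1)
        with pytest.raises(ValueError, match="strain variance"):
            mech.stiffness_middle50(b)


class TestHysteresis:
    def test_retraced_loop_is_zero(self):
        eps = np.linspace(0, 1.0, 200)
        stress = 40 * (eps / 1.0) ** 1.5
        loading = mech.CycleBranch(stress, eps, "loading", 1)
        unloading = mech.CycleBranch(stress[::-1], eps[::-1], "unloading", 1)
        assert abs(mech.normalized_hysteresis(loading, unloading)) < 1e-12

    def test_total_dissipation_is_one(self):
        eps = np.linspace(0, 1.0, 200)
        loading = mech.CycleBranch(40 * eps, eps, "loading", 1)
        # unloading at zero stress back to the start
        unloading = mech.CycleBranch(np.zeros(200), eps[::-1], "unloading", 1)
        assert mech.normalized_hysteresis(loading, unloading) == pytest.approx(1.0)

    def test_elliptical_loop_matches_adaptive_quadrature(self):
        from scipy.integrate import quad
        delta, s_m, s_a, e_a = 0.1, 20.5, 19.5, 0.005
        th_load = np.linspace(-np.pi / 2, np.pi / 2, 200001)
        th_unload = np.linspace(np.pi / 2, 3 * np.pi / 2, 200001)

        def sigma(th):
            return s_m + s_a * np.sin(th)

        def eps_pct(th):
            return 100 * e_a * np.sin(th - delta)

        loading = mech.CycleBranch(sigma(th_load), eps_pct(th_load), "loading", 1)
        unloading = mech.CycleBranch(sigma(th_unload), eps_pct(th_unload), "unloading", 1)
        got = mech.normalized_hysteresis(loading, unloading)

        def dwork(th):
            return sigma(th) * e_a * np.cos(th - delta)

        w_load, _ = quad(dwork, -np.pi / 2, np.pi / 2, epsabs=1e-14)
        w_unload, _ = quad(dwork, np.pi / 2, 3 * np.pi / 2, epsabs=1e-14)
        expected = (w_load - abs(w_unload)) / w_load
        assert got == pytest.approx(expected, rel=1e-6)

    def test_dissipative_cycles_bounded(self, two_layer_record):
        record, _ = two_layer_record
        for m in mech.summarize_cycles(record, mech.TOTAL_CYCLES):
            assert 0.0 < m.normalized_hysteresis < 1.0

    def test_mismatched_cycles_rejected(self):
        a = mech.CycleBranch(np.array([0, 1.0]), np.array([0, 1.0]), "loading", 1)
        b = mech.CycleBranch(np.array([1.0, 0]), np.array([1.0, 0]), "unloading", 2)
        with pytest.raises(ValueError):
            mech.normalized_hysteresis(a, b)


class TestSummarize:
    def test_analysis_cycle_sets(self, two_layer_record):
        record, _ = two_layer_record
        total = mech.summarize_cycles(record, mech.TOTAL_CYCLES)
        assert [m.cycle_index for m in total] == list(mech.TOTAL_CYCLES)
        layers = mech.summarize_cycles(record, mech.LAYER_CYCLES)
        assert [m.cycle_index for m in layers] == [1, 2, 3, 5, 9]

    def test_stiffening_cycle99_ge_cycle1(self, two_layer_record):
        record, _ = two_layer_record
        m1, m99 = mech.summarize_cycles(record, [1, 99])
        assert m99.stiffness >= m1.stiffness

    def test_missing_cycle_rejected_with_range(self, geometry):
        record = sine_record(geometry, periods=3.5)
        with pytest.raises(ValueError, match="1..3"):
            mech.summarize_cycles(record, [7])
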