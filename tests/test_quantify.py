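"""The measurement formulas: indices, ratios, velocities, profile normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import minimum_filter1d

from midlinesim.quantify import (
    GolgiMeasure,
    IntensityProfile,
    MeasurementError,
    PairedProfile,
    apical_basal_signal_ratio,
    estimate_kymograph_angle,
    golgi_position_index,
    kymograph_velocity,
    normalize_paired_profile,
    nuclear_cytoplasmic_ratio,
    positive_fraction,
)
from midlinesim.synthetic import make_kymograph, make_paired_profile


class TestGolgiIndex:
    @pytest.mark.parametrize(
        "L,a,b,expected",
        [(10, 4, 6, 0.5), (10, 10, 10, 1.0), (10, 0, 0, 0.0), (8, 2, 6, 0.5)],
    )
    def test_values(self, L, a, b, expected):
        assert golgi_position_index(GolgiMeasure(L, a, b)) == pytest.approx(expected)

    @pytest.mark.parametrize("L,a,b", [(0, 0, 0), (10, 6, 4), (10, 2, 11), (10, -1, 4)])
    def test_invalid_measures(self, L, a, b):
        with pytest.raises(MeasurementError):
            GolgiMeasure(L, a, b)

    @given(
        st.floats(0.5, 100),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    @settings(deadline=None, derandomize=True)
    def test_reflection_equivariance(self, L, u1, u2):
        """Reflecting the cell front-to-back maps the index to 1 - index."""
        a, b = sorted((u1 * L, u2 * L))
        m = GolgiMeasure(L, a, b)
        reflected = GolgiMeasure(L, L - b, L - a)
        assert golgi_position_index(reflected) == pytest.approx(
            1 - golgi_position_index(m), abs=1e-9
        )


class TestApicalBasalRatio:
    def test_uniform_profile_is_one(self):
        p = IntensityProfile(np.arange(10.0), np.ones(10))
        assert apical_basal_signal_ratio(p) == pytest.approx(1.0)

    def test_hand_summed_example(self):
        # first 3 of 10 samples sum to 3, last 3 sum to 6
        p = IntensityProfile(np.arange(10.0), np.array([1, 1, 1, 0, 0, 0, 0, 2, 2, 2.0]))
        assert apical_basal_signal_ratio(p, fraction=0.3) == pytest.approx(0.5)

    def test_reflection_gives_reciprocal(self):
        p = IntensityProfile(np.arange(10.0), np.array([1, 1, 1, 0, 0, 0, 0, 2, 2, 2.0]))
        r = apical_basal_signal_ratio(p)
        assert apical_basal_signal_ratio(p.reflected()) == pytest.approx(1 / r)

    def test_signal_in_final_fraction_only(self):
        p = IntensityProfile(np.arange(10.0), np.array([0, 0, 0, 0, 0, 0, 0, 2, 2, 2.0]))
        assert apical_basal_signal_ratio(p) == pytest.approx(0.0)

    def test_zero_basal_sum_rejected(self):
        p = IntensityProfile(np.arange(10.0), np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0.0]))
        with pytest.raises(MeasurementError):
            apical_basal_signal_ratio(p)

    def test_fraction_validated(self):
        p = IntensityProfile(np.arange(10.0), np.ones(10))
        with pytest.raises(MeasurementError):
            apical_basal_signal_ratio(p, fraction=0.7)


class TestKymographVelocity:
    def test_unit_conversion(self):
        assert kymograph_velocity(45, 1, 1) == pytest.approx(1.0)
        assert kymograph_velocity(0, 1, 1) == 0.0
        assert kymograph_velocity(30, 0.5, 2) == pytest.approx(np.tan(np.radians(30)) * 0.25)

    def test_vertical_line_undefined(self):
        with pytest.raises(MeasurementError):
            kymograph_velocity(90, 1, 1)

    @pytest.mark.parametrize("velocity", [0.0, 0.5, 1.0, 2.0])
    def test_recovers_generating_velocity(self, velocity):
        """Closed loop: synthetic kymograph -> angle -> velocity within 5%."""
        image, truth = make_kymograph(velocity, duration=120, noise_sd=0.03, seed=7)
        angle = estimate_kymograph_angle(image)
        v = kymograph_velocity(angle, truth.space_per_px, truth.time_per_row)
        assert v == pytest.approx(velocity, rel=0.05, abs=0.01)


class TestCountsAndRatios:
    @pytest.mark.parametrize("npos,ntot,expected", [(0, 8, 0.0), (12, 12, 1.0), (3, 12, 0.25)])
    def test_positive_fraction(self, npos, ntot, expected):
        assert positive_fraction(npos, ntot) == pytest.approx(expected)

    def test_positive_fraction_errors(self):
        with pytest.raises(MeasurementError):
            positive_fraction(1, 0)
        with pytest.raises(MeasurementError):
            positive_fraction(5, 3)

    @pytest.mark.parametrize("nuc,cyt,expected", [(1, 1, 1.0), (2, 1, 2.0), (0, 3, 0.0)])
    def test_nc_ratio(self, nuc, cyt, expected):
        assert nuclear_cytoplasmic_ratio(nuc, cyt) == pytest.approx(expected)

    def test_nc_ratio_errors(self):
        with pytest.raises(MeasurementError):
            nuclear_cytoplasmic_ratio(1.0, 0.0)
        with pytest.raises(MeasurementError):
            nuclear_cytoplasmic_ratio(-1.0, 1.0)


class TestProfileNormalization:
    def flat_pair(self, n=200, signal=3.0, ref=2.0):
        x = np.linspace(0, 100, n)
        return PairedProfile(
            IntensityProfile(x, np.full(n, signal)), IntensityProfile(x, np.full(n, ref))
        )

    def test_flat_inputs_give_all_ones(self):
        out = normalize_paired_profile(self.flat_pair(), filter_window=11, n_bins=20)
        np.testing.assert_array_equal(out, np.ones(20))

    def test_exactly_one_bin_is_one(self):
        pp, _ = make_paired_profile(seed=3, noise_sd=0.01)
        out = normalize_paired_profile(pp)
        assert np.sum(out == 1.0) == 1
        assert out.max() == 1.0

    def test_narrow_reference_spikes_removed(self):
        """Isolated spikes narrower than the window leave the output unchanged,
        matching a brute-force running-minimum oracle."""
        n, win = 300, 11
        x = np.linspace(0, 100, n)
        ref = np.full(n, 2.0)
        spiky = ref.copy()
        spiky[[50, 51, 120, 200]] += 6.0  # spikes of width << window
        sig = np.linspace(1, 3, n)
        clean = normalize_paired_profile(
            PairedProfile(IntensityProfile(x, sig), IntensityProfile(x, ref)), win, 20
        )
        despiked = normalize_paired_profile(
            PairedProfile(IntensityProfile(x, sig), IntensityProfile(x, spiky)), win, 20
        )
        np.testing.assert_allclose(despiked, clean)
        # brute-force oracle for the running-minimum primitive
        brute = np.array(
            [spiky[max(0, i - win // 2): i + win // 2 + 1].min() for i in range(n)]
        )
        np.testing.assert_array_equal(minimum_filter1d(spiky, win, mode="nearest"), brute)

    def test_linear_ramp_recovers_bin_centers(self):
        """signal = ramp, reference = const: bins reproduce the analytic ramp
        means rescaled to max 1."""
        n, n_bins = 4000, 20
        x = np.linspace(0, 1, n)
        pp = PairedProfile(IntensityProfile(x, x.copy()), IntensityProfile(x, np.ones(n)))
        out = normalize_paired_profile(pp, 11, n_bins)
        edges = np.linspace(0, 1, n_bins + 1)
        analytic = 0.5 * (edges[:-1] + edges[1:])
        analytic /= analytic.max()
        np.testing.assert_allclose(out, analytic, atol=2e-3)

    def test_common_scaling_invariances(self):
        pp, _ = make_paired_profile(seed=1, noise_sd=0.0)
        base = normalize_paired_profile(pp)
        both = PairedProfile(
            IntensityProfile(pp.signal.positions, 7.0 * pp.signal.values),
            IntensityProfile(pp.reference.positions, 7.0 * pp.reference.values),
        )
        sig_only = PairedProfile(
            IntensityProfile(pp.signal.positions, 3.5 * pp.signal.values), pp.reference
        )
        np.testing.assert_allclose(normalize_paired_profile(both), base, atol=1e-12)
        np.testing.assert_allclose(normalize_paired_profile(sig_only), base, atol=1e-12)

    def test_parameter_validation(self):
        pp = self.flat_pair()
        with pytest.raises(MeasurementError):
            normalize_paired_profile(pp, filter_window=4)
        with pytest.raises(MeasurementError):
            normalize_paired_profile(pp, n_bins=1)

    def test_zero_baseline_rejected(self):
        x = np.arange(50.0)
        pp = PairedProfile(
            IntensityProfile(x, np.ones(50)), IntensityProfile(x, np.zeros(50))
        )
        with pytest.raises(MeasurementError):
            normalize_paired_profile(pp)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(MeasurementError):
            PairedProfile(
                IntensityProfile(np.arange(5.0), np.ones(5)),
                IntensityProfile(np.arange(1.0, 6.0), np.ones(5)),
            )
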