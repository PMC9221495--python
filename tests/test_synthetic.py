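import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cisquant import (
    DatasetDesign,
    KineticParams,
    absorbance_to_channels,
    generate_dataset,
    kinetic_curve,
    render_frames,
)


class TestKineticCurve:
    def test_closed_form_value(self):
        # A = 0.5 * (1 - e^-1.5) with Amax=1, c_half=100, k=0.05, c=100, t=30
        params = KineticParams(
            max_amplitude=1.0, half_saturation_conc=100.0,
            rate_base=0.05, rate_conc_exponent=0.0,
        )
        a = kinetic_curve(100.0, np.array([30.0]), params)
        assert a[0] == pytest.approx(0.5 * (1 - np.exp(-1.5)), abs=1e-12)
        assert a[0] == pytest.approx(0.38843, abs=5e-6)

    def test_zero_concentration_and_zero_time(self):
        params = KineticParams()
        t = np.linspace(0, 150, 151)
        assert np.all(kinetic_curve(0.0, t, params) == 0.0)
        assert kinetic_curve(500.0, np.array([0.0]), params)[0] == 0.0

    @given(
        c1=st.floats(0.0, 2000.0),
        c2=st.floats(0.0, 2000.0),
        t=st.floats(0.0, 300.0),
    )
    def test_monotone_in_concentration_and_time(self, c1, c2, t):
        params = KineticParams()
        lo, hi = sorted([c1, c2])
        grid = np.array([t, t + 10.0])
        a_lo = kinetic_curve(lo, grid, params)
        a_hi = kinetic_curve(hi, grid, params)
        assert a_hi[0] >= a_lo[0] - 1e-12  # non-decreasing in c
        assert a_hi[1] >= a_hi[0] - 1e-12  # non-decreasing in t

    def test_rejects_invalid_inputs(self):
        params = KineticParams()
        with pytest.raises(ValueError):
            kinetic_curve(-1.0, np.array([0.0]), params)
        with pytest.raises(ValueError):
            kinetic_curve(1.0, np.array([-1.0, 2.0]), params)
        with pytest.raises(ValueError):
            kinetic_curve(1.0, np.array([5.0, 2.0]), params)


class TestAbsorbanceToChannels:
    def test_zero_absorbance_is_baseline(self):
        params = KineticParams(baseline_rgb=(0.9, 0.8, 0.7))
        np.testing.assert_allclose(
            absorbance_to_channels(0.0, params), [0.9, 0.8, 0.7]
        )

    def test_beer_lambert_closed_form(self):
        params = KineticParams(
            baseline_rgb=(1.0, 1.0, 1.0), channel_extinction=(1.0, 0.5, 0.0)
        )
        out = absorbance_to_channels(1.0, params)
        np.testing.assert_allclose(out, [0.1, 10 ** -0.5, 1.0], atol=1e-12)

    @given(a=st.floats(0.0, 3.0), gap=st.floats(1e-9, 1.0))
    def test_red_strictly_decreasing_in_absorbance(self, a, gap):
        params = KineticParams()
        red_lo = absorbance_to_channels(a, params)[0]
        red_hi = absorbance_to_channels(a + gap, params)[0]
        assert red_hi < red_lo

    def test_rejects_negative_absorbance(self):
        with pytest.raises(ValueError):
            absorbance_to_channels(-0.1, KineticParams())


class TestGenerateDataset:
    def test_default_design_counts(self):
        design = DatasetDesign()
        assert design.n_tubes == 62
        assert design.n_timepoints == 150
        low = [c for c, _ in design.levels if c <= 65]
        high = [(c, n) for c, n in design.levels if c >= 100]
        assert sum(n for c, n in design.levels if c <= 65) == 22
        assert low == [1.5, 3, 6.5, 17, 33, 45, 65]
        assert high == [(c, 4) for c in
                        (100, 200, 350, 500, 600, 700, 900, 1000, 1100, 1200)]
        dataset = generate_dataset(design, KineticParams(), seed=0)
        assert len(dataset) == 62
        assert all(s.n_timepoints == 150 and s.n_channels == 3
                   for s in dataset)

    def test_per_level_counts_match_design(self, small_design):
        dataset = generate_dataset(small_design, KineticParams(), seed=3)
        for conc, n in small_design.levels:
            assert sum(s.true_concentration == conc for s in dataset) == n

    def test_noise_free_replicates_identical(self, small_design,
                                             noiseless_params):
        dataset = generate_dataset(small_design, noiseless_params, seed=1)
        by_level = {}
        for s in dataset:
            by_level.setdefault(s.true_concentration, []).append(s)
        for reps in by_level.values():
            for other in reps[1:]:
                np.testing.assert_array_equal(reps[0].values, other.values)

    def test_seed_determinism(self, small_design):
        a = generate_dataset(small_design, KineticParams(), seed=7)
        b = generate_dataset(small_design, KineticParams(), seed=7)
        c = generate_dataset(small_design, KineticParams(), seed=8)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.values, t.values)
        assert any(not np.array_equal(s.values, t.values)
                   for s, t in zip(a, c))

    def test_noise_free_red_channel_monotone_in_concentration(
        self, noiseless_params
    ):
        design = DatasetDesign(
            levels=((10.0, 1), (100.0, 1), (1000.0, 1)), duration_s=50.0
        )
        dataset = generate_dataset(design, noiseless_params, seed=0)
        red = [s.channel("R") for s in dataset]
        # higher concentration -> more blue product -> darker red, everywhere
        # after t=0
        assert np.all(red[0][1:] > red[1][1:])
        assert np.all(red[1][1:] > red[2][1:])

    def test_design_validation(self):
        with pytest.raises(ValueError):
            DatasetDesign(levels=((5.0, 1), (3.0, 1)))
        with pytest.raises(ValueError):
            DatasetDesign(levels=((5.0, 0),))
        with pytest.raises(ValueError):
            DatasetDesign(duration_s=10.0, frame_rate_hz=0.25)
        with pytest.raises(ValueError):
            KineticParams(noise_sd=-0.1)
        with pytest.raises(ValueError):
            KineticParams(baseline_rgb=(1.5, 0.5, 0.5))


class TestRenderFrames:
    def test_one_frame_per_timepoint_and_roi_content(self, small_design,
                                                     noiseless_params):
        series = generate_dataset(small_design, noiseless_params, seed=0)[0]
        frames = render_frames(series, image_size=(32, 40),
                               tube_roi=(10, 8, 30, 24))
        assert frames.shape == (30, 32, 40, 3)
        assert frames.dtype == np.uint8
        # ROI carries the series, quantized to 8 bits
        roi_mean = frames[:, 8:24, 10:30, :].reshape(30, -1, 3).mean(axis=1)
        np.testing.assert_allclose(
            roi_mean / 255.0, series.values.T, atol=1 / 510 + 1e-9
        )

    def test_constant_series_gives_identical_frames(self):
        from conftest import make_series

        series = make_series(np.full((3, 5), 0.4), channels=("R", "G", "B"))
        frames = render_frames(series)
        for f in frames[1:]:
            np.testing.assert_array_equal(frames[0], f)

    def test_roi_outside_image_rejected(self):
        from conftest import make_series

        series = make_series(np.full((3, 2), 0.4), channels=("R", "G", "B"))
        with pytest.raises(ValueError):
            render_frames(series, image_size=(20, 20), tube_roi=(0, 0, 25, 10))
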