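"""Beamforming: receive delay law, DAS vs brute-force oracle, coherence
factor, compounding, envelope detection and log compression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from oracles import naive_das_focused

import fusviz as fv
from fusviz.beamform import BeamformedImage


def _image(values, kind, dx=1e-3, dz=1e-3):
    values = np.asarray(values, dtype=float)
    nz, nx = values.shape
    return BeamformedImage(values, np.arange(nx) * dx, (1 + np.arange(nz)) * dz, kind)


class TestReceiveDelay:
    def test_on_axis_round_trip(self):
        tau = fv.receive_delay(x=0.0, x_c=0.0, z=30e-3, c=1540.0)
        assert tau * 1e6 == pytest.approx(38.96, abs=0.01)

    def test_transmit_delay_is_additive(self):
        base = fv.receive_delay(2e-3, 0.0, 10e-3, 1540.0, tau_f=0.0)
        shifted = fv.receive_delay(2e-3, 0.0, 10e-3, 1540.0, tau_f=1e-6)
        assert shifted - base == pytest.approx(1e-6)

    def test_shallow_limit_is_lateral_path(self):
        x, xc, c = 3e-3, 1e-3, 1540.0
        tau = fv.receive_delay(x, xc, 1e-9, c)
        assert tau == pytest.approx(abs(x - xc) / c, rel=1e-6)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            fv.receive_delay(0.0, 0.0, -1e-3, 1540.0)


class TestCoherenceFactor:
    def test_identical_channels_fully_coherent(self):
        assert fv.coherence_factor(np.full(8, 3.2)) == pytest.approx(1.0)

    def test_cancelling_pair_zero(self):
        assert fv.coherence_factor(np.array([1.5, -1.5])) == pytest.approx(0.0)

    def test_half_coherent_example(self):
        assert fv.coherence_factor(np.array([1.0, 1.0, 0.0, 0.0])) == pytest.approx(0.5)

    def test_zero_energy_defined_as_zero(self):
        assert fv.coherence_factor(np.zeros(4)) == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        hnp.arrays(
            dtype=float,
            shape=st.integers(1, 32),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_bounded_unit_interval(self, s):
        cf = fv.coherence_factor(s)
        assert 0.0 <= cf <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        hnp.arrays(
            dtype=float,
            shape=st.integers(2, 16),
            elements=st.floats(-100, 100, allow_nan=False),
        ),
        st.floats(1e-3, 1e3).filter(lambda g: g != 0),
    )
    def test_scale_invariance(self, s, g):
        assert fv.coherence_factor(g * s) == pytest.approx(
            fv.coherence_factor(s), abs=1e-12
        )


class TestApplyCF:
    def test_unit_map_is_identity(self):
        y = _image(np.random.default_rng(0).normal(size=(5, 4)), "y")
        cf = _image(np.ones((5, 4)), "cf_map")
        np.testing.assert_array_equal(fv.apply_cf(y, cf).values, y.values)

    def test_zero_map_annihilates(self):
        y = _image(np.ones((3, 3)), "y")
        cf = _image(np.zeros((3, 3)), "cf_map")
        assert np.all(fv.apply_cf(y, cf).values == 0.0)

    def test_never_amplifies(self):
        rng = np.random.default_rng(1)
        y = _image(rng.normal(size=(6, 5)), "y")
        cf = _image(rng.uniform(0, 1, size=(6, 5)), "cf_map")
        out = fv.apply_cf(y, cf)
        assert np.all(np.abs(out.values) <= np.abs(y.values) + 1e-15)

    def test_grid_mismatch_rejected(self):
        y = _image(np.ones((3, 3)), "y")
        cf = _image(np.ones((4, 3)), "cf_map")
        with pytest.raises(ValueError):
            fv.apply_cf(y, cf)


@pytest.fixture(scope="module")
def small_setup():
    """8-element aperture over a 10-scatterer random scene."""
    arr = fv.make_array(n_elements=8, pitch=0.3048e-3)
    rng = np.random.default_rng(4)
    pts = tuple(
        fv.PointTarget(x, z, level_db=0.0)
        for x, z in zip(
            rng.uniform(-1e-3, 1e-3, 10), rng.uniform(8e-3, 14e-3, 10)
        )
    )
    scene = fv.build_scene(fv.SceneSpec(background=False, points=pts), 0)
    tx = fv.focused_delays(arr, (0.0, 11e-3))
    pulse = fv.make_pulse(2)
    rf = fv.simulate_rf(arr, tx, pulse, scene, min_record_time=2.5e-5)
    return arr, rf, pulse


class TestDASFocused:
    def test_zero_rf_gives_zero_image(self):
        arr = fv.make_array(n_elements=4)
        tx = fv.focused_delays(arr, (0.0, 20e-3))
        rf = fv.RFFrame(np.zeros((400, 4)), arr.fs, 0.0, tx)
        res = fv.das_focused(rf, arr, np.linspace(5e-3, 12e-3, 20))
        assert np.all(res.y.values == 0.0)
        assert np.all(res.cf.values == 0.0)

    def test_matches_bruteforce_oracle(self, small_setup):
        """Vectorized DAS equals an independent triple-loop delay-and-sum
        to better than 1e-6 relative error."""
        arr, rf, pulse = small_setup
        z_grid = np.linspace(9e-3, 13e-3, 40)
        res = fv.das_focused(rf, arr, z_grid, f_number=1.0,
                             wavelet_peak_time=pulse.peak_time)
        ref = naive_das_focused(
            rf.data, rf.t0, rf.fs, arr.element_x, rf.tx.delays, z_grid,
            arr.c, 1.0, peak_time=pulse.peak_time,
        )
        err = np.linalg.norm(res.y.values - ref) / np.linalg.norm(ref)
        assert err < 1e-6

    def test_linearity_in_rf(self, small_setup):
        arr, rf, pulse = small_setup
        z_grid = np.linspace(9e-3, 13e-3, 15)
        y1 = fv.das_focused(rf, arr, z_grid).y.values
        rf3 = fv.RFFrame(3.0 * rf.data, rf.fs, rf.t0, rf.tx)
        y3 = fv.das_focused(rf3, arr, z_grid).y.values
        np.testing.assert_allclose(y3, 3.0 * y1, rtol=1e-12)

    def test_scatterer_at_focus_peaks_at_focus(self):
        arr = fv.make_array(n_elements=8, pitch=0.3048e-3)
        focus = (0.0, 11e-3)
        tx = fv.focused_delays(arr, focus)
        pulse = fv.make_pulse(2)
        scene = fv.build_scene(
            fv.SceneSpec(background=False, points=(fv.PointTarget(*focus, 0.0),)), 0
        )
        rf = fv.simulate_rf(arr, tx, pulse, scene, min_record_time=2.5e-5)
        z_grid = np.arange(9e-3, 13e-3, arr.dz)
        res = fv.das_focused(rf, arr, z_grid, wavelet_peak_time=pulse.peak_time)
        env = fv.envelope(res.y)
        iz, ix = np.unravel_index(np.argmax(env.values), env.values.shape)
        assert abs(env.x_grid[ix] - focus[0]) <= arr.pitch
        assert abs(env.z_grid[iz] - focus[1]) <= pulse.n_samples * arr.dz

    def test_channel_samples_sum_to_beamformed_output(self, small_setup):
        """The optionally exposed delayed/apodized subaperture samples sum
        to the DAS output and vanish outside the dynamic aperture."""
        arr, rf, pulse = small_setup
        z_grid = np.linspace(9e-3, 13e-3, 12)
        res = fv.das_focused(rf, arr, z_grid, f_number=4.0, store_channels=True)
        assert res.channels.shape == (12, arr.n_elements, arr.n_elements)
        np.testing.assert_allclose(
            res.channels.sum(axis=2), res.y.values, atol=1e-12
        )
        # at the shallowest depth the aperture is narrowest: far elements
        # of an edge line lie outside it and contribute exactly zero
        half = z_grid[0] / 8.0
        outside = np.abs(arr.element_x - arr.element_x[0]) > half
        assert outside.any()
        assert np.all(res.channels[0, 0, outside] == 0.0)

    def test_bad_f_number_rejected(self, small_setup):
        arr, rf, _ = small_setup
        with pytest.raises(ValueError):
            fv.das_focused(rf, arr, np.linspace(9e-3, 13e-3, 5), f_number=0.0)

    def test_requires_focused_event(self, small_setup):
        arr, rf, _ = small_setup
        pw = fv.RFFrame(rf.data, rf.fs, rf.t0, fv.plane_wave_delays(arr, 0.0))
        with pytest.raises(ValueError):
            fv.das_focused(pw, arr, np.linspace(9e-3, 13e-3, 5))


class TestPlaneWaveDASAndCompounding:
    def test_zero_rf_gives_zero_image(self):
        arr = fv.make_array(n_elements=4)
        tx = fv.plane_wave_delays(arr, 0.1)
        rf = fv.RFFrame(np.zeros((400, 4)), arr.fs, 0.0, tx)
        res = fv.das_plane_wave(rf, arr, 0.1, np.linspace(5e-3, 12e-3, 10))
        assert np.all(res.y.values == 0.0)

    def test_point_target_at_true_position(self):
        arr = fv.make_array(n_elements=16, pitch=0.3048e-3)
        tx = fv.plane_wave_delays(arr, 0.0)
        pulse = fv.make_pulse(2)
        target = (0.5e-3, 12e-3)
        scene = fv.build_scene(
            fv.SceneSpec(background=False, points=(fv.PointTarget(*target, 0.0),)), 0
        )
        rf = fv.simulate_rf(arr, tx, pulse, scene, min_record_time=2.5e-5)
        z_grid = np.arange(10e-3, 14e-3, arr.dz)
        res = fv.das_plane_wave(rf, arr, 0.0, z_grid, wavelet_peak_time=pulse.peak_time)
        env = fv.envelope(res.y)
        iz, ix = np.unravel_index(np.argmax(env.values), env.values.shape)
        assert abs(env.x_grid[ix] - target[0]) <= arr.pitch
        assert abs(env.z_grid[iz] - target[1]) <= pulse.n_samples * arr.dz

    def test_compound_sums_and_identity(self):
        img = _image(np.random.default_rng(2).normal(size=(4, 3)), "y")
        np.testing.assert_array_equal(fv.compound([img]).values, img.values)
        np.testing.assert_allclose(
            fv.compound([img, img, img]).values, 3.0 * img.values
        )

    def test_compound_grid_mismatch_rejected(self):
        a = _image(np.ones((3, 3)), "y")
        b = _image(np.ones((3, 3)), "y", dx=2e-3)
        with pytest.raises(ValueError):
            fv.compound([a, b])

    def test_compounding_lowers_point_sidelobes(self, point_acq):
        """Coherently compounding the seven steered plane waves yields a
        lower peak-sidelobe-to-mainlobe ratio than any single angle."""
        arr = point_acq.array
        peak_t = point_acq.pulse.peak_time
        z_grid = np.arange(28e-3, 32e-3, arr.dz)
        singles = [
            fv.das_plane_wave(f, arr, f.tx.angle, z_grid, wavelet_peak_time=peak_t).y
            for f in point_acq.plane_waves
        ]

        def psl(img_rf):
            env = fv.envelope(img_rf).values
            iz = np.argmax(env.max(axis=1))
            prof = env[max(0, iz - 4): iz + 5, :].max(axis=0)
            prof_db = 20 * np.log10(prof / prof.max() + 1e-300)
            x = singles[0].x_grid
            side = np.abs(x - x[np.argmax(prof)]) > 1.5e-3
            return prof_db[side].max()

        compound_psl = psl(fv.compound(singles))
        assert all(compound_psl < psl(s) for s in singles)


class TestEnvelopeAndLogCompression:
    def test_zero_input_zero_envelope(self):
        y = _image(np.zeros((16, 2)), "y")
        assert np.all(fv.envelope(y).values == 0.0)

    def test_windowed_tone_envelope_recovers_amplitude(self):
        n = 512
        tone = 2.7 * np.sin(2 * np.pi * 0.125 * np.arange(n))
        y = _image(tone[:, None], "y")
        env = fv.envelope(y).values[:, 0]
        mid = env[n // 4 : 3 * n // 4]
        np.testing.assert_allclose(mid, 2.7, rtol=0.02)
        assert np.all(env >= 0.0)

    def test_log_compress_reference_points(self):
        env = _image(np.array([[10.0, 1.0, 0.0]]).T, "envelope")
        db = fv.log_compress(env, floor_db=-80.0).values[:, 0]
        assert db[0] == 0.0
        assert db[1] == pytest.approx(-20.0)
        assert db[2] == -80.0  # clipped at the floor
        inten = _image(np.array([[100.0, 1.0]]).T, "intensity")
        db_i = fv.log_compress(inten).values[:, 0]
        assert db_i[1] == pytest.approx(-20.0)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            fv.log_compress(_image(np.zeros((3, 3)), "envelope"))

    def test_rf_input_rejected(self):
        with pytest.raises(ValueError):
            fv.log_compress(_image(np.ones((3, 3)), "y"))
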