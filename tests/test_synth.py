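"""Synthetic OPM-MEG generator: geometry, lead fields, burst dynamics."""

import numpy as np
import pytest

from opmbursts.paradigm import CUE_WINDOW_S, generate_schedule
from opmbursts.synth import (
    BurstSpec,
    build_helmet_array,
    make_source_model,
    region_lead_field,
    simulate_recording,
    simulate_source_timecourse,
    sphere_lead_field,
)


class TestHelmetArray:
    def test_sensor_and_channel_counts(self):
        array = build_helmet_array(64, 0.12, rng=0)
        assert array.n_sensors == 64
        assert array.n_channels == 192

    def test_axis_triads_orthonormal(self):
        array = build_helmet_array(16, 0.12, rng=1)
        for triad in array.axes:
            assert np.allclose(triad @ triad.T, np.eye(3), atol=1e-10)

    def test_no_duplicate_sensors_across_seeds(self):
        for seed in range(100):
            pos = build_helmet_array(12, 0.12, rng=seed).positions
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 0

    def test_sensors_outside_conductor(self):
        array = build_helmet_array(32, 0.12, rng=2)
        assert (np.linalg.norm(array.positions, axis=1) > 0.09).all()

    def test_rejects_empty_array(self):
        with pytest.raises(ValueError):
            build_helmet_array(0, 0.12, rng=0)


def _sympy_sphere_field(r0, q, r):
    """Independent closed-form oracle: B = (mu0/4pi) * grad[(q x r0 . r)/F],
    with the gradient taken symbolically."""
    import sympy as sp

    x, y, z = sp.symbols("x y z", real=True)
    rv = sp.Matrix([x, y, z])
    r0v = sp.Matrix(r0)
    qv = sp.Matrix(q)
    av = rv - r0v
    a = sp.sqrt(av.dot(av))
    rn = sp.sqrt(rv.dot(rv))
    F = a * (rn * a + rn**2 - r0v.dot(rv))
    g = qv.cross(r0v).dot(rv) / F
    grad = sp.Matrix([sp.diff(g, v) for v in (x, y, z)])
    fn = sp.lambdify((x, y, z), grad, "numpy")
    return 1e-7 * np.asarray(fn(*r), dtype=float).ravel()


class TestSphereLeadField:
    def test_central_dipole_is_silent(self):
        sensor = np.array([0.0, 0.0, 0.12])
        for axis in np.eye(3):
            b = sphere_lead_field(np.zeros(3), np.array([1e-8, 2e-8, 0]),
                                  sensor, axis)
            assert b == pytest.approx(0.0, abs=1e-25)

    def test_radial_dipole_is_silent(self):
        pos = np.array([0.0, 0.03, 0.05])
        moment = 1e-8 * pos / np.linalg.norm(pos)     # purely radial
        array = build_helmet_array(8, 0.12, rng=0)
        for cpos, cax in zip(array.channel_positions, array.channel_axes):
            assert abs(sphere_lead_field(pos, moment, cpos, cax)) < 1e-22

    def test_linearity_in_moment(self):
        pos = np.array([0.02, -0.01, 0.05])
        moment = np.array([1e-8, 0.5e-8, 0.0])
        sensor, axis = np.array([0.05, 0.02, 0.11]), np.array([0.0, 1.0, 0.0])
        b1 = sphere_lead_field(pos, moment, sensor, axis)
        b2 = sphere_lead_field(pos, 2 * moment, sensor, axis)
        assert b2 == pytest.approx(2 * b1, rel=1e-12)

    def test_matches_symbolic_gradient_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            r0 = rng.uniform(-0.04, 0.04, 3)
            radial = r0 / np.linalg.norm(r0)
            q = rng.standard_normal(3) * 1e-8
            q -= (q @ radial) * radial                 # tangential dipole
            r = rng.standard_normal(3)
            r = 0.12 * r / np.linalg.norm(r)
            expected = _sympy_sphere_field(r0, q, r)
            for axis in np.eye(3):
                got = sphere_lead_field(r0, q, r, axis)
                assert got == pytest.approx(expected @ axis, rel=1e-12, abs=1e-30)

    def test_geometry_preconditions(self):
        with pytest.raises(ValueError):
            sphere_lead_field(np.array([0, 0, 0.1]), np.ones(3),
                              np.array([0, 0, 0.12]), np.array([0, 0, 1.0]),
                              conductor_radius=0.09)
        with pytest.raises(ValueError):
            sphere_lead_field(np.array([0, 0, 0.05]), np.ones(3),
                              np.array([0, 0, 0.08]), np.array([0, 0, 1.0]),
                              conductor_radius=0.09)


class TestSourceTimecourse:
    def test_unmodulated_burst_rate_recovers_baseline(self):
        sched = generate_schedule(36, 9, rng=0)        # 640 s
        spec = BurstSpec(attended_rate_factor=1.0, stim_suppression_factor=1.0)
        _, iv = simulate_source_timecourse(sched, spec, 200.0, rng=1,
                                           region_hand="right")
        T = sched.total_duration_s
        rate = len(iv) / T
        se = np.sqrt(spec.baseline_rate / T)
        assert abs(rate - spec.baseline_rate) < 3 * se

    def test_zero_attended_factor_empties_attended_windows(self):
        sched = generate_schedule(20, 10, rng=2)
        spec = BurstSpec(attended_rate_factor=0.0)
        _, iv = simulate_source_timecourse(sched, spec, 200.0, rng=3,
                                           region_hand="right")
        for trial in sched.task_trials:
            if trial.cue != "right":
                continue
            rel = iv[:, 0] - trial.start_s
            in_att = ((rel >= CUE_WINDOW_S[0]) & (rel < CUE_WINDOW_S[1])) | (
                (rel >= 7.0) & (rel < 12.5))
            assert not in_att.any()

    def test_burst_segments_are_pan_spectral(self):
        # alpha peak plus beta shoulder, both above the 35-48 Hz floor
        from opmbursts.bursts import multitaper_psd

        sched = generate_schedule(18, 9, rng=4)
        spec = BurstSpec(background_sd_frac=0.0, attended_rate_factor=1.0,
                         stim_suppression_factor=1.0)
        x, iv = simulate_source_timecourse(sched, spec, 200.0, rng=5)
        segs = [x[int(a * 200):int(b * 200)] for a, b in iv
                if (b - a) >= 0.3]
        cat = np.concatenate(segs)
        freqs, psd = multitaper_psd(cat, 200.0, win_s=0.3, step_s=0.3)

        def band_mean(lo, hi):
            sel = (freqs >= lo) & (freqs <= hi)
            return psd[sel].mean()

        alpha, beta, high = band_mean(8, 13), band_mean(13, 30), band_mean(35, 48)
        assert alpha > beta > high
        assert beta > 3 * high

    def test_fs_floor_enforced(self):
        sched = generate_schedule(2, 10, rng=0)
        with pytest.raises(ValueError):
            simulate_source_timecourse(sched, BurstSpec(), 100.0, rng=0)


class TestSimulateRecording:
    def test_noise_free_recording_is_linear_projection(self, small_schedule):
        array = build_helmet_array(6, 0.12, rng=0)
        model = make_source_model(2)
        ds = simulate_recording(small_schedule, model, array, BurstSpec(),
                                noise_sd=0.0, drift_amplitude=0.0,
                                fs=200.0, rng=11)
        expected = np.zeros_like(ds.recording.data)
        for r in range(model.n_regions):
            gain = region_lead_field(model, array, r) @ ds.truth_orientations[r]
            expected += np.outer(gain, ds.truth_sources[r])
        assert np.allclose(ds.recording.data, expected, rtol=1e-12, atol=1e-20)

    def test_attended_window_burst_suppression_ratio(self):
        sched = generate_schedule(200, 10, rng=6)
        spec = BurstSpec(stim_suppression_factor=1.0)
        _, iv = simulate_source_timecourse(sched, spec, 200.0, rng=7,
                                           region_hand="right")
        att = non = 0
        for trial in sched.task_trials:
            rel = iv[:, 0] - trial.start_s
            n = ((rel >= CUE_WINDOW_S[0]) & (rel < CUE_WINDOW_S[1])).sum()
            if trial.cue == "right":
                att += n
            else:
                non += n
        expected_att = 100 * 2 * spec.baseline_rate * spec.attended_rate_factor
        expected_non = 100 * 2 * spec.baseline_rate
        ratio = att / non
        se = spec.attended_rate_factor * np.sqrt(1 / expected_att + 1 / expected_non)
        assert abs(ratio - spec.attended_rate_factor) < 3 * se

    def test_seed_determinism(self, small_schedule):
        array = build_helmet_array(4, 0.12, rng=0)
        model = make_source_model(2)
        kw = dict(noise_sd=1e-13, drift_amplitude=1e-12, fs=200.0)
        a = simulate_recording(small_schedule, model, array, BurstSpec(), rng=13, **kw)
        b = simulate_recording(small_schedule, model, array, BurstSpec(), rng=13, **kw)
        assert np.array_equal(a.recording.data, b.recording.data)
        assert all(np.array_equal(a.truth_bursts[k], b.truth_bursts[k])
                   for k in a.truth_bursts)

    def test_truth_bursts_lie_within_recording(self, tiny_dataset):
        T = tiny_dataset.recording.duration_s
        for iv in tiny_dataset.truth_bursts.values():
            if len(iv):
                assert iv[:, 0].min() >= 0 and iv[:, 1].max() <= T + 1e-9
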