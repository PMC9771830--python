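"""Tuned BOLD generation and the signal-cleaning contract."""

import numpy as np
import pytest
import scipy.signal

import navdecode as nd
from navdecode.bold import VoxelTuningSpec, _dct_highpass_basis, _regress_out


class TestTuningResponse:
    def test_peak_at_preferred_direction(self):
        assert nd.tuning_response(123.0, 123.0, 30.0) == pytest.approx(1.0)

    def test_flat_tuning_limit(self):
        # sd -> infinity: even the antipode responds fully
        assert nd.tuning_response(0.0, 180.0, 1e9) == pytest.approx(1.0, abs=1e-6)

    def test_one_sigma_offset(self):
        assert nd.tuning_response(30.0, 0.0, 30.0) == pytest.approx(np.exp(-0.5))

    def test_circular_wrap(self):
        # 350 vs 10 degrees are 20 degrees apart, not 340
        assert nd.tuning_response(350.0, 10.0, 20.0) == pytest.approx(np.exp(-0.5))

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            nd.tuning_response(0.0, 0.0, 0.0)


class TestGenerateTunedBold:
    def test_volume_count_is_ceil_duration_over_tr(self, arena):
        traj = nd.simulate_trajectory(arena, 708.0, 0.1, 40.0, 2.0, seed=0)
        run = nd.generate_tuned_bold(traj, VoxelTuningSpec(4), TR=2.36, seed=1)
        assert run.n_volumes == 300

    def test_seed_determinism_and_noise_independence(self, short_trajectory):
        spec = VoxelTuningSpec(10)
        a = nd.generate_tuned_bold(short_trajectory, spec, seed=7)
        b = nd.generate_tuned_bold(short_trajectory, spec, seed=7)
        c = nd.generate_tuned_bold(short_trajectory, spec, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_zero_gain_data_carries_no_direction_signal(self, arena):
        # same seed, two trajectories with different headings: identical output
        t1 = nd.simulate_trajectory(arena, 150.0, 0.1, 40.0, 2.0, seed=2)
        t2 = nd.simulate_trajectory(arena, 150.0, 0.1, 40.0, 2.0, seed=3)
        spec = VoxelTuningSpec(8, gain=0.0, preferred_direction=np.zeros(8),
                               tuned_mask=np.ones(8, bool))
        a = nd.generate_tuned_bold(t1, spec, seed=9)
        b = nd.generate_tuned_bold(t2, spec, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_argmax_voxel_tracks_lagged_heading_bin(self, arena):
        # six noiseless, sharply tuned voxels at the bin centers: for every
        # volume the most active voxel names the lag-shifted heading bin
        traj = nd.simulate_trajectory(arena, 300.0, 0.1, 10.0, 2.0, seed=4)
        centers = np.arange(30.0, 360.0, 60.0)
        spec = VoxelTuningSpec(
            6, tuning_sd=15.0, gain=1.0, baseline=0.0, noise_sd=0.0,
            fraction_tuned=1.0, preferred_direction=centers,
            tuned_mask=np.ones(6, bool),
        )
        TR, lag = 2.36, 2 * 2.36
        run = nd.generate_tuned_bold(traj, spec, TR=TR, lag=lag,
                                     drift_amplitude=0.0, seed=5)
        bins = nd.bin_direction(traj.heading)
        vol_of_sample = np.floor((traj.t + lag) / TR).astype(int)
        checked = 0
        for v in range(run.n_volumes):
            sample_bins = bins[vol_of_sample == v]
            if len(sample_bins) == 0 or len(np.unique(sample_bins)) > 1:
                continue  # empty or mixed-direction volume: no unique answer
            assert centers[np.argmax(run.data[v])] == sample_bins[0]
            checked += 1
        assert checked > 20

    def test_too_short_trajectory_rejected(self, arena):
        traj = nd.simulate_trajectory(arena, 4.0, 0.1, 40.0, 2.0, seed=6)
        with pytest.raises(ValueError):
            nd.generate_tuned_bold(traj, VoxelTuningSpec(2), TR=2.36)

    def test_save_load_round_trip(self, short_trajectory, tmp_path):
        run = nd.generate_tuned_bold(short_trajectory, VoxelTuningSpec(5), seed=10)
        run.save(tmp_path / "run")
        back = nd.BoldRun.load(tmp_path / "run")
        assert back.TR == run.TR
        assert np.allclose(back.data, run.data)
        assert list(back.confounds.columns) == list(run.confounds.columns)


class TestDownstreamDecodability:
    """Generator-to-decoder contracts that only show up end to end."""

    def test_noiseless_bin_center_tuning_decodes_at_ceiling(self):
        # piecewise-constant walking aligned to the TR grid (every segment
        # is exactly 3 volumes of one direction), one indicator voxel per
        # bin center, vanishing noise: the full pipeline must decode
        # perfectly. Free navigation cannot reach this ceiling because
        # boundary volumes mix directions; TR alignment removes that.
        rng = np.random.default_rng(92)
        centers = np.arange(30.0, 360.0, 60.0)
        TR, dwell_volumes, dt = 2.0, 3, 0.1
        blocks = [rng.permutation(np.tile(centers, 4)) for _ in range(3)]
        segment_headings = np.concatenate(blocks)  # 72 segments, fold-balanced
        samples_per_seg = int(dwell_volumes * TR / dt)
        headings = np.repeat(segment_headings, samples_per_seg)
        t = np.arange(len(headings)) * dt
        rad = np.deg2rad(headings)
        x = np.concatenate([[0.0], np.cumsum(np.cos(rad[:-1]) * dt)])
        y = np.concatenate([[0.0], np.cumsum(np.sin(rad[:-1]) * dt)])
        traj = nd.Trajectory(t, x, y, headings)
        spec = VoxelTuningSpec(
            6, tuning_sd=20.0, gain=5.0, noise_sd=1e-4, fraction_tuned=1.0,
            preferred_direction=centers, tuned_mask=np.ones(6, bool),
        )
        run = nd.generate_tuned_bold(traj, spec, TR=TR, lag=2 * TR,
                                     drift_amplitude=0.0, seed=93)
        es = nd.events_to_examples(
            nd.extract_events(traj), nd.clean_signal(run), TR=TR, lag_TRs=2
        )
        ok, _ = nd.check_class_distribution(es)
        assert ok
        assert nd.cross_validate(es, seed=0).balanced_accuracy == 1.0

    def test_higher_gain_never_hurts_mean_accuracy(self):
        from conftest import simulate_session

        means = []
        for gain in (0.0, 2.0, 4.0):
            scores = []
            for subject in range(17):
                es = simulate_session(subject=subject, gain=gain,
                                      n_voxels=24, duration=300.0)
                if es is None:
                    continue
                scores.append(nd.cross_validate(es, seed=0).balanced_accuracy)
            assert len(scores) >= 15
            means.append(np.mean(scores))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0] + 0.05  # the grid spans a real effect


class TestCleanSignal:
    def test_linear_ramp_annihilated_and_flagged_constant(self):
        n = 100
        ramp = np.linspace(0.0, 5.0, n)[:, None]
        run = nd.BoldRun(2.0, np.hstack([ramp, np.random.default_rng(0).standard_normal((n, 1))]))
        cleaned = nd.clean_signal(run)
        assert cleaned.constant_voxels[0]
        assert not cleaned.constant_voxels[1]
        assert np.allclose(cleaned.data[:, 0], 0.0)

    def test_stopband_cosine_strongly_attenuated(self):
        # cosine at period 256 s lies inside the stop band of the 128 s
        # high-pass; measure attenuation before the z-scoring step
        TR, n = 2.0, 256
        t = (np.arange(n) + 0.5) * TR
        probe = np.cos(2 * np.pi * t / 256.0)[:, None]
        detrended = scipy.signal.detrend(probe, axis=0)
        resid = _regress_out(detrended, _dct_highpass_basis(n, TR, 128.0))
        assert np.abs(resid).max() < 0.05  # > 95 % amplitude attenuation

    def test_arbitrary_phase_matches_direct_projection_oracle(self):
        # implementation equals the independent least-squares projection
        TR, n = 2.0, 200
        rng = np.random.default_rng(1)
        t = (np.arange(n) + 0.5) * TR
        sig = np.sin(2 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi))[:, None]
        sig = scipy.signal.detrend(sig, axis=0)
        basis = _dct_highpass_basis(n, TR, 128.0)
        impl = _regress_out(sig, basis)
        X = np.column_stack([np.ones(n), basis])
        oracle = sig - X @ np.linalg.pinv(X) @ sig
        assert np.allclose(impl, oracle, atol=1e-10)

    def test_white_noise_output_is_z_scored(self):
        rng = np.random.default_rng(2)
        run = nd.BoldRun(2.0, rng.standard_normal((120, 7)))
        cleaned = nd.clean_signal(run)
        assert np.allclose(cleaned.data.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(cleaned.data.std(axis=0), 1.0, atol=1e-6)
        assert cleaned.data.shape == run.data.shape

    def test_confound_regression_removes_known_component(self, short_trajectory):
        run = nd.generate_tuned_bold(
            short_trajectory, VoxelTuningSpec(6, noise_sd=0.5),
            drift_amplitude=5.0, seed=3,
        )
        cleaned = nd.clean_signal(run)
        # residual correlation with the generative drift components ~ 0
        for col in ["drift_0", "drift_1", "drift_2"]:
            drift = run.confounds[col].to_numpy()
            corr = np.corrcoef(drift, cleaned.data[:, 0])[0, 1]
            assert abs(corr) < 1e-8

    def test_collinear_confounds_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((80, 3))
        import pandas as pd

        conf = pd.DataFrame({"a": rng.standard_normal(80)})
        conf["b"] = 2.0 * conf["a"]  # exactly collinear
        run = nd.BoldRun(2.0, data, conf)
        with pytest.warns(UserWarning, match="collinear"):
            cleaned = nd.clean_signal(run)
        assert np.allclose(cleaned.data.std(axis=0), 1.0, atol=1e-6)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            nd.clean_signal(nd.BoldRun(2.0, np.zeros((2, 2))))
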