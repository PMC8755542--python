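"""MSD, power-law classification, velocity and stroke-rate contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smquant import motion, simulate
from smquant.motion import DistanceTrace, MSDCurve
from smquant.tracking import Trajectory


def _traj(x, dt=1.0):
    x = np.asarray(x, dtype=float)
    return Trajectory(time=np.arange(x.size) * dt, position=x)


def brute_force_msd(x, dt):
    """Literal double-loop evaluation of the MSD sum (independent oracle)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    out = []
    for n in range(1, N):
        s = 0.0
        for i in range(N - n):
            s += (x[i + n] - x[i]) ** 2
        out.append(s / (N - n))
    return np.asarray(out)


class TestComputeMSD:
    def test_constant_trajectory_zero_everywhere(self):
        msd = motion.compute_msd(_traj([5.0] * 10))
        np.testing.assert_array_equal(msd.msd, 0.0)

    def test_printed_sum_on_linear_ramp(self):
        # X = [0,1,2,3] -> MSD(1)=1, MSD(2)=4, MSD(3)=9
        msd = motion.compute_msd(_traj([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(msd.msd, [1.0, 4.0, 9.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    def test_equals_brute_force_double_loop(self, xs):
        msd = motion.compute_msd(_traj(xs))
        np.testing.assert_allclose(msd.msd, brute_force_msd(xs, 1.0), rtol=1e-12, atol=1e-9)

    def test_brownian_ensemble_matches_2Ddt(self, rng):
        # 1D diffusion: <MSD(n)> = 2 D n dt
        D, dt, N, n_walks = 1e4, 0.1, 100, 500  # nm^2/s
        lag_msds = []
        for _ in range(n_walks):
            steps = rng.normal(0, np.sqrt(2 * D * dt), N - 1)
            x = np.concatenate([[0.0], np.cumsum(steps)])
            lag_msds.append(motion.compute_msd(_traj(x, dt)).msd[:10])
        lag_msds = np.asarray(lag_msds)
        for n in range(1, 11):
            vals = lag_msds[:, n - 1]
            sem = vals.std(ddof=1) / np.sqrt(n_walks)
            assert abs(vals.mean() - 2 * D * n * dt) < 3 * sem

    def test_nonuniform_spacing_rejected(self):
        tr = Trajectory(time=np.array([0.0, 1.0, 3.0]), position=np.zeros(3))
        with pytest.raises(ValueError, match="uniform"):
            motion.compute_msd(tr)


class TestFitMSD:
    def test_exact_ballistic_alpha_two(self):
        n = np.arange(1, 100)
        msd = MSDCurve(lag=n, lag_time=n * 1.0, msd=(5.0 * n) ** 2, n_frames=100)
        fit = motion.fit_msd(msd)
        assert fit.alpha == pytest.approx(2.0, abs=0.01)
        assert fit.label == "superdiffusive"

    def test_exact_linear_alpha_one(self):
        n = np.arange(1, 100)
        msd = MSDCurve(lag=n, lag_time=n * 1.0, msd=2 * 0.01 * n, n_frames=100)
        fit = motion.fit_msd(msd)
        assert fit.alpha == pytest.approx(1.0, abs=0.01)
        assert fit.label == "diffusive"

    @pytest.mark.parametrize("D", [1e-3, 1.0, 1e4])
    def test_alpha_recovery_independent_of_prefactor(self, D):
        n = np.arange(1, 50)
        msd = MSDCurve(lag=n, lag_time=n * 0.997, msd=D * (n * 0.997) ** 1.4, n_frames=50)
        assert motion.fit_msd(msd).alpha == pytest.approx(1.4, abs=1e-3)

    def test_simulated_diffusion_alpha_near_one(self, rng):
        alphas = []
        for _ in range(100):
            steps = rng.normal(0, np.sqrt(2 * 1e4 * 0.997), 499)
            x = np.concatenate([[0.0], np.cumsum(steps)])
            fit = motion.fit_msd(motion.compute_msd(_traj(x, 0.997)))
            alphas.append(fit.alpha)
        assert 0.8 <= float(np.median(alphas)) <= 1.2

    def test_static_flag_on_zero_msd(self):
        msd = motion.compute_msd(_traj([2.0] * 30))
        fit = motion.fit_msd(msd)
        assert fit.static and fit.label == "static"


class TestClassifyMotion:
    @pytest.mark.parametrize(
        "alpha,label",
        [(1.5, "superdiffusive"), (0.8, "diffusive"), (1.0, "diffusive")],
    )
    def test_threshold_rule(self, alpha, label):
        assert motion.classify_motion(alpha) == label

    def test_nonfinite_alpha_rejected(self):
        with pytest.raises(ValueError):
            motion.classify_motion(np.nan)


class TestEstimateVelocity:
    def test_linear_track_exact(self):
        t = np.arange(0, 101, 1.0)
        assert motion.estimate_velocity(_traj(10.0 * t)) == pytest.approx(10.0, rel=1e-6)

    def test_static_track_zero(self):
        assert motion.estimate_velocity(_traj(np.full(200, 7.0))) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_linear_within_ten_percent(self, rng):
        t = np.arange(0, 100, 1.0)
        vels = [
            motion.estimate_velocity(_traj(10.0 * t + rng.normal(0, 30.0, t.size)))
            for _ in range(20)
        ]
        assert np.mean(vels) == pytest.approx(10.0, rel=0.10)

    def test_invariant_under_offset_and_sign_flip(self, rng):
        t = np.arange(0, 200, 1.0)
        x = 5.0 * t + rng.normal(0, 10.0, t.size)
        v = motion.estimate_velocity(_traj(x))
        assert motion.estimate_velocity(_traj(x + 1e4)) == pytest.approx(v, rel=1e-9)
        assert motion.estimate_velocity(_traj(-x)) == pytest.approx(v, rel=1e-9)

    def test_short_track_rejected_and_window_clipped(self):
        with pytest.raises(ValueError):
            motion.estimate_velocity(_traj([0.0, 1.0, 2.0]))
        # shorter than the default 51-frame window: clipped, not an error
        t = np.arange(0, 21, 1.0)
        assert motion.estimate_velocity(_traj(3.0 * t)) == pytest.approx(3.0, rel=1e-3)

    @pytest.mark.parametrize("v", [5.0, 14.0, 30.0])
    def test_directed_simulation_recovery(self, v, rng):
        # tracked-quality noise (sigma ~15 nm) on directed motion at the
        # speeds seen across conditions; mean of 20 tracks within 10%
        t = np.arange(0, 300, 0.997)
        vels = [
            motion.estimate_velocity(_traj(v * t + rng.normal(0, 15.0, t.size), dt=0.997))
            for _ in range(20)
        ]
        assert np.mean(vels) == pytest.approx(v, rel=0.10)


class TestStrokeRates:
    def test_single_slope_single_component(self):
        t = np.arange(0, 100, 1.0)
        fit = motion.extract_stroke_rates(DistanceTrace(time=t, distance=3.3 * t))
        assert fit.segment_rates.size == 1
        assert fit.segment_rates[0] == pytest.approx(3.3, abs=0.05)
        assert fit.n_components == 1

    def test_pause_only_trace_zero_rate(self):
        t = np.arange(0, 100, 1.0)
        fit = motion.extract_stroke_rates(DistanceTrace(time=t, distance=np.full(t.size, 42.0)))
        assert fit.mean_burst_rate != fit.mean_burst_rate  # no bursts -> NaN
        np.testing.assert_allclose(fit.segment_rates, 0.0, atol=1e-9)

    def test_alternating_bursts_two_components(self):
        trace, _ = simulate.simulate_distance_trace(
            burst_rate_mean=5.0, burst_rate_rel_sd=0.0, burst_dur=40.0,
            pause_dur=40.0, total_dur=400.0, noise_sigma=0.2, seed=1,
        )
        fit = motion.extract_stroke_rates(trace)
        assert fit.n_components == 2
        assert fit.means[0] == pytest.approx(0.0, abs=0.3)
        assert fit.means[1] == pytest.approx(5.0, abs=0.3)

    def test_burst_mean_recovered_across_traces(self):
        # 30 seeded traces at the generator defaults; pipeline mean within
        # 3 s.e. of the true drawn-rate mean
        est, true = [], []
        for s in range(30):
            trace, truth = simulate.simulate_distance_trace(seed=100 + s)
            fit = motion.extract_stroke_rates(trace)
            est.extend(fit.burst_rates)
            true.extend(truth.burst_rates)
        est, true = np.asarray(est), np.asarray(true)
        sem = true.std(ddof=1) / np.sqrt(true.size)
        assert abs(est.mean() - true.mean()) < 3 * sem + 0.05

    def test_trace_shorter_than_window_rejected(self):
        t = np.arange(0, 5, 1.0)
        with pytest.raises(ValueError):
            motion.extract_stroke_rates(DistanceTrace(time=t, distance=t))
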