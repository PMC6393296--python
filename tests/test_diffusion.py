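"""MSD, diffusion-coefficient fitting, mobility, and the K-S comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnacurtain import (
    MsdCurve,
    SimulationConfig,
    Trajectory,
    classify_mobile,
    compare_diffusion,
    compute_msd,
    fit_diffusion_coefficient,
    percent_mobile,
    simulate_ensemble,
    summarize_condition,
)


def _traj(positions, dt=1.0):
    n = len(positions)
    return Trajectory(0, np.arange(n), np.arange(n) * dt, positions, dt)


def msd_double_loop(y, n_max):
    """Direct evaluation of the defining MSD sum (independent oracle)."""
    N = len(y)
    out = []
    for n in range(1, n_max + 1):
        acc = 0.0
        for i in range(N - n):
            acc += (y[i + n] - y[i]) ** 2
        out.append(acc / (N - n))
    return np.array(out)


class TestMsd:
    def test_constant_trajectory_zero_msd(self):
        msd = compute_msd(_traj(np.full(50, 2.5)), n_max=10)
        assert np.all(msd.msd_values == 0.0)

    def test_ballistic_closed_form(self):
        v = 0.3
        y = v * np.arange(40)
        msd = compute_msd(_traj(y), n_max=10)
        expected = (v * np.arange(1, 11)) ** 2
        assert np.allclose(msd.msd_values, expected)

    def test_alternating_positions_printed_formula(self):
        msd = compute_msd(_traj(np.array([0.0, 1, 0, 1, 0])), n_max=4)
        assert np.allclose(msd.msd_values, [1.0, 0.0, 1.0, 0.0])
        assert np.array_equal(msd.n_pairs_per_lag, [4, 3, 2, 1])

    def test_matches_double_loop_on_random_trajectories(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(12, 40))
            y = rng.normal(size=N)
            msd = compute_msd(_traj(y), n_max=10)
            assert np.allclose(msd.msd_values, msd_double_loop(y, 10), atol=1e-12)

    def test_too_short_trajectory_error_names_minimum(self):
        with pytest.raises(ValueError, match="11"):
            compute_msd(_traj(np.zeros(10)), n_max=10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        y=st.lists(st.floats(-100, 100), min_size=12, max_size=40),
        shift=st.floats(-1000, 1000),
    )
    def test_msd_invariances_property(self, y, shift):
        """MSD is invariant under time reversal and position shifts."""
        y = np.asarray(y)
        a = compute_msd(_traj(y)).msd_values
        assert np.allclose(a, compute_msd(_traj(y[::-1].copy())).msd_values,
                           rtol=1e-9, atol=1e-9)
        assert np.allclose(a, compute_msd(_traj(y + shift)).msd_values,
                           rtol=1e-7, atol=1e-6)

    def test_time_reversal_and_shift_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=60)
        a = compute_msd(_traj(y)).msd_values
        b = compute_msd(_traj(y[::-1].copy())).msd_values
        c = compute_msd(_traj(y + 17.3)).msd_values
        assert np.allclose(a, b)
        assert np.allclose(a, c)


class TestDiffusionFit:
    def test_exact_line_recovers_d(self):
        lags = np.arange(1, 11) * 0.05
        msd = MsdCurve(lags=lags, msd_values=2 * 0.05 * lags,
                       n_pairs_per_lag=np.arange(99, 89, -1))
        est = fit_diffusion_coefficient(msd)
        assert est.diffusion_coefficient == pytest.approx(0.05)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_additive_offset_shifts_intercept_only(self):
        lags = np.arange(1, 11) * 0.05
        base = 2 * 0.05 * lags
        offset = 4 * 0.03**2
        est0 = fit_diffusion_coefficient(
            MsdCurve(lags, base, np.arange(10)))
        est1 = fit_diffusion_coefficient(
            MsdCurve(lags, base + offset, np.arange(10)))
        assert est1.slope == pytest.approx(est0.slope)
        assert est1.intercept == pytest.approx(offset)

    def test_negative_slope_flagged_not_dropped(self):
        lags = np.arange(1, 11) * 0.05
        est = fit_diffusion_coefficient(
            MsdCurve(lags, 1.0 - 0.5 * lags, np.arange(10)))
        assert est.non_physical
        assert est.diffusion_coefficient == 0.0

    def test_simulated_ensemble_mean_within_10pct(self, brownian_ensemble):
        cfg, trajectories, _ = brownian_ensemble
        ds = [
            fit_diffusion_coefficient(compute_msd(t)).diffusion_coefficient
            for t in trajectories
        ]
        assert np.mean(ds) == pytest.approx(cfg.diffusion_coefficient, rel=0.10)

    def test_estimator_bias_shrinks_with_trajectory_length(self):
        biases = {}
        for n_frames in (100, 400, 1600):
            cfg = SimulationConfig(
                diffusion_coefficient=0.1, localization_sigma=0.0,
                n_frames=n_frames, dna_length=500.0, start_position=250.0,
                seed=1234,
            )
            trajs, _ = simulate_ensemble(cfg, 150)
            ds = [
                fit_diffusion_coefficient(compute_msd(t)).diffusion_coefficient
                for t in trajs
            ]
            biases[n_frames] = abs(np.mean(ds) - 0.1) / 0.1
        assert biases[1600] < 0.05
        assert biases[1600] <= biases[100] + 0.01


class TestMobility:
    def test_static_noise_only_immobile(self):
        rng = np.random.default_rng(2)
        sigma = 0.03
        y = rng.normal(0, sigma, 200) + 5.0
        msd = compute_msd(_traj(y, dt=0.05))
        est = fit_diffusion_coefficient(msd)
        assert not classify_mobile(est, msd, noise_sigma=sigma)

    def test_diffusing_molecule_mobile(self):
        cfg = SimulationConfig(diffusion_coefficient=0.1, seed=3, n_frames=400)
        trajs, _ = simulate_ensemble(cfg, 1)
        msd = compute_msd(trajs[0])
        est = fit_diffusion_coefficient(msd)
        assert classify_mobile(est, msd, noise_sigma=cfg.localization_sigma)

    @pytest.mark.parametrize(
        "n_mobile,n_total,expected", [(62, 64, 97), (60, 67, 90), (79, 81, 98)]
    )
    def test_percent_mobile_rounding(self, n_mobile, n_total, expected):
        assert percent_mobile(n_mobile, n_total) == expected

    def test_summary_flags_small_samples(self):
        lags = np.arange(1, 11) * 0.05
        ests = [
            fit_diffusion_coefficient(MsdCurve(lags, 2 * d * lags, np.arange(10)))
            for d in np.linspace(0.05, 0.15, 10)
        ]
        s = summarize_condition(ests, condition="tiny")
        assert not s.reportable
        assert s.n_molecules == 10


def ks_brute_force(xs, ys):
    """sup |ECDF1 - ECDF2| by direct evaluation at every sample point."""
    xs, ys = np.sort(xs), np.sort(ys)
    best = 0.0
    for t in np.concatenate([xs, ys]):
        f1 = np.mean(xs <= t)
        f2 = np.mean(ys <= t)
        best = max(best, abs(f1 - f2))
    return best


class TestKolmogorovSmirnov:
    def test_identical_samples_zero(self):
        d, _ = compare_diffusion([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_fully_separated_samples_one(self):
        d, p = compare_diffusion([1.0, 2.0], [5.0, 6.0])
        assert d == 1.0

    def test_small_shifted_samples(self):
        d, _ = compare_diffusion([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert d == pytest.approx(ks_brute_force([1, 2, 3], [2, 3, 4]))

    def test_exhaustive_small_sample_pairs_match_brute_force(self):
        """Exact agreement on every pair of samples of size <= 6 from {0..3}."""
        values = [0.0, 1.0, 2.0, 3.0]
        samples = []
        for size in (2, 3, 4):
            samples.extend(
                list(c) for c in itertools.combinations_with_replacement(values, size)
            )
        for xs in samples:
            for ys in samples:
                d, _ = compare_diffusion(xs, ys)
                assert d == pytest.approx(ks_brute_force(xs, ys), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_diffusion([], [1.0, 2.0])
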