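"""Collision-zone segmentation, bypass summaries, and condition comparison."""

import numpy as np
import pytest
from scipy import stats

from dnacurtain import (
    CollisionRecord,
    CollisionZone,
    SimulationConfig,
    Trajectory,
    compare_bypass,
    free_walk_bypass_reference,
    segment_collisions,
    summarize_bypass,
)


def _traj(positions, dt=0.05):
    n = len(positions)
    return Trajectory(7, np.arange(n), np.arange(n) * dt, positions, dt)


ZONE = CollisionZone(nucleosome_id=0, center=0.0, half_width=0.08)


class TestSegmentation:
    def test_left_to_right_is_bypass(self):
        records = segment_collisions(_traj([-0.2, -0.05, 0.05, 0.2]), [ZONE])
        assert len(records) == 1
        r = records[0]
        assert (r.entry_side, r.exit_side, r.outcome) == ("left", "right", "bypass")

    def test_same_side_is_no_bypass(self):
        records = segment_collisions(_traj([-0.2, -0.05, -0.2]), [ZONE])
        assert len(records) == 1
        assert records[0].outcome == "no_bypass"
        assert records[0].entry_side == records[0].exit_side == "left"

    def test_never_in_zone_gives_no_records(self):
        assert segment_collisions(_traj([-0.5, -0.3, 0.3, 0.5]), [ZONE]) == []

    def test_start_inside_zone_censored(self):
        records = segment_collisions(_traj([0.0, 0.02, 0.2]), [ZONE])
        assert len(records) == 1
        assert records[0].outcome == "censored"
        assert records[0].entry_side == "censored"

    def test_end_inside_zone_censored(self):
        records = segment_collisions(_traj([-0.2, -0.05, 0.01]), [ZONE])
        assert records[0].outcome == "censored"
        assert records[0].exit_side == "censored"

    def test_multiple_excursions_counted_separately(self):
        y = [-0.2, 0.0, -0.2, 0.0, 0.2]
        records = segment_collisions(_traj(y), [ZONE])
        assert [r.outcome for r in records] == ["no_bypass", "bypass"]

    def test_overlapping_zones_rejected(self):
        zones = [CollisionZone(0, 0.0, 0.08), CollisionZone(1, 0.1, 0.08)]
        with pytest.raises(ValueError, match="overlap"):
            segment_collisions(_traj([-0.5, 0.5]), zones)


def _records(codes):
    out = []
    for k, c in enumerate(codes):
        out.append(
            CollisionRecord(
                molecule_id=k, nucleosome_id=0, entry_frame=k, exit_frame=k + 1,
                entry_side="left", exit_side="right" if c else "left",
                outcome="bypass" if c else "no_bypass",
            )
        )
    return out


class TestSummarize:
    def test_half_bypass(self):
        s = summarize_bypass(_records([1, 1, 0, 0]), seed=0)
        assert s.p_bypass == 0.5
        assert s.n_collisions == 4

    def test_all_bypass_degenerate_ci(self):
        s = summarize_bypass(_records([1, 1, 1, 1, 1]), seed=0)
        assert s.p_bypass == 1.0
        assert (s.ci_low, s.ci_high) == (1.0, 1.0)

    def test_censored_records_excluded_from_denominator(self):
        records = _records([1, 0])
        records.append(
            CollisionRecord(9, 0, 5, 6, "left", "censored", "censored")
        )
        s = summarize_bypass(records, seed=0)
        assert s.n_collisions == 2
        assert s.n_censored == 1

    def test_all_censored_is_error(self):
        records = [CollisionRecord(0, 0, 0, 1, "censored", "left", "censored")]
        with pytest.raises(ValueError, match="censored"):
            summarize_bypass(records)

    def test_bootstrap_ci_matches_independent_resampling_loop(self):
        codes = np.array([1] * 30 + [0] * 70)
        s = summarize_bypass(_records(codes), n_bootstrap=1000, seed=123)
        rng = np.random.default_rng(123)
        reps = []
        for _ in range(1000):
            idx = rng.integers(0, len(codes), size=len(codes))
            reps.append(codes[idx].mean())
        lo, hi = np.percentile(reps, [2.5, 97.5])
        assert s.p_bypass == pytest.approx(0.30)
        assert s.ci_low == pytest.approx(lo)
        assert s.ci_high == pytest.approx(hi)

    def test_resample_by_molecule_supported(self):
        s = summarize_bypass(
            _records([1, 0, 1, 0, 1, 0]), n_bootstrap=200, seed=5,
            resample_by="molecule",
        )
        assert 0.0 <= s.ci_low <= s.p_bypass <= s.ci_high <= 1.0


def _logistic_wald_oracle(y, group):
    """Independent Wald p-value via direct likelihood maximization."""
    from scipy.optimize import minimize

    X = np.column_stack([np.ones_like(group), group])

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)

    res = minimize(nll, np.zeros(2), method="BFGS")
    beta = res.x
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = p * (1 - p)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    z = beta[1] / np.sqrt(cov[1, 1])
    return beta[1], 2 * stats.norm.sf(abs(z))


class TestCompare:
    def test_identical_groups_coefficient_zero(self):
        a = summarize_bypass(_records([1] * 50 + [0] * 50), seed=0)
        b = summarize_bypass(_records([1] * 50 + [0] * 50), seed=1)
        res = compare_bypass(a, b)
        assert res["coef"] == pytest.approx(0.0, abs=1e-8)
        assert res["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_p_value_matches_independent_optimizer(self):
        ya = np.array([1] * 30 + [0] * 70)
        yb = np.array([1] * 18 + [0] * 82)
        a = summarize_bypass(_records(ya), seed=0)
        b = summarize_bypass(_records(yb), seed=0)
        res = compare_bypass(a, b)
        y = np.concatenate([ya, yb]).astype(float)
        group = np.concatenate([np.zeros(100), np.ones(100)])
        coef, p = _logistic_wald_oracle(y, group)
        assert res["p_value"] == pytest.approx(p, rel=1e-3)
        assert res["coef"] == pytest.approx(coef, rel=1e-4)

    def test_complete_separation_falls_back_to_fisher(self):
        a = summarize_bypass(_records([1] * 20), seed=0)
        b = summarize_bypass(_records([0] * 20), seed=0)
        res = compare_bypass(a, b)
        assert res["separated"]
        assert res["method"] == "fisher_exact"
        assert res["p_value"] < 0.05


class TestFreeWalkReference:
    def test_unobstructed_walk_consistent_with_half(self):
        """Bypass of a free walk is binomially indistinguishable from 50%.

        Measured in the fast-diffusion regime (per-frame step well above
        the zone width) where the sampled-excursion classifier approaches
        the theoretical ceiling.
        """
        cfg = SimulationConfig(
            diffusion_coefficient=1.6, frame_interval=0.05, n_frames=1500,
            localization_sigma=0.0, seed=77,
        )
        s = free_walk_bypass_reference(cfg, n_trajectories=100, n_bootstrap=200)
        assert s.n_collisions >= 1000
        p = stats.binomtest(s.n_bypass, s.n_collisions, 0.5).pvalue
        assert p > 0.01

    def test_impermeable_obstacle_near_zero_bypass(self):
        cfg = SimulationConfig(
            diffusion_coefficient=0.4, n_frames=1500, localization_sigma=0.0,
            obstacle_positions=[6.45], obstacle_bypass_prob=0.0, seed=78,
        )
        from dnacurtain import simulate_ensemble

        trajs, _ = simulate_ensemble(cfg, 50)
        zone = CollisionZone(0, 6.45, 0.08)
        records = []
        for t in trajs:
            records.extend(segment_collisions(t, [zone]))
        s = summarize_bypass(records, seed=0)
        assert s.p_bypass < 0.02

    def test_macroscopic_bypass_monotone_in_microscopic_prob(self):
        measured = []
        for p0 in (0.0, 0.25, 0.5, 0.75, 1.0):
            from dnacurtain import simulate_ensemble

            cfg = SimulationConfig(
                diffusion_coefficient=0.4, n_frames=1000, localization_sigma=0.0,
                obstacle_positions=[6.45], obstacle_bypass_prob=p0, seed=79,
            )
            trajs, _ = simulate_ensemble(cfg, 40)
            zone = CollisionZone(0, 6.45, 0.08)
            records = []
            for t in trajs:
                records.extend(segment_collisions(t, [zone]))
            measured.append(summarize_bypass(records, seed=0).p_bypass)
        assert all(b >= a - 0.03 for a, b in zip(measured, measured[1:]))
        # the free walk (p0 = 1) bounds every obstructed condition
        assert max(measured[:-1]) <= measured[-1] + 0.03

    def test_config_with_obstacles_rejected(self):
        cfg = SimulationConfig(obstacle_positions=[5.0])
        with pytest.raises(ValueError, match="no obstacles"):
            free_walk_bypass_reference(cfg, n_trajectories=2)
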