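"""Entropy computation, query-grid support, clamping, and simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import songdev
from songdev.devmodel import GaussianSnapshot
from songdev.entropy import (
    daily_min_det,
    daily_targets,
    entropy_trajectory,
    fit_entropy_lmm,
    fix_entropy,
    gaussian_entropy,
    sample_query_times,
    simulate_development,
)
from conftest import random_spd

LN2PI = np.log(2 * np.pi)


class TestGaussianEntropy:
    def test_closed_forms(self):
        assert gaussian_entropy(np.eye(1)) == pytest.approx(0.5 * (1 + LN2PI), abs=1e-12)
        assert gaussian_entropy(np.eye(2)) == pytest.approx(1 + LN2PI, abs=1e-12)
        assert gaussian_entropy(np.diag([4.0, 1.0])) == pytest.approx(
            0.5 * np.log(4) + 1 + LN2PI, abs=1e-12)

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            gaussian_entropy(np.diag([1.0, -1.0]))
        with pytest.raises(ValueError, match="match k"):
            gaussian_entropy(np.eye(3), k=2)

    def test_matches_monte_carlo_estimate(self):
        """MC differential entropy -E[log p] on draws from N(0, Sigma)."""
        rng = np.random.default_rng(0)
        sigma = random_spd(rng, 3)
        z = rng.multivariate_normal(np.zeros(3), sigma, size=100000)
        from scipy.stats import multivariate_normal

        mc = -multivariate_normal(np.zeros(3), sigma).logpdf(z).mean()
        assert gaussian_entropy(sigma) == pytest.approx(mc, abs=0.02)


def _rend_table(tods_by_day: dict[int, list[float]]):
    rows = [dict(day_index=d, time_of_day_h=t, age_dph=d + t / 24)
            for d, ts in tods_by_day.items() for t in ts]
    return pd.DataFrame(rows)


class TestQueryTimes:
    def test_empty_dataset_gives_empty_grid(self):
        assert len(sample_query_times(pd.DataFrame(columns=["day_index", "time_of_day_h"]),
                                      (7, 21))) == 0

    def test_burst_of_forty_renditions_supports_only_nearby_grid_times(self):
        df = _rend_table({65: [10.0] * 40})
        q = sample_query_times(df, (7.0, 21.0), min_count=30)
        # closed window: grid times within 15 min of 10:00
        expected = [9.75, 9.75 + 1 / 12, 9.75 + 2 / 12, 10.0, 10.0 + 1 / 12, 10.0 + 2 / 12, 10.25]
        np.testing.assert_allclose(sorted(q.time_of_day_h), expected, atol=1e-9)
        assert (q.n_support == 40).all()

    def test_twenty_nine_renditions_everywhere_is_below_threshold(self):
        df = _rend_table({65: [10.0] * 29})
        assert len(sample_query_times(df, (7.0, 21.0), min_count=30)) == 0

    def test_scaled_min_count(self):
        df = _rend_table({65: list(np.linspace(8, 20, 200))})
        q = sample_query_times(df, (7.0, 21.0), min_count=5)
        assert len(q) > 0
        assert (q.n_support >= 5).all()


class TestFixEntropy:
    def test_isotropic_case(self):
        np.testing.assert_allclose(fix_entropy(4.0 * np.eye(2), 1.0), np.eye(2), atol=1e-12)

    def test_hand_arithmetic_preserves_eigenratio(self):
        out = fix_entropy(np.diag([8.0, 2.0]), 1.0)
        np.testing.assert_allclose(out, np.diag([2.0, 0.5]), atol=1e-12)

    def test_identity_when_target_is_current_det(self):
        rng = np.random.default_rng(1)
        sigma = random_spd(rng, 4)
        np.testing.assert_allclose(fix_entropy(sigma, np.linalg.det(sigma)), sigma, atol=1e-10)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fix_entropy(np.eye(2), -1.0)
        with pytest.raises(ValueError, match="positive definite"):
            fix_entropy(np.diag([1.0, -2.0]), 1.0)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 8))
    def test_clamp_exactness_properties(self, seed, k):
        """det hits target to 1e-8 relative; eigenbasis/eigenvalue ratios kept;
        idempotent; entropy equals the closed form of the target det."""
        rng = np.random.default_rng(seed)
        sigma = random_spd(rng, k)
        target = float(rng.uniform(0.1, 10.0))
        fixed = fix_entropy(sigma, target)
        assert np.linalg.det(fixed) == pytest.approx(target, rel=1e-8)
        lam0, q0 = np.linalg.eigh(sigma)
        lam1, q1 = np.linalg.eigh(fixed)
        np.testing.assert_allclose(lam1 / lam1[0], lam0 / lam0[0], rtol=1e-8)
        np.testing.assert_allclose(np.abs(q0.T @ q1), np.eye(k), atol=1e-6)
        np.testing.assert_allclose(fix_entropy(fixed, target), fixed, atol=1e-10)
        assert gaussian_entropy(fixed) == pytest.approx(
            0.5 * np.log(target) + 0.5 * k * (1 + LN2PI), abs=1e-8)


class _ConstModel:
    def __init__(self, mu, sigma):
        self.mu, self.sigma = np.asarray(mu, float), np.asarray(sigma, float)
        self.k = self.mu.size

    def snapshot(self, age, tod):
        return GaussianSnapshot.from_covariance(self.mu, self.sigma)


class TestTrajectoryAndTargets:
    def test_time_constant_model_gives_flat_trajectory(self):
        model = _ConstModel(np.zeros(2), np.diag([2.0, 0.5]))
        q = pd.DataFrame({"age_dph": [65.3, 65.5], "time_of_day_h": [8.0, 12.0],
                          "day_index": [65, 65], "n_support": [50, 50]})
        traj = entropy_trajectory(model, q)
        assert traj.entropy.nunique() == 1
        assert daily_min_det(model, q) == pytest.approx(1.0, rel=1e-12)

    def test_doubling_sigma_raises_entropy_by_half_k_ln2(self):
        a = gaussian_entropy(np.diag([2.0, 3.0, 1.0]))
        b = gaussian_entropy(2 * np.diag([2.0, 3.0, 1.0]))
        assert b - a == pytest.approx(1.5 * np.log(2), abs=1e-12)

    def test_true_model_trajectory_declines_within_each_day(self, defaults_params,
                                                            defaults_query_times):
        model = songdev.TrueGaussianModel(defaults_params, 0, 0)
        q = defaults_query_times[("bird00", "b00_s00")]
        traj = entropy_trajectory(model, q)
        for _day, sub in traj.groupby("day_index"):
            med = sub.time_of_day_h.median()
            assert sub[sub.time_of_day_h < med].entropy.mean() > \
                sub[sub.time_of_day_h >= med].entropy.mean()

    def test_daily_min_det_attained_at_latest_time(self, defaults_params):
        model = songdev.TrueGaussianModel(defaults_params, 0, 0)
        q = pd.DataFrame({"time_of_day_h": np.linspace(7.1, 20.9, 30)})
        q["day_index"] = 70
        q["age_dph"] = 70 + q.time_of_day_h / 24
        dets = [np.linalg.det(model.snapshot(a, t).Sigma)
                for a, t in zip(q.age_dph, q.time_of_day_h)]
        assert daily_min_det(model, q) == pytest.approx(dets[-1], rel=1e-9)

    def test_no_valid_times_raises(self):
        with pytest.raises(ValueError, match="no valid query times"):
            daily_min_det(_ConstModel(np.zeros(2), np.eye(2)), pd.DataFrame(
                columns=["age_dph", "time_of_day_h"]))


class TestSimulation:
    def _obs(self, n=200, day=65, seed=0):
        rng = np.random.default_rng(seed)
        tod = rng.uniform(7, 21, n)
        return pd.DataFrame({"bird_id": "b0", "syllable_id": "s0",
                             "age_dph": day + tod / 24, "time_of_day_h": tod,
                             "day_index": day})

    def test_sample_mean_matches_mu_within_3se(self):
        sigma = np.diag([2.0, 0.5])
        model = _ConstModel([1.0, -2.0], sigma)
        sim = simulate_development(model, self._obs(n=10000), "baseline", seed=3)
        se = np.sqrt(np.diag(sigma) / 10000)
        dev = np.abs(sim[["z1", "z2"]].mean(axis=0).to_numpy() - [1.0, -2.0])
        assert np.all(dev < 3.5 * se)

    def test_deterministic_and_timestamps_preserved(self):
        model = _ConstModel(np.zeros(2), np.eye(2))
        obs = self._obs(n=50)
        a = simulate_development(model, obs, "baseline", seed=1)
        b = simulate_development(model, obs, "baseline", seed=1)
        pd.testing.assert_frame_equal(a, b)
        np.testing.assert_array_equal(a.age_dph, obs.age_dph)
        assert (a.condition == "baseline").all()

    def test_tiny_covariance_collapses_onto_mean(self):
        model = _ConstModel([3.0, 4.0], 1e-12 * np.eye(2))
        sim = simulate_development(model, self._obs(n=100), "baseline", seed=2)
        np.testing.assert_allclose(sim[["z1", "z2"]].to_numpy(),
                                   np.tile([3.0, 4.0], (100, 1)), atol=1e-4)

    def test_fixed_entropy_flattens_within_day_determinant(self, defaults_params):
        """Baseline draws show the generator's within-day contraction;
        clamped draws do not."""
        model = songdev.TrueGaussianModel(defaults_params, 0, 0)
        rng = np.random.default_rng(4)
        frames = []
        for day in (65, 66, 67):
            tod = np.sort(rng.uniform(7, 21, 3000))
            frames.append(pd.DataFrame({"bird_id": "b", "syllable_id": "s",
                                        "age_dph": day + tod / 24,
                                        "time_of_day_h": tod, "day_index": day}))
        obs = pd.concat(frames, ignore_index=True)
        q = obs.rename(columns={})[["age_dph", "time_of_day_h", "day_index"]]
        targets = daily_targets(model, q)
        zc = [f"z{i + 1}" for i in range(defaults_params.k)]
        ratios = {}
        for mode in ("baseline", "fixed_entropy"):
            sim = simulate_development(model, obs, mode, seed=5, targets=targets)
            r = []
            for day, sub in sim.groupby("day_index"):
                mo = sub[sub.time_of_day_h < 12][zc].to_numpy()
                ev = sub[sub.time_of_day_h > 16][zc].to_numpy()
                r.append(np.linalg.slogdet(np.cov(mo.T))[1] - np.linalg.slogdet(np.cov(ev.T))[1])
            ratios[mode] = np.mean(r)
        assert ratios["baseline"] > 0.8  # generator's decline, in log-det units
        assert abs(ratios["fixed_entropy"]) < 0.4

    def test_days_without_target_are_skipped(self, caplog):
        model = _ConstModel(np.zeros(2), np.eye(2))
        obs = pd.concat([self._obs(50, day=65), self._obs(50, day=66)], ignore_index=True)
        sim = simulate_development(model, obs, "fixed_entropy", seed=0, targets={65: 1.0})
        assert set(sim.day_index) == {65}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            simulate_development(_ConstModel(np.zeros(2), np.eye(2)), self._obs(10), "nope")


class TestEntropyLmm:
    def test_noise_free_linear_data_recovered_exactly(self):
        rows = []
        for b in range(3):
            for s in range(3):
                for t in np.linspace(7, 21, 15):
                    rows.append(dict(bird_id=f"b{b}", syllable_id=f"b{b}s{s}",
                                     time_of_day_h=t, entropy=5.0 - 0.08 * t))
        res = fit_entropy_lmm(pd.DataFrame(rows))
        assert res.params["Intercept"] == pytest.approx(5.0, abs=1e-6)
        assert res.params["time_of_day_h"] == pytest.approx(-0.08, abs=1e-6)

    def test_generator_sign_recovered_significant(self, defaults_params, trained_dev_models,
                                                  defaults_query_times):
        frames = []
        for (bird, syl), model in trained_dev_models.items():
            q = defaults_query_times[(bird, syl)]
            frames.append(entropy_trajectory(model, q, bird_id=bird, syllable_id=syl))
        res = fit_entropy_lmm(pd.concat(frames, ignore_index=True))
        assert res.params["time_of_day_h"] < 0
        assert res.pvalues["time_of_day_h"] < 0.05

    def test_tod_by_age_variant_has_interaction_term(self):
        rng = np.random.default_rng(0)
        rows = []
        for b in range(3):
            for s in range(2):
                for _ in range(60):
                    t, a = rng.uniform(7, 21), rng.uniform(60, 90)
                    rows.append(dict(bird_id=f"b{b}", syllable_id=f"b{b}s{s}",
                                     time_of_day_h=t, age_dph=a,
                                     entropy=8 - 0.06 * t - 0.03 * a + 0.001 * t * a
                                     + rng.normal(0, 0.05)))
        res = fit_entropy_lmm(pd.DataFrame(rows), variant="tod_by_age")
        assert "time_of_day_h:age_dph" in res.params
        assert res.params["age_dph"] == pytest.approx(-0.03, abs=0.01)
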