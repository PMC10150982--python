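"""Density network: input encoding, covariance construction, NLL, training,
and shuffle-based evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import songdev
from songdev._nn import MLP
from songdev.devmodel import (
    ARCHITECTURES,
    DevModel,
    GaussianSnapshot,
    encode_inputs,
    eval_loglik,
    nll,
    train_dev_model,
)

_LOG2PI = np.log(2 * np.pi)


class TestEncodeInputs:
    def test_six_hours_maps_to_sin_one_cos_zero(self):
        u = encode_inputs(70.0, 6.0, 70.0, 5.0)
        np.testing.assert_allclose(u, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_midnight_and_24h_are_periodic(self):
        a = encode_inputs(70.0, 0.0, 70.0, 5.0)
        b = encode_inputs(71.0, 24.0, 70.0, 5.0)
        np.testing.assert_allclose(a[0, 1:], b[0, 1:], atol=1e-12)
        np.testing.assert_allclose(a[0, 1:], [0.0, 1.0], atol=1e-12)

    def test_same_clock_time_on_different_days_shares_circadian_input(self):
        a = encode_inputs(63.4, 9.6, 70.0, 5.0)
        b = encode_inputs(88.4, 9.6, 70.0, 5.0)
        np.testing.assert_allclose(a[0, 1:], b[0, 1:], atol=1e-12)
        assert a[0, 0] != b[0, 0]

    def test_mean_age_zscores_to_zero_and_zero_sd_rejected(self):
        assert encode_inputs(70.0, 12.0, 70.0, 5.0)[0, 0] == 0.0
        with pytest.raises(ValueError, match="SD"):
            encode_inputs(70.0, 12.0, 70.0, 0.0)


def _toy_model(k=3, seed=0, eps=1e-4):
    n_out = k + k * (k + 1) // 2 + k
    mlp = MLP(3, [8], n_out, activation="relu").init(np.random.default_rng(seed))
    return DevModel(mlp=mlp, k=k, age_mean=70.0, age_sd=5.0, eps=eps)


class TestSnapshot:
    def test_zero_l_zero_d_gives_one_plus_eps_identity(self):
        k = 4
        snap = GaussianSnapshot(mu=np.zeros(k), L=np.zeros((k, k)), d=np.zeros(k), eps=1e-4)
        np.testing.assert_allclose(snap.Sigma, (1 + 1e-4) * np.eye(k), atol=1e-15)

    def test_sigma_always_spd_over_input_grid(self):
        model = _toy_model()
        for age in np.linspace(55, 85, 7):
            for tod in np.linspace(0, 24, 9):
                np.linalg.cholesky(model.snapshot(age, tod).Sigma)  # must not raise

    def test_perturbing_d_changes_only_the_diagonal(self):
        model = _toy_model()
        snap = model.snapshot(70.0, 12.0)
        bumped = GaussianSnapshot(mu=snap.mu, L=snap.L, d=snap.d + 0.3, eps=snap.eps)
        diff = bumped.Sigma - snap.Sigma
        assert np.abs(diff - np.diag(np.diag(diff))).max() < 1e-14
        assert np.abs(np.diag(diff)).min() > 0

    def test_from_covariance_roundtrip(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 4))
        sigma = a @ a.T + 0.5 * np.eye(4)
        snap = GaussianSnapshot.from_covariance(rng.normal(size=4), sigma)
        np.testing.assert_allclose(snap.Sigma, sigma, atol=1e-12)


class TestNll:
    def test_standard_normal_at_origin(self):
        snap = GaussianSnapshot.from_covariance(np.zeros(1), np.eye(1))
        assert nll(snap, np.zeros(1)) == pytest.approx(0.5 * _LOG2PI, abs=1e-12)

    def test_at_mean_equals_half_logdet_2pi_sigma(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3, 3))
        sigma = a @ a.T + np.eye(3)
        mu = rng.normal(size=3)
        snap = GaussianSnapshot.from_covariance(mu, sigma)
        expected = 0.5 * np.linalg.slogdet(2 * np.pi * sigma)[1]
        assert nll(snap, mu) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_density_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 3))
        sigma = a @ a.T + np.eye(3)
        mu = rng.normal(size=3)
        snap = GaussianSnapshot.from_covariance(mu, sigma)
        x = rng.normal(size=(10, 3))
        expected = -multivariate_normal(mu, sigma).logpdf(x)
        np.testing.assert_allclose(nll(snap, x), expected, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        snap = GaussianSnapshot.from_covariance(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="dimension"):
            nll(snap, np.zeros(3))


def test_architecture_parameter_counts_match_reported_families():
    """Printed parameter-count windows pin the hidden sizes exactly."""
    expected = {
        ("wide", 6): 141089, ("wide", 7): 143402,
        ("narrow64", 6): 10721, ("narrow64", 8): 11956,
        ("shallow", 6): 75297, ("shallow", 8): 80180,
    }
    for (arch, k), count in expected.items():
        n_out = k + k * (k + 1) // 2 + k
        mlp = MLP(3, ARCHITECTURES[arch], n_out, activation="relu").init(np.random.default_rng(0))
        assert mlp.n_params == count, (arch, k)


def _stationary_table(n=4000, k=3, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(k, k))
    sigma = a @ a.T / k + np.eye(k)
    mu = rng.normal(0, 2, size=k)
    days = rng.integers(60, 70, n)
    tod = rng.uniform(7, 21, n)
    z = rng.multivariate_normal(mu, sigma, size=n)
    df = pd.DataFrame({f"z{i + 1}": z[:, i] for i in range(k)})
    df["age_dph"] = days + tod / 24
    df["time_of_day_h"] = tod
    df["day_index"] = days
    return df, mu, sigma


class TestTraining:
    def test_stationary_data_fits_constant_gaussian(self):
        df, mu, sigma = _stationary_table()
        model = train_dev_model(df, architecture=[16, 16], seed=0, max_epochs=120, patience=10)
        se = np.sqrt(np.diag(sigma) / len(df))
        for age, tod in [(62.4, 9.5), (65.5, 13.0), (68.8, 19.5)]:
            snap = model.snapshot(age, tod)
            assert np.all(np.abs(snap.mu - mu) < 8 * se)
            assert np.linalg.slogdet(snap.Sigma)[1] == pytest.approx(
                np.linalg.slogdet(sigma)[1], abs=0.25)

    def test_deterministic_given_seed(self):
        df, *_ = _stationary_table(n=600)
        m1 = train_dev_model(df, architecture=[8], seed=5, max_epochs=10, patience=5)
        m2 = train_dev_model(df, architecture=[8], seed=5, max_epochs=10, patience=5)
        for w1, w2 in zip(m1.mlp.weights, m2.mlp.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_too_few_renditions_rejected(self):
        df, *_ = _stationary_table(n=5)
        with pytest.raises(ValueError, match="at least"):
            train_dev_model(df, architecture=[8], seed=0)


class TestEvalLoglik:
    def test_exact_generating_gaussian_reaches_analytic_expected_loglik(self):
        """At a single timestamp, mean log density under the true model
        approaches -(k/2)(1+ln 2 pi) - (1/2)ln|Sigma| (MC error)."""
        rng = np.random.default_rng(8)
        k = 3
        a = rng.normal(size=(k, k))
        sigma = a @ a.T / k + np.eye(k)
        z = rng.multivariate_normal(np.zeros(k), sigma, size=20000)
        snap = GaussianSnapshot.from_covariance(np.zeros(k), sigma)
        mean_ll = float(np.mean(-nll(snap, z)))
        expected = -0.5 * k * (1 + _LOG2PI) - 0.5 * np.linalg.slogdet(sigma)[1]
        assert mean_ll == pytest.approx(expected, abs=0.05)

    def test_time_constant_model_is_shuffle_invariant(self):
        df, *_ = _stationary_table(n=500, seed=1)
        k = 3
        mlp = MLP(3, [4], k + k * (k + 1) // 2 + k, activation="relu").init(np.random.default_rng(0))
        for w in mlp.weights:
            w[:] = 0.0  # constant output regardless of production time
        model = DevModel(mlp=mlp, k=k, age_mean=65.0, age_sd=3.0)
        rep = eval_loglik(model, df, "total", n_permutations=20, seed=0)
        np.testing.assert_allclose(rep.perm_means, rep.unshuffled, atol=1e-10)

    def test_within_day_shuffle_with_day_resolution_times_is_identity(self):
        df, *_ = _stationary_table(n=300, seed=2)
        df["time_of_day_h"] = 12.0
        df["age_dph"] = df["day_index"].astype(float) + 0.5
        model = train_dev_model(df, architecture=[8], seed=0, max_epochs=5, patience=5)
        rep = eval_loglik(model, df, "within_day", n_permutations=20, seed=0)
        np.testing.assert_allclose(rep.perm_means, rep.unshuffled, atol=1e-10)

    def test_loglik_ordering_on_developmental_data(self, defaults_splits, trained_dev_models):
        key = ("bird00", "b00_s00")
        _train, ev = defaults_splits[key]
        model = trained_dev_models[key]
        none = eval_loglik(model, ev, "none")
        tot = eval_loglik(model, ev, "total", 100, seed=3)
        wd = eval_loglik(model, ev, "within_day", 100, seed=3)
        assert none.unshuffled > wd.mean_perm > tot.mean_perm
        assert tot.exceedance_fraction == 1.0


def test_dev_model_serialization_roundtrip(tmp_path):
    df, *_ = _stationary_table(n=400, seed=3)
    model = train_dev_model(df, architecture=[8], seed=0, max_epochs=8, patience=5)
    from songdev.devmodel import load_model, save_model

    save_model(model, str(tmp_path / "dm"))
    again = load_model(str(tmp_path / "dm"))
    a = model.snapshot(64.5, 10.0)
    b = again.snapshot(64.5, 10.0)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.Sigma, b.Sigma)
    assert again.k == model.k and again.age_mean == model.age_mean
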