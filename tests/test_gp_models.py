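"""Gibbs samplers for VG, VGR and FA(1): oracles, nesting, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from hapsparse import (
    EnvBLUEs,
    KinshipMatrix,
    ModelSpec,
    fit_fa,
    fit_vg,
    fit_vgr,
    geweke_z,
    predict,
)


def _lines(n):
    return [f"L{i:03d}" for i in range(n)]


def _rand_K(n, seed, p=60):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    K = X @ X.T / p
    K = K / np.diag(K).mean()
    return KinshipMatrix(_lines(n), K, "marker")


def _blues(Y, lines, mask=None):
    values = pd.DataFrame(
        Y, index=lines, columns=[f"E{j + 1}" for j in range(Y.shape[1])]
    )
    b = EnvBLUEs(values=values)
    if mask is not None:
        b = b.with_mask(pd.DataFrame(mask, index=values.index, columns=values.columns))
    return b


def test_vg_matches_ridge_blup_closed_form():
    """Fixed variances, single environment: posterior mean of g must equal
    the mixed-model-equations solution within Monte-Carlo error."""
    n = 20
    K = _rand_K(n, 0)
    rng = np.random.default_rng(1)
    y = rng.multivariate_normal(np.zeros(n), K.values + 0.5 * np.eye(n))
    blues = _blues(y[:, None], _lines(n))
    spec = ModelSpec(
        model="VG", n_iter=10_000, burn_in=2_000, seed=3,
        fixed={"mu": 0.0, "v": [0.0], "s2_g": 1.0, "s2_e": 0.5},
    )
    fit = fit_vg(blues, K, spec)
    P = np.eye(n) / 0.5 + np.linalg.inv(K.values)
    g_star = np.linalg.solve(P, y / 0.5)
    post_sd = np.sqrt(np.diag(np.linalg.inv(P)))
    mcse = post_sd / np.sqrt(8_000 / 20)  # conservative effective sample size
    assert np.max(np.abs(fit.post_mean["g"] - g_star) / mcse) < 3.0


def test_vgr_with_pinned_zero_interaction_reduces_to_vg():
    n, e = 40, 3
    K = _rand_K(n, 2)
    rng = np.random.default_rng(3)
    g = rng.multivariate_normal(np.zeros(n), K.values)
    Y = g[:, None] + rng.normal(0, 0.5, (n, e))
    blues = _blues(Y, _lines(n))
    spec_vg = ModelSpec(model="VG", n_iter=3_000, burn_in=1_000, seed=5)
    spec_vgr = ModelSpec(
        model="VGR", n_iter=3_000, burn_in=1_000, seed=5, fixed={"s2_r": 1e-8}
    )
    p_vg = predict(fit_vg(blues, K, spec_vg))
    p_vgr = predict(fit_vgr(blues, K, spec_vgr))
    # same model in distribution -> same predictions up to MC noise
    assert np.corrcoef(p_vg.to_numpy().ravel(), p_vgr.to_numpy().ravel())[0, 1] > 0.999


def test_vgr_matches_multi_kernel_blup_oracle():
    """5 lines x 2 envs, all variances fixed: posterior mean of the total
    genetic signal equals the closed-form GLS/BLUP on the summed kernel."""
    n, e = 5, 2
    K = _rand_K(n, 4, p=30)
    rng = np.random.default_rng(5)
    Y = rng.normal(0, 1, (n, e))
    blues = _blues(Y, _lines(n))
    s2g, s2r, s2e = 0.8, 0.6, 0.4
    spec = ModelSpec(
        model="VGR", n_iter=20_000, burn_in=4_000, seed=6,
        fixed={"mu": 0.0, "v": [0.0, 0.0], "s2_g": s2g, "s2_r": s2r, "s2_e": s2e},
    )
    fit = fit_vgr(blues, K, spec)
    got = (fit.post_mean["g"][:, None] + fit.post_mean["r"]).ravel(order="F")
    # oracle over stacked cells (env-major), Sigma_gen = J (x) K s2g + I (x) K s2r
    Kv = K.values
    J = np.ones((e, e))
    Sg = np.kron(J, Kv) * s2g + np.kron(np.eye(e), Kv) * s2r
    Sy = Sg + s2e * np.eye(n * e)
    y = Y.ravel(order="F")
    m_star = Sg @ np.linalg.solve(Sy, y)
    post_cov = Sg - Sg @ np.linalg.solve(Sy, Sg)
    mcse = np.sqrt(np.diag(post_cov)) / np.sqrt(16_000 / 30)
    assert np.max(np.abs(got - m_star) / mcse) < 3.0


def test_fa_matches_kronecker_gls_oracle():
    n, e = 12, 2
    K = _rand_K(n, 7, p=40)
    rng = np.random.default_rng(8)
    Y = rng.normal(0, 1, (n, e))
    blues = _blues(Y, _lines(n))
    lam = np.array([0.9, 0.7])
    pi = np.array([0.3, 0.5])
    se = np.array([0.4, 0.6])
    spec = ModelSpec(
        model="FA", n_iter=20_000, burn_in=4_000, seed=9,
        fixed={"mu_env": [0.0, 0.0], "lambda": lam, "pi": pi, "s2_e": se},
    )
    fit = fit_fa(blues, K, spec)
    got = fit.post_mean["g_env"].ravel(order="F")
    psi = np.outer(lam, lam) + np.diag(pi)
    Su = np.kron(psi, K.values)
    Sy = Su + np.kron(np.diag(se), np.eye(n))
    y = Y.ravel(order="F")
    u_star = Su @ np.linalg.solve(Sy, y)
    post_cov = Su - Su @ np.linalg.solve(Sy, Su)
    mcse = np.sqrt(np.diag(post_cov)) / np.sqrt(16_000 / 30)
    assert np.max(np.abs(got - u_star) / mcse) < 3.0


def test_seed_reproducibility():
    n = 25
    K = _rand_K(n, 10)
    rng = np.random.default_rng(11)
    Y = rng.normal(0, 1, (n, 3))
    blues = _blues(Y, _lines(n))
    for fitter, model in ((fit_vg, "VG"), (fit_vgr, "VGR"), (fit_fa, "FA")):
        spec = ModelSpec(model=model, n_iter=500, burn_in=100, seed=42)
        f1 = fitter(blues, K, spec)
        f2 = fitter(blues, K, ModelSpec(model=model, n_iter=500, burn_in=100, seed=42))
        for k in f1.post_mean:
            np.testing.assert_array_equal(f1.post_mean[k], f2.post_mean[k])
        for k in f1.chains:
            np.testing.assert_array_equal(f1.chains[k], f2.chains[k])


def test_constant_phenotypes_give_null_genetic_effects():
    n = 20
    K = _rand_K(n, 12)
    blues = _blues(np.full((n, 2), 3.0), _lines(n))
    fit = fit_vg(blues, K, ModelSpec(model="VG", n_iter=2_000, burn_in=500, seed=1))
    assert np.abs(fit.post_mean["g"]).max() < 0.05


def test_identity_K_gives_no_information_flow_to_unphenotyped():
    n = 30
    K = KinshipMatrix(_lines(n), np.eye(n), "marker")
    rng = np.random.default_rng(13)
    Y = rng.normal(0, 1, (n, 2))
    mask = np.zeros((n, 2), bool)
    mask[-5:] = True  # last 5 lines fully unphenotyped
    blues = _blues(Y, _lines(n), mask)
    fit = fit_vg(blues, K, ModelSpec(model="VG", n_iter=2_000, burn_in=500, seed=2))
    pred = predict(fit)
    baseline = fit.post_mean["mu"] + fit.post_mean["v"]
    np.testing.assert_allclose(
        pred.iloc[-5:].to_numpy(), np.tile(baseline, (5, 1)), atol=1e-8
    )


def test_duplicate_line_limit():
    """An unphenotyped line whose K row duplicates a training line inherits
    that line's fitted genetic value as residual noise vanishes."""
    n = 15
    K0 = _rand_K(n, 14).values
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = K0
    K[n, :n] = K0[0, :]
    K[:n, n] = K0[:, 0]
    K[n, n] = K0[0, 0]
    Km = KinshipMatrix(_lines(n + 1), K, "marker")
    rng = np.random.default_rng(15)
    g = rng.multivariate_normal(np.zeros(n), K0)
    Y = np.concatenate([g, [np.nan]])[:, None]
    blues = _blues(Y, _lines(n + 1))
    spec = ModelSpec(
        model="VG", n_iter=4_000, burn_in=1_000, seed=3,
        fixed={"mu": 0.0, "v": [0.0], "s2_g": 1.0, "s2_e": 1e-6},
    )
    pred = predict(fit_vg(blues, Km, spec))
    assert pred.iloc[n, 0] == pytest.approx(pred.iloc[0, 0], abs=1e-3)


def test_fa_rank_one_structure_detected():
    """Data generated with Pi = 0 should yield a near-rank-1 fitted Psi_u."""
    n, e = 150, 4
    K = _rand_K(n, 16, p=200)
    rng = np.random.default_rng(17)
    f = rng.multivariate_normal(np.zeros(n), K.values)
    lam = np.array([1.0, 0.9, 1.1, 1.0])
    Y = lam[None, :] * f[:, None] + rng.normal(0, 0.15, (n, e))
    blues = _blues(Y, _lines(n))
    fit = fit_fa(blues, K, ModelSpec(model="FA", n_iter=2_000, burn_in=500, seed=4))
    w = np.linalg.eigvalsh(fit.psi_u)
    assert w[-1] > 0
    assert w[0] / w[-1] < 0.1


def test_geweke_diagnostics_on_fixture_chains():
    n = 40
    K = _rand_K(n, 18)
    rng = np.random.default_rng(19)
    g = rng.multivariate_normal(np.zeros(n), K.values)
    Y = g[:, None] + rng.normal(0, 0.6, (n, 3))
    blues = _blues(Y, _lines(n))
    fit = fit_vg(blues, K, ModelSpec(model="VG", n_iter=4_000, burn_in=1_000, seed=5))
    for name in ("s2_g", "s2_e"):
        assert -3 < geweke_z(fit.chains[name]) < 3


def test_predict_unknown_line_errors():
    n = 10
    K = _rand_K(n, 20)
    Y = np.random.default_rng(21).normal(0, 1, (n, 2))
    blues = _blues(Y, _lines(n))
    fit = fit_vg(blues, K, ModelSpec(model="VG", n_iter=300, burn_in=100, seed=6))
    with pytest.raises(ValueError, match="absent"):
        predict(fit, targets=[("nope", "E1")])


def test_environment_without_unmasked_cells_errors():
    n = 10
    K = _rand_K(n, 22)
    Y = np.random.default_rng(23).normal(0, 1, (n, 2))
    mask = np.zeros((n, 2), bool)
    mask[:, 1] = True
    blues = _blues(Y, _lines(n), mask)
    with pytest.raises(ValueError, match="unmasked"):
        fit_vg(blues, K, ModelSpec(model="VG", n_iter=300, burn_in=100))
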