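"""Fold construction, Fig-1-style masking, accuracy and model comparison."""

import numpy as np
import pandas as pd
import pytest

from hapsparse import (
    EnvBLUEs,
    KinshipMatrix,
    ModelSpec,
    accuracy,
    build_schedule,
    compare_models,
    fisher_z,
    make_folds,
    mask_training,
    run_cv,
)


def _blues(n, e, seed=0, lines=None):
    rng = np.random.default_rng(seed)
    lines = lines or [f"L{i:03d}" for i in range(n)]
    return EnvBLUEs(
        values=pd.DataFrame(
            rng.normal(0, 1, (n, e)), index=lines, columns=[f"E{j + 1}" for j in range(e)]
        )
    )


def test_fold_sizes_and_partition():
    lines = [f"L{i}" for i in range(344)]
    folds = make_folds(lines, 5, seed=1)
    assert sorted(len(f) for f in folds) == [68, 69, 69, 69, 69]
    flat = [l for f in folds for l in f]
    assert sorted(flat) == sorted(lines)
    assert make_folds(lines, 5, seed=1) == folds  # deterministic
    assert make_folds(lines, 5, seed=2) != folds


def test_too_few_lines_for_folds():
    with pytest.raises(ValueError):
        make_folds(["a", "b"], 5)


def test_mask_target_zero_is_identity():
    b = _blues(10, 4)
    pat = mask_training(b, 0.0, seed=3)
    assert not pat.mask.to_numpy().any()
    assert pat.achieved_rate == 0.0


def test_mask_small_example_contract():
    b = _blues(10, 4)
    pat = mask_training(b, 0.10, seed=4)
    m = pat.mask.to_numpy()
    assert m.sum() == 4  # ceil(0.1 * 40)
    assert m.sum(axis=1).max() <= 1  # at most one cell per line in pass 1
    assert np.all(pat.per_env_rate > 0.05) and np.all(pat.per_env_rate < 1)


@pytest.mark.parametrize("rate", [0.1, 0.3, 0.5, 0.7, 0.9])
def test_mask_contract_across_rates_and_seeds(rate):
    b = _blues(40, 4)
    n_cells = 160
    for seed in range(10):
        pat = mask_training(b, rate, seed=seed)
        m = pat.mask.to_numpy()
        assert m.sum() == int(np.ceil(rate * n_cells))
        assert abs(pat.achieved_rate - rate) <= 1.0 / n_cells
        per_env = m.mean(axis=0)
        assert np.all(per_env > rate / 2) and np.all(per_env < 1)
        # line-by-line passes: per-line masses differ by at most one
        per_line = m.sum(axis=1)
        assert per_line.max() - per_line.min() <= 1


def test_mask_high_rate_audit():
    b = _blues(100, 4)
    pat = mask_training(b, 0.9, seed=5)
    m = pat.mask.to_numpy()
    assert m.sum() == 360
    assert np.all(pat.per_env_rate > 0.45) and np.all(pat.per_env_rate < 1)


def test_mask_infeasible_constraint_reported():
    # 2 environments at rate 0.9: per-env > 0.45 and < 1 with 1.8 cells/line
    # masked means one env would need > 80% while the other < 100%; with a
    # tiny population the balance is impossible often enough to exhaust draws
    b = _blues(2, 2)
    with pytest.raises(RuntimeError, match="balance"):
        mask_training(b, 0.9, seed=6, max_rejections=50)


def test_mask_rate_out_of_range():
    with pytest.raises(ValueError):
        mask_training(_blues(5, 2), 0.95)


def test_accuracy_trivial_and_affine_invariance():
    b = _blues(30, 3, seed=7)
    lines = b.line_ids
    pred = b.values.copy()
    np.testing.assert_allclose(accuracy(pred, b, lines), 1.0)
    np.testing.assert_allclose(accuracy(2.5 * pred + 3, b, lines), 1.0)


def test_accuracy_permutation_null():
    b = _blues(50, 2, seed=8)
    lines = b.line_ids
    rng = np.random.default_rng(9)
    rs = []
    for _ in range(100):
        pred = b.values.sample(frac=1, random_state=rng.integers(2**31)).set_axis(
            b.values.index
        )
        rs.append(accuracy(pred, b, lines).mean())
    assert abs(np.mean(rs)) < 0.03


def test_accuracy_zero_variance_is_missing_not_zero():
    b = _blues(10, 2, seed=10)
    pred = b.values.copy()
    pred["E1"] = 1.0
    acc = accuracy(pred, b, b.line_ids)
    assert np.isnan(acc["E1"]) and np.isfinite(acc["E2"])


def test_fisher_z_properties():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(-0.6) == pytest.approx(-fisher_z(0.6))
    assert fisher_z(0.5) == pytest.approx(0.5 * np.log(1.5 / 0.5))


def test_compare_models_identity_null():
    rec = pd.DataFrame(
        {
            "missing_rate": [0.1] * 6,
            "cv_repeat": [0, 0, 1, 1, 2, 2],
            "mask_repeat": 0,
            "env": ["E1", "E2"] * 3,
            "accuracy": [0.5, 0.6, 0.55, 0.62, 0.51, 0.59],
        }
    )
    t, p = compare_models(rec, rec.copy())
    assert t == 0.0 and p == 1.0


def test_compare_models_matches_paired_t_oracle():
    rng = np.random.default_rng(11)
    za = rng.normal(0.6, 0.05, 12)
    d = rng.normal(0.1, 0.02, 12)
    zb = za - d
    rec_a = pd.DataFrame(
        {
            "missing_rate": 0.3,
            "cv_repeat": np.arange(12),
            "mask_repeat": 0,
            "env": "E1",
            "accuracy": np.tanh(za),
        }
    )
    rec_b = rec_a.assign(accuracy=np.tanh(zb))
    t, p = compare_models(rec_a, rec_b)
    diffs = za - zb
    t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
    assert t == pytest.approx(t_hand)
    assert 0 < p < 1


def test_compare_models_needs_three_pairs():
    rec = pd.DataFrame(
        {"missing_rate": [0.1], "cv_repeat": [0], "mask_repeat": [0], "env": ["E1"],
         "accuracy": [0.5]}
    )
    with pytest.raises(ValueError):
        compare_models(rec, rec)


def test_schedule_bookkeeping():
    sched = build_schedule(
        n_folds=5, cv_repeats=10, mask_repeats=10,
        missing_rates=(0.0, 0.1, 0.5), models=("VG",), codings=("marker",),
    )
    per_rate = sched.groupby("missing_rate").size()
    assert per_rate[0.1] == 500 and per_rate[0.5] == 500
    assert per_rate[0.0] == 50  # mask repeats collapse at rate 0
    divisions = sched[["cv_repeat", "fold"]].drop_duplicates()
    assert len(divisions) == 50


def test_run_cv_smoke_and_determinism():
    n = 40
    rng = np.random.default_rng(12)
    X = rng.standard_normal((n, 80))
    K = X @ X.T / 80
    K /= np.diag(K).mean()
    lines = [f"L{i:03d}" for i in range(n)]
    g = rng.multivariate_normal(np.zeros(n), K)
    Y = g[:, None] + rng.normal(0, 0.4, (n, 3))
    blues = EnvBLUEs(
        values=pd.DataFrame(Y, index=lines, columns=["E1", "E2", "E3"])
    )
    km = {"marker": KinshipMatrix(lines, K, "marker")}
    spec = ModelSpec(n_iter=400, burn_in=100)
    res1 = run_cv(blues, km, models=("VG",), missing_rates=(0.0, 0.3),
                  cv_repeats=1, mask_repeats=2, spec=spec, seed=5)
    res2 = run_cv(blues, km, models=("VG",), missing_rates=(0.0, 0.3),
                  cv_repeats=1, mask_repeats=2, spec=spec, seed=5)
    pd.testing.assert_frame_equal(res1.records, res2.records)
    # rate 0 deduplicates to one mask repeat: 3 env records + 2*3 at rate .3
    assert len(res1.records) == 3 + 6
    assert res1.records["accuracy"].notna().all()
    assert res1.records["accuracy"].between(-1, 1).all()
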