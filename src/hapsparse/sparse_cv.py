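"""CV1 cross-validation with sparse-phenotyping masking of the training set.

The scheme mimics predicting newly developed lines that were never field
tested: lines are split into 5 folds, four train and one tests, and on top
of that the training set's environment-specific BLUEs are stochastically
masked to a target missing rate.  Masking proceeds line by line — one
randomly chosen BLUE per line, then a second pass if one per line is not
enough — and a whole pattern is rejected and redrawn until every
environment's missing fraction lies strictly between half the total rate
and 1, which keeps the phenotypic information per environment comparable.

Accuracy is the per-environment Pearson correlation between the
concatenated test-set predictions of one cross-validation repeat and the
observed BLUEs; model comparisons use a paired Student t-test on Fisher
z-transformed accuracies, z = 0.5 ln((1+r)/(1-r)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gp_models import FitResult, ModelSpec, fit_model, predict
from .kinship import KinshipMatrix
from .pheno_two_stage import EnvBLUEs

__all__ = [
    "MaskPattern",
    "CVResult",
    "make_folds",
    "mask_training",
    "build_schedule",
    "run_cv",
    "accuracy",
    "fisher_z",
    "compare_models",
]


@dataclass
class MaskPattern:
    """Accepted sparse-phenotyping pattern over (training line, environment)."""

    mask: pd.DataFrame  # True = masked
    target_rate: float
    achieved_rate: float
    per_env_rate: np.ndarray
    seed: int
    n_rejected: int = 0


@dataclass
class CVResult:
    """Tidy accuracy records, one per
    (model, coding, missing_rate, cv_repeat, mask_repeat, env)."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby(["model", "coding", "missing_rate"])["accuracy"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"mean": "accuracy_mean", "std": "accuracy_sd"})


def make_folds(line_ids: list[str], k: int = 5, seed: int = 0) -> list[list[str]]:
    """Random partition into k folds with sizes differing by at most one."""
    n = len(line_ids)
    if n < k:
        raise ValueError(f"cannot split {n} lines into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [[line_ids[i] for i in chunk] for chunk in np.array_split(perm, k)]


def _draw_pattern(
    n_lines: int, n_env: int, n_mask: int, rng: np.random.Generator
) -> np.ndarray:
    """One masking draw: line-by-line passes through random env orders."""
    mask = np.zeros((n_lines, n_env), dtype=bool)
    line_order = rng.permutation(n_lines)
    env_orders = np.array([rng.permutation(n_env) for _ in range(n_lines)])
    left = n_mask
    for p in range(n_env):
        if left == 0:
            break
        for li in line_order:
            if left == 0:
                break
            mask[li, env_orders[li, p]] = True
            left -= 1
    return mask


def mask_training(
    blues: EnvBLUEs, target_rate: float, seed: int = 0, max_rejections: int = 1000
) -> MaskPattern:
    """Sparse-phenotype the training-set BLUEs at ``target_rate``.

    Exactly ceil(target_rate * n_cells) cells are masked; the whole draw is
    rejected and resampled (fresh sub-seed) until every environment's
    missing fraction is strictly larger than target_rate / 2 and strictly
    smaller than 1.
    """
    if not 0.0 <= target_rate <= 0.9:
        raise ValueError("target_rate must be in [0, 0.9]")
    n_lines, n_env = blues.values.shape
    n_cells = n_lines * n_env
    n_mask = math.ceil(target_rate * n_cells)
    if n_mask == 0:
        mask = pd.DataFrame(
            False, index=blues.values.index, columns=blues.values.columns
        )
        return MaskPattern(mask, target_rate, 0.0, np.zeros(n_env), seed)
    ss = np.random.SeedSequence(seed)
    for attempt, child in enumerate(ss.spawn(max_rejections)):
        rng = np.random.default_rng(child)
        m = _draw_pattern(n_lines, n_env, n_mask, rng)
        per_env = m.mean(axis=0)
        if np.all(per_env > target_rate / 2.0) and np.all(per_env < 1.0):
            mask = pd.DataFrame(
                m, index=blues.values.index, columns=blues.values.columns
            )
            return MaskPattern(
                mask, target_rate, n_mask / n_cells, per_env, seed, attempt
            )
    raise RuntimeError(
        f"no masking pattern satisfying rate/2 < per-env rate < 1 found for "
        f"target_rate={target_rate} after {max_rejections} draws; the per-"
        f"environment balance constraint appears infeasible for this layout"
    )


def accuracy(
    predictions: pd.DataFrame, blues: EnvBLUEs, test_lines: list[str]
) -> pd.Series:
    """Per-environment Pearson r between predictions and observed BLUEs.

    Cells whose BLUE is missing are dropped; an environment with fewer than
    3 observed test lines or zero variance yields NaN (undefined, not 0).
    """
    out = {}
    for env in blues.env_ids:
        obs = blues.values.loc[test_lines, env].to_numpy(float)
        pred = predictions.loc[test_lines, env].to_numpy(float)
        ok = np.isfinite(obs) & np.isfinite(pred)
        if ok.sum() < 3 or np.std(obs[ok]) == 0 or np.std(pred[ok]) == 0:
            out[env] = np.nan
            continue
        out[env] = float(np.corrcoef(pred[ok], obs[ok])[0, 1])
    return pd.Series(out, name="accuracy")


def fisher_z(r) -> np.ndarray:
    return np.arctanh(r)


def build_schedule(
    n_folds: int = 5,
    cv_repeats: int = 10,
    mask_repeats: int = 10,
    missing_rates=tuple(np.round(np.arange(0.0, 0.91, 0.1), 10)),
    models=("VG",),
    codings=("marker",),
) -> pd.DataFrame:
    """Enumerate every planned calibration.

    At missing rate 0 the mask repeats collapse to a single distinct
    training set, so only one is scheduled.  With the study protocol
    (5 folds, 10 CV repeats, 10 mask repeats) each positive missing rate
    gets 5 x 10 x 10 = 500 calibrations per model/coding over the
    5 x 10 = 50 train/test divisions.
    """
    rows = []
    for model in models:
        for coding in codings:
            for rate in missing_rates:
                m_reps = 1 if rate == 0 else mask_repeats
                for cv_rep in range(cv_repeats):
                    for fold in range(n_folds):
                        for m_rep in range(m_reps):
                            rows.append(
                                {
                                    "model": model,
                                    "coding": coding,
                                    "missing_rate": rate,
                                    "cv_repeat": cv_rep,
                                    "fold": fold,
                                    "mask_repeat": m_rep,
                                }
                            )
    return pd.DataFrame(rows)


def run_cv(
    blues: EnvBLUEs,
    kinships: dict[str, KinshipMatrix],
    models=("VG",),
    missing_rates=(0.0, 0.3),
    cv_repeats: int = 10,
    mask_repeats: int = 10,
    n_folds: int = 5,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> CVResult:
    """Full CV1 sparse-phenotyping evaluation.

    For each (cv repeat, fold, missing rate, mask repeat, model, coding):
    mask the training lines' BLUEs, fit on the unmasked cells, predict all
    test cells.  Per cv repeat the five folds' test predictions are
    concatenated before the per-environment accuracy is computed, so each
    (model, coding, rate, cv repeat, mask repeat, env) yields one record.
    """
    spec = spec or ModelSpec()
    line_ids = blues.line_ids
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(cv_repeats)
    records = []
    for cv_rep in range(cv_repeats):
        folds = make_folds(line_ids, n_folds, int(fold_seeds[cv_rep].generate_state(1)[0] % 2**31))
        for rate in missing_rates:
            m_reps = 1 if rate == 0 else mask_repeats
            for m_rep in range(m_reps):
                # one concatenated prediction table per cv repeat
                preds = {
                    (model, coding): pd.DataFrame(
                        np.nan, index=blues.values.index, columns=blues.values.columns
                    )
                    for model in models
                    for coding in kinships
                }
                for fold_i, test_lines in enumerate(folds):
                    train_lines = [l for l in line_ids if l not in set(test_lines)]
                    tr_blues = EnvBLUEs(values=blues.values.loc[train_lines])
                    mseed = int(
                        np.random.SeedSequence(
                            (seed, cv_rep, fold_i, int(rate * 100), m_rep)
                        ).generate_state(1)[0]
                        % 2**31
                    )
                    pattern = mask_training(tr_blues, rate, seed=mseed)
                    tr_blues = tr_blues.with_mask(pattern.mask)
                    for coding, K in kinships.items():
                        for model in models:
                            fit_spec = ModelSpec(
                                model=model,
                                n_iter=spec.n_iter,
                                burn_in=spec.burn_in,
                                thin=spec.thin,
                                prior_df=spec.prior_df,
                                prior_partition=spec.prior_partition,
                                seed=mseed + 7,
                            )
                            fit = fit_model(tr_blues, K, fit_spec)
                            table = predict(fit)
                            preds[(model, coding)].loc[test_lines] = table.loc[
                                test_lines, blues.values.columns
                            ]
                for (model, coding), table in preds.items():
                    accs = accuracy(table, blues, line_ids)
                    for env, r in accs.items():
                        records.append(
                            {
                                "model": model,
                                "coding": coding,
                                "missing_rate": rate,
                                "cv_repeat": cv_rep,
                                "mask_repeat": m_rep,
                                "env": env,
                                "accuracy": r,
                                "z": float(fisher_z(r)) if np.isfinite(r) else np.nan,
                            }
                        )
    return CVResult(records=pd.DataFrame(records))


def compare_models(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Paired two-sided t-test on Fisher-z-transformed accuracies.

    ``a`` and ``b`` are CVResult record slices sharing
    (cv_repeat, mask_repeat, env, missing_rate) keys.
    """
    keys = ["missing_rate", "cv_repeat", "mask_repeat", "env"]
    keys = [k for k in keys if k in a.columns and k in b.columns]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    za = fisher_z(merged["accuracy_a"].to_numpy(float))
    zb = fisher_z(merged["accuracy_b"].to_numpy(float))
    ok = np.isfinite(za) & np.isfinite(zb)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired records")
    if np.allclose(za[ok], zb[ok]):
        return 0.0, 1.0
    t, p = stats.ttest_rel(za[ok], zb[ok])
    return float(t), float(p)
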