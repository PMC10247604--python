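"""Two-stage phenotypic analysis of multi-environment field trials.

Stage 1 fits, within each environment, the model

    y = 1 mu + X_w w + Z_l l + eps

where ``w`` collects experimental-design effects (replicate, row, column —
whichever the trial has) treated as i.i.d. random, and the genetic effect of
lines ``l`` is treated once as fixed (giving environment-specific BLUEs) and
once as random (giving the Cullis repeatability).  Stage 2 combines the
per-environment BLUEs in

    y_hat = 1 mu + Z_v v + Z_g g + e

with environment and line effects random, and reports the Cullis
generalized heritability

    1 - c_bar / (2 sigma_g^2)

where c_bar is the mean variance of a difference between two line BLUPs.
Variance components are estimated by REML, maximized directly (L-BFGS-B on
log variances) over the Henderson mixed-model-equations representation of
the likelihood, which keeps every fit at these problem sizes in the
millisecond range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "EnvBLUEs",
    "VarianceComponents",
    "MixedModelFit",
    "fit_mixed",
    "fit_stage1",
    "stage1_all_envs",
    "fit_stage2",
    "cullis_from_pev",
]

DESIGN_TERMS = ("replicate", "row", "column")


@dataclass
class VarianceComponents:
    """Named variance components (trait units squared) plus derived ratios."""

    components: dict[str, float]
    derived: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.components.items():
            if v < 0:
                raise ValueError(f"negative variance component {k}={v}")


@dataclass
class EnvBLUEs:
    """Line x environment table of stage-1 BLUEs with a maskable cell grid.

    ``mask`` marks cells excluded from downstream likelihoods (sparse
    phenotyping); masked cells retain their value.  ``repeatability`` maps
    environment -> Cullis repeatability when stage 1 was run.
    """

    values: pd.DataFrame
    mask: pd.DataFrame | None = None
    repeatability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if not self.mask.index.equals(self.values.index) or not self.mask.columns.equals(
            self.values.columns
        ):
            raise ValueError("mask must be aligned with values")

    @property
    def line_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def env_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def observed(self) -> pd.DataFrame:
        """Long table of unmasked, non-missing (line, env, value) cells."""
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["line", "env", "value"]
        masked = self.mask.stack().to_numpy()
        return long.loc[~masked & np.isfinite(long["value"].to_numpy())]

    def with_mask(self, mask: pd.DataFrame) -> "EnvBLUEs":
        return EnvBLUEs(
            values=self.values, mask=mask, repeatability=dict(self.repeatability)
        )

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)


@dataclass
class MixedModelFit:
    beta: np.ndarray
    blups: dict[str, np.ndarray]
    sigma2: dict[str, float]
    loglik: float
    pev: dict[str, np.ndarray]
    converged: bool


def _indicator(levels: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(levels)
    Z = np.zeros((len(levels), len(cats.categories)))
    Z[np.arange(len(levels)), cats.codes] = 1.0
    return Z, list(cats.categories)


def fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    pev_terms: tuple[str, ...] = (),
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixedModelFit:
    """REML for y = X beta + sum_k Z_k u_k + e with u_k ~ N(0, I sigma_k^2).

    The REML objective is evaluated through the Henderson MME coefficient
    matrix (precomputed cross-products, one Cholesky per evaluation) and
    maximized over log variances; a variance shrinking to the lower bound is
    reported as (effectively) zero with a logged warning.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    names = list(Zs.keys())
    Zmats = [np.asarray(Zs[k], float) for k in names]
    W = np.concatenate([X] + Zmats, axis=1) if Zmats else X
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    q_sizes = [Z.shape[1] for Z in Zmats]
    q_tot = sum(q_sizes)
    vy = max(float(np.var(y)), 1e-12)
    lo, hi = np.log(vy * 1e-8), np.log(vy * 1e6)

    ridge = np.zeros(p + q_tot)

    def neg2ll(logs: np.ndarray) -> float:
        s2 = np.exp(logs)
        se2 = s2[-1]
        C = WtW / se2
        off = p
        for qi, sk in zip(q_sizes, s2[:-1]):
            C[off : off + qi, off : off + qi] += np.eye(qi) / sk
            off += qi
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e12
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        theta = cho_solve(cf, Wty / se2, check_finite=False)
        yPy = yty / se2 - float(theta @ Wty) / se2
        val = n * np.log(se2) + sum(
            qi * np.log(sk) for qi, sk in zip(q_sizes, s2[:-1])
        )
        return val + logdetC + yPy

    x0 = np.full(len(q_sizes) + 1, np.log(vy / (len(q_sizes) + 1)))
    if q_sizes:
        res = minimize(
            neg2ll,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(x0),
            options={"ftol": tol, "maxiter": max_iter},
        )
        logs = res.x
        converged = bool(res.success)
    else:
        # pure fixed-effects model: sigma_e^2 has a closed form
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        logs = np.array([np.log(max(float(resid @ resid) / max(n - p, 1), vy * 1e-10))])
        converged = True
    s2 = np.exp(logs)
    if q_sizes and np.any(logs[:-1] <= lo + 1e-6):
        logger.warning("a variance component hit its lower bound (treated as ~0)")
    se2 = s2[-1]
    C = WtW / se2
    off = p
    for qi, sk in zip(q_sizes, s2[:-1]):
        C[off : off + qi, off : off + qi] += np.eye(qi) / sk
        off += qi
    cf = cho_factor(C, lower=True, check_finite=False)
    theta = cho_solve(cf, Wty / se2, check_finite=False)
    ll = -0.5 * neg2ll(logs)
    beta = theta[:p]
    blups: dict[str, np.ndarray] = {}
    pev: dict[str, np.ndarray] = {}
    off = p
    Cinv = None
    for name, qi in zip(names, q_sizes):
        blups[name] = theta[off : off + qi]
        if name in pev_terms:
            if Cinv is None:
                Cinv = cho_solve(cf, np.eye(p + q_tot), check_finite=False)
            pev[name] = Cinv[off : off + qi, off : off + qi]
        off += qi
    sigma2 = {name: float(sk) for name, sk in zip(names, s2[:-1])}
    sigma2["residual"] = float(se2)
    return MixedModelFit(
        beta=beta, blups=blups, sigma2=sigma2, loglik=ll, pev=pev, converged=converged
    )


def cullis_from_pev(pev: np.ndarray, sigma2_g: float) -> float:
    """Cullis generalized heritability 1 - c_bar / (2 sigma_g^2).

    ``c_bar`` is the exact mean over all line pairs of
    Var(BLUP_i - BLUP_j) = PEV_ii + PEV_jj - 2 PEV_ij.
    """
    n = pev.shape[0]
    if n < 2 or sigma2_g <= 0:
        return 0.0
    tr = np.trace(pev)
    total = pev.sum()
    c_bar = 2.0 * (n * tr - total) / (n * (n - 1))
    h2 = 1.0 - c_bar / (2.0 * sigma2_g)
    if h2 < 0.0:
        logger.warning("Cullis estimate below 0 (%.3f); clamped", h2)
    return float(np.clip(h2, 0.0, 1.0))


def _design_Zs(df: pd.DataFrame, design_terms) -> dict[str, np.ndarray]:
    Zs: dict[str, np.ndarray] = {}
    for term in design_terms:
        if term in df.columns and df[term].notna().all() and df[term].nunique() > 1:
            Zs[term], _ = _indicator(df[term])
    return Zs


def fit_stage1(
    plots: pd.DataFrame,
    env: str,
    design_terms=DESIGN_TERMS,
) -> tuple[pd.Series, float, VarianceComponents]:
    """Per-environment spatial adjustment: BLUEs, repeatability, components.

    ``plots`` is the long plot table (env, line, replicate, row, column,
    value).  Two fits are run: lines fixed (BLUEs) and lines random
    (repeatability via the Cullis formula); design effects are random in
    both.
    """
    sub = plots.loc[plots["env"].astype(str) == str(env)]
    if sub.empty:
        raise ValueError(f"no plot records for environment {env!r}")
    y = sub["value"].to_numpy(float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    Zs = _design_Zs(sub, design_terms)

    # (a) lines fixed -> BLUEs (cell-means coding: one column per line)
    Xl, line_levels = _indicator(sub["line"].astype(str))
    fit_a = fit_mixed(y, Xl, Zs)
    blues = pd.Series(fit_a.beta, index=[str(l) for l in line_levels], name=str(env))

    # (b) lines random -> Cullis repeatability
    counts = sub.groupby("line").size()
    if counts.max() < 2:
        logger.warning("environment %s has single replication; repeatability NaN", env)
        return blues, float("nan"), VarianceComponents(
            components={**fit_a.sigma2}, derived={"repeatability": float("nan")}
        )
    Zl, _ = _indicator(sub["line"].astype(str))
    fit_b = fit_mixed(
        y, np.ones((len(y), 1)), {"line": Zl, **Zs}, pev_terms=("line",)
    )
    rep = cullis_from_pev(fit_b.pev["line"], fit_b.sigma2["line"])
    vc = VarianceComponents(
        components=dict(fit_b.sigma2), derived={"repeatability": rep}
    )
    return blues, rep, vc


def stage1_all_envs(plots: pd.DataFrame, design_terms=DESIGN_TERMS) -> EnvBLUEs:
    """Run stage 1 in every environment and assemble the BLUE table."""
    envs = [str(e) for e in pd.unique(plots["env"].astype(str))]
    series = {}
    reps = {}
    for env in envs:
        blues, rep, _ = fit_stage1(plots, env, design_terms)
        series[env] = blues
        reps[env] = rep
    values = pd.DataFrame(series)
    return EnvBLUEs(values=values, repeatability=reps)


def fit_stage2(blues: EnvBLUEs) -> tuple[pd.Series, float, VarianceComponents]:
    """Combined analysis of environment-specific BLUEs.

    Fits mu + env (random) + line (random) by REML and reports overall
    genetic effects (line BLUPs) and the Cullis heritability.
    """
    obs = blues.observed()
    if obs["env"].nunique() < 2:
        raise ValueError(
            "stage 2 needs >= 2 environments; use stage-1 repeatability instead"
        )
    y = obs["value"].to_numpy(float)
    Zv, _ = _indicator(obs["env"].astype(str))
    Zg, line_levels = _indicator(obs["line"].astype(str))
    fit = fit_mixed(
        y, np.ones((len(y), 1)), {"env": Zv, "line": Zg}, pev_terms=("line",)
    )
    h2 = cullis_from_pev(fit.pev["line"], fit.sigma2["line"])
    g = pd.Series(fit.blups["line"], index=[str(l) for l in line_levels], name="g")
    vc = VarianceComponents(components=dict(fit.sigma2), derived={"heritability": h2})
    return g, h2, vc
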