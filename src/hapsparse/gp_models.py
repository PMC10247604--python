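"""Bayesian multi-environment genomic prediction: VG, VGR and FA(1).

All three models regress environment-specific BLUEs on a genomic
relationship matrix K via Gibbs sampling:

``VG``   y = 1 mu + Z_v v + Z_g g + e, with v ~ N(0, I s2_v) environment
         main effects and g ~ N(0, K s2_g) — no genotype-by-environment
         interaction.

``VGR``  adds a reaction-norm interaction r ~ N(0, (Z_v Z_v') o (Z_g K Z_g')
         s2_r); the Hadamard-product kernel is block diagonal by
         environment, so r is sampled per environment as a Gaussian process
         with covariance K s2_r.

``FA``   the factor-analytic model: per-environment genetic effects
         u = (g_1', ..., g_l')' ~ N(0, Psi_u (x) K) with
         Psi_u = Lambda Lambda' + Pi and one latent factor (t = 1),
         heteroscedastic residuals per environment.  Sampled through the
         equivalent decomposition g_j = lambda_j f + d_j with common factor
         scores f ~ N(0, K) and specific deviations d_j ~ N(0, K pi_j);
         identifiability is enforced by flipping the sign of (Lambda, f)
         whenever the first loading goes negative.

Masked or missing cells contribute nothing to any likelihood; posterior
genetic values remain defined for every line through K.  Samplers run on
the phenotyped (training) lines; effects of unphenotyped lines are obtained
by the exact conditional-mean projection K[test, train] K[train, train]^-1
applied to the posterior means, which is identical to carrying them in the
chain.  Variance priors are scaled inverse chi-square with ``prior_df``
degrees of freedom and scales placing the prior mode at an equal split of
the phenotypic variance across model terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix
from .pheno_two_stage import EnvBLUEs

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_vg",
    "fit_vgr",
    "fit_fa",
    "fit_model",
    "predict",
    "geweke_z",
]

MODELS = ("VG", "VGR", "FA")


@dataclass
class ModelSpec:
    """Sampler settings.  Defaults mirror the study protocol: 10,000
    iterations with the first 4,000 discarded as burn-in, one latent factor."""

    model: str = "VG"
    n_iter: int = 10_000
    burn_in: int = 4_000
    thin: int = 1
    prior_df: float = 5.0
    prior_partition: float | None = None
    n_factors: int = 1
    seed: int = 0
    #: optionally pin parameters (degenerate priors), e.g. {"s2_g": 1.0,
    #: "mu": 0.0} for VG/VGR or {"lambda": [...], "pi": [...]} for FA
    fixed: dict | None = None

    def __post_init__(self) -> None:
        if self.model.upper() not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        self.model = self.model.upper()
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.model == "FA" and self.n_factors != 1:
            raise ValueError("only the single-factor FA model is supported")


@dataclass
class FitResult:
    model: str
    spec: ModelSpec
    line_ids: list[str]  # training lines, in sampler order
    env_ids: list[str]
    post_mean: dict[str, np.ndarray]
    var_components: dict[str, float]
    chains: dict[str, np.ndarray] = field(default_factory=dict)
    psi_u: np.ndarray | None = None
    psi_u_corr: np.ndarray | None = None
    kinship: KinshipMatrix | None = None
    train_idx: np.ndarray | None = None


class _ScaledInvChi2:
    """Conjugate scaled-inverse-chi-square update helper."""

    def __init__(self, df: float, mode: float):
        self.df = df
        self.scale = mode * (df + 2.0) / df  # prior mode = df*scale/(df+2)

    def draw(self, rng: np.random.Generator, ss: float, n: float) -> float:
        df_post = self.df + n
        return (self.df * self.scale + ss) / rng.chisquare(df_post)


class _GP:
    """Shared machinery for sampling a Gaussian-process effect a ~ N(0, K s2)
    observed through a 0/1 diagonal design with homoscedastic noise.

    Uses the eigenbasis of K: when every line is observed the conditional
    precision is diagonal there; otherwise a dense Cholesky is taken.
    """

    def __init__(self, K: np.ndarray):
        vals, U = np.linalg.eigh((K + K.T) / 2.0)
        if vals.min() < -1e-8 * max(vals.max(), 1.0):
            raise ValueError(
                f"kinship matrix is not PSD (min eigenvalue {vals.min():.3e})"
            )
        self.vals = np.maximum(vals, vals.max() * 1e-8)  # ridge on eigenvalue scale
        self.U = U
        self.Kinv = (U / self.vals) @ U.T
        self.n = K.shape[0]

    def sample(
        self,
        rng: np.random.Generator,
        rhs: np.ndarray,
        obs_w: np.ndarray,
        prior_var: float,
    ) -> np.ndarray:
        """Draw from N(P^-1 rhs, P^-1), P = diag(obs_w) + K^-1 / prior_var.

        ``obs_w`` is the per-line data precision (0 for unobserved lines);
        ``rhs`` already includes the data-precision weighting.
        """
        w0 = obs_w[0]
        if np.all(obs_w == w0):
            prec = w0 + 1.0 / (self.vals * prior_var)
            r = self.U.T @ rhs
            mean = r / prec
            draw = mean + rng.standard_normal(self.n) / np.sqrt(prec)
            return self.U @ draw
        P = self.Kinv / prior_var
        P[np.diag_indices(self.n)] += obs_w
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, rhs)
        z = rng.standard_normal(self.n)
        return mean + np.linalg.solve(L.T, z)

    def quad(self, a: np.ndarray) -> float:
        return float(a @ (self.Kinv @ a))


def _prepare(blues: EnvBLUEs, K: KinshipMatrix):
    env_ids = blues.env_ids
    lines = blues.line_ids
    missing = [l for l in lines if l not in set(K.line_ids)]
    if missing:
        raise ValueError(f"lines absent from kinship matrix: {missing[:5]}")
    Y = blues.values.to_numpy(float)
    O = (~blues.mask.to_numpy()) & np.isfinite(Y)
    train = O.any(axis=1)
    if (O.sum(axis=0) < 1).any():
        j = int(np.flatnonzero(O.sum(axis=0) < 1)[0])
        raise ValueError(f"environment {env_ids[j]} has no unmasked cells")
    t_lines = [lines[i] for i in np.flatnonzero(train)]
    kpos = {l: i for i, l in enumerate(K.line_ids)}
    train_idx = np.array([kpos[l] for l in t_lines])
    Kt = K.values[np.ix_(train_idx, train_idx)]
    return Y[train], O[train], t_lines, env_ids, Kt, train_idx


def _fit_sampler(blues: EnvBLUEs, K: KinshipMatrix, spec: ModelSpec) -> FitResult:
    Y, O, t_lines, env_ids, Kt, train_idx = _prepare(blues, K)
    n_t, n_env = Y.shape
    rng = np.random.default_rng(spec.seed)
    gp = _GP(Kt)
    y_obs = Y[O]
    vy = max(float(np.var(y_obs)), 1e-12)
    n_obs = int(O.sum())
    obs_f = O.astype(float)
    counts = O.sum(axis=1).astype(float)  # per line
    n_per_env = O.sum(axis=0).astype(float)
    Yz = np.where(O, Y, 0.0)

    model = spec.model
    n_terms = {"VG": 3, "VGR": 4, "FA": 3}[model]
    part = spec.prior_partition if spec.prior_partition is not None else 1.0 / n_terms
    pri = _ScaledInvChi2(spec.prior_df, part * vy)

    keep = range(spec.burn_in, spec.n_iter, spec.thin)
    n_keep = len(keep)
    keep_set = set(keep)

    fixed = spec.fixed or {}

    if model in ("VG", "VGR"):
        mu = float(fixed.get("mu", np.mean(y_obs)))
        v = np.asarray(fixed["v"], float) if "v" in fixed else np.zeros(n_env)
        g = np.zeros(n_t)
        r = np.zeros((n_t, n_env))
        s2v = float(fixed.get("s2_v", part * vy))
        s2g = float(fixed.get("s2_g", part * vy))
        s2e = float(fixed.get("s2_e", part * vy))
        s2r = float(fixed.get("s2_r", part * vy))
        acc = {"mu": 0.0, "v": np.zeros(n_env), "g": np.zeros(n_t),
               "r": np.zeros((n_t, n_env))}
        ch = {k: np.empty(n_keep) for k in ("s2_v", "s2_g", "s2_e") + (("s2_r",) if model == "VGR" else ())}
        ki = 0
        for it in range(spec.n_iter):
            fitted_gr = g[:, None] + r if model == "VGR" else g[:, None]
            # mu
            if "mu" not in fixed:
                s = float((Yz - obs_f * (v[None, :] + fitted_gr))[O].sum())
                mu = s / n_obs + rng.standard_normal() * np.sqrt(s2e / n_obs)
            # v per environment
            if "v" not in fixed:
                resid_v = Yz - obs_f * (mu + fitted_gr)
                prec_v = n_per_env / s2e + 1.0 / s2v
                mean_v = (resid_v * obs_f).sum(axis=0) / s2e / prec_v
                v = mean_v + rng.standard_normal(n_env) / np.sqrt(prec_v)
            # g jointly over training lines
            resid_g = Yz - obs_f * (mu + v[None, :] + (r if model == "VGR" else 0.0))
            t = (resid_g * obs_f).sum(axis=1)
            g = gp.sample(rng, t / s2e, counts / s2e, s2g)
            if model == "VGR":
                base = mu + v[None, :] + g[:, None]
                for j in range(n_env):
                    rhs = obs_f[:, j] * (Yz[:, j] - obs_f[:, j] * base[:, j]) / s2e
                    r[:, j] = gp.sample(rng, rhs, obs_f[:, j] / s2e, s2r)
                if "s2_r" not in fixed:
                    s2r = pri.draw(
                        rng, sum(gp.quad(r[:, j]) for j in range(n_env)), n_t * n_env
                    )
            # variances
            if "s2_v" not in fixed:
                s2v = pri.draw(rng, float(v @ v), n_env)
            if "s2_g" not in fixed:
                s2g = pri.draw(rng, gp.quad(g), n_t)
            if "s2_e" not in fixed:
                resid = (Y - mu - v[None, :] - g[:, None] - (r if model == "VGR" else 0.0))[O]
                s2e = pri.draw(rng, float(resid @ resid), n_obs)
            if it in keep_set:
                acc["mu"] += mu
                acc["v"] += v
                acc["g"] += g
                if model == "VGR":
                    acc["r"] += r
                ch["s2_v"][ki] = s2v
                ch["s2_g"][ki] = s2g
                ch["s2_e"][ki] = s2e
                if model == "VGR":
                    ch["s2_r"][ki] = s2r
                ki += 1
        post = {k: val / n_keep for k, val in acc.items()}
        var_c = {k: float(c.mean()) for k, c in ch.items()}
        return FitResult(
            model=model, spec=spec, line_ids=t_lines, env_ids=env_ids,
            post_mean=post, var_components=var_c, chains=ch,
            kinship=K, train_idx=train_idx,
        )

    # FA(1)
    mu_j = (
        np.asarray(fixed["mu_env"], float)
        if "mu_env" in fixed
        else np.array([float(Y[O[:, j], j].mean()) for j in range(n_env)])
    )
    f = np.zeros(n_t)
    d = np.zeros((n_t, n_env))
    lam = np.asarray(fixed["lambda"], float) if "lambda" in fixed else np.full(
        n_env, np.sqrt(part * vy)
    )
    pi = np.asarray(fixed["pi"], float) if "pi" in fixed else np.full(n_env, part * vy)
    se = np.asarray(fixed["s2_e"], float) if "s2_e" in fixed else np.full(
        n_env, part * vy
    )
    tau_lam = vy  # Gaussian prior variance for loadings
    acc_mu = np.zeros(n_env)
    acc_G = np.zeros((n_t, n_env))
    acc_lam = np.zeros(n_env)
    acc_psi = np.zeros((n_env, n_env))
    acc_corr = np.zeros((n_env, n_env))
    ch = {"s2_e": np.empty((n_keep, n_env)), "pi": np.empty((n_keep, n_env)),
          "lambda": np.empty((n_keep, n_env))}
    ki = 0
    for it in range(spec.n_iter):
        # per-env intercepts
        if "mu_env" not in fixed:
            for j in range(n_env):
                o = O[:, j]
                resid = Y[o, j] - lam[j] * f[o] - d[o, j]
                nj = n_per_env[j]
                mu_j[j] = resid.sum() / nj + rng.standard_normal() * np.sqrt(se[j] / nj)
        # common factor scores f ~ N(0, K)
        rhs = np.zeros(n_t)
        w = np.zeros(n_t)
        for j in range(n_env):
            o = obs_f[:, j]
            rhs += (lam[j] / se[j]) * o * (Yz[:, j] - o * (mu_j[j] + d[:, j]))
            w += (lam[j] ** 2 / se[j]) * o
        f = gp.sample(rng, rhs, w, 1.0)
        # specific deviations d_j ~ N(0, K pi_j)
        for j in range(n_env):
            o = obs_f[:, j]
            rhs = o * (Yz[:, j] - o * (mu_j[j] + lam[j] * f)) / se[j]
            d[:, j] = gp.sample(rng, rhs, o / se[j], pi[j])
        # loadings
        if "lambda" not in fixed:
            for j in range(n_env):
                o = O[:, j]
                resid = Y[o, j] - mu_j[j] - d[o, j]
                prec = float(f[o] @ f[o]) / se[j] + 1.0 / tau_lam
                mean = float(f[o] @ resid) / se[j] / prec
                lam[j] = mean + rng.standard_normal() / np.sqrt(prec)
            if lam[0] < 0:  # sign identifiability per draw
                lam = -lam
                f = -f
        # variances
        for j in range(n_env):
            if "pi" not in fixed:
                pi[j] = pri.draw(rng, gp.quad(d[:, j]), n_t)
            if "s2_e" not in fixed:
                o = O[:, j]
                resid = Y[o, j] - mu_j[j] - lam[j] * f[o] - d[o, j]
                se[j] = pri.draw(rng, float(resid @ resid), int(o.sum()))
        if it in keep_set:
            G = lam[None, :] * f[:, None] + d
            psi = np.outer(lam, lam) + np.diag(pi)
            sd = np.sqrt(np.diag(psi))
            acc_mu += mu_j
            acc_G += G
            acc_lam += lam
            acc_psi += psi
            acc_corr += psi / np.outer(sd, sd)
            ch["s2_e"][ki] = se
            ch["pi"][ki] = pi
            ch["lambda"][ki] = lam
            ki += 1
    psi_mean = acc_psi / n_keep
    post = {
        "mu_env": acc_mu / n_keep,
        "g_env": acc_G / n_keep,
        "lambda": acc_lam / n_keep,
    }
    var_c = {f"s2_e[{env_ids[j]}]": float(ch["s2_e"][:, j].mean()) for j in range(n_env)}
    var_c.update({f"pi[{env_ids[j]}]": float(ch["pi"][:, j].mean()) for j in range(n_env)})
    return FitResult(
        model="FA", spec=spec, line_ids=t_lines, env_ids=env_ids,
        post_mean=post, var_components=var_c, chains=ch,
        psi_u=psi_mean, psi_u_corr=acc_corr / n_keep,
        kinship=K, train_idx=train_idx,
    )


def fit_vg(blues: EnvBLUEs, K: KinshipMatrix, spec: ModelSpec | None = None) -> FitResult:
    spec = spec or ModelSpec(model="VG")
    if spec.model != "VG":
        raise ValueError("spec.model must be VG")
    return _fit_sampler(blues, K, spec)


def fit_vgr(blues: EnvBLUEs, K: KinshipMatrix, spec: ModelSpec | None = None) -> FitResult:
    spec = spec or ModelSpec(model="VGR")
    if spec.model != "VGR":
        raise ValueError("spec.model must be VGR")
    return _fit_sampler(blues, K, spec)


def fit_fa(blues: EnvBLUEs, K: KinshipMatrix, spec: ModelSpec | None = None) -> FitResult:
    spec = spec or ModelSpec(model="FA")
    if spec.model != "FA":
        raise ValueError("spec.model must be FA")
    if len(blues.env_ids) < 2:
        raise ValueError("FA model needs >= 2 environments")
    return _fit_sampler(blues, K, spec)


def fit_model(blues: EnvBLUEs, K: KinshipMatrix, spec: ModelSpec) -> FitResult:
    return {"VG": fit_vg, "VGR": fit_vgr, "FA": fit_fa}[spec.model](blues, K, spec)


def predict(fit: FitResult, targets: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Posterior-mean genetic values (excluding residual) for (line, env) cells.

    Returns a lines x environments table covering every line in K; effects
    of unphenotyped lines flow purely through the relationship matrix (and
    Psi_u for FA).  ``targets`` optionally restricts the output to listed
    cells (returned as a long DataFrame).
    """
    K = fit.kinship
    if K is None:
        raise ValueError("fit carries no kinship matrix")
    n_all = K.n_lines
    tr = fit.train_idx
    Kt = K.values[np.ix_(tr, tr)]
    vals, U = np.linalg.eigh((Kt + Kt.T) / 2.0)
    vals = np.maximum(vals, vals.max() * 1e-8)
    proj = K.values[:, tr] @ ((U / vals) @ U.T)  # rows for train lines = identity

    if fit.model in ("VG", "VGR"):
        g_all = proj @ fit.post_mean["g"]
        pred = fit.post_mean["mu"] + fit.post_mean["v"][None, :] + g_all[:, None]
        if fit.model == "VGR":
            pred = pred + proj @ fit.post_mean["r"]
    else:
        pred = fit.post_mean["mu_env"][None, :] + proj @ fit.post_mean["g_env"]
    table = pd.DataFrame(pred, index=K.line_ids, columns=fit.env_ids)
    if targets is None:
        return table
    missing = [l for l, _ in targets if l not in set(K.line_ids)]
    if missing:
        raise ValueError(f"target lines absent from kinship matrix: {missing[:5]}")
    rows = [{"line": l, "env": e, "prediction": table.at[l, e]} for l, e in targets]
    return pd.DataFrame(rows)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    chain = np.asarray(chain, float)
    n = len(chain)
    a = chain[: max(int(first * n), 2)]
    b = chain[-max(int(last * n), 2):]
    return float((a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
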