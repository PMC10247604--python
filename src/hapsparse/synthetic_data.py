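"""Synthetic inbred-line populations with block-structured LD and
factor-analytic multi-environment phenotypes.

The generator emulates the structure the analysis assumes, at desk scale:

* Founder haplotypes are mosaics of ancestry blocks.  Within a block each
  founder carries one of a small number of distinct haplotype strings, so
  adjacent SNPs inside a block are in near-complete LD; blocks are separated
  by recombination hotspots, so LD decays sharply across boundaries.
* Recombinant inbred lines (RILs) descend from the founders through a
  multi-way crossing funnel followed by doubled-haploid-style instant
  homozygosity: every gamete recombines with a Haldane map (crossover count
  Poisson in the genetic length, positions uniform in cM).
* Per-environment genetic values follow a rank-1-plus-diagonal (FA)
  covariance: u_ij = lambda_j f_i + sqrt(pi_j) s_ij, where the common factor
  score f and the specific deviations s are linear in the genome — a mix of
  additive SNP effects and within-block haplotype-allele effects in
  proportion (1 - local_epistasis_frac) : local_epistasis_frac.
* Plot records add an environment mean, random replicate/row/column design
  effects and residual noise scaled so the line-mean heritability in each
  environment hits the target h2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hap_features import enumerate_haplotypes
from .io_qc import GenotypeMatrix
from .ld_blocks import HaplotypeBlock
from .pheno_two_stage import EnvBLUEs

__all__ = ["SimConfig", "TruthRecord", "simulate_genotypes", "simulate_phenotypes",
           "simulate_population", "PRESETS"]


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults describe a mid-size multi-parent RIL population: 8 founders,
    300 lines, 3 chromosomes of 2 Mb carrying 80 SNPs each, ancestry blocks
    of 40-160 kb, 4 environments whose genetic covariance follows a single
    factor with heterogeneous loadings, line-mean h2 of 0.8 per environment
    and 3 replicates.
    """

    n_founders: int = 8
    n_lines: int = 300
    n_chrom: int = 3
    snps_per_chrom: int = 80
    chrom_length_bp: int = 2_000_000
    block_length_bp: tuple[int, int] = (40_000, 160_000)
    n_block_haplotypes: tuple[int, int] = (2, 4)
    cm_per_mb: float = 4.0
    hotspot_morgans: float = 5.0  # recombination fraction ~0.5 at boundaries
    cross_rounds: int = 3  # 8-way funnel: 8 -> 4 -> 2 -> 1
    h2: float = 0.8
    local_epistasis_frac: float = 0.3
    n_envs: int = 4
    lambda_loadings: tuple[float, ...] | None = None
    psi_specifics: tuple[float, ...] | None = None
    env_mean_sd: float = 1.0
    n_reps: int = 3
    design_sigmas: dict = field(
        default_factory=lambda: {"replicate": 0.05, "row": 0.05, "column": 0.05}
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if not 0 <= self.local_epistasis_frac <= 1:
            raise ValueError("local_epistasis_frac must be in [0, 1]")
        if self.lambda_loadings is None:
            base = np.linspace(0.7, 1.2, self.n_envs)
            self.lambda_loadings = tuple(base)
        if self.psi_specifics is None:
            self.psi_specifics = tuple(np.full(self.n_envs, 0.3))
        if len(self.lambda_loadings) != self.n_envs or len(self.psi_specifics) != self.n_envs:
            raise ValueError("loadings/specifics length must equal n_envs")
        if min(self.chrom_length_bp, self.snps_per_chrom, self.n_lines) <= 0:
            raise ValueError("sizes must be positive")


#: Population presets mirroring the three study populations' magnitudes.
PRESETS = {
    "pop1-like": dict(n_lines=344, n_envs=8, local_epistasis_frac=0.4),
    "pop2-like": dict(n_lines=254, n_envs=4, snps_per_chrom=50),
    "pop3-like": dict(n_lines=1048, n_envs=4, n_founders=8),
}


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    genetic_values: pd.DataFrame | None = None  # lines x envs (u)
    factor_scores: np.ndarray | None = None
    env_means: np.ndarray | None = None
    env_corr: np.ndarray | None = None  # realized between-env genetic correlation
    implied_corr: np.ndarray | None = None
    blocks: list[HaplotypeBlock] = field(default_factory=list)
    snp_effects: np.ndarray | None = None
    hotspot_bounds: list[tuple[str, int]] = field(default_factory=list)


def _founder_haplotypes(cfg: SimConfig, rng: np.random.Generator):
    """Per chromosome: SNP positions, block assignment, founder haplotypes, cM map."""
    chroms = []
    for c in range(cfg.n_chrom):
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chrom_length_bp, 50), cfg.snps_per_chrom, replace=False
            )
        ).astype(np.int64)
        # ancestry blocks tile the chromosome
        bounds = [0]
        while bounds[-1] < cfg.chrom_length_bp:
            bounds.append(bounds[-1] + int(rng.integers(*cfg.block_length_bp)))
        block_of = np.searchsorted(np.asarray(bounds[1:]), pos, side="right")
        n_blocks = block_of.max() + 1
        founders = np.zeros((cfg.n_founders, cfg.snps_per_chrom), dtype=np.int8)
        for b in range(n_blocks):
            sidx = np.flatnonzero(block_of == b)
            if len(sidx) == 0:
                continue
            k = int(rng.integers(*cfg.n_block_haplotypes)) if cfg.n_founders > 1 else 1
            k = min(k, cfg.n_founders)
            protos = rng.integers(0, 2, size=(k, len(sidx)))
            assign = np.concatenate(
                [np.arange(k), rng.integers(0, k, size=cfg.n_founders - k)]
            )
            rng.shuffle(assign)
            founders[:, sidx] = protos[assign]
        # genetic map: uniform background plus hotspots at block boundaries
        cm = pos / 1e6 * cfg.cm_per_mb
        for b in range(1, n_blocks):
            boundary_bp = bounds[b]
            cm = cm + np.where(pos >= boundary_bp, cfg.hotspot_morgans * 100.0, 0.0)
        chroms.append(
            {
                "chrom": str(c + 1),
                "pos": pos,
                "block_of": block_of,
                "founders": founders,
                "cm": cm,
                "bounds": bounds[1:-1],
            }
        )
    return chroms


def _gamete(h1: np.ndarray, h2: np.ndarray, cm: np.ndarray, rng) -> np.ndarray:
    """Recombine two haplotypes: Poisson crossovers on the cM map (Haldane)."""
    total_m = (cm[-1] - cm[0]) / 100.0
    n_x = rng.poisson(total_m)
    cur = int(rng.integers(0, 2))
    if n_x == 0:
        return (h1 if cur == 0 else h2).copy()
    xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_x))
    seg = cur + np.searchsorted(xpos, cm, side="right")
    return np.where(seg % 2 == 0, h1, h2)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate fully homozygous RIL dosages with block-structured LD."""
    rng = np.random.default_rng(cfg.seed)
    chroms = _founder_haplotypes(cfg, rng)
    n_snps_total = sum(len(ch["pos"]) for ch in chroms)
    if cfg.n_founders < 1:
        raise ValueError("need at least one founder")
    dosage = np.zeros((cfg.n_lines, n_snps_total))
    col = 0
    truth = TruthRecord()
    snp_ids: list[str] = []
    chrom_lbl: list[str] = []
    pos_all: list[int] = []
    truth_blocks: list[HaplotypeBlock] = []
    for ch in chroms:
        m = len(ch["pos"])
        for li in range(cfg.n_lines):
            if cfg.n_founders == 1:
                hap = ch["founders"][0]
            else:
                pool = list(rng.permutation(cfg.n_founders))
                haps = [ch["founders"][i] for i in pool]
                while len(haps) > 1:
                    nxt = []
                    for a in range(0, len(haps) - 1, 2):
                        nxt.append(_gamete(haps[a], haps[a + 1], ch["cm"], rng))
                    if len(haps) % 2:
                        nxt.append(haps[-1])
                    haps = nxt
                hap = haps[0]
            dosage[li, col : col + m] = 2.0 * hap  # instant homozygosity (DH-style)
        for b in np.unique(ch["block_of"]):
            sidx = np.flatnonzero(ch["block_of"] == b) + col
            if len(sidx) >= 2:
                truth_blocks.append(
                    HaplotypeBlock(
                        chrom=ch["chrom"],
                        snp_indices=sidx,
                        start_bp=int(ch["pos"][sidx[0] - col]),
                        end_bp=int(ch["pos"][sidx[-1] - col]),
                    )
                )
        snp_ids += [f"snp_{ch['chrom']}_{p}" for p in ch["pos"]]
        chrom_lbl += [ch["chrom"]] * m
        pos_all += list(ch["pos"])
        truth.hotspot_bounds += [(ch["chrom"], int(b)) for b in ch["bounds"]]
        col += m
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = np.nan
    g = GenotypeMatrix(
        line_ids=[f"L{i:04d}" for i in range(cfg.n_lines)],
        snp_ids=snp_ids,
        chrom=np.array(chrom_lbl, dtype=object),
        pos_bp=np.array(pos_all),
        dosage=dosage,
    )
    truth.blocks = truth_blocks
    return g, truth


def _genetic_score(
    g: GenotypeMatrix,
    hap_dosage: np.ndarray | None,
    lef: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized genome-wide score mixing additive and local-epistatic parts."""
    X = np.nan_to_num(g.dosage, nan=np.nanmean(g.dosage))
    Xc = X - X.mean(axis=0)
    add = Xc @ rng.standard_normal(Xc.shape[1])
    sd = add.std()
    add = add / sd if sd > 0 else add
    if lef > 0 and hap_dosage is not None and hap_dosage.shape[1] > 0:
        Hc = hap_dosage - hap_dosage.mean(axis=0)
        loc = Hc @ rng.standard_normal(Hc.shape[1])
        sd = loc.std()
        loc = loc / sd if sd > 0 else loc
        score = np.sqrt(1 - lef) * add + np.sqrt(lef) * loc
    else:
        score = add
    sd = score.std()
    return score / sd if sd > 0 else score


def simulate_phenotypes(
    g: GenotypeMatrix, blocks: list[HaplotypeBlock], cfg: SimConfig
) -> tuple[pd.DataFrame, EnvBLUEs, TruthRecord]:
    """Plot records plus noiseless truth BLUEs under the FA(1) structure."""
    rng = np.random.default_rng(cfg.seed + 1)
    for bl in blocks:
        if (bl.snp_indices >= g.n_snps).any():
            raise ValueError("blocks reference SNPs absent from the genotype matrix")
    hap = None
    if cfg.local_epistasis_frac > 0 and blocks:
        hap = enumerate_haplotypes(g, blocks).dosage
    lam = np.asarray(cfg.lambda_loadings, float)
    pi = np.asarray(cfg.psi_specifics, float)
    scores = np.column_stack(
        [
            _genetic_score(g, hap, cfg.local_epistasis_frac, rng)
            for _ in range(cfg.n_envs + 1)
        ]
    )
    # Gram-Schmidt: the factor score and the specific deviations must be
    # uncorrelated in sample, or the realized between-environment covariance
    # would drift from Lambda Lambda' + Pi (the genome's effective dimension
    # is small under block LD, so raw scores are noticeably correlated)
    q, rmat = np.linalg.qr(scores - scores.mean(axis=0))
    q *= np.sign(np.diag(rmat))  # keep original orientation
    scores = q * np.sqrt(g.n_lines)
    f = scores[:, 0]
    s = scores[:, 1:]
    u = lam[None, :] * f[:, None] + np.sqrt(pi)[None, :] * s
    env_means = rng.normal(0.0, cfg.env_mean_sd, size=cfg.n_envs)
    env_ids = [f"E{j + 1}" for j in range(cfg.n_envs)]

    psi = np.outer(lam, lam) + np.diag(pi)
    sd = np.sqrt(np.diag(psi))
    truth = TruthRecord(
        genetic_values=pd.DataFrame(u, index=g.line_ids, columns=env_ids),
        factor_scores=f,
        env_means=env_means,
        env_corr=np.corrcoef(u.T),
        implied_corr=psi / np.outer(sd, sd),
        blocks=list(blocks),
    )

    sig_design = cfg.design_sigmas or {}
    n_rows = int(np.ceil(np.sqrt(cfg.n_lines)))
    rows = []
    for j, env in enumerate(env_ids):
        var_u = max(float(u[:, j].var()), 1e-12)
        rowcol_var = sig_design.get("row", 0.0) + sig_design.get("column", 0.0)
        # line-mean noise: (sigma_e^2 + rowcol variance) / n_reps
        se2 = max(cfg.n_reps * var_u * (1 - cfg.h2) / cfg.h2 - rowcol_var, 1e-12)
        for rep in range(cfg.n_reps):
            rep_eff = rng.normal(0, np.sqrt(sig_design.get("replicate", 0.0)))
            perm = rng.permutation(cfg.n_lines)  # field layout re-randomized per rep
            row_eff = rng.normal(0, np.sqrt(sig_design.get("row", 0.0)), n_rows)
            col_eff = rng.normal(0, np.sqrt(sig_design.get("column", 0.0)), n_rows)
            for k, li in enumerate(perm):
                rr, cc = divmod(k, n_rows)
                y = (
                    env_means[j]
                    + u[li, j]
                    + rep_eff
                    + row_eff[rr]
                    + col_eff[cc % n_rows]
                    + rng.normal(0, np.sqrt(se2))
                )
                rows.append(
                    {
                        "env": env,
                        "line": g.line_ids[li],
                        "replicate": rep + 1,
                        "row": rr + 1,
                        "column": (cc % n_rows) + 1,
                        "value": y,
                    }
                )
    plots = pd.DataFrame(rows)
    truth_blues = EnvBLUEs(
        values=pd.DataFrame(
            env_means[None, :] + u, index=g.line_ids, columns=env_ids
        )
    )
    return plots, truth_blues, truth


def simulate_population(cfg: SimConfig):
    """Convenience wrapper: genotypes, truth blocks, plots, truth BLUEs, truth."""
    g, gtruth = simulate_genotypes(cfg)
    plots, truth_blues, truth = simulate_phenotypes(g, gtruth.blocks, cfg)
    truth.hotspot_bounds = gtruth.hotspot_bounds
    return g, plots, truth_blues, truth
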