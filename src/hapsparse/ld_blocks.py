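"""Haplotype-block detection from D' confidence intervals.

Blocks are runs of adjacent SNPs in strong linkage disequilibrium, found with
the confidence-interval procedure of Gabriel et al.: for each SNP pair within
a physical window the 90% CI of |D'| is computed from the multinomial
likelihood of the two-locus haplotype counts, pairs are classified as strong
LD / strong recombination / noninformative, and a span of SNPs forms a block
when its outermost pair is in strong LD and at least ``strong_frac`` of its
informative pairs are.  Inbred lines contribute their single homozygous
haplotype twice, matching diploid haplotype counting.

Detected blocks can then be segmented into fixed-length fragments of two or
three SNPs; a trailing fragment of one SNP is returned but is treated
downstream as a plain SNP, not a haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_qc import GenotypeMatrix

__all__ = [
    "PairLD",
    "HaplotypeBlock",
    "estimate_pair_ld",
    "classify_pair",
    "pair_class_matrix",
    "find_blocks",
    "segment_blocks",
    "write_blocks",
]

STRONG_LD = "strong_ld"
STRONG_RECOMB = "strong_recomb"
NONINFORMATIVE = "noninformative"

#: |D'| grid used for the likelihood-based confidence interval.
_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass
class PairLD:
    snp_i: int
    snp_j: int
    d_prime: float
    ci_low: float
    ci_high: float
    klass: str


@dataclass
class HaplotypeBlock:
    """A contiguous span of SNPs; ``snp_indices`` are indices into the map order."""

    chrom: str
    snp_indices: np.ndarray
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.int64)

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def _dprime_point(n: np.ndarray) -> tuple[float, float, float]:
    """|D'| point estimate plus allele frequencies from 2x2 haplotype counts."""
    tot = n.sum()
    pA = (n[1, 0] + n[1, 1]) / tot  # freq of allele "1" at first locus
    pB = (n[0, 1] + n[1, 1]) / tot
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus in haplotype counts")
    p11 = n[1, 1] / tot
    D = p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    return min(dprime, 1.0), pA, pB


def estimate_pair_ld(
    hapcounts: np.ndarray, snp_i: int = 0, snp_j: int = 1
) -> PairLD:
    """Point estimate and 90% CI of |D'| from 2x2 two-locus haplotype counts.

    ``hapcounts[a, b]`` counts haplotypes carrying allele ``a`` at the first
    locus and ``b`` at the second.  The CI is obtained by evaluating the
    multinomial likelihood on a 1001-point grid of |D'| in [0, 1] with allele
    frequencies held at their sample estimates, normalizing, and reading off
    the 5th and 95th cumulative percentiles.
    """
    n = np.asarray(hapcounts, dtype=float)
    if n.shape != (2, 2) or (n < 0).any() or n.sum() <= 0:
        raise ValueError("hapcounts must be a nonnegative 2x2 table with positive total")
    dprime, pA, pB = _dprime_point(n)
    # orient to positive D so the grid parameterizes |D'|
    p11 = n[1, 1] / n.sum()
    if p11 - pA * pB < 0:
        n = n[:, ::-1]
        pB = 1 - pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    q11 = pA * pB + _GRID * dmax
    q10 = pA - q11
    q01 = pB - q11
    q00 = 1 - pA - pB + q11
    probs = np.clip(np.stack([q00, q01, q10, q11]), 1e-12, None)
    counts = np.array([n[0, 0], n[0, 1], n[1, 0], n[1, 1]])
    loglik = counts @ np.log(probs)
    w = np.exp(loglik - logsumexp(loglik))
    cum = np.cumsum(w / w.sum())
    ci_low = float(_GRID[np.searchsorted(cum, 0.05)])
    ci_high = float(_GRID[np.searchsorted(cum, 0.95)])
    pair = PairLD(snp_i, snp_j, dprime, ci_low, ci_high, NONINFORMATIVE)
    pair.klass = classify_pair(pair)
    return pair


def classify_pair(
    p: PairLD,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
) -> str:
    """Gabriel classification from the |D'| CI bounds."""
    if p.ci_low >= strong_low and p.ci_high >= strong_high:
        return STRONG_LD
    if p.ci_high < recomb_high:
        return STRONG_RECOMB
    return NONINFORMATIVE


def _hap_alleles(dosage_col: np.ndarray) -> np.ndarray:
    """Haplotype allele per line from an inbred dosage column (0->0, 2->1)."""
    return dosage_col / 2.0


def pair_class_matrix(
    g: GenotypeMatrix,
    idx: np.ndarray,
    window_bp: int = 200_000,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    min_haplotypes: int = 10,
) -> np.ndarray:
    """Classification codes for all SNP pairs of ``idx`` within the window.

    Returns an upper-triangular integer matrix: 1 strong LD, 0 strong
    recombination, -1 noninformative, -2 never evaluated (outside window).
    Pairs use complete observations; inbred lines count as two identical
    haplotypes, and pairs with fewer than ``min_haplotypes`` haplotypes are
    noninformative.
    """
    m = len(idx)
    klass = np.full((m, m), -2, dtype=np.int8)
    hap = _hap_alleles(g.dosage[:, idx])
    pos = g.pos_bp[idx]
    for a in range(m - 1):
        for b in range(a + 1, m):
            if pos[b] - pos[a] > window_bp:
                break
            ok = ~np.isnan(hap[:, a]) & ~np.isnan(hap[:, b])
            if 2 * ok.sum() < min_haplotypes:
                klass[a, b] = -1
                continue
            ha = hap[ok, a].astype(int)
            hb = hap[ok, b].astype(int)
            counts = np.zeros((2, 2))
            np.add.at(counts, (ha, hb), 2.0)  # inbred: 2 identical haplotypes
            if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
                klass[a, b] = -1  # monomorphic in complete observations
                continue
            pair = estimate_pair_ld(counts, a, b)
            c = classify_pair(pair, strong_low, strong_high, recomb_high)
            klass[a, b] = {STRONG_LD: 1, STRONG_RECOMB: 0, NONINFORMATIVE: -1}[c]
    return klass


def _spans_from_classes(
    klass: np.ndarray,
    pos: np.ndarray,
    window_bp: int,
    strong_frac: float,
    min_informative: int,
) -> list[tuple[int, int]]:
    """Candidate (a, b) spans passing the outermost-pair and fraction rules."""
    m = klass.shape[0]
    spans = []
    for a in range(m - 1):
        for b in range(a + 1, m):
            if pos[b] - pos[a] > window_bp:
                break
            if klass[a, b] != 1:
                continue
            sub = klass[a : b + 1, a : b + 1]
            n_strong = int((sub == 1).sum())
            n_inf = n_strong + int((sub == 0).sum())
            if n_inf >= min_informative and n_strong >= strong_frac * n_inf:
                spans.append((a, b))
    return spans


def find_blocks(
    g: GenotypeMatrix,
    window_bp: int = 200_000,
    strong_frac: float = 0.95,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    min_informative: int = 1,
    min_haplotypes: int = 10,
) -> list[HaplotypeBlock]:
    """Detect haplotype blocks chromosome by chromosome.

    Candidate spans (outermost pair strong, >= ``strong_frac`` of informative
    pairs strong) are sorted by bp length descending with ties broken by
    leftmost start, then accepted greedily when not overlapping an accepted
    block.
    """
    blocks: list[HaplotypeBlock] = []
    for c in pd.unique(pd.Series(g.chrom.astype(str))):
        idx = np.flatnonzero(g.chrom.astype(str) == c)
        if len(idx) < 2:
            continue
        pos = g.pos_bp[idx]
        klass = pair_class_matrix(
            g, idx, window_bp, strong_low, strong_high, recomb_high, min_haplotypes
        )
        spans = _spans_from_classes(klass, pos, window_bp, strong_frac, min_informative)
        spans.sort(key=lambda ab: (-(pos[ab[1]] - pos[ab[0]]), ab[0]))
        taken = np.zeros(len(idx), dtype=bool)
        for a, b in spans:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            blocks.append(
                HaplotypeBlock(
                    chrom=str(c),
                    snp_indices=idx[a : b + 1],
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                )
            )
    blocks.sort(key=lambda bl: (str(bl.chrom), bl.start_bp))
    return blocks


def segment_blocks(
    blocks: list[HaplotypeBlock], k: int, g: GenotypeMatrix | None = None
) -> list[HaplotypeBlock]:
    """Split blocks left-to-right into fragments of exactly ``k`` SNPs.

    A trailing remainder of fewer than ``k`` SNPs becomes its own fragment;
    a 1-SNP fragment is subsequently treated as a plain SNP by the feature
    builder rather than as a haplotype.  When ``g`` is given, fragment spans
    are taken from its map; otherwise the parent block's span is inherited.
    """
    if k not in (2, 3):
        raise ValueError("fragment length k must be 2 or 3")
    frags: list[HaplotypeBlock] = []
    for bl in blocks:
        for s in range(0, bl.n_snps, k):
            sub = bl.snp_indices[s : s + k]
            if g is not None:
                start, end = int(g.pos_bp[sub[0]]), int(g.pos_bp[sub[-1]])
            else:
                start, end = bl.start_bp, bl.end_bp
            frags.append(
                HaplotypeBlock(
                    chrom=bl.chrom, snp_indices=sub, start_bp=start, end_bp=end
                )
            )
    return frags


def write_blocks(
    blocks: list[HaplotypeBlock], g: GenotypeMatrix, path: str | Path
) -> None:
    """Write a tabular .blocks-style file (one row per block)."""
    rows = []
    for bl in blocks:
        rows.append(
            {
                "chrom": bl.chrom,
                "start_bp": bl.start_bp,
                "end_bp": bl.end_bp,
                "span_kb": bl.span_bp / 1000.0,
                "n_snps": bl.n_snps,
                "snp_ids": ";".join(g.snp_ids[i] for i in bl.snp_indices),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
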