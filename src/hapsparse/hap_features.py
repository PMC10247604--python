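"""Haplotype-allele dosage coding and variant-set assembly.

Within each block (or fixed-length fragment) every distinct observed
haplotype becomes an allele column; an inbred line carries two copies of its
single haplotype, so dosages are {0, 2}, or 0 everywhere when a missing call
makes the line's haplotype unresolvable.  Rare alleles are filtered with the
same strict-inequality 0.05 threshold used for SNP MAF, and a block that
loses all its informative alleles is dropped with its SNPs rerouted to the
plain-SNP set.

A :class:`VariantSet` is what the kinship module consumes: for the marker
coding it is the QC-passed SNPs; for haplotype codings it is the SNPs not in
any used block plus the haplotype-allele columns (the paper's H-matrix
input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, mean_impute
from .ld_blocks import HaplotypeBlock

__all__ = [
    "HaplotypeAlleleMatrix",
    "VariantSet",
    "enumerate_haplotypes",
    "filter_rare_alleles",
    "build_variant_set",
    "CODINGS",
]

CODINGS = ("marker", "hap_complete", "hap_2snp", "hap_3snp")


@dataclass
class HaplotypeAlleleMatrix:
    """Line x haplotype-allele copy counts.

    ``allele_ids`` are namespaced ``"<block>:<haplotype string>"`` where the
    block key carries chromosome, first-SNP index and fragment index so 2-
    and 3-SNP codings can coexist.  ``allele_freq`` is computed over lines
    whose haplotype in that block is resolved (no missing member call).
    """

    line_ids: list[str]
    allele_ids: list[str]
    dosage: np.ndarray
    allele_freq: np.ndarray
    allele_block: list[str]
    allele_string: list[str]
    blocks: dict[str, HaplotypeBlock] = field(default_factory=dict)
    unresolved: np.ndarray | None = None  # lines x blocks flag

    @property
    def block_snp_indices(self) -> np.ndarray:
        """Indices of all SNPs that belong to a used block."""
        if not self.blocks:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate([b.snp_indices for b in self.blocks.values()]))

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        pd.DataFrame(self.dosage, index=self.line_ids, columns=self.allele_ids).to_csv(
            path
        )
        if sidecar is not None:
            pd.DataFrame(
                {
                    "allele_id": self.allele_ids,
                    "block": self.allele_block,
                    "haplotype": self.allele_string,
                    "freq": self.allele_freq,
                }
            ).to_csv(sidecar, sep="\t", index=False)


@dataclass
class VariantSet:
    """Dosage columns feeding the relationship matrix."""

    coding: str
    line_ids: list[str]
    column_ids: list[str]
    matrix: np.ndarray

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def _block_key(bl: HaplotypeBlock, frag_index: int) -> str:
    return f"{bl.chrom}:{bl.snp_indices[0]}-{bl.snp_indices[-1]}#f{frag_index}"


def enumerate_haplotypes(
    g: GenotypeMatrix, blocks: list[HaplotypeBlock]
) -> HaplotypeAlleleMatrix:
    """Count copies of each distinct haplotype per block.

    Blocks of a single SNP (trailing segmentation remainders) are skipped so
    their SNP stays in the plain-SNP set.  A line with any missing call
    inside a block gets dosage 0 for all of that block's alleles and is
    excluded from the allele-frequency denominator.
    """
    n = g.n_lines
    cols: list[np.ndarray] = []
    allele_ids: list[str] = []
    allele_block: list[str] = []
    allele_string: list[str] = []
    freqs: list[float] = []
    used: dict[str, HaplotypeBlock] = {}
    unresolved_cols: list[np.ndarray] = []
    for fi, bl in enumerate(blocks):
        if bl.n_snps < 2:
            continue
        if (bl.snp_indices < 0).any() or (bl.snp_indices >= g.n_snps).any():
            raise ValueError(f"block {bl.chrom}:{bl.start_bp} references absent SNPs")
        key = _block_key(bl, fi)
        sub = g.dosage[:, bl.snp_indices]
        miss = np.isnan(sub).any(axis=1)
        # inbred haplotype string from half-dosages
        strings = np.array(
            ["".join(str(int(v // 2)) for v in row) for row in np.nan_to_num(sub)],
            dtype=object,
        )
        strings[miss] = None
        n_res = int((~miss).sum())
        for hstr in sorted({s for s in strings if s is not None}):
            carrier = (strings == hstr) & ~miss
            col = np.where(carrier, 2.0, 0.0)
            cols.append(col)
            allele_ids.append(f"{key}:{hstr}")
            allele_block.append(key)
            allele_string.append(hstr)
            freqs.append(carrier.sum() / n_res if n_res else 0.0)
        used[key] = bl
        unresolved_cols.append(miss)
    dosage = np.column_stack(cols) if cols else np.empty((n, 0))
    return HaplotypeAlleleMatrix(
        line_ids=list(g.line_ids),
        allele_ids=allele_ids,
        dosage=dosage,
        allele_freq=np.asarray(freqs, dtype=float),
        allele_block=allele_block,
        allele_string=allele_string,
        blocks=used,
        unresolved=np.column_stack(unresolved_cols) if unresolved_cols else None,
    )


def filter_rare_alleles(
    h: HaplotypeAlleleMatrix, freq_min: float = 0.05
) -> HaplotypeAlleleMatrix:
    """Drop allele columns with frequency < ``freq_min`` or without variation.

    A monomorphic block (single allele at frequency 1) carries no contrast
    and is dropped; blocks losing every allele are removed from the used set
    so :func:`build_variant_set` reroutes their SNPs to the plain-SNP set.
    """
    keep = (h.allele_freq >= freq_min) & (h.allele_freq < 1.0 - 1e-12)
    kept_blocks = {h.allele_block[i] for i in np.flatnonzero(keep)}
    blocks = {k: v for k, v in h.blocks.items() if k in kept_blocks}
    idx = np.flatnonzero(keep)
    return HaplotypeAlleleMatrix(
        line_ids=list(h.line_ids),
        allele_ids=[h.allele_ids[i] for i in idx],
        dosage=h.dosage[:, idx],
        allele_freq=h.allele_freq[idx],
        allele_block=[h.allele_block[i] for i in idx],
        allele_string=[h.allele_string[i] for i in idx],
        blocks=blocks,
        unresolved=None,
    )


def build_variant_set(
    g: GenotypeMatrix, h: HaplotypeAlleleMatrix | None, coding: str
) -> VariantSet:
    """Assemble the dosage columns for a coding.

    ``marker``: all QC-passed SNPs, mean-imputed.  Haplotype codings:
    mean-imputed SNPs outside every used block, concatenated with the
    haplotype-allele columns.
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    if coding == "marker":
        return VariantSet(
            coding=coding,
            line_ids=list(g.line_ids),
            column_ids=list(g.snp_ids),
            matrix=mean_impute(g),
        )
    if h is None:
        raise ValueError(f"coding {coding!r} requires a HaplotypeAlleleMatrix")
    if list(h.line_ids) != list(g.line_ids):
        raise ValueError("line ids of genotypes and haplotype alleles differ")
    in_block = np.zeros(g.n_snps, dtype=bool)
    in_block[h.block_snp_indices] = True
    out_idx = np.flatnonzero(~in_block)
    snp_part = mean_impute(g.subset_snps(out_idx)) if len(out_idx) else np.empty(
        (g.n_lines, 0)
    )
    matrix = np.concatenate([snp_part, h.dosage], axis=1)
    column_ids = [g.snp_ids[i] for i in out_idx] + list(h.allele_ids)
    return VariantSet(
        coding=coding, line_ids=list(g.line_ids), column_ids=column_ids, matrix=matrix
    )
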