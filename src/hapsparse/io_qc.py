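"""Genotype input, quality control and mean imputation.

Genotypes are biallelic SNP dosages on inbred (or phased homozygous) lines,
coded as copies of the VCF ALT allele: 0, 1 (heterozygous), 2, or missing
(NaN).  The processing order used throughout the package is

    read -> het_to_missing -> qc_filter -> (blocks / features) -> mean_impute

Heterozygous calls are set to missing before any frequency is computed, so
minor-allele frequency and missing rate are always defined over homozygous
calls only.  Removal rules are strict inequalities: a SNP is dropped when
MAF < ``maf_min`` or missing rate > ``miss_max``; boundary values are kept.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "read_genotypes",
    "write_vcf",
    "write_dosage_csv",
    "het_to_missing",
    "qc_filter",
    "mean_impute",
]

MISSING_CODE = "NA"


@dataclass
class GenotypeMatrix:
    """Lines x SNPs dosage matrix with a physical marker map.

    ``dosage`` holds copies of the alternative allele in {0, 1, 2} with NaN
    for missing calls.  The map (``chrom``, ``pos_bp``) is sorted by
    chromosome then position; positions are 1-based and strictly increasing
    within a chromosome.
    """

    line_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        for c in np.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on chromosome {c}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            dosage=self.dosage[:, idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.line_ids, columns=self.snp_ids)


@dataclass
class QCReport:
    """Per-SNP QC bookkeeping.  A SNP failing both rules is counted under MAF."""

    n_snps_in: int
    n_removed_maf: int
    n_removed_missing: int
    n_snps_out: int
    maf: np.ndarray = field(repr=False)
    miss_rate: np.ndarray = field(repr=False)
    snp_ids: list[str] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if self.n_snps_out != self.n_snps_in - self.n_removed_maf - self.n_removed_missing:
            raise ValueError("QCReport counts are inconsistent")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"snp_id": self.snp_ids, "maf": self.maf, "miss_rate": self.miss_rate}
        )
        with open(path, "w") as fh:
            fh.write(
                f"# n_snps_in={self.n_snps_in}\tn_removed_maf={self.n_removed_maf}\t"
                f"n_removed_missing={self.n_removed_missing}\tn_snps_out={self.n_snps_out}\n"
            )
            df.to_csv(fh, sep="\t", index=False)


def _sort_by_map(line_ids, snp_ids, chrom, pos_bp, dosage) -> GenotypeMatrix:
    chrom = np.asarray(chrom, dtype=object)
    pos_bp = np.asarray(pos_bp, dtype=np.int64)
    order = np.lexsort((pos_bp, chrom.astype(str)))
    return GenotypeMatrix(
        line_ids=list(line_ids),
        snp_ids=[snp_ids[i] for i in order],
        chrom=chrom[order],
        pos_bp=pos_bp[order],
        dosage=np.asarray(dosage, dtype=float)[:, order],
    )


def _read_csv(path: str | Path) -> GenotypeMatrix:
    """Dosage CSV dialect: header row of SNP ids, first column line id, NA missing.

    The marker map travels in two reserved rows named ``#chrom`` / ``#pos``
    directly under the header; if absent, all SNPs fall on one chromosome at
    consecutive positions.
    """
    df = pd.read_csv(path, index_col=0, na_values=[MISSING_CODE])
    chrom = None
    pos = None
    if "#chrom" in df.index:
        chrom = df.loc["#chrom"].to_numpy(dtype=object)
        df = df.drop(index="#chrom")
    if "#pos" in df.index:
        pos = df.loc["#pos"].to_numpy(dtype=np.int64)
        df = df.drop(index="#pos")
    snp_ids = [str(c) for c in df.columns]
    if chrom is None:
        chrom = np.array(["1"] * len(snp_ids), dtype=object)
    if pos is None:
        pos = np.arange(1, len(snp_ids) + 1, dtype=np.int64)
    dosage = df.to_numpy(dtype=float)
    bad = ~(np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid dosage {dosage[i, j]} for line {df.index[i]}, SNP {snp_ids[j]}"
        )
    return _sort_by_map([str(i) for i in df.index], snp_ids, chrom, pos, dosage)


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    cols: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    lut = np.array([0.0, 1.0, np.nan, 2.0])
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} ({rec.ID}) is not biallelic "
                f"(ALT={rec.ALT})"
            )
        sid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        snp_ids.append(sid)
        chrom.append(str(rec.CHROM))
        pos.append(int(rec.POS))
        cols.append(lut[rec.gt_types])
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicate SNP ids in VCF")
    dosage = np.column_stack(cols) if cols else np.empty((len(line_ids), 0))
    return _sort_by_map(line_ids, snp_ids, chrom, pos, dosage)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF 4.x or the dosage-CSV dialect.

    Parameters
    ----------
    path:
        Input file.  ``format`` may be ``"vcf"`` or ``"csv"``; if None it is
        inferred from the suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "csv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 with GT calls (inbreds: 0/0, 0/1, 1/1)."""
    gtmap = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(pd.Series(g.chrom.astype(str))):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.line_ids)
            + "\n"
        )
        for m in range(g.n_snps):
            calls = "\t".join(
                gtmap.get(g.dosage[i, m], "./.") for i in range(g.n_lines)
            )
            fh.write(
                f"{g.chrom[m]}\t{g.pos_bp[m]}\t{g.snp_ids[m]}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_dosage_csv(g: GenotypeMatrix, path: str | Path) -> None:
    df = g.to_dataframe()
    map_rows = pd.DataFrame(
        [g.chrom, g.pos_bp], index=["#chrom", "#pos"], columns=df.columns
    )
    pd.concat([map_rows, df]).to_csv(path, na_rep=MISSING_CODE)


def het_to_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Set every heterozygous call (dosage 1) to missing; other entries unchanged."""
    dosage = g.dosage.copy()
    dosage[dosage == 1.0] = np.nan
    return dataclasses.replace(g, dosage=dosage)


def _maf_miss(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import warnings

    miss = np.isnan(dosage)
    miss_rate = miss.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        freq = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return maf, miss_rate


def qc_filter(
    g: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.1
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with MAF < ``maf_min`` or missing rate > ``miss_max``.

    Boundary values pass.  MAF is computed over non-missing calls, so
    :func:`het_to_missing` must have been applied first when raw data can
    contain heterozygotes.  An all-missing SNP (MAF undefined) is removed
    under the missing-rate rule.
    """
    maf, miss_rate = _maf_miss(g.dosage)
    fail_maf = np.where(np.isnan(maf), False, maf < maf_min)  # all-missing -> miss rule
    fail_miss = miss_rate > miss_max
    removed_maf = int(fail_maf.sum())
    removed_miss = int((fail_miss & ~fail_maf).sum())
    keep = ~(fail_maf | fail_miss)
    report = QCReport(
        n_snps_in=g.n_snps,
        n_removed_maf=removed_maf,
        n_removed_missing=removed_miss,
        n_snps_out=int(keep.sum()),
        maf=maf,
        miss_rate=miss_rate,
        snp_ids=list(g.snp_ids),
    )
    return g.subset_snps(np.flatnonzero(keep)), report


def mean_impute(g: GenotypeMatrix) -> np.ndarray:
    """Replace missing dosages by the SNP's mean over fingerprinted lines.

    Returns a dense float matrix; observed cells are untouched, so per-SNP
    allele frequencies are conserved exactly.
    """
    dosage = g.dosage.copy()
    miss = np.isnan(dosage)
    if miss.all(axis=0).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValueError(
            f"SNP {g.snp_ids[j]} has no non-missing calls; run qc_filter first"
        )
    col_mean = np.nanmean(dosage, axis=0)
    dosage[miss] = np.broadcast_to(col_mean, dosage.shape)[miss]
    return dosage
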