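"""Genomic relationship matrices (G from markers, H from SNPs + haplotypes).

The entries are the centered, frequency-scaled cross-products averaged over
the p variant columns:

    K_ii' = (1/p) * sum_m (x_im - 2 d_m)(x_i'm - 2 d_m) / (2 d_m (1 - d_m))

where x_im counts copies of the alternative allele (or haplotype) and d_m is
its frequency.  The same formula serves marker and haplotype columns; which
one it is only changes which VariantSet is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hap_features import VariantSet

__all__ = ["KinshipMatrix", "compute_K", "read_kinship"]


@dataclass
class KinshipMatrix:
    line_ids: list[str]
    values: np.ndarray
    coding: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match line ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(
            path
        )


def compute_K(v: VariantSet) -> KinshipMatrix:
    """VanRaden-style relationship matrix from a variant set.

    Requires complete dosages (impute upstream) and polymorphic columns:
    a column with frequency 0 or 1 has no defined scaling and raises.
    """
    X = np.asarray(v.matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("variant set contains missing values; impute first")
    delta = X.mean(axis=0) / 2.0
    bad = (delta <= 0.0) | (delta >= 1.0)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"column {v.column_ids[j]} has allele frequency {delta[j]:.3f}; "
            "filter monomorphic columns first"
        )
    W = X - 2.0 * delta
    scale = 2.0 * delta * (1.0 - delta)
    K = (W / scale) @ W.T / v.p
    K = (K + K.T) / 2.0  # enforce exact symmetry
    return KinshipMatrix(line_ids=list(v.line_ids), values=K, coding=v.coding)


def read_kinship(path: str | Path, coding: str = "unknown") -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(
        line_ids=[str(i) for i in df.index], values=df.to_numpy(float), coding=coding
    )
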