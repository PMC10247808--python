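"""Transforms and filters applied ahead of discovery and estimation.

Discovery (the protein-wide association scan) runs on rank-based inverse
normal transformed values; genotype-probability estimation runs on
natural-log values.  SNP panels are restricted to minor allele frequency
strictly greater than a threshold (default 5%).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, ProteomeMatrix

__all__ = ["log_transform", "rank_int", "maf_filter"]

logger = logging.getLogger(__name__)


def log_transform(p: ProteomeMatrix) -> ProteomeMatrix:
    """Natural log, elementwise; requires raw, strictly positive values."""
    if p.transform_state != "raw":
        raise ValueError(f"log_transform requires raw values, got {p.transform_state!r}")
    arr = p.values.to_numpy(dtype=float)
    bad = ~(np.isfinite(arr) & (arr > 0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive abundance at subject {p.values.index[i]!r}, "
            f"protein {p.values.columns[j]!r}: {arr[i, j]!r}"
        )
    out = pd.DataFrame(np.log(arr), index=p.values.index, columns=p.values.columns)
    return ProteomeMatrix(out, transform_state="log",
                          genotype_adjusted=p.genotype_adjusted)


def rank_int(p: ProteomeMatrix, offset: float = 3.0 / 8.0) -> ProteomeMatrix:
    """Rank-based inverse normal transform, per protein column.

    Each value maps to ``Phi^{-1}((rank - c) / (n - 2c + 1))`` with the
    Blom offset ``c = 3/8`` by default; ties receive the average rank.
    Columns with fewer than 3 distinct values are transformed anyway with
    a logged warning (their output is nearly degenerate).
    """
    if p.transform_state != "raw":
        raise ValueError(f"rank_int requires raw values, got {p.transform_state!r}")
    arr = p.values.to_numpy(dtype=float)
    n = arr.shape[0]
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if len(np.unique(col)) < 3:
            logger.warning(
                "protein %r has < 3 distinct values; rank-INT output degenerate",
                p.values.columns[j],
            )
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    df = pd.DataFrame(out, index=p.values.index, columns=p.values.columns)
    return ProteomeMatrix(df, transform_state="rank_int",
                          genotype_adjusted=p.genotype_adjusted)


def maf_filter(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs whose sample MAF is strictly greater than ``threshold``.

    MAF is ``min(p, 1-p)`` with ``p = mean(dosage)/2`` over non-missing
    calls.  Removing every SNP is an error (an empty panel is never what
    the caller wants).
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    keep = g.maf() > threshold
    if not keep.any():
        raise ValueError(
            f"MAF filter at threshold {threshold} removed every SNP"
        )
    dosages = g.dosages.loc[:, keep[keep].index]
    alleles = None if g.alleles is None else g.alleles.loc[dosages.columns]
    return GenotypeMatrix(dosages.copy(), alleles)
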