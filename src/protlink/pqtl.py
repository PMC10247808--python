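"""pQTL discovery: protein-wide association scan and panel reduction.

Every (SNP, protein) pair is tested with simple ordinary least squares of
the (rank-inverse-normal transformed) protein level on minor-allele
dosage, additive model, no covariates.  Benjamini-Hochberg FDR marks
significant associations; the significant set is then reduced to a 1:1
protein <-> SNP matching: per protein keep the smallest-p SNP, then per
SNP keep the smallest-p protein, resolving cross-cohort conflicts by
smallest p.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix, ProteomeMatrix
from .preprocess import maf_filter, rank_int

__all__ = [
    "PqtlTable",
    "pwas",
    "bh_fdr",
    "reduce_pairs",
    "select_top_k",
    "discover",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["protein_id", "snp_id", "beta", "se", "t", "p", "n", "cohort"]


@dataclasses.dataclass
class PqtlTable:
    """Table of protein-SNP association records.

    ``records`` has columns protein_id, snp_id, beta, se, t, p, n,
    cohort and (after FDR) q.  A *reduced* table is a perfect matching:
    every protein and every SNP appears exactly once.
    """

    records: pd.DataFrame
    reduced: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in ("protein_id", "snp_id", "p") if c not in self.records]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if self.reduced:
            if self.records["protein_id"].duplicated().any():
                raise ValueError("reduced table repeats a protein")
            if self.records["snp_id"].duplicated().any():
                raise ValueError("reduced table repeats a SNP")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.records["protein_id"], self.records["snp_id"]))

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], cohort: str = "truth"
    ) -> "PqtlTable":
        """Build a reduced table straight from known (protein, SNP) pairs.

        Useful when the panel is known by construction (simulated truth)
        rather than discovered; the statistics columns are filled with
        placeholders (p = 0).
        """
        rows = [
            {
                "protein_id": prot,
                "snp_id": snp,
                "beta": np.nan,
                "se": np.nan,
                "t": np.nan,
                "p": 0.0,
                "n": 0,
                "cohort": cohort,
                "q": 0.0,
            }
            for prot, snp in pairs
        ]
        return cls(pd.DataFrame(rows, columns=RECORD_COLUMNS + ["q"]), reduced=True)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, reduced: bool = False) -> "PqtlTable":
        return cls(pd.read_csv(path, sep="\t"), reduced=reduced)


def pwas(
    g: GenotypeMatrix,
    p: ProteomeMatrix,
    cohort: str = "cohort",
    min_n: int = 3,
) -> pd.DataFrame:
    """All-pairs OLS scan of protein level on dosage (additive model).

    For every (SNP, protein) pair, fits intercept + slope by least
    squares and reports the two-sided t test on the slope.  Subjects with
    a missing dosage are dropped pairwise; SNPs left with zero dosage
    variance are skipped with a log entry.
    """
    if p.transform_state != "rank_int":
        raise ValueError(
            "discovery expects rank-inverse-normal values; call rank_int first"
        )
    shared = g.subjects.intersection(p.subjects)
    if len(shared) < min_n:
        raise ValueError(f"need >= {min_n} shared subjects, have {len(shared)}")
    X = g.dosages.loc[shared].to_numpy(dtype=float)
    Y = p.values.loc[shared].to_numpy(dtype=float)
    snp_ids = list(g.snp_ids)
    prot_ids = list(p.proteins)
    frames = []
    for j, snp in enumerate(snp_ids):
        x = X[:, j]
        mask = ~np.isnan(x)
        n = int(mask.sum())
        if n < min_n:
            logger.info("SNP %r skipped: only %d non-missing subjects", snp, n)
            continue
        xm = x[mask]
        ym = Y[mask]
        xc = xm - xm.mean()
        sxx = float(xc @ xc)
        if sxx == 0.0:
            logger.info("SNP %r skipped: zero dosage variance", snp)
            continue
        yc = ym - ym.mean(axis=0)
        beta = (xc @ yc) / sxx
        rss = (yc * yc).sum(axis=0) - beta**2 * sxx
        dof = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / (dof * sxx))
            t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
        pv = 2.0 * stats.t.sf(np.abs(t), dof)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": prot_ids,
                    "snp_id": snp,
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": pv,
                    "n": n,
                    "cohort": cohort,
                }
            )
        )
    if not frames:
        raise ValueError("no testable SNPs in the scan")
    return pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pv = np.asarray(pvalues, dtype=float)
    if pv.size == 0:
        return pv.copy()
    if np.isnan(pv).any() or (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pv, method="fdr_bh")[1]


def _deterministic_sort(records: pd.DataFrame) -> pd.DataFrame:
    """Smallest p first; ties broken by larger |t|, then lexicographic ids."""
    key = records.assign(_negabs_t=-records["t"].abs().fillna(0.0))
    key = key.sort_values(
        ["p", "_negabs_t", "protein_id", "snp_id"], kind="mergesort"
    )
    return key.drop(columns="_negabs_t")


def reduce_pairs(
    tables: PqtlTable | Sequence[PqtlTable],
    alpha: float = 0.05,
) -> PqtlTable:
    """Merge cohort tables and reduce to the unique 1:1 pQTL panel.

    Records must already carry q-values; only q < ``alpha`` survive.
    Per protein, the single smallest-p record is kept (conflicts across
    cohorts resolved by smallest p); per remaining SNP, again the single
    smallest-p record.  The result is a perfect protein <-> SNP matching.
    """
    if isinstance(tables, PqtlTable):
        tables = [tables]
    if not tables:
        raise ValueError("no pQTL tables given")
    merged = pd.concat([t.records for t in tables], ignore_index=True)
    if "q" not in merged:
        raise ValueError("records must carry BH q-values before reduction")
    merged = merged[merged["q"] < alpha]
    if merged.empty:
        raise ValueError("no FDR-significant records to reduce")
    ordered = _deterministic_sort(merged)
    per_protein = ordered.drop_duplicates("protein_id", keep="first")
    per_snp = _deterministic_sort(per_protein).drop_duplicates("snp_id", keep="first")
    out = _deterministic_sort(per_snp).reset_index(drop=True)
    return PqtlTable(out, reduced=True)


def select_top_k(t: PqtlTable, k: int) -> PqtlTable:
    """Keep the k smallest-p pairs of a reduced table (deterministic ties)."""
    if not t.reduced:
        raise ValueError("select_top_k expects a reduced table")
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = t.records.sort_values(
        ["p", "protein_id", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    if k >= len(ordered):
        if k > len(ordered):
            warnings.warn(
                f"requested top {k} pairs but only {len(ordered)} available",
                stacklevel=2,
            )
        return PqtlTable(ordered, reduced=True)
    return PqtlTable(ordered.iloc[:k].reset_index(drop=True), reduced=True)


def discover(
    g: GenotypeMatrix,
    p_raw: ProteomeMatrix,
    cohort: str = "cohort",
    maf: float = 0.05,
    fdr: float = 0.05,
) -> PqtlTable:
    """Full single-cohort discovery: MAF filter, rank-INT, scan, BH FDR.

    Returns the (unreduced) table of FDR-significant associations; the
    FDR correction is applied within this cohort's full scan.
    """
    g_f = maf_filter(g, maf)
    records = pwas(g_f, rank_int(p_raw), cohort=cohort)
    records = records.assign(q=bh_fdr(records["p"].to_numpy()))
    sig = records[records["q"] < fdr].reset_index(drop=True)
    return PqtlTable(sig, reduced=False)
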