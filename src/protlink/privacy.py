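"""Genotype-mean obfuscation of proteomes and its exact reversal.

A proteome that carries pQTL signal can be linked to a genome; removing
each panel protein's genotype-class mean erases that signal.  On the log
scale, for a subject with dosage g at the paired SNP:

    x' = x - mu_g + mu_overall,

where mu_g and the count-weighted grand mean mu_overall come from a
reference model (the linking model by default, or self-estimated from
the data being published).  The per-class corrections are returned so a
holder of the genotypes can restore the original values exactly.  A
module-level t-test utility checks that non-genetic biomarker-phenotype
associations survive the adjustment.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, ProteomeMatrix
from .linker import NBModel, fit_nb
from .pqtl import PqtlTable

__all__ = [
    "CorrectionTable",
    "genotype_adjust",
    "genotype_deadjust",
    "association_ttest",
    "compare_associations",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CorrectionTable:
    """Per (protein, SNP, genotype class) additive log-scale correction.

    ``correction`` is what was subtracted from the published value, i.e.
    class mean minus grand mean when recentering.  Only classes observed
    in the reference (count > 0) have entries.
    """

    corrections: pd.DataFrame  # protein_id, snp_id, genotype, correction
    recenter: bool = True

    def __post_init__(self) -> None:
        need = {"protein_id", "snp_id", "genotype", "correction"}
        missing = need - set(self.corrections.columns)
        if missing:
            raise ValueError(f"corrections missing columns {sorted(missing)}")

    def to_tsv(self, path) -> None:
        self.corrections.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CorrectionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def _lookup(self) -> dict[tuple[str, str], np.ndarray]:
        out: dict[tuple[str, str], np.ndarray] = {}
        for (prot, snp), grp in self.corrections.groupby(
            ["protein_id", "snp_id"], sort=False
        ):
            arr = np.full(3, np.nan)
            arr[grp["genotype"].to_numpy(dtype=int)] = grp["correction"].to_numpy()
            out[(prot, snp)] = arr
        return out


def _reference_model(
    p: ProteomeMatrix,
    g: GenotypeMatrix,
    panel: PqtlTable | None,
    reference: NBModel | None,
) -> NBModel:
    if reference is not None:
        return reference
    if panel is None:
        raise ValueError("either a reference model or a pQTL panel is required")
    return fit_nb(p, g, panel)


def genotype_adjust(
    p: ProteomeMatrix,
    g: GenotypeMatrix,
    panel: PqtlTable | None = None,
    reference: NBModel | None = None,
    recenter: bool = True,
) -> tuple[ProteomeMatrix, CorrectionTable]:
    """Subtract genotype-class means from panel proteins (log scale).

    With ``recenter`` (default) the grand mean is added back so adjusted
    values stay on the original scale; otherwise the bare class mean is
    subtracted.  Non-panel proteins are untouched.  Subjects with a
    missing dosage at a pair are left unadjusted for that protein (with
    a log entry).  Returns the adjusted matrix (flagged
    ``genotype_adjusted``) and the corrections needed for reversal.
    """
    if p.transform_state != "log":
        raise ValueError("genotype adjustment operates on log values")
    if p.genotype_adjusted:
        raise ValueError("proteome is already genotype-adjusted")
    m = _reference_model(p, g, panel, reference)
    for prot in m.proteins:
        if prot not in p.proteins:
            raise ValueError(f"panel protein {prot!r} absent from proteome matrix")
    for snp in m.snps:
        if snp not in g.snp_ids:
            raise ValueError(f"panel SNP {snp!r} absent from genotype matrix")

    mu = m.mu
    counts = m.counts
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (counts * mu).sum(axis=1) / totals
    grand = np.where(totals > 0, grand, 0.0)
    corr = mu - (grand[:, None] if recenter else 0.0)

    values = p.values.copy()
    rows = []
    for i, (prot, snp) in enumerate(zip(m.proteins, m.snps)):
        dose = g.dosages[snp].reindex(values.index).to_numpy(dtype=float)
        adj = np.zeros(len(values))
        observed = ~np.isnan(dose)
        if (~observed).any():
            logger.info(
                "%d subjects missing dosage at %s; protein %s left unadjusted",
                int((~observed).sum()), snp, prot,
            )
        for cls in (0, 1, 2):
            if counts[i, cls] > 0:
                adj[observed & (dose == cls)] = corr[i, cls]
            elif (observed & (dose == cls)).any():
                raise ValueError(
                    f"dosage class {cls} at pair ({prot}, {snp}) unseen in "
                    "reference; cannot adjust"
                )
        values[prot] = values[prot].to_numpy(dtype=float) - adj
        for cls in (0, 1, 2):
            if counts[i, cls] > 0:
                rows.append((prot, snp, cls, corr[i, cls]))
    table = CorrectionTable(
        pd.DataFrame(rows, columns=["protein_id", "snp_id", "genotype", "correction"]),
        recenter=recenter,
    )
    adjusted = ProteomeMatrix(values, transform_state="log", genotype_adjusted=True)
    return adjusted, table


def genotype_deadjust(
    p_adj: ProteomeMatrix,
    g: GenotypeMatrix,
    corrections: CorrectionTable,
) -> ProteomeMatrix:
    """Exact inverse of :func:`genotype_adjust` given the genotypes.

    Requires a matrix flagged ``genotype_adjusted`` (double reversal is
    rejected) and a correction entry for every observed dosage class.
    """
    if not p_adj.genotype_adjusted:
        raise ValueError("matrix is not genotype-adjusted; nothing to reverse")
    values = p_adj.values.copy()
    for (prot, snp), corr in corrections._lookup().items():
        if prot not in values.columns:
            raise ValueError(f"correction protein {prot!r} absent from matrix")
        if snp not in g.snp_ids:
            raise ValueError(f"correction SNP {snp!r} absent from genotype matrix")
        dose = g.dosages[snp].reindex(values.index).to_numpy(dtype=float)
        adj = np.zeros(len(values))
        for cls in (0, 1, 2):
            sel = dose == cls
            if not sel.any():
                continue
            if np.isnan(corr[cls]):
                raise ValueError(
                    f"missing correction entry for ({prot}, {snp}), class {cls}"
                )
            adj[sel] = corr[cls]
        values[prot] = values[prot].to_numpy(dtype=float) + adj
    return ProteomeMatrix(values, transform_state="log", genotype_adjusted=False)


def association_ttest(p: ProteomeMatrix, phenotype: pd.Series) -> pd.DataFrame:
    """Welch two-sample t-test of each protein against a binary phenotype.

    Returns a frame indexed by protein with columns ``t`` and ``p``.
    A protein constant in both groups gets t = 0, p = 1 with a warning.
    """
    if p.transform_state != "log":
        raise ValueError("association tests operate on log values")
    y = phenotype.reindex(p.subjects)
    if y.isna().any():
        raise ValueError("phenotype missing for some subjects")
    y = y.to_numpy(dtype=int)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both phenotype groups must be non-empty")
    arr = p.values.to_numpy(dtype=float)
    a, b = arr[y == 1], arr[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, pv = stats.ttest_ind(a, b, equal_var=False, axis=0)
    t = np.asarray(t, dtype=float)
    pv = np.asarray(pv, dtype=float)
    const = np.isnan(t)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant protein column(s); reporting p = 1",
            stacklevel=2,
        )
        t[const] = 0.0
        pv[const] = 1.0
    return pd.DataFrame({"t": t, "p": pv}, index=p.proteins)


def compare_associations(
    before: pd.DataFrame, after: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-protein change in association statistics across an adjustment.

    Reports the t-statistic delta, its relative magnitude, the p-value
    ratio, and whether significance status at ``alpha`` flipped.
    """
    if not before.index.equals(after.index):
        raise ValueError("before/after must cover the same proteins")
    delta = after["t"] - before["t"]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (delta.abs() / before["t"].abs()).replace(np.inf, np.nan)
        ratio = after["p"] / before["p"]
    sig_before = before["p"] < alpha
    sig_after = after["p"] < alpha
    return pd.DataFrame(
        {
            "t_before": before["t"],
            "t_after": after["t"],
            "delta_t": delta,
            "rel_delta_t": rel,
            "p_before": before["p"],
            "p_after": after["p"],
            "p_ratio": ratio,
            "sig_before": sig_before,
            "sig_after": sig_after,
            "status_changed": sig_before != sig_after,
        }
    )
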