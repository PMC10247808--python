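"""Core data containers: proteome and genotype matrices.

Both containers wrap a pandas DataFrame (subjects on rows) and validate
their invariants on construction.  Dosage codes the minor-allele count
(0/1/2) at a biallelic SNP; ``NaN`` marks a missing call.  Proteome
values are strictly positive relative-fluorescence-like abundances on
the raw scale; the ``transform_state`` marker tracks which transform
(natural log or rank-based inverse normal) has been applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

TRANSFORM_STATES = ("raw", "log", "rank_int")

__all__ = ["ProteomeMatrix", "GenotypeMatrix", "TRANSFORM_STATES"]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclasses.dataclass
class ProteomeMatrix:
    """Subjects x proteins abundance matrix with a transform marker.

    Parameters
    ----------
    values
        DataFrame indexed by subject id with one column per protein.
    transform_state
        One of ``"raw"``, ``"log"``, ``"rank_int"``.  Raw values must be
        strictly positive and finite.
    genotype_adjusted
        True once the privacy module has subtracted genotype-class
        means; guards against double adjustment / double reversal.
    """

    values: pd.DataFrame
    transform_state: str = "raw"
    genotype_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(
                f"transform_state must be one of {TRANSFORM_STATES}, "
                f"got {self.transform_state!r}"
            )
        _check_unique(self.values.index, "subject")
        _check_unique(self.values.columns, "protein")
        arr = self.values.to_numpy(dtype=float)
        if self.transform_state == "raw":
            bad = ~(np.isfinite(arr) & (arr > 0))
        else:
            bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "invalid abundance at subject "
                f"{self.values.index[i]!r}, protein {self.values.columns[j]!r}: "
                f"{arr[i, j]!r} (raw values must be strictly positive)"
            )

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def proteins(self) -> pd.Index:
        return self.values.columns

    @property
    def n_subjects(self) -> int:
        return len(self.values.index)

    def copy(self) -> "ProteomeMatrix":
        return ProteomeMatrix(
            self.values.copy(), self.transform_state, self.genotype_adjusted
        )


@dataclasses.dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix.

    ``dosages`` holds floats in {0, 1, 2} with NaN for missing calls.
    ``alleles`` is an optional per-SNP metadata frame (index = snp id,
    columns ``ref``/``alt``); the ALT allele is the counted (minor)
    allele.
    """

    dosages: pd.DataFrame
    alleles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "subject")
        _check_unique(self.dosages.columns, "SNP")
        self.dosages = self.dosages.astype(float)
        arr = self.dosages.to_numpy()
        ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage at subject {self.dosages.index[i]!r}, SNP "
                f"{self.dosages.columns[j]!r} is {arr[i, j]!r}; "
                "must be 0, 1, 2 or missing"
            )
        if self.alleles is not None and not self.dosages.columns.isin(
            self.alleles.index
        ).all():
            raise ValueError("alleles table does not cover every SNP")

    @property
    def subjects(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_subjects(self) -> int:
        return len(self.dosages.index)

    def maf(self) -> pd.Series:
        """Per-SNP sample minor allele frequency.

        Computed as ``min(p, 1 - p)`` with ``p = mean(dosage) / 2`` over
        non-missing entries, so a mis-polarized column still reports the
        frequency of its rarer allele.
        """
        p_hat = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(p_hat, 1.0 - p_hat).rename("maf")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            None if self.alleles is None else self.alleles.copy(),
        )
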