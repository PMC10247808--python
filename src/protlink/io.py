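"""Plain-text readers/writers for the tool's exchange formats.

Genotypes travel either as a dosage TSV (rows = subjects, columns = SNP
ids, entries 0/1/2 or empty for missing) or as a minimal VCF carrying
only GT fields, one sample column per subject.  Proteome matrices are
TSV with ``#``-prefixed header comments recording the transform state.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ProteomeMatrix

__all__ = [
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_proteome_tsv",
    "write_proteome_tsv",
]

_GT_FOR_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    g.dosages.to_csv(path, sep="\t", index_label="subject_id", na_rep="")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return GenotypeMatrix(df)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT-only) with one sample per subject.

    SNPs are placed on chromosome 1 at consecutive positions; the ALT
    allele is the counted minor allele.
    """
    alleles = g.alleles
    lines = [
        "##fileformat=VCFv4.2",
        "##source=protlink",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(map(str, g.subjects)),
    ]
    arr = g.dosages.to_numpy()
    for j, snp in enumerate(g.snp_ids):
        if alleles is not None and snp in alleles.index:
            ref, alt = alleles.loc[snp, "ref"], alleles.loc[snp, "alt"]
        else:
            ref, alt = "A", "C"
        gts = [
            "./." if np.isnan(d) else _GT_FOR_DOSAGE[int(d)] for d in arr[:, j]
        ]
        lines.append(
            f"1\t{j + 1}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (ALT-allele count per subject).

    Only biallelic records are accepted; a multiallelic record raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[list[float]] = []
    ref_alt: list[tuple[str, str]] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record {var.ID or var.POS} not supported"
            )
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        ref_alt.append((var.REF, var.ALT[0]))
        dos = []
        for gt in var.genotypes:
            a = gt[:-1]  # trailing element is phasing flag
            dos.append(np.nan if min(a) < 0 else float(sum(a)))
        rows.append(dos)
    dosages = pd.DataFrame(
        np.array(rows, dtype=float).T,
        index=pd.Index(subjects, name="subject_id"),
        columns=snp_ids,
    )
    alleles = pd.DataFrame(ref_alt, index=snp_ids, columns=["ref", "alt"])
    return GenotypeMatrix(dosages, alleles)


def write_proteome_tsv(p: ProteomeMatrix, path) -> None:
    header = (
        f"# transform_state={p.transform_state}\n"
        f"# genotype_adjusted={p.genotype_adjusted}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        p.values.to_csv(fh, sep="\t", index_label="subject_id")


def read_proteome_tsv(path) -> ProteomeMatrix:
    state, adjusted = "raw", False
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "transform_state":
                state = val.strip()
            elif key.strip() == "genotype_adjusted":
                adjusted = val.strip().lower() == "true"
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return ProteomeMatrix(df, transform_state=state, genotype_adjusted=adjusted)
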