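"""Synthetic cohort simulator.

Generates the statistical structure the linking method assumes: biallelic
genotypes in Hardy-Weinberg equilibrium with configurable (optionally
population-specific) minor allele frequencies, protein abundances that are
log-normal with an additive per-allele genotype effect on the log scale,
sibling families via Mendelian transmission, a genotype-independent binary
phenotype with log-scale protein shifts, and injected sample-handling
errors (reciprocal plasma swaps at a single visit, DNA mislabels).

Every operation is a pure function of its inputs and a seed.  Random
streams are derived from the master seed keyed by operation and by SNP or
protein id, so adding a SNP/protein to a config does not perturb draws for
the ones already present.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ProteomeMatrix

__all__ = [
    "SnpSpec",
    "EffectSpec",
    "SwapEvent",
    "SwapLedger",
    "simulate_genotypes",
    "simulate_proteome",
    "simulate_visits",
    "simulate_families",
    "inject_swaps",
    "simulate_phenotype",
    "random_panel",
]

# stream codes keeping independent operations on independent substreams
_GENO, _PROT, _FAM, _PHEN, _VISIT, _PANEL, _MISS = range(7)


def _key(s: str) -> int:
    return zlib.crc32(str(s).encode())


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))
    )


@dataclasses.dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP with a minor-allele frequency in (0, 0.5]."""

    snp_id: str
    maf: float
    population_mafs: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        mafs = {None: self.maf, **(self.population_mafs or {})}
        for pop, q in mafs.items():
            if not 0.0 < q <= 0.5:
                where = f" (population {pop!r})" if pop is not None else ""
                raise ValueError(
                    f"SNP {self.snp_id!r}{where}: MAF must be in (0, 0.5], got {q}"
                )

    def maf_for(self, population: str | None) -> float:
        if population is not None and self.population_mafs:
            return self.population_mafs.get(population, self.maf)
        return self.maf


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """Additive pQTL effect on one protein's log abundance.

    Log abundance is ``baseline_mu + beta * dosage + Normal(0, sigma)``;
    the simulator returns ``exp`` of that, i.e. a strictly positive
    log-normal abundance.
    """

    protein_id: str
    snp_id: str
    baseline_mu: float
    beta: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(
                f"effect for {self.protein_id!r}: sigma must be > 0, got {self.sigma}"
            )


@dataclasses.dataclass(frozen=True)
class SwapEvent:
    """One sample-handling error.

    ``plasma_swap``: the two subjects' proteome rows are exchanged at a
    single visit.  ``dna_mislabel``: the two subjects' genotype rows are
    exchanged (a chain-of-custody DNA tube swap, persistent across
    visits); ``visit`` is None.
    """

    kind: str
    subjects: tuple[str, str]
    visit: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("plasma_swap", "dna_mislabel"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if len(self.subjects) != 2 or self.subjects[0] == self.subjects[1]:
            raise ValueError("event needs two distinct subjects")
        if self.kind == "plasma_swap" and self.visit is None:
            raise ValueError("plasma_swap needs a visit label")


@dataclasses.dataclass
class SwapLedger:
    """Ground-truth record of injected sample-handling errors."""

    events: list[SwapEvent] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": e.kind,
                    "subject_a": e.subjects[0],
                    "subject_b": e.subjects[1],
                    "visit": e.visit or "",
                }
                for e in self.events
            ],
            columns=["kind", "subject_a", "subject_b", "visit"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SwapLedger":
        events = [
            SwapEvent(
                row["kind"],
                (row["subject_a"], row["subject_b"]),
                row["visit"] or None if isinstance(row["visit"], str) else None,
            )
            for _, row in df.iterrows()
        ]
        return cls(events)


def _subject_ids(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def simulate_genotypes(
    n_subjects: int,
    snps: Sequence[SnpSpec],
    population: str | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    subject_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Draw independent Hardy-Weinberg genotypes for every SNP.

    With minor allele frequency q the dosage distribution is
    P(0) = (1-q)^2, P(1) = 2q(1-q), P(2) = q^2.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    ids = list(subject_ids) if subject_ids is not None else _subject_ids(n_subjects, "S")
    if len(ids) != n_subjects:
        raise ValueError("subject_ids length mismatch")
    cols = {}
    for spec in snps:
        q = spec.maf_for(population)
        rng = _rng(seed, _GENO, _key(spec.snp_id))
        d = rng.choice(
            np.array([0.0, 1.0, 2.0]),
            size=n_subjects,
            p=[(1 - q) ** 2, 2 * q * (1 - q), q**2],
        )
        if missing_rate > 0.0:
            d = d.copy()
            d[_rng(seed, _MISS, _key(spec.snp_id)).random(n_subjects) < missing_rate] = np.nan
        cols[spec.snp_id] = d
    dosages = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))
    alleles = pd.DataFrame(
        {"ref": "A", "alt": "C"}, index=pd.Index([s.snp_id for s in snps])
    )
    return GenotypeMatrix(dosages, alleles)


def _effect_log_means(effects: Sequence[EffectSpec], g: GenotypeMatrix) -> np.ndarray:
    """(n_subjects, n_effects) matrix of baseline_mu + beta * dosage."""
    out = np.empty((g.n_subjects, len(effects)))
    for j, eff in enumerate(effects):
        if eff.snp_id not in g.dosages.columns:
            raise ValueError(
                f"effect {eff.protein_id!r} references unknown SNP {eff.snp_id!r}"
            )
        dose = g.dosages[eff.snp_id].to_numpy()
        if np.isnan(dose).any():
            raise ValueError(
                f"SNP {eff.snp_id!r} has missing dosages; simulate proteomes "
                "from complete genotypes"
            )
        out[:, j] = eff.baseline_mu + eff.beta * dose
    return out


def _check_unique_proteins(effects: Sequence[EffectSpec]) -> None:
    seen = set()
    for eff in effects:
        if eff.protein_id in seen:
            raise ValueError(f"duplicate protein id in effects: {eff.protein_id!r}")
        seen.add(eff.protein_id)


def simulate_proteome(
    genotypes: GenotypeMatrix,
    effects: Sequence[EffectSpec],
    seed: int = 0,
) -> ProteomeMatrix:
    """Simulate raw-scale protein abundances from genotype effects.

    Per protein, log abundance is Gaussian around
    ``baseline_mu + beta * dosage`` with SD ``sigma``; the returned
    matrix is the elementwise exponential (strictly positive).
    """
    _check_unique_proteins(effects)
    means = _effect_log_means(effects, genotypes)
    n = genotypes.n_subjects
    cols = {}
    for j, eff in enumerate(effects):
        rng = _rng(seed, _PROT, _key(eff.protein_id))
        cols[eff.protein_id] = np.exp(means[:, j] + rng.normal(0.0, eff.sigma, n))
    values = pd.DataFrame(cols, index=genotypes.subjects.copy())
    return ProteomeMatrix(values, transform_state="raw")


def simulate_visits(
    genotypes: GenotypeMatrix,
    effects: Sequence[EffectSpec],
    n_visits: int,
    seed: int = 0,
    visit_noise_frac: float = 0.3,
    visit_labels: Sequence[str] | None = None,
) -> dict[str, ProteomeMatrix]:
    """Simulate a multi-visit proteome series per subject.

    Each subject has a stable individual log level (baseline + genotype
    effect + Normal(0, sigma)); each visit adds independent noise with SD
    ``visit_noise_frac * sigma``, emulating biological/assay drift between
    clinic visits while keeping a subject's serial proteomes mutually
    closest.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    _check_unique_proteins(effects)
    labels = (
        list(visit_labels)
        if visit_labels is not None
        else [f"V{v}" for v in range(1, n_visits + 1)]
    )
    if len(labels) != n_visits:
        raise ValueError("visit_labels length mismatch")
    means = _effect_log_means(effects, genotypes)
    n = genotypes.n_subjects
    latent = np.empty_like(means)
    for j, eff in enumerate(effects):
        rng = _rng(seed, _PROT, _key(eff.protein_id))
        latent[:, j] = means[:, j] + rng.normal(0.0, eff.sigma, n)
    out = {}
    for v, label in enumerate(labels):
        x = latent.copy()
        for j, eff in enumerate(effects):
            rng = _rng(seed, _VISIT, _key(eff.protein_id), v)
            x[:, j] += rng.normal(0.0, visit_noise_frac * eff.sigma, n)
        values = pd.DataFrame(
            np.exp(x),
            index=genotypes.subjects.copy(),
            columns=[e.protein_id for e in effects],
        )
        out[label] = ProteomeMatrix(values, transform_state="raw")
    return out


def simulate_families(
    n_families: int,
    snps: Sequence[SnpSpec],
    seed: int = 0,
    n_offspring: int = 2,
    population: str | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate nuclear families: HWE parents, Mendelian offspring.

    Per SNP each offspring receives one allele from each parent; a parent
    with dosage d transmits the minor allele with probability d/2.
    Returns the genotype matrix for all members plus a pedigree table
    (subject_id, family_id, father_id, mother_id, role).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if n_offspring < 2:
        raise ValueError("need >= 2 offspring per family for sibling pairs")
    fam_ids = [f"F{k:03d}" for k in range(1, n_families + 1)]
    fathers = [f"{f}_P1" for f in fam_ids]
    mothers = [f"{f}_P2" for f in fam_ids]
    kids = [[f"{f}_C{c}" for c in range(1, n_offspring + 1)] for f in fam_ids]
    cols = {}
    for spec in snps:
        q = spec.maf_for(population)
        rng = _rng(seed, _FAM, _key(spec.snp_id))
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        dad = rng.choice(np.array([0.0, 1.0, 2.0]), size=n_families, p=hwe)
        mom = rng.choice(np.array([0.0, 1.0, 2.0]), size=n_families, p=hwe)
        child = np.empty((n_families, n_offspring))
        for c in range(n_offspring):
            child[:, c] = rng.binomial(1, dad / 2.0) + rng.binomial(1, mom / 2.0)
        col = np.concatenate([dad, mom, child.T.reshape(-1)])
        cols[spec.snp_id] = col
    ids = fathers + mothers + [k for c in range(n_offspring) for k in
                               [kids[f][c] for f in range(n_families)]]
    dosages = pd.DataFrame(cols, index=pd.Index(ids, name="subject_id"))
    rows = []
    for f, fam in enumerate(fam_ids):
        rows.append((fathers[f], fam, "", "", "parent"))
        rows.append((mothers[f], fam, "", "", "parent"))
        for kid in kids[f]:
            rows.append((kid, fam, fathers[f], mothers[f], "offspring"))
    pedigree = pd.DataFrame(
        rows, columns=["subject_id", "family_id", "father_id", "mother_id", "role"]
    )
    alleles = pd.DataFrame(
        {"ref": "A", "alt": "C"}, index=pd.Index([s.snp_id for s in snps])
    )
    return GenotypeMatrix(dosages, alleles), pedigree


def inject_swaps(
    proteomes: Mapping[str, ProteomeMatrix],
    genotypes: GenotypeMatrix,
    ledger: SwapLedger,
    seed: int = 0,
) -> tuple[dict[str, ProteomeMatrix], GenotypeMatrix, SwapLedger]:
    """Apply a ledger of sample-handling errors to multi-visit data.

    ``plasma_swap`` exchanges the two subjects' proteome rows at the named
    visit only; ``dna_mislabel`` exchanges the two subjects' genotype rows
    (so each subject's true dosages end up under the other's label).  The
    ledger is returned unmodified as ground truth.  Two events touching
    the same row are rejected.
    """
    touched: set[tuple] = set()
    for e in ledger.events:
        if e.kind == "plasma_swap":
            if e.visit not in proteomes:
                raise ValueError(f"unknown visit {e.visit!r} in event {e}")
            keys = [("plasma", e.visit, s) for s in e.subjects]
            for s in e.subjects:
                if s not in proteomes[e.visit].subjects:
                    raise ValueError(f"unknown subject {s!r} at visit {e.visit!r}")
        else:
            keys = [("dna", s) for s in e.subjects]
            for s in e.subjects:
                if s not in genotypes.subjects:
                    raise ValueError(f"unknown subject {s!r} in genotype matrix")
        for k in keys:
            if k in touched:
                raise ValueError(f"overlapping events touch the same row: {k}")
            touched.add(k)

    new_prot = {v: pm.copy() for v, pm in proteomes.items()}
    new_geno = genotypes.copy()
    for e in ledger.events:
        a, b = e.subjects
        if e.kind == "plasma_swap":
            vals = new_prot[e.visit].values
            vals.loc[[a, b]] = vals.loc[[b, a]].to_numpy()
        else:
            dos = new_geno.dosages
            dos.loc[[a, b]] = dos.loc[[b, a]].to_numpy()
    return new_prot, new_geno, ledger


def simulate_phenotype(
    proteomes: ProteomeMatrix,
    affected_proteins: Sequence[str],
    shift: float,
    prevalence: float,
    seed: int = 0,
) -> tuple[pd.Series, ProteomeMatrix]:
    """Assign a genotype-independent binary phenotype with protein shifts.

    Case status is Bernoulli(prevalence) independent of everything else;
    in cases, each affected protein is shifted by ``shift`` on the log
    scale (multiplied by exp(shift) on the raw scale).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    missing = [pid for pid in affected_proteins if pid not in proteomes.proteins]
    if missing:
        raise ValueError(f"unknown affected proteins: {missing}")
    rng = _rng(seed, _PHEN, 0)
    y = (rng.random(proteomes.n_subjects) < prevalence).astype(int)
    values = proteomes.values.copy()
    cases = y.astype(bool)
    cols = list(affected_proteins)
    if proteomes.transform_state == "raw":
        values.loc[cases, cols] = values.loc[cases, cols] * np.exp(shift)
    elif proteomes.transform_state == "log":
        values.loc[cases, cols] = values.loc[cases, cols] + shift
    else:
        raise ValueError("phenotype shifts require raw or log values")
    phen = pd.Series(y, index=proteomes.subjects, name="phenotype")
    return phen, ProteomeMatrix(
        values, proteomes.transform_state, proteomes.genotype_adjusted
    )


def random_panel(
    n_pairs: int,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    beta: float | tuple[float, float] = 1.0,
    sigma: float = 1.0,
    baseline_range: tuple[float, float] = (6.0, 9.0),
    snp_prefix: str = "rs",
    protein_prefix: str = "P",
) -> tuple[list[SnpSpec], list[EffectSpec]]:
    """Draw a 1:1 protein/SNP panel of pQTL effects for simulation.

    MAFs are uniform on ``maf_range``; log-scale baselines uniform on
    ``baseline_range`` (e^6..e^9 covers typical relative-fluorescence
    magnitudes); ``beta`` may be a constant or a uniform range.
    """
    rng = _rng(seed, _PANEL, 0)
    mafs = rng.uniform(*maf_range, n_pairs)
    baselines = rng.uniform(*baseline_range, n_pairs)
    if isinstance(beta, tuple):
        betas = rng.uniform(beta[0], beta[1], n_pairs)
    else:
        betas = np.full(n_pairs, float(beta))
    snps = [SnpSpec(f"{snp_prefix}{i + 1:05d}", float(mafs[i])) for i in range(n_pairs)]
    effects = [
        EffectSpec(
            f"{protein_prefix}{i + 1:04d}",
            snps[i].snp_id,
            float(baselines[i]),
            float(betas[i]),
            float(sigma),
        )
        for i in range(n_pairs)
    ]
    return snps, effects
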