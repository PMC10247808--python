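"""Canned synthetic-cohort studies exercising the full pipeline.

Each study simulates a cohort under the conditions the method assumes,
runs the relevant pipeline stage end to end, and returns a dict of
measured quantities.  The designs mirror the real-data workflow: pQTL
discovery in two training cohorts sized like the original ones
(1184 + 1028 subjects), cross-cohort merge to a 1:1 panel, incremental
naive Bayes training, then evaluation on an independent test cohort of
500 subjects with strong pQTL effects (per-allele log shift beta = 1,
residual SD sigma = 1, MAF uniform on 0.1-0.5, 100-pair panel).

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import preprocess, pqtl, simcohort
from . import linker, privacy
from .containers import GenotypeMatrix, ProteomeMatrix
from .identity import diagnose_mismatches, link_visits, relative_detection
from .pqtl import PqtlTable

__all__ = [
    "train_and_test_cohorts",
    "matching_power_study",
    "null_calibration_study",
    "obfuscation_study",
    "noise_degradation_study",
    "swap_diagnosis_study",
    "association_preservation_study",
    "sibling_study",
    "pwas_calibration_study",
]

N_TRAIN_A = 1184
N_TRAIN_B = 1028
N_TEST = 500
N_PAIRS = 100


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def train_and_test_cohorts(
    seed: int,
    n_pairs: int = N_PAIRS,
    beta: float = 1.0,
    sigma: float = 1.0,
    n_test: int = N_TEST,
):
    """Simulate two training cohorts plus an independent test cohort."""
    snps, effects = simcohort.random_panel(n_pairs, seed=seed, beta=beta, sigma=sigma)
    g_a = simcohort.simulate_genotypes(
        N_TRAIN_A, snps, seed=seed + 1, subject_ids=_ids("A", N_TRAIN_A)
    )
    p_a = simcohort.simulate_proteome(g_a, effects, seed=seed + 2)
    g_b = simcohort.simulate_genotypes(
        N_TRAIN_B, snps, seed=seed + 3, subject_ids=_ids("B", N_TRAIN_B)
    )
    p_b = simcohort.simulate_proteome(g_b, effects, seed=seed + 4)
    g_t = simcohort.simulate_genotypes(
        n_test, snps, seed=seed + 5, subject_ids=_ids("T", n_test)
    )
    p_t = simcohort.simulate_proteome(g_t, effects, seed=seed + 6)
    return snps, effects, (g_a, p_a), (g_b, p_b), (g_t, p_t)


def _train_model(
    effects, cohort_a, cohort_b, discovered_panel: bool = True
) -> tuple[linker.NBModel, PqtlTable, float]:
    """Discover the panel in both cohorts, merge, and train incrementally.

    Returns (model, panel, fraction of true pairs recovered).  With
    ``discovered_panel`` False the true simulated pairs are used instead
    (needed when effects are null and nothing is discoverable).
    """
    (g_a, p_a), (g_b, p_b) = cohort_a, cohort_b
    truth = {(e.protein_id, e.snp_id) for e in effects}
    if discovered_panel:
        t_a = pqtl.discover(g_a, p_a, cohort="cohortA")
        t_b = pqtl.discover(g_b, p_b, cohort="cohortB")
        panel = pqtl.reduce_pairs([t_a, t_b])
        recovered = len(truth & set(panel.pairs)) / len(truth)
    else:
        panel = PqtlTable.from_pairs(sorted(truth))
        recovered = float("nan")
    model = linker.fit_nb(preprocess.log_transform(p_a), g_a, panel)
    model = linker.update_nb(model, preprocess.log_transform(p_b), g_b)
    return model, panel, recovered


def matching_power_study(seed: int = 0) -> dict:
    """Strong-effect matching: discovery, training, independent testing."""
    snps, effects, a, b, (g_t, p_t) = train_and_test_cohorts(seed)
    model, panel, recovered = _train_model(effects, a, b)
    truth = {s: s for s in p_t.subjects}
    res = linker.evaluate_matching(model, preprocess.log_transform(p_t), g_t, truth)
    return {
        "model": model,
        "panel": panel,
        "pair_recovery": recovered,
        "test": (g_t, p_t),
        "top1": res["top1"],
        "top3": res["top3"],
        "top1pct": res["top1pct"],
        "window": res["window"],
        "n": res["n"],
    }


def null_calibration_study(seed: int = 0) -> dict:
    """Same design with beta = 0: matching should be at chance (1/n)."""
    snps, effects, a, b, (g_t, p_t) = train_and_test_cohorts(seed, beta=0.0)
    model, panel, _ = _train_model(effects, a, b, discovered_panel=False)
    truth = {s: s for s in p_t.subjects}
    res = linker.evaluate_matching(model, preprocess.log_transform(p_t), g_t, truth)
    return {"top1": res["top1"], "n": res["n"], "chance": 1.0 / res["n"]}


def obfuscation_study(seed: int = 0) -> dict:
    """Genotype-mean adjustment kills linking; reversal restores it.

    The adjustment reference is the linking model itself (attack model =
    defense model), so the measured residual linkability is what the
    attacker could still achieve.
    """
    power = matching_power_study(seed)
    model = power["model"]
    g_t, p_t = power["test"]
    p_log = preprocess.log_transform(p_t)
    truth = {s: s for s in p_t.subjects}
    adjusted, corrections = privacy.genotype_adjust(p_log, g_t, reference=model)
    res_adj = linker.evaluate_matching(model, adjusted, g_t, truth)
    restored = privacy.genotype_deadjust(adjusted, g_t, corrections)
    res_back = linker.evaluate_matching(model, restored, g_t, truth)
    roundtrip = float(
        np.abs(restored.values.to_numpy() - p_log.values.to_numpy()).max()
    )
    return {
        "baseline_top1": power["top1"],
        "adjusted_top1": res_adj["top1"],
        "restored_top1": res_back["top1"],
        "roundtrip_max_abs_error": roundtrip,
        "n": res_adj["n"],
        "chance": 1.0 / res_adj["n"],
    }


def noise_degradation_study(seed: int = 0, n_null: int = 400) -> dict:
    """Appending null pairs to an informative panel must not help.

    100 informative pairs (beta = 1) plus ``n_null`` null pairs
    (beta = 0, own SNPs/proteins) are trained together; accuracy with
    the padded panel is compared against the informative-only panel.
    """
    snps_i, eff_i = simcohort.random_panel(N_PAIRS, seed=seed, beta=1.0, sigma=1.0)
    snps_n, eff_n = simcohort.random_panel(
        n_null, seed=seed + 7, beta=0.0, sigma=1.0,
        snp_prefix="nullrs", protein_prefix="NP",
    )
    snps = list(snps_i) + list(snps_n)
    effects = list(eff_i) + list(eff_n)
    g_tr = simcohort.simulate_genotypes(
        N_TRAIN_A, snps, seed=seed + 1, subject_ids=_ids("A", N_TRAIN_A)
    )
    p_tr = simcohort.simulate_proteome(g_tr, effects, seed=seed + 2)
    g_t = simcohort.simulate_genotypes(
        N_TEST, snps, seed=seed + 5, subject_ids=_ids("T", N_TEST)
    )
    p_t = simcohort.simulate_proteome(g_t, effects, seed=seed + 6)
    truth = {s: s for s in p_t.subjects}
    p_tr_log, p_t_log = preprocess.log_transform(p_tr), preprocess.log_transform(p_t)
    panel_info = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in eff_i])
    panel_all = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
    res = {}
    for name, panel in (("informative", panel_info), ("padded", panel_all)):
        m = linker.fit_nb(p_tr_log, g_tr, panel)
        res[name] = linker.evaluate_matching(m, p_t_log, g_t, truth)["top1"]
    return {"top1_informative": res["informative"], "top1_padded": res["padded"]}


def swap_diagnosis_study(
    seed: int = 0,
    n_subjects: int = 50,
    n_visits: int = 3,
    n_train: int = 300,
    n_pairs: int = 300,
    theta: float = 0.99,
) -> dict:
    """Inject 2 reciprocal plasma swaps + 1 DNA mislabel; diagnose them.

    Uses a 300-pair panel: mislabel diagnosis presumes per-link accuracy
    near 100%, the regime the densest proteome platforms reach, so the
    study emulates a larger assay than the 100-pair matching study.
    """
    snps, effects = simcohort.random_panel(n_pairs, seed=seed, beta=1.0, sigma=1.0)
    g_tr = simcohort.simulate_genotypes(
        n_train, snps, seed=seed + 1, subject_ids=_ids("R", n_train)
    )
    p_tr = simcohort.simulate_proteome(g_tr, effects, seed=seed + 2)
    panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
    model = linker.fit_nb(preprocess.log_transform(p_tr), g_tr, panel)

    g = simcohort.simulate_genotypes(n_subjects, snps, seed=seed + 5)
    visits = simcohort.simulate_visits(
        g, effects, n_visits, seed=seed + 6, visit_noise_frac=0.3
    )
    subjects = list(g.subjects)
    vlabels = list(visits)
    ledger = simcohort.SwapLedger(
        [
            simcohort.SwapEvent("plasma_swap", (subjects[0], subjects[1]), vlabels[1]),
            simcohort.SwapEvent("plasma_swap", (subjects[2], subjects[3]), vlabels[2]),
            simcohort.SwapEvent("dna_mislabel", (subjects[4], subjects[5])),
        ]
    )
    sw_prot, sw_geno, ledger = simcohort.inject_swaps(visits, g, ledger, seed=seed + 8)
    logged = {v: preprocess.log_transform(pm) for v, pm in sw_prot.items()}
    report = diagnose_mismatches(link_visits(model, logged, sw_geno), theta=theta)

    truth_set = {
        (e.kind, frozenset(e.subjects), e.visit) for e in ledger.events
    }
    found_set = {
        (
            e.kind,
            frozenset(e.subjects),
            e.visits[0] if e.kind == "plasma_swap" else None,
        )
        for e in report.events
        if e.kind != "indeterminate"
    }
    extra = [
        e for e in report.events
        if (
            e.kind,
            frozenset(e.subjects),
            e.visits[0] if e.kind == "plasma_swap" else None,
        )
        not in truth_set
    ]
    clean_report = diagnose_mismatches(
        link_visits(model, {v: preprocess.log_transform(pm) for v, pm in visits.items()}, g),
        theta=theta,
    )
    return {
        "report": report,
        "ledger": ledger,
        "n_events_true": len(ledger.events),
        "n_events_recovered": len(truth_set & found_set),
        "n_false_positives": len(extra),
        "n_events_clean_cohort": len(clean_report.events),
    }


def association_preservation_study(
    seed: int = 0,
    n_subjects: int = 1000,
    beta: float = 0.25,
    shift: float = 1.0,
    n_affected: int = 5,
) -> dict:
    """Genotype-independent phenotype associations survive adjustment.

    Panel proteins carry a modest pQTL effect (beta = 0.25 on the log
    scale, a few percent of variance, typical of rank-and-file pQTLs); a
    genotype-independent binary phenotype shifts ``n_affected`` of them
    by ``shift`` on the log scale.  Welch t statistics are compared
    before and after genotype-mean adjustment.
    """
    snps, effects = simcohort.random_panel(N_PAIRS, seed=seed, beta=beta, sigma=1.0)
    g = simcohort.simulate_genotypes(n_subjects, snps, seed=seed + 1)
    p = simcohort.simulate_proteome(g, effects, seed=seed + 2)
    affected = [e.protein_id for e in effects[:n_affected]]
    phen, p_shifted = simcohort.simulate_phenotype(
        p, affected, shift=shift, prevalence=0.5, seed=seed + 3
    )
    panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
    p_log = preprocess.log_transform(p_shifted)
    before = privacy.association_ttest(p_log, phen)
    adjusted, _ = privacy.genotype_adjust(p_log, g, panel=panel)
    after = privacy.association_ttest(adjusted, phen)
    comp = privacy.compare_associations(before, after)
    rel = comp.loc[affected, "rel_delta_t"]
    return {
        "comparison": comp,
        "affected": affected,
        "max_rel_delta_t": float(rel.max()),
        "any_status_changed": bool(comp.loc[affected, "status_changed"].any()),
    }


def sibling_study(
    seed: int = 0, n_families: int = 60, n_unrelated: int = 440
) -> dict:
    """Rank sibling genomes among unrelated candidates via the linker.

    Families have three offspring so "at least one sibling in the top 1%"
    and "all siblings in the top 1%" are distinct summaries.
    """
    snps, effects = simcohort.random_panel(N_PAIRS, seed=seed, beta=1.0, sigma=1.0)
    fam_g, pedigree = simcohort.simulate_families(
        n_families, snps, seed=seed + 9, n_offspring=3
    )
    unrel = simcohort.simulate_genotypes(
        n_unrelated, snps, seed=seed + 5, subject_ids=_ids("U", n_unrelated)
    )
    genomes = GenotypeMatrix(
        fam_g.dosages.combine_first(unrel.dosages).loc[
            list(fam_g.subjects) + list(unrel.subjects)
        ],
        None,
    )
    g_tr = simcohort.simulate_genotypes(
        N_TRAIN_A, snps, seed=seed + 1, subject_ids=_ids("R", N_TRAIN_A)
    )
    p_tr = simcohort.simulate_proteome(g_tr, effects, seed=seed + 2)
    panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
    model = linker.fit_nb(preprocess.log_transform(p_tr), g_tr, panel)
    offspring = pedigree[pedigree["role"] == "offspring"]["subject_id"]
    off_g = GenotypeMatrix(fam_g.dosages.loc[list(offspring)], None)
    proteomes = preprocess.log_transform(
        simcohort.simulate_proteome(off_g, effects, seed=seed + 6)
    )
    table, summary = relative_detection(model, proteomes, genomes, pedigree)
    return {"table": table, "n_genomes": genomes.n_subjects, **summary}


def pwas_calibration_study(
    seed: int = 0, n_subjects: int = 500, n_snps: int = 20, n_proteins: int = 100
) -> dict:
    """Null pWAS scan: type-I error at alpha = 0.05 over null pairs."""
    snps, _ = simcohort.random_panel(n_snps, seed=seed, beta=0.0, sigma=1.0)
    _, effects = simcohort.random_panel(
        n_proteins, seed=seed + 7, beta=0.0, sigma=1.0, protein_prefix="NP"
    )
    # proteins independent of every scanned SNP: attach them to other SNPs
    own_snps, _ = simcohort.random_panel(
        n_proteins, seed=seed + 8, beta=0.0, sigma=1.0, snp_prefix="ownrs"
    )
    g = simcohort.simulate_genotypes(n_subjects, snps + own_snps, seed=seed + 1)
    effects = [
        simcohort.EffectSpec(e.protein_id, own_snps[i].snp_id, e.baseline_mu, 0.0, e.sigma)
        for i, e in enumerate(effects)
    ]
    p = simcohort.simulate_proteome(g, effects, seed=seed + 2)
    g_scan = GenotypeMatrix(g.dosages[[s.snp_id for s in snps]], None)
    records = pqtl.pwas(g_scan, preprocess.rank_int(p))
    rate = float((records["p"] < 0.05).mean())
    return {"n_pairs": len(records), "rejection_rate": rate}
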