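"""Gaussian naive Bayes training, posteriors, and odds-product ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from protlink import GenotypeMatrix, ProteomeMatrix
from protlink import simcohort as sc
from protlink import preprocess
from protlink.linker import (
    NBModel,
    evaluate_matching,
    fit_nb,
    genotype_posterior,
    log_odds_genome,
    rank_genomes,
    score_matrix,
    top_pct_window,
    update_nb,
)
from protlink.pqtl import PqtlTable


def _log_pm(values, subjects=None, proteins=None):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = subjects or [f"S{i}" for i in range(len(df))]
    df.columns = proteins or [f"P{j + 1}" for j in range(df.shape[1])]
    return ProteomeMatrix(df, transform_state="log")


def _gm(values, subjects=None, snps=None):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = subjects or [f"S{i}" for i in range(len(df))]
    df.columns = snps or [f"rs{j + 1}" for j in range(df.shape[1])]
    return GenotypeMatrix(df)


def _panel(n):
    return PqtlTable.from_pairs([(f"P{i + 1}", f"rs{i + 1}") for i in range(n)])


def direct_posterior(x, mus, sigmas, priors):
    """Brute-force three-term Bayes formula in plain arithmetic."""
    dens = [
        pr * math.exp(-0.5 * ((x - mu) / sd) ** 2) / (math.sqrt(2 * math.pi) * sd)
        for mu, sd, pr in zip(mus, sigmas, priors)
    ]
    tot = sum(dens)
    return [d / tot for d in dens]


class TestFit:
    def test_hand_computed_class_stats(self):
        # class 0 holds {1, 3}: mean 2, SD sqrt(2) with the n-1 denominator
        p = _log_pm([[1.0], [3.0], [5.0], [7.0], [4.0], [6.0]])
        g = _gm([[0], [0], [1], [1], [2], [2]])
        m = fit_nb(p, g, _panel(1))
        assert m.counts[0].tolist() == [2, 2, 2]
        assert m.mu[0, 0] == pytest.approx(2.0)
        assert m.sigma[0, 0] == pytest.approx(math.sqrt(2.0))
        assert np.allclose(m.priors[0], [1 / 3, 1 / 3, 1 / 3])

    def test_identical_class_data_identical_gaussians(self):
        p = _log_pm([[1.0], [3.0], [1.0], [3.0], [1.0], [3.0]])
        g = _gm([[0], [0], [1], [1], [2], [2]])
        m = fit_nb(p, g, _panel(1))
        assert np.allclose(m.mu[0], m.mu[0, 0])
        assert np.allclose(m.sigma[0], m.sigma[0, 0])

    def test_parameter_recovery_on_simulated_truth(self):
        snps, effects = sc.random_panel(10, seed=70, beta=1.0, sigma=1.0)
        g = sc.simulate_genotypes(2000, snps, seed=71)
        p = sc.simulate_proteome(g, effects, seed=72)
        panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
        m = fit_nb(preprocess.log_transform(p), g, panel)
        for i, eff in enumerate(effects):
            for cls in range(3):
                n = m.counts[i, cls]
                if n < 2:
                    continue
                truth = eff.baseline_mu + eff.beta * cls
                # 4 standard errors: 30 simultaneous class-mean estimates
                assert abs(m.mu[i, cls] - truth) < 4 * eff.sigma / math.sqrt(n)

    def test_absent_pair_rejected(self):
        p = _log_pm([[1.0], [2.0], [3.0]])
        g = _gm([[0], [1], [2]])
        with pytest.raises(ValueError, match="P9"):
            fit_nb(p, g, PqtlTable.from_pairs([("P9", "rs1")]))

    def test_requires_log_and_reduced(self):
        g = _gm([[0], [1], [2]])
        raw = ProteomeMatrix(pd.DataFrame({"P1": [1.0, 2, 3]}, index=g.subjects))
        with pytest.raises(ValueError, match="log"):
            fit_nb(raw, g, _panel(1))

    def test_missing_dosage_contributes_to_no_class(self):
        p = _log_pm([[1.0], [3.0], [5.0]])
        g = _gm([[0], [np.nan], [2]])
        m = fit_nb(p, g, _panel(1))
        assert m.counts[0].tolist() == [1, 0, 1]
        assert m.priors[0, 1] == 0.0


class TestUpdate:
    @pytest.fixture()
    def split_cohorts(self):
        snps, effects = sc.random_panel(8, seed=80, beta=1.0)
        g = sc.simulate_genotypes(300, snps, seed=81)
        p = preprocess.log_transform(sc.simulate_proteome(g, effects, seed=82))
        panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
        return g, p, panel

    def test_update_with_empty_cohort_is_identity(self, split_cohorts):
        g, p, panel = split_cohorts
        m = fit_nb(p, g, panel)
        empty_p = ProteomeMatrix(p.values.iloc[:0], transform_state="log")
        empty_g = GenotypeMatrix(g.dosages.iloc[:0])
        m2 = update_nb(m, empty_p, empty_g)
        assert np.array_equal(m2.counts, m.counts)
        assert np.array_equal(m2.sums, m.sums)

    def test_incremental_equals_single_pass(self, split_cohorts):
        g, p, panel = split_cohorts
        rng = np.random.default_rng(83)
        for _ in range(5):
            mask = rng.random(g.n_subjects) < rng.uniform(0.2, 0.8)
            pa = ProteomeMatrix(p.values[mask], transform_state="log")
            ga = GenotypeMatrix(g.dosages[mask])
            pb = ProteomeMatrix(p.values[~mask], transform_state="log")
            gb = GenotypeMatrix(g.dosages[~mask])
            m = update_nb(fit_nb(pa, ga, panel), pb, gb)
            full = fit_nb(p, g, panel)
            assert np.allclose(m.mu, full.mu, atol=1e-10)
            assert np.allclose(m.sigma, full.sigma, atol=1e-10)
            assert np.allclose(m.priors, full.priors, atol=1e-12)

    def test_duplicate_update_doubles_counts(self, split_cohorts):
        g, p, panel = split_cohorts
        m = fit_nb(p, g, panel)
        m2 = update_nb(m, p, g)
        assert np.array_equal(m2.counts, 2 * m.counts)
        assert np.allclose(m2.mu, m.mu, atol=1e-12)

    def test_panel_mismatch_rejected(self, split_cohorts):
        g, p, panel = split_cohorts
        m = fit_nb(p, g, panel)
        bad_p = ProteomeMatrix(
            p.values.rename(columns=lambda c: c + "_x"), transform_state="log"
        )
        with pytest.raises(ValueError):
            update_nb(m, bad_p, g)


class TestPosterior:
    def _model(self, mus, sigmas, counts=(100, 100, 100)):
        c = np.array([counts], dtype=float)
        mus = np.array([mus], dtype=float)
        sig = np.array([sigmas], dtype=float)
        sums = c * mus
        # suffstats whose sample mean/SD (n-1 denominator) equal mus/sigmas
        sumsqs = np.where(
            c > 0, sums**2 / np.maximum(c, 1) + sig**2 * (c - 1), 0.0
        )
        return NBModel(
            np.array(["P1"], dtype=object), np.array(["rs1"], dtype=object),
            c, sums, sumsqs,
        )

    def test_symmetric_classes_give_uniform_posterior(self):
        m = self._model([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
        post = genotype_posterior(m, ("P1", "rs1"), 4.2)
        assert np.allclose(post, 1 / 3, atol=1e-12)

    def test_well_separated_tail(self):
        m = self._model([0.0, 10.0, 20.0], [1.0, 1.0, 1.0])
        post = genotype_posterior(m, ("P1", "rs1"), 0.0)
        assert post[0] > 0.999

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(90)
        for _ in range(50):
            mus = rng.normal(5, 2, 3)
            sigmas = rng.uniform(0.5, 2.0, 3)
            counts = rng.integers(5, 200, 3)
            m = self._model(mus, sigmas, counts)
            x = rng.normal(5, 3)
            expect = direct_posterior(
                x, m.mu[0], m.sigma[0], m.priors[0]
            )
            post = genotype_posterior(m, 0, x)
            assert np.allclose(post, expect, atol=1e-12)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_extreme_x_never_nan(self):
        m = self._model([0.0, 1.0, 2.0], [0.1, 0.1, 0.1])
        post = genotype_posterior(m, 0, 1e6)
        assert np.isfinite(post).all()
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_class_excluded_from_support(self):
        m = self._model([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], counts=(50, 50, 0))
        post = genotype_posterior(m, 0, 2.0)
        assert post[2] == 0.0
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_x_rejected(self):
        m = self._model([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            genotype_posterior(m, 0, np.inf)


class TestOddsProduct:
    def test_single_pair_odds_arithmetic(self):
        # within-class spread keeps class SDs (and hence odds) non-degenerate
        p = _log_pm([[0.0], [0.4], [1.0], [1.4], [2.0], [2.4]])
        g = _gm([[0], [0], [1], [1], [2], [2]])
        m = fit_nb(p, g, _panel(1))
        x = 0.3
        post = genotype_posterior(m, 0, x)
        for dose in (0, 1, 2):
            got = log_odds_genome(
                m, pd.Series({"P1": x}), pd.Series({"rs1": float(dose)})
            )
            assert got == pytest.approx(
                math.log(post[dose] / (1 - post[dose])), abs=1e-10
            )

    def test_five_pair_product_oracle(self):
        snps, effects = sc.random_panel(5, seed=91, beta=1.0)
        g = sc.simulate_genotypes(400, snps, seed=92)
        p = preprocess.log_transform(sc.simulate_proteome(g, effects, seed=93))
        panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
        m = fit_nb(p, g, panel)
        row_p = p.values.iloc[7]
        row_g = g.dosages.iloc[11]
        product = 1.0
        for prot, snp in m.pairs:
            post = genotype_posterior(m, (prot, snp), row_p[prot])
            pr = post[int(row_g[snp])]
            product *= pr / (1 - pr)
        got = log_odds_genome(m, row_p, row_g)
        assert got == pytest.approx(math.log(product), abs=1e-10)

    def test_missing_dosage_pair_skipped(self):
        p = _log_pm([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0], [0.0, 1.0]])
        g = _gm([[0, 1], [1, 2], [2, 0], [1, 1]])
        m = fit_nb(p, g, _panel(2))
        full = log_odds_genome(
            m, p.values.iloc[0], pd.Series({"rs1": 0.0, "rs2": 1.0})
        )
        part = log_odds_genome(
            m, p.values.iloc[0], pd.Series({"rs1": 0.0, "rs2": np.nan})
        )
        post1 = genotype_posterior(m, ("P1", "rs1"), p.values.iloc[0]["P1"])
        assert part == pytest.approx(
            math.log(post1[0] / (1 - post1[0])), abs=1e-10
        )
        assert part != full


@pytest.fixture(scope="module")
def trained():
    snps, effects = sc.random_panel(30, seed=94, beta=1.0)
    g = sc.simulate_genotypes(300, snps, seed=95)
    p = preprocess.log_transform(sc.simulate_proteome(g, effects, seed=96))
    panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
    return fit_nb(p, g, panel), g, p


class TestRanking:
    def test_single_genome_is_top1(self, trained):
        m, g, p = trained
        sub = GenotypeMatrix(g.dosages.iloc[[3]])
        res = rank_genomes(m, p.values.iloc[0], sub, true_genome=g.subjects[3])
        assert res.top1 and res.rank_of_true == 1

    def test_duplicate_genomes_tie_with_identical_scores(self, trained):
        m, g, p = trained
        dup = g.dosages.iloc[[0, 0]].copy()
        dup.index = ["dupA", "dupB"]
        res = rank_genomes(m, p.values.iloc[0], GenotypeMatrix(dup))
        assert res.log_odds[0] == res.log_odds[1]
        assert list(res.genome_ids) == ["dupA", "dupB"]  # tie broken by id

    def test_empty_genome_set_rejected(self, trained):
        m, g, p = trained
        empty = GenotypeMatrix(g.dosages.iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            rank_genomes(m, p.values.iloc[0], empty)

    def test_score_matrix_agrees_with_row_scoring(self, trained):
        m, g, p = trained
        sub_p = ProteomeMatrix(p.values.iloc[:3], transform_state="log")
        sub_g = GenotypeMatrix(g.dosages.iloc[:4])
        S = score_matrix(m, sub_p, sub_g)
        for pid in sub_p.subjects:
            for gid in sub_g.subjects:
                direct = log_odds_genome(
                    m, sub_p.values.loc[pid], sub_g.dosages.loc[gid]
                )
                assert S.loc[pid, gid] == pytest.approx(direct, abs=1e-9)


class TestEvaluate:
    def test_noiseless_limit_perfect(self):
        snps, effects = sc.random_panel(20, seed=97, beta=1.0, sigma=1e-3)
        g = sc.simulate_genotypes(100, snps, seed=98)
        p = preprocess.log_transform(sc.simulate_proteome(g, effects, seed=99))
        panel = PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
        m = fit_nb(p, g, panel)
        res = evaluate_matching(m, p, g, {s: s for s in p.subjects})
        assert res["top1"] == res["top3"] == res["top1pct"] == 1.0

    def test_accuracies_nested(self, small_cohort, small_model):
        _, _, g, p, _ = small_cohort
        res = evaluate_matching(
            small_model, preprocess.log_transform(p), g, {s: s for s in p.subjects}
        )
        assert res["top1"] <= res["top3"] <= res["top1pct"]

    def test_population_stratification(self, small_cohort, small_model):
        _, _, g, p, _ = small_cohort
        pops = {s: ("X" if i % 2 else "Y") for i, s in enumerate(p.subjects)}
        res = evaluate_matching(
            small_model, preprocess.log_transform(p), g,
            {s: s for s in p.subjects}, populations=pops,
        )
        assert set(res["by_population"]) == {"X", "Y"}
        ns = [res["by_population"][k]["n"] for k in ("X", "Y")]
        assert sum(ns) == res["n"]

    def test_unmapped_proteome_rejected(self, small_cohort, small_model):
        _, _, g, p, _ = small_cohort
        truth = {s: s for s in p.subjects}
        truth.pop(p.subjects[0])
        with pytest.raises(ValueError, match="truth"):
            evaluate_matching(small_model, preprocess.log_transform(p), g, truth)

    def test_top_pct_window_rounding(self):
        assert top_pct_window(2698, mode="ceil") == 27
        assert top_pct_window(2698, mode="floor") == 26
        assert top_pct_window(50) == 1
        assert top_pct_window(10, mode="floor") == 1  # never below 1


def test_model_json_roundtrip(tmp_path, small_model):
    path = tmp_path / "model.json"
    small_model.to_json(path)
    back = NBModel.from_json(path)
    assert np.array_equal(back.counts, small_model.counts)
    assert np.allclose(back.sums, small_model.sums)
    assert np.allclose(back.mu, small_model.mu)
    assert list(back.proteins) == list(small_model.proteins)
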