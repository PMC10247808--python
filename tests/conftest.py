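import pytest

from protlink import linker, pqtl, preprocess
from protlink import simcohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """300 subjects, 20 strong pQTL pairs, with the true panel."""
    snps, effects = sc.random_panel(20, seed=7, beta=1.0, sigma=1.0)
    g = sc.simulate_genotypes(300, snps, seed=8)
    p = sc.simulate_proteome(g, effects, seed=9)
    panel = pqtl.PqtlTable.from_pairs([(e.protein_id, e.snp_id) for e in effects])
    return snps, effects, g, p, panel


@pytest.fixture(scope="session")
def small_model(small_cohort):
    _, _, g, p, panel = small_cohort
    return linker.fit_nb(preprocess.log_transform(p), g, panel)
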