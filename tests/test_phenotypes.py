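"""Log-odds phenotype models, misclassification, and ascertainment."""

import numpy as np
import pytest

from kbac.phenotypes import (PhenotypeModel, ScenarioConfig,
                             apply_misclassification, ascertain_case_control,
                             assign_causal_sites, disease_probability,
                             main_effect_or, pick_common_interactor)
from kbac.popgen import HaplotypePool


def test_assign_causal_sites_rounding():
    rng = np.random.default_rng(0)
    assert assign_causal_sites(10, 0.5, rng).sum() == 5
    assert assign_causal_sites(10, 1.0, rng).all()
    assert not assign_causal_sites(10, 0.0, rng).any()
    # ties round up: 0.5 * 5 = 2.5 -> 3
    assert assign_causal_sites(5, 0.5, rng).sum() == 3


def test_main_effect_or_fixed_and_variable():
    assert main_effect_or("main_fixed", [0.003, 0.01]).tolist() == [3.0, 3.0]
    v = main_effect_or("main_variable", [0.01, 1e-6, 1e-8])
    assert v[0] == pytest.approx(2.0)
    assert v[1] == pytest.approx(20.0)
    assert v[2] == 20.0  # clamped
    # inverse correlation with MAF
    grid = main_effect_or("main_variable", [0.01, 0.005, 0.001, 1e-4])
    assert (np.diff(grid) > 0).all()
    with pytest.raises(ValueError):
        main_effect_or("main_fixed", [0.0])


def test_reciprocal_map_matches_alternative_form():
    v = main_effect_or("main_variable", [0.01, 1e-4, 0.002],
                       or_map="reciprocal")
    np.testing.assert_allclose(v, [2.0, 20.0, 10.0])


def test_disease_probability_wildtype_and_single_het():
    model = PhenotypeModel(kind="main_fixed", baseline_odds=0.02)
    maf = np.array([0.005])
    causal = np.array([True])
    p0 = disease_probability(model, dosage=[0], maf=maf, causal=causal)
    assert p0 == pytest.approx(0.02 / 1.02)
    p1 = disease_probability(model, dosage=[1], maf=maf, causal=causal)
    assert p1 == pytest.approx(0.02 * 3 / (1 + 0.02 * 3))


def test_disease_probability_monotone_in_causal_count():
    model = PhenotypeModel(kind="main_fixed")
    maf = np.array([0.004, 0.008])
    causal = np.array([True, True])
    probs = [disease_probability(model, dosage=d, maf=maf, causal=causal)
             for d in ([0, 0], [1, 0], [1, 1], [2, 1])]
    assert all(a < b for a, b in zip(probs, probs[1:]))


def test_within_gene_cis_only():
    model = PhenotypeModel(kind="within_gene", baseline_odds=0.01)
    causal = np.array([True, False])  # site 0 causal rare, site 2 = common
    # haplotype 1 carries rare allele AND common minor allele (cis)
    h1 = np.array([[1, 0, 1]])
    h2 = np.array([[0, 0, 0]])
    p_cis = disease_probability(model, phase=(h1, h2),
                                causal=np.array([True, False, False]),
                                common_site=2)
    assert p_cis == pytest.approx(0.03 / 1.03)
    # trans configuration: rare allele on the other haplotype -> baseline
    h1t = np.array([[0, 0, 1]])
    h2t = np.array([[1, 0, 0]])
    p_trans = disease_probability(model, phase=(h1t, h2t),
                                  causal=np.array([True, False, False]),
                                  common_site=2)
    assert p_trans == pytest.approx(0.01 / 1.01)


def test_between_gene_silencing():
    b = 0.01
    model = PhenotypeModel(kind="between_gene", baseline_odds=b)
    causal = np.array([True, True])
    # one causal allele in each gene: gene-2 effect silenced -> OR 4 total
    p = disease_probability(model, dosage=[1, 1], causal=causal, gene_split=1)
    assert p == pytest.approx(4 * b / (1 + 4 * b))
    # gene 2 alone: OR 2 applies
    p2 = disease_probability(model, dosage=[0, 1], causal=causal, gene_split=1)
    assert p2 == pytest.approx(2 * b / (1 + 2 * b))


def toy_pool(freqs, n_hap=200, seed=0):
    rng = np.random.default_rng(seed)
    H = (rng.random((n_hap, len(freqs))) < np.asarray(freqs)).astype(np.uint8)
    # force exact frequencies are not needed; recompute
    f = H.mean(axis=0)
    keep = (f > 0) & (f < 1)
    return HaplotypePool(haplotypes=H[:, keep], site_freq=f[keep],
                         site_selection=np.zeros(int(keep.sum())))


def test_ascertainment_returns_exact_quotas():
    pool = toy_pool([0.005, 0.008, 0.3])
    model = PhenotypeModel(kind="main_fixed", baseline_odds=0.5)
    gm, ph = ascertain_case_control(pool, model, NA=30, NU=40, rng=1)
    assert ph.n_cases == 30 and ph.n_controls == 40
    assert gm.n_individuals == 70
    assert gm.phase is not None


def test_ascertainment_reproducible():
    pool = toy_pool([0.01, 0.3])
    model = PhenotypeModel(kind="main_fixed", baseline_odds=0.3)
    a = ascertain_case_control(pool, model, 10, 10, rng=7)[0]
    b = ascertain_case_control(pool, model, 10, 10, rng=7)[0]
    assert np.array_equal(a.dosages, b.dosages)


def test_ascertainment_cap_on_impossible_case_probability():
    pool = toy_pool([0.01, 0.3])
    model = PhenotypeModel(kind="main_fixed", baseline_odds=1e-9)
    with pytest.raises(RuntimeError, match="cap"):
        ascertain_case_control(pool, model, 50, 5, rng=0, batch=1000,
                               max_draws=5000)


def make_flagged(n_causal=10, n_noncausal=10):
    from kbac.data import GenotypeMatrix

    s = n_causal + n_noncausal
    gm = GenotypeMatrix(dosages=np.zeros((4, s), np.int8),
                        site_ids=[f"s{i}" for i in range(s)],
                        site_maf=np.full(s, 0.005),
                        is_rare=np.ones(s, bool),
                        is_causal=np.array([True] * n_causal
                                           + [False] * n_noncausal))
    return gm


@pytest.mark.parametrize("exclude,include,expect_causal,expect_noncausal", [
    (0.0, 0.0, 10, 0),
    (0.0, 1.0, 10, 10),
    (0.6, 0.0, 4, 0),
    (0.2, 0.0, 8, 0),
    (0.0, 0.4, 10, 4),
])
def test_misclassification_site_counts(exclude, include, expect_causal,
                                       expect_noncausal):
    gm = make_flagged()
    scen = ScenarioConfig(exclude_causal_fraction=exclude,
                          include_noncausal_fraction=include)
    view = apply_misclassification(gm, scen, rng=0)
    assert int(view.is_causal.sum()) == expect_causal
    assert int((~view.is_causal).sum()) == expect_noncausal


def test_misclassification_both_knobs_rejected():
    with pytest.raises(ValueError):
        ScenarioConfig(exclude_causal_fraction=0.2,
                       include_noncausal_fraction=0.2)


def test_pick_common_interactor():
    pool = toy_pool([0.01, 0.35, 0.02], n_hap=2000, seed=3)
    idx = pick_common_interactor(pool, rng=0)
    assert pool.minor_freq()[idx] > 0.20
    rare_only = toy_pool([0.01, 0.02], n_hap=2000, seed=4)
    with pytest.raises(ValueError, match="regenerate"):
        pick_common_interactor(rare_only, rng=0)


def test_between_gene_replicate_end_to_end():
    from kbac.phenotypes import ascertain_between_gene

    p1 = toy_pool([0.006, 0.009, 0.3], n_hap=1000, seed=5)
    p2 = toy_pool([0.004, 0.007, 0.4], n_hap=1000, seed=6)
    model = PhenotypeModel(kind="between_gene", causal_fraction=1.0,
                           baseline_odds=0.2)
    gm, ph, split = ascertain_between_gene(p1, p2, model, NA=40, NU=40,
                                           rng=3, batch=2000)
    assert ph.n_cases == 40 and ph.n_controls == 40
    assert 0 < split <= gm.n_sites
    assert gm.is_causal.all()


def test_load_site_frequencies(tmp_path):
    from kbac.popgen import load_site_frequencies

    f = tmp_path / "sfs.tsv"
    f.write_text("0.01\n0.002\n0.0005\n")
    np.testing.assert_allclose(load_site_frequencies(str(f)),
                               [0.01, 0.002, 0.0005])
    bad = tmp_path / "bad.tsv"
    bad.write_text("0.7\n")
    with pytest.raises(ValueError):
        load_site_frequencies(str(bad))
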