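"""Forward simulator checked against neutral coalescent expectations."""

import numpy as np
import pytest

from kbac.popgen import (DemographyModel, HaplotypePool, SelectionModel,
                         generate_pool_set, sample_haplotype_pairs,
                         sample_individual, sfs_genotype_generator,
                         simulate_haplotype_pool)


@pytest.fixture(scope="module")
def neutral_runs():
    """200 neutral constant-size loci; shared by the Watterson and SFS checks.

    theta = 4*N*mu_locus = 2 with N = 60 diploids; samples of 20 haplotypes.
    """
    N, theta, n_samp, reps = 60, 2.0, 20, 200
    dem = DemographyModel(epochs=[(N, 1)], burn_in=12 * N)
    rng = np.random.default_rng(99)
    seg_counts, sfs = [], np.zeros(n_samp - 1)
    for i in range(reps):
        pool = simulate_haplotype_pool(dem, SelectionModel.neutral(),
                                       mu=theta / (4 * N), L=1, seed=5000 + i)
        idx = rng.choice(pool.n_haplotypes, n_samp, replace=False)
        cnt = pool.haplotypes[idx].sum(axis=0)
        seg = (cnt > 0) & (cnt < n_samp)
        seg_counts.append(int(seg.sum()))
        for c in cnt[seg]:
            sfs[c - 1] += 1
    return theta, n_samp, np.array(seg_counts), sfs


def test_watterson_segregating_sites(neutral_runs):
    theta, n_samp, seg, _ = neutral_runs
    a1 = sum(1.0 / i for i in range(1, n_samp))
    expected = theta * a1
    se = seg.std(ddof=1) / np.sqrt(len(seg))
    assert abs(seg.mean() - expected) < 3 * se + 0.05 * expected


def test_neutral_sfs_proportional_to_1_over_i(neutral_runs):
    from scipy import stats

    theta, n_samp, _, sfs = neutral_runs
    i = np.arange(1, n_samp)
    expected = (1.0 / i) / (1.0 / i).sum() * sfs.sum()
    # pool sparse high-frequency classes for a valid chi-square
    lump = i >= 10
    obs = np.concatenate([sfs[~lump], [sfs[lump].sum()]])
    exp = np.concatenate([expected[~lump], [expected[lump].sum()]])
    chi2 = ((obs - exp) ** 2 / exp).sum()
    p = stats.chi2.sf(chi2, df=len(obs) - 1)
    assert p > 0.001


def test_purifying_selection_lowers_mean_frequency():
    dem = DemographyModel(epochs=[(60, 1)], burn_in=600)
    sel = SelectionModel(dfe_shape=0.5, dfe_scale=0.2, dominance=0.5)
    diffs = []
    for i in range(25):
        p_neu = simulate_haplotype_pool(dem, SelectionModel.neutral(),
                                        mu=0.01, L=1, seed=100 + i)
        p_sel = simulate_haplotype_pool(dem, sel, mu=0.01, L=1, seed=100 + i)
        if p_neu.n_sites and p_sel.n_sites:
            diffs.append(p_neu.site_freq.mean() - p_sel.site_freq.mean())
    assert np.median(diffs) > 0  # paired sign comparison


def test_pool_set_reproducible_and_distinct():
    dem = DemographyModel(epochs=[(30, 1)], burn_in=60)
    sel = SelectionModel.neutral()
    a = generate_pool_set(3, dem, sel, mu=0.01, L=1, seed=1)
    b = generate_pool_set(3, dem, sel, mu=0.01, L=1, seed=1)
    c = generate_pool_set(3, dem, sel, mu=0.01, L=1, seed=2)
    assert [p.pool_id for p in a] == [0, 1, 2]
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.haplotypes, pb.haplotypes)
    assert any(not np.array_equal(pa.haplotypes, pc.haplotypes)
               for pa, pc in zip(a, c))


def test_sample_individual_hwe(small_neutral_pools):
    pool = next(p for p in small_neutral_pools if p.n_sites > 0)
    rng = np.random.default_rng(0)
    j = int(np.argmax(pool.site_freq))
    f = pool.site_freq[j]
    n = 8000
    h1, h2 = sample_haplotype_pairs(pool, n, rng)
    dos = (h1[:, j].astype(int) + h2[:, j]).astype(int)
    counts = np.bincount(dos, minlength=3)
    exp = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    for obs, e in zip(counts, exp):
        se = np.sqrt(e * (1 - e / n))
        assert abs(obs - e) < 4 * se + 1


def test_sample_individual_phase_sums():
    pool = HaplotypePool(haplotypes=np.array([[1, 0], [0, 1]], np.uint8),
                         site_freq=np.array([0.5, 0.5]),
                         site_selection=np.zeros(2))
    rng = np.random.default_rng(1)
    h1, h2, dos = sample_individual(pool, rng)
    assert np.array_equal(h1 + h2, dos)


def test_single_haplotype_pool_gives_homozygotes():
    pool = HaplotypePool(haplotypes=np.array([[1, 0]], np.uint8),
                         site_freq=np.array([0.9, 0.1]),
                         site_selection=np.zeros(2))
    _, _, dos = sample_individual(pool, np.random.default_rng(0))
    assert dos.tolist() == [2, 0]


def test_sfs_generator_moments():
    rng = np.random.default_rng(12)
    gm = sfs_genotype_generator([0.5], 10000, rng)
    mean_dos = gm.dosages.mean()
    assert abs(mean_dos - 1.0) < 3 * np.sqrt(0.5 / 10000) + 0.02
    f = 0.01
    gm2 = sfs_genotype_generator([f], 10000, rng)
    carrier = (gm2.dosages > 0).mean()
    exp = 1 - (1 - f) ** 2
    assert abs(carrier - exp) < 3 * np.sqrt(exp * (1 - exp) / 10000) + 1e-3


def test_sfs_generator_validation():
    assert sfs_genotype_generator([], 5).n_sites == 0
    with pytest.raises(ValueError):
        sfs_genotype_generator([0.6], 5)
    with pytest.raises(ValueError):
        sfs_genotype_generator([0.0], 5)


def test_rescaled_run_preserves_neutral_sfs_shape():
    """Sizes/c with mu*c reproduce the sample SFS within sampling error."""
    from scipy import stats

    n_samp = 12
    counts = {}
    for label, (N, mu, reps) in {"base": (80, 0.005, 120),
                                 "rescaled": (40, 0.010, 120)}.items():
        dem = DemographyModel(epochs=[(N, 1)], burn_in=12 * N)
        rng = np.random.default_rng(3)
        sfs = np.zeros(n_samp - 1)
        for i in range(reps):
            pool = simulate_haplotype_pool(dem, SelectionModel.neutral(),
                                           mu=mu, L=1, seed=9000 + i)
            idx = rng.choice(pool.n_haplotypes, n_samp, replace=False)
            cnt = pool.haplotypes[idx].sum(axis=0)
            seg = (cnt > 0) & (cnt < n_samp)
            for c in cnt[seg]:
                sfs[c - 1] += 1
        counts[label] = sfs
    tab = np.vstack([counts["base"], counts["rescaled"]])
    # lump classes >= 6 to keep expected cells populated
    tab = np.hstack([tab[:, :5], tab[:, 5:].sum(axis=1, keepdims=True)])
    _, p, _, _ = stats.chi2_contingency(tab)
    assert p > 0.001


def test_site_overflow_guard():
    from kbac.popgen import SiteOverflowError

    dem = DemographyModel(epochs=[(50, 1)], burn_in=200)
    with pytest.raises(SiteOverflowError):
        simulate_haplotype_pool(dem, SelectionModel.neutral(), mu=2.0, L=1,
                                seed=0, max_sites=50)
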