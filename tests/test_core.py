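"""KBAC statistic, permutation and Monte Carlo significance, and power."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kbac.core import (kbac_statistic, monte_carlo_power, monte_carlo_pvalue,
                       permutation_pvalue, permutation_pvalue_from_tally)
from kbac.data import GenotypeMatrix, PatternTally, PhenotypeTable, tally_patterns
from kbac.kernels import kernel_weights

from conftest import random_tally


def exhaustive_permutation_p(gm, ph, kernel="hypergeometric", sided="two"):
    """Oracle: exact p over all case-label assignments (small N only)."""
    N = gm.n_individuals
    NA = ph.n_cases
    t_obs = tally_patterns(gm, ph)
    s_obs = kbac_statistic(t_obs, kernel, sided)
    hits = total = 0
    for combo in itertools.combinations(range(N), NA):
        status = np.zeros(N, dtype=int)
        status[list(combo)] = 1
        t = tally_patterns(gm, PhenotypeTable(status=status))
        s = kbac_statistic(t, kernel, sided)
        hits += s >= s_obs - 1e-12
        total += 1
    return hits / total


def test_worked_example_statistic(worked_example):
    gm, ph = worked_example
    t = tally_patterns(gm, ph)
    s1, w = kbac_statistic(t, "hypergeometric", "one", return_weights=True)
    # patterns sorted lexicographically: (0,1) control singleton, (1,0) cases
    np.testing.assert_allclose(w, [0.5, 1.0], atol=1e-12)
    assert s1 == pytest.approx(0.375, abs=1e-12)
    assert kbac_statistic(t, "hypergeometric", "two") == pytest.approx(
        0.140625, abs=1e-12)


def test_balanced_patterns_zero_statistic():
    # every pattern split proportionally between cases and controls -> S = 0
    dos = np.array([[1, 0]] * 4 + [[0, 1]] * 2 + [[0, 0]] * 6)
    status = [1, 1, 0, 0, 1, 0, 1, 1, 1, 0, 0, 0]
    t = tally_patterns(GenotypeMatrix(dosages=dos, site_ids=["a", "b"]),
                       PhenotypeTable(status=status))
    assert kbac_statistic(t, sided="one") == pytest.approx(0.0, abs=1e-12)


def test_statistic_invariant_to_site_order(worked_example):
    gm, ph = worked_example
    flipped = GenotypeMatrix(dosages=gm.dosages[:, ::-1], site_ids=["b", "a"])
    assert kbac_statistic(tally_patterns(gm, ph)) == pytest.approx(
        kbac_statistic(tally_patterns(flipped, ph)), abs=1e-14)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_two_sided_is_square_of_one_sided(seed):
    t = random_tally(np.random.default_rng(seed))
    s1 = kbac_statistic(t, sided="one")
    s2 = kbac_statistic(t, sided="two")
    assert s2 == pytest.approx(s1 * s1, rel=1e-12, abs=1e-14)


def test_permutation_matches_exhaustive_oracle(worked_example):
    gm, ph = worked_example
    p_exact = exhaustive_permutation_p(gm, ph)
    res = permutation_pvalue(gm, ph, B=20000, seed=3)
    # B = 20000 resolves p to ~ +/-3*sqrt(p(1-p)/B) ~ 0.009
    assert res.p_value == pytest.approx(p_exact, abs=0.01)


def test_permutation_all_wildtype():
    gm = GenotypeMatrix(dosages=np.zeros((8, 0), np.int8), site_ids=[])
    ph = PhenotypeTable(status=[1] * 4 + [0] * 4)
    res = permutation_pvalue(gm, ph, B=100, seed=0)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_monte_carlo_close_to_permutation_moderate_n():
    rng = np.random.default_rng(5)
    # one moderately sized null dataset: MC and permutation p agree
    dos = (rng.random((400, 6)) < 0.01).astype(np.int8)
    ph = PhenotypeTable(status=rng.permutation([1] * 200 + [0] * 200))
    gm = GenotypeMatrix(dosages=dos, site_ids=[f"s{i}" for i in range(6)])
    t = tally_patterns(gm, ph)
    p_mc = monte_carlo_pvalue(t, M=4000, seed=1).p_value
    p_pm = permutation_pvalue_from_tally(t, B=4000, seed=2).p_value
    assert p_mc == pytest.approx(p_pm, abs=0.05)


def test_seed_reproducibility(worked_example):
    gm, ph = worked_example
    a = permutation_pvalue(gm, ph, B=500, seed=11).p_value
    b = permutation_pvalue(gm, ph, B=500, seed=11).p_value
    assert a == b


def test_monte_carlo_power_null_equals_alpha():
    # identical case/control frequencies: rejection rate ~ alpha
    f = np.array([0.02, 0.01, 0.005])
    pw = monte_carlo_power(f, f, NA=500, NU=500, alpha=0.05,
                           M1=60, M2=100, M0=400, seed=9)
    assert pw == pytest.approx(0.05, abs=0.03)


def test_monte_carlo_power_alpha_one():
    f = np.array([0.02])
    assert monte_carlo_power(f, 2 * f, 100, 100, alpha=1.0) == 1.0


def brute_force_power(pA, pU, NA, NU, alpha, reps, seed):
    """Dataset-level oracle: simulate full case-control draws, test each."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        nA_carr = rng.binomial(NA, pA)
        nU_carr = rng.binomial(NU, pU)
        if nA_carr + nU_carr == 0:
            continue
        t = PatternTally(patterns=np.array([[1]]),
                         n=[nA_carr + nU_carr], nA=[nA_carr], nU=[nU_carr],
                         n0=NA + NU - nA_carr - nU_carr,
                         nA0=NA - nA_carr, nU0=NU - nU_carr,
                         N=NA + NU, NA=NA, NU=NU)
        p = monte_carlo_pvalue(t, M=1500, seed=rng.integers(2**31)).p_value
        rejections += p <= alpha
    return rejections / reps


def test_monte_carlo_power_matches_brute_force():
    """Single-pattern alternative: Algorithm-2 power vs full-dataset oracle."""
    pA, pU, NA, NU, alpha = 0.05, 0.01, 1000, 1000, 0.01
    pw = monte_carlo_power(np.array([pA]), np.array([pU]), NA, NU, alpha,
                           M1=80, M2=150, M0=1200, seed=21)
    oracle = brute_force_power(pA, pU, NA, NU, alpha, reps=400, seed=22)
    assert pw == pytest.approx(oracle, abs=0.03)


def test_monte_carlo_power_rejects_invalid_frequencies():
    with pytest.raises(ValueError):
        monte_carlo_power(np.array([0.6, 0.6]), np.array([0.0, 0.0]),
                          100, 100, alpha=0.05)
    with pytest.raises(ValueError):
        monte_carlo_power(np.array([0.02]), np.array([0.01]), 10, 10, alpha=0.0)
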