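"""Comparator rare-variant tests: CMC collapsing, WSS, and RVE.

These are the three benchmark methods the adaptive-cluster test is evaluated
against:

* **CMC** collapses all rare sites to a carrier indicator and compares carrier
  frequencies between cases and controls with Pearson's chi-square (1 df,
  analytic p-value, no continuity correction).
* **WSS** (Madsen-Browning weighted sum) scores each individual by the sum of
  dosages weighted by 1/sqrt(N q(1-q)), q the +1/+2-smoothed control minor
  allele frequency, and uses the sum of case ranks of the scores as the
  statistic; significance by label permutation with the control-frequency
  weights recomputed per permutation.
* **RVE** compares carriers of case-exclusive variants among cases with
  carriers of control-exclusive variants among controls via a two-sided
  Fisher exact test; the empirical p-value comes from label permutations in
  which site exclusivity is re-determined for each permuted labelling.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .core import TestResult, _empirical_p
from .data import GenotypeMatrix, PhenotypeTable


def _check(gm: GenotypeMatrix, ph: PhenotypeTable) -> None:
    if gm.n_individuals != len(ph.status):
        raise ValueError("genotype/phenotype row mismatch")
    if ph.n_cases == 0 or ph.n_controls == 0:
        raise ValueError("degenerate phenotype: need both cases and controls")


def carrier_table(gm: GenotypeMatrix, ph: PhenotypeTable) -> np.ndarray:
    """2x2 contingency: (carrier, non-carrier) x (case, control)."""
    carrier = (gm.dosages > 0).any(axis=1) if gm.n_sites else \
        np.zeros(gm.n_individuals, bool)
    y = ph.status.astype(bool)
    a = int((carrier & y).sum())
    b = int((carrier & ~y).sum())
    return np.array([[a, b], [ph.n_cases - a, ph.n_controls - b]])


def cmc_test(gm: GenotypeMatrix, ph: PhenotypeTable) -> TestResult:
    """Collapsing test: Pearson chi-square on the carrier 2x2 table."""
    _check(gm, ph)
    tab = carrier_table(gm, ph)
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        warnings.warn("zero margin in carrier table; p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, method="CMC")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return TestResult(statistic=float(chi2), p_value=max(float(p), np.nextafter(0, 1)),
                      method="CMC")


def _wss_case_rank_sum(dosages: np.ndarray, y: np.ndarray, NU: int) -> float:
    """Sum of case ranks of control-frequency-weighted mutation scores."""
    m_u = dosages[y == 0].sum(axis=0)
    q = (m_u + 1.0) / (2.0 * NU + 2.0)
    w = 1.0 / np.sqrt(len(y) * q * (1.0 - q))
    scores = dosages @ w
    ranks = stats.rankdata(scores)
    return float(ranks[y == 1].sum())


def wss_test(gm: GenotypeMatrix, ph: PhenotypeTable, B: int = 5000,
             seed: int | np.random.Generator = 0,
             sided: str = "two") -> TestResult:
    """Madsen-Browning weighted-sum rank test with permutation p-value."""
    _check(gm, ph)
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    y = ph.status
    NA, NU = ph.n_cases, ph.n_controls
    N = len(y)
    if gm.n_sites == 0 or not gm.dosages.any():
        return TestResult(statistic=0.0, p_value=1.0, method="WSS",
                          sided=sided, resamples=B)
    X = gm.dosages.astype(float)
    s_obs = _wss_case_rank_sum(X, y, NU)
    center = NA * (N + 1) / 2.0  # permutation mean of the case rank sum
    # all permutations at once: weights from permuted control frequencies,
    # then ranks of the weighted scores, column per permutation.  Non-carriers
    # score exactly 0 under every weighting, so only carriers need ranking;
    # the zero block contributes its average tied rank (n0+1)/2.
    Y = rng.permuted(np.tile(y, (B, 1)), axis=1)
    m_u = (1 - Y) @ X  # (B, sites) control minor-allele counts
    q = (m_u + 1.0) / (2.0 * NU + 2.0)
    W = 1.0 / np.sqrt(N * q * (1.0 - q))
    car = X.sum(axis=1) > 0
    n0 = int(N - car.sum())
    scores_car = X[car] @ W.T  # (carriers, B)
    ranks_car = stats.rankdata(scores_car, axis=0) + n0
    Yc = Y[:, car].astype(float)
    case_car = Yc.sum(axis=1)
    s_perm = (NA - case_car) * (n0 + 1) / 2.0 \
        + np.einsum("cb,bc->b", ranks_car, Yc)
    if sided == "one":
        hits = int((s_perm >= s_obs - 1e-9).sum())
    else:
        hits = int((np.abs(s_perm - center) >= abs(s_obs - center) - 1e-9).sum())
    return TestResult(statistic=s_obs, p_value=_empirical_p(hits, B),
                      method="WSS", sided=sided, resamples=B)


def _rve_fisher_p(dosages_pos: np.ndarray, y: np.ndarray, NA: int, NU: int,
                  cache: dict) -> float:
    """Two-sided Fisher p of the exclusive-carrier 2x2 for one labelling."""
    case_cnt = y @ dosages_pos
    tot_cnt = dosages_pos.sum(axis=0)
    case_excl = (case_cnt == tot_cnt) & (tot_cnt > 0)
    ctrl_excl = case_cnt == 0
    a = int((dosages_pos[:, case_excl].any(axis=1) & (y == 1)).sum()) \
        if case_excl.any() else 0
    b = int((dosages_pos[:, ctrl_excl].any(axis=1) & (y == 0)).sum()) \
        if ctrl_excl.any() else 0
    key = (a, b)
    if key not in cache:
        cache[key] = stats.fisher_exact(
            [[a, NA - a], [b, NU - b]], alternative="two-sided")[1]
    return cache[key]


def rve_test(gm: GenotypeMatrix, ph: PhenotypeTable, B: int = 5000,
             seed: int | np.random.Generator = 0) -> TestResult:
    """Exclusive-variant test with exclusivity recomputed per permutation.

    A variant observed in both a case and a control is excluded from both
    exclusive sets.  The reported statistic is the observed Fisher two-sided
    p-value; the reported p-value is the permutation fraction of labelings
    with a Fisher p at least as extreme.
    """
    _check(gm, ph)
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    y = ph.status.astype(np.int64)
    NA, NU = ph.n_cases, ph.n_controls
    if gm.n_sites == 0:
        return TestResult(statistic=1.0, p_value=1.0, method="RVE", resamples=B)
    pos = (gm.dosages > 0).astype(np.int64)
    cache: dict = {}
    p_obs = _rve_fisher_p(pos, y, NA, NU, cache)
    hits = 0
    for _ in range(B):
        yp = rng.permutation(y)
        hits += _rve_fisher_p(pos, yp, NA, NU, cache) <= p_obs + 1e-12
    return TestResult(statistic=float(p_obs), p_value=_empirical_p(hits, B),
                      method="RVE", resamples=B)
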