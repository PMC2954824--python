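"""The KBAC statistic and its permutation / Monte Carlo significance.

The one-sided statistic aggregates, over non-wild-type multi-site genotype
patterns, the kernel-weighted difference of pattern frequencies between cases
and controls::

    S = sum_i  w_i * (nA_i / NA - nU_i / NU)

with the wild-type pattern excluded (its contribution is a constant offset
that cancels in the score function).  The two-sided statistic is S**2.  The
statistic has no closed-form null distribution; p-values are obtained either
by label permutation or by the Monte Carlo approximation that redraws each
pattern's case count as an independent Binomial(n_i, NA/N) -- valid because
rare patterns are approximately independent given the pattern counts.

Both resampling schemes recompute the adaptive weights inside every
iteration: weighting is phenotype-dependent, and freezing the observed
weights would inflate type I error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, PatternTally, PhenotypeTable, tally_patterns
from .kernels import kernel_weights, weight_table


@dataclass
class TestResult:
    """Outcome of one association test on one region."""

    statistic: float
    p_value: float
    method: str
    kernel: str | None = None
    sided: str = "two"
    resamples: int = 0
    seed: int | None = None
    per_pattern_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def _statistic_from_counts(nA_counts: np.ndarray, table: np.ndarray,
                           n: np.ndarray, NA: int, NU: int,
                           sided: str) -> np.ndarray:
    """KBAC statistic for one or many case-count vectors via table lookup.

    ``nA_counts`` has shape (..., k); ``table`` is a weight lookup from
    :func:`kbac.kernels.weight_table`.
    """
    w = np.take_along_axis(
        np.broadcast_to(table, nA_counts.shape[:-1] + table.shape),
        nA_counts[..., None], axis=-1)[..., 0]
    s = (w * (nA_counts / NA - (n - nA_counts) / NU)).sum(axis=-1)
    return s * s if sided == "two" else s


def kbac_statistic(t: PatternTally, kernel: str = "hypergeometric",
                   sided: str = "two", *, return_weights: bool = False):
    """KBAC statistic of an observed tally (see module docstring for the form)."""
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if t.k == 0:
        warnings.warn("no rare-variant patterns; statistic is 0", stacklevel=2)
        return (0.0, np.zeros(0)) if return_weights else 0.0
    w = np.asarray(kernel_weights(t.n, t.nA, t.N, t.NA, kernel))
    s = float((w * (t.nA / t.NA - t.nU / t.NU)).sum())
    s = s * s if sided == "two" else s
    return (s, w) if return_weights else s


def _empirical_p(n_ge: int, resamples: int) -> float:
    return (1.0 + n_ge) / (resamples + 1.0)


def permutation_pvalue(gm: GenotypeMatrix, ph: PhenotypeTable,
                       kernel: str = "hypergeometric", sided: str = "two",
                       B: int = 5000, seed: int | np.random.Generator = 0
                       ) -> TestResult:
    """Empirical KBAC p-value by case/control label permutation.

    Labels are permuted B times; pattern case counts, kernel weights and the
    statistic are recomputed for each permutation.  Because the pattern
    partition of individuals is fixed under permutation, shuffling labels is
    carried out equivalently (and exactly) at the tally level: the permuted
    case counts across patterns follow a multivariate hypergeometric draw of
    NA cases over the pattern classes, the wild-type class included.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    t = tally_patterns(gm, ph)
    return permutation_pvalue_from_tally(t, kernel, sided, B, seed)


def permutation_pvalue_from_tally(t: PatternTally,
                                  kernel: str = "hypergeometric",
                                  sided: str = "two", B: int = 5000,
                                  seed: int | np.random.Generator = 0
                                  ) -> TestResult:
    rng = np.random.default_rng(seed)
    s_obs, w_obs = kbac_statistic(t, kernel, sided, return_weights=True)
    if t.k == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="KBAC-perm",
                          kernel=kernel, sided=sided, resamples=B)
    table = weight_table(t.n, t.N, t.NA, kernel)
    colors = np.append(t.n, t.n0)
    # one label permutation == one multivariate-hypergeometric draw of the
    # case labels over the pattern classes (wild-type class included)
    draws = rng.multivariate_hypergeometric(colors, t.NA, size=B)
    s_perm = _statistic_from_counts(draws[:, : t.k], table, t.n, t.NA, t.NU, sided)
    p = _empirical_p(int((s_perm >= s_obs - 1e-12).sum()), B)
    return TestResult(statistic=float(s_obs), p_value=p, method="KBAC-perm",
                      kernel=kernel, sided=sided, resamples=B,
                      per_pattern_weights=w_obs)


def monte_carlo_pvalue(t: PatternTally, kernel: str = "hypergeometric",
                       sided: str = "two", M: int = 10000,
                       seed: int | np.random.Generator = 0) -> TestResult:
    """Monte Carlo KBAC p-value: nA_i* ~ Binomial(n_i, NA/N) independently."""
    if M < 100:
        raise ValueError("M must be >= 100")
    rng = np.random.default_rng(seed)
    s_obs, w_obs = kbac_statistic(t, kernel, sided, return_weights=True)
    if t.k == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="KBAC-mc",
                          kernel=kernel, sided=sided, resamples=M)
    table = weight_table(t.n, t.N, t.NA, kernel)
    draws = rng.binomial(t.n, t.NA / t.N, size=(M, t.k))
    s_mc = _statistic_from_counts(draws, table, t.n, t.NA, t.NU, sided)
    p = _empirical_p(int((s_mc >= s_obs - 1e-12).sum()), M)
    return TestResult(statistic=float(s_obs), p_value=p, method="KBAC-mc",
                      kernel=kernel, sided=sided, resamples=M,
                      per_pattern_weights=w_obs)


def monte_carlo_power(freqA: np.ndarray, freqU: np.ndarray, NA: int, NU: int,
                      alpha: float = 0.01, M1: int = 100, M2: int = 200,
                      M0: int = 1000, seed: int | np.random.Generator = 0,
                      kernel: str = "hypergeometric", sided: str = "two"
                      ) -> float:
    """Monte Carlo power of KBAC under specified pattern frequencies.

    ``freqA``/``freqU`` are the multi-site-genotype pattern frequencies in
    cases and controls (the remainder to 1 is wild-type).  For each of M1
    multinomial draws of total pattern counts n ~ Multinomial(N, q) with
    q_i = (NA*pA_i + NU*pU_i)/N, the conditional null (1-alpha) quantile of
    the statistic is estimated from M0 null binomial redraws; M2 alternative
    redraws with nA_i* ~ Binomial(n_i, pi_i), pi_i = NA*pA_i/(NA*pA_i+NU*pU_i),
    are compared against it.  Unconditional power averages the conditional
    rejection rates over the M1 count vectors.
    """
    freqA = np.asarray(freqA, dtype=float)
    freqU = np.asarray(freqU, dtype=float)
    if freqA.shape != freqU.shape:
        raise ValueError("freqA and freqU must have the same length")
    if freqA.sum() > 1 + 1e-12 or freqU.sum() > 1 + 1e-12:
        raise ValueError("pattern frequencies must sum to <= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha == 1.0:
        return 1.0
    rng = np.random.default_rng(seed)
    N = NA + NU
    q = (NA * freqA + NU * freqU) / N
    if q.sum() > 1 + 1e-12:
        raise ValueError("mixture pattern frequencies sum to > 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(q > 0, NA * freqA / (N * q), 0.0)
    rates = np.empty(M1)
    for m in range(M1):
        counts = rng.multinomial(N, np.append(q, 1.0 - q.sum()))
        n = counts[:-1]
        seg = n > 0
        n_seg = n[seg]
        if n_seg.size == 0:
            rates[m] = 0.0
            continue
        table = weight_table(n_seg, N, NA, kernel)
        null_draws = rng.binomial(n_seg, NA / N, size=(M0, len(n_seg)))
        s_null = _statistic_from_counts(null_draws, table, n_seg, NA, NU, sided)
        crit = np.quantile(s_null, 1.0 - alpha)
        alt_draws = rng.binomial(n_seg, pi[seg], size=(M2, len(n_seg)))
        s_alt = _statistic_from_counts(alt_draws, table, n_seg, NA, NU, sided)
        rates[m] = (s_alt > crit).mean()
    return float(rates.mean())
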