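"""Adaptive kernel weights for multi-site genotype patterns.

Each non-wild-type pattern i, carried by ``n_i`` individuals of whom ``nA_i``
are cases, receives a weight equal to the null cumulative probability of
observing at most ``nA_i`` cases among its carriers.  Conditional on the
pattern counts and the numbers of cases and controls, that null distribution
is hypergeometric (exact), marginally binomial, or asymptotically normal; the
three kernels are asymptotically equivalent and the hypergeometric kernel is
the default.  Under the null hypothesis the weights are (asymptotically)
uniform on [0, 1]; case-enriched patterns are up-weighted under the
alternative.  The weight is a monotone function of the pattern's sample risk
-- the case fraction among its carriers relative to the overall case fraction
-- so weighting by cumulative probability of the observed sample risk and of
the observed case count coincide.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

KERNELS = ("hypergeometric", "binomial", "normal")


def sample_risk(nA, n, NA, N):
    """Per-pattern sample risk (nA_i/n_i) / (NA/N).

    A consistent estimator of P(affected | pattern) / P(affected) under
    case-control sampling; 1 for patterns split proportionally between cases
    and controls, >1 for case-enriched patterns.
    """
    nA = np.asarray(nA, dtype=float)
    n = np.asarray(n, dtype=float)
    if NA <= 0 or NA >= N:
        raise ValueError("need 0 < NA < N")
    return (nA / n) / (NA / N)


def kernel_weight_hypergeometric(n_i, nA_i, N, NA):
    """Inclusive hypergeometric CDF of the pattern's case count.

    w = sum_{u<=nA_i} C(n_i,u) C(N-n_i, NA-u) / C(N, NA), evaluated through
    scipy's log-space hypergeometric CDF (numerically stable).
    Accepts scalars or arrays for ``n_i``/``nA_i``.
    """
    n_i = np.asarray(n_i)
    nA_i = np.asarray(nA_i)
    if not (0 < NA < N):
        raise ValueError("need 0 < NA < N")
    if (n_i < 0).any() or (n_i > N).any() or (nA_i < 0).any() or (nA_i > n_i).any():
        raise ValueError("need 0 <= nA_i <= n_i <= N")
    return stats.hypergeom.cdf(nA_i, N, NA, n_i)


def kernel_weight_binomial(n_i, nA_i, p):
    """Inclusive binomial CDF: w = sum_{u<=nA_i} C(n_i,u) p^u (1-p)^(n_i-u)."""
    n_i = np.asarray(n_i)
    nA_i = np.asarray(nA_i)
    if not 0 < p < 1:
        raise ValueError("p must be in (0,1)")
    if (nA_i < 0).any() or (nA_i > n_i).any():
        raise ValueError("need 0 <= nA_i <= n_i")
    return stats.binom.cdf(nA_i, n_i, p)


def kernel_weight_normal(n_i, nA_i, N, NA):
    """Normal-approximation weight: the large-n_i limit of the discrete kernels.

    Phi((nA_i + 1/2 - n_i p) / sqrt(n_i p (1-p))) with p = NA/N -- the
    standardized per-pattern case count with a half-integer continuity
    correction, so that the normal kernel approximates the *inclusive*
    discrete CDF (without the correction the gap at the distribution's centre
    is half a probability mass, ~0.03 even at n_i = 200).  Asymptotically
    this is Phi of the standardized case fraction.
    """
    n_i = np.asarray(n_i, dtype=float)
    nA_i = np.asarray(nA_i, dtype=float)
    if (n_i < 1).any():
        raise ValueError("n_i must be >= 1")
    p = NA / N
    if not 0 < p < 1:
        raise ValueError("need 0 < NA < N")
    z = (nA_i + 0.5 - n_i * p) / np.sqrt(n_i * p * (1 - p))
    return stats.norm.cdf(z)


def kernel_weights(n, nA, N, NA, kernel: str = "hypergeometric"):
    """Weights for a vector of patterns under the chosen kernel."""
    if kernel == "hypergeometric":
        return kernel_weight_hypergeometric(n, nA, N, NA)
    if kernel == "binomial":
        return kernel_weight_binomial(n, nA, NA / N)
    if kernel == "normal":
        return kernel_weight_normal(n, nA, N, NA)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


def weight_table(n, N, NA, kernel: str = "hypergeometric") -> np.ndarray:
    """Precomputed weight lookup table over all possible case counts.

    Returns a (k, max(n)+1) array T with T[i, a] the weight of pattern i when
    a of its n[i] carriers are cases (entries with a > n[i] are unused).  The
    table depends only on (n, N, NA), which permutation and Monte Carlo
    resampling hold fixed, so resampled statistics reduce to table lookups
    while the weights remain fully recomputed for every resample.
    """
    n = np.asarray(n, dtype=np.int64)
    if len(n) == 0:
        return np.zeros((0, 1))
    amax = int(n.max())
    a = np.arange(amax + 1)
    grid_n = np.repeat(n[:, None], amax + 1, axis=1)
    grid_a = np.minimum(np.broadcast_to(a, grid_n.shape), grid_n)
    return np.asarray(kernel_weights(grid_n, grid_a, N, NA, kernel))
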