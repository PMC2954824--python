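"""Forward-time Wright-Fisher simulation and SFS-driven genotype generation.

Haplotype pools for a 1500-bp coding locus are produced by an individual-based
infinite-sites Wright-Fisher simulation with diploid viability selection and
no intralocus recombination.  Each generation: new mutations arrive as a
Poisson(2 N mu L) influx at fresh sites, each with a selection coefficient
drawn from a gamma distribution of fitness effects (DFE); haplotypes are
paired at random into diploids whose fitness is multiplicative over sites
(1, 1-h*s, 1-s for the three genotype classes); the next generation's 2N
haplotypes are drawn from parents proportionally to fitness; fixed and lost
sites are pruned.  Demography is an ordered list of (diploid size, duration)
epochs -- a two-epoch expansion or a multi-epoch bottleneck.

Population sizes of tens of thousands are out of reach for a desk run, so a
standard rescaling is supported: sizes and durations shrink by a factor c
while mu and s grow by c, preserving the population-scaled parameters theta,
N*s and drift time (selection coefficients are clamped below 0.95 after
rescaling; mutations that strong are effectively never observed segregating
either way).

An alternative generator bypasses population genetics entirely: given a set
of per-site minor-allele frequencies (a site frequency spectrum realisation),
genotypes are drawn independently per site as Binomial(2, f), emulating a
region in linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix


@dataclass
class DemographyModel:
    """Ordered (diploid size, duration in generations) epochs, oldest first.

    ``burn_in`` generations at the first epoch's size precede the epoch
    schedule so the ancestral population starts near mutation-selection-drift
    equilibrium; the default of 10x the first epoch's diploid size is
    conservative for a non-recombining locus.
    """

    epochs: list[tuple[int, int]]
    burn_in: int | None = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("need at least one epoch")
        for size, dur in self.epochs:
            if size < 2:
                raise ValueError("population sizes must be >= 2")
            if dur < 1:
                raise ValueError("epoch durations must be >= 1")
        if self.burn_in is None:
            self.burn_in = 10 * self.epochs[0][0]

    @classmethod
    def two_epoch(cls, n_ancestral: int, n_current: int,
                  duration: int, burn_in: int | None = None
                  ) -> "DemographyModel":
        """Instantaneous size change ``duration`` generations before present."""
        return cls(epochs=[(n_ancestral, 1), (n_current, duration)],
                   burn_in=burn_in if burn_in is not None else 10 * n_ancestral)

    def rescaled(self, c: float) -> "DemographyModel":
        if c <= 0:
            raise ValueError("rescaling factor must be positive")
        return DemographyModel(
            epochs=[(max(2, round(s / c)), max(1, round(d / c)))
                    for s, d in self.epochs],
            burn_in=max(1, round(self.burn_in / c)))


@dataclass
class SelectionModel:
    """Gamma DFE of deleterious fitness effects.

    ``dfe_shape``/``dfe_scale`` parameterise the gamma distribution of the
    (positive) selection coefficient s of a new deleterious mutation;
    ``dominance`` maps s to the heterozygote disadvantage h*s;
    ``fraction_neutral`` mutations carry s = 0.
    """

    dfe_shape: float = 0.184
    dfe_scale: float = 0.234  # mean s = shape*scale ~ 0.043
    dominance: float = 0.5
    fraction_neutral: float = 0.0

    def __post_init__(self) -> None:
        if self.dfe_shape <= 0 or self.dfe_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0 <= self.dominance <= 1:
            raise ValueError("dominance must be in [0,1]")
        if not 0 <= self.fraction_neutral <= 1:
            raise ValueError("fraction_neutral must be in [0,1]")

    @classmethod
    def neutral(cls) -> "SelectionModel":
        return cls(dfe_shape=1.0, dfe_scale=1e-12, fraction_neutral=1.0)

    def draw_s(self, size: int, rng: np.random.Generator,
               rescale: float = 1.0, s_max: float = 0.95) -> np.ndarray:
        s = rng.gamma(self.dfe_shape, self.dfe_scale, size=size) * rescale
        if self.fraction_neutral > 0:
            s[rng.random(size) < self.fraction_neutral] = 0.0
        return np.minimum(s, s_max)


@dataclass
class HaplotypePool:
    """Final-generation haplotypes of one simulated locus."""

    haplotypes: np.ndarray  # (2N, S) uint8
    site_freq: np.ndarray  # derived-allele frequency per site, in (0,1)
    site_selection: np.ndarray
    locus_length: int = 1500
    pool_id: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.site_freq = np.asarray(self.site_freq, dtype=float)
        if ((self.site_freq <= 0) | (self.site_freq >= 1)).any():
            raise ValueError("site frequencies must be strictly inside (0,1)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def minor_freq(self) -> np.ndarray:
        """Minor-allele frequency per site (derived allele may be major)."""
        return np.minimum(self.site_freq, 1.0 - self.site_freq)


class SiteOverflowError(RuntimeError):
    pass


def simulate_haplotype_pool(dem: DemographyModel, sel: SelectionModel,
                            mu: float = 1.8e-8, L: int = 1500,
                            seed: int | np.random.Generator = 0, *,
                            rescale: float = 1.0, max_sites: int = 20000,
                            pool_id: int = 0) -> HaplotypePool:
    """Run one forward simulation and return the final generation's haplotypes.

    ``mu`` is the per-bp per-generation mutation rate before rescaling;
    ``rescale`` shrinks population sizes and durations by c and multiplies mu
    and s by c.
    """
    if mu <= 0 or L <= 0:
        raise ValueError("mu and L must be positive")
    rng = np.random.default_rng(seed)
    dem_r = dem.rescaled(rescale) if rescale != 1.0 else dem
    mu_hap = mu * L * rescale  # per-haplotype per-generation locus rate

    n0 = dem_r.epochs[0][0]
    H = np.zeros((2 * n0, 0), dtype=np.uint8)
    s_coef = np.zeros(0)
    schedule = [(n0, dem_r.burn_in)] + list(dem_r.epochs)
    for size, duration in schedule:
        for _ in range(duration):
            H, s_coef = _one_generation(H, s_coef, size, mu_hap, sel,
                                        rescale, rng)
            if H.shape[1] > max_sites:
                raise SiteOverflowError(
                    f"{H.shape[1]} segregating sites exceed cap {max_sites}; "
                    "increase the rescaling factor")
    freq = H.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    return HaplotypePool(haplotypes=H[:, keep], site_freq=freq[keep],
                         site_selection=s_coef[keep], locus_length=L,
                         pool_id=pool_id)


def _one_generation(H: np.ndarray, s_coef: np.ndarray, n_next: int,
                    mu_hap: float, sel: SelectionModel, rescale: float,
                    rng: np.random.Generator):
    n_hap = H.shape[0]
    n_par = n_hap // 2
    # random monogamous pairing of the parental haplotypes into diploids
    order = rng.permutation(n_hap)
    h1, h2 = order[:n_par], order[n_par:2 * n_par]
    if s_coef.size:
        dos = H[h1].astype(np.int8) + H[h2].astype(np.int8)
        log_het = np.log1p(-sel.dominance * s_coef)
        log_hom = np.log1p(-s_coef)
        logw = (dos == 1) @ log_het + (dos == 2) @ log_hom
        w = np.exp(logw - logw.max())
        w /= w.sum()
    else:
        w = np.full(n_par, 1.0 / n_par)
    # each offspring haplotype: fitness-weighted parent, then one of its two
    # haplotypes uniformly (no recombination: the haplotype copies whole)
    parents = rng.choice(n_par, size=2 * n_next, p=w)
    which = rng.integers(0, 2, size=2 * n_next)
    src = np.where(which == 0, h1[parents], h2[parents])
    H_next = H[src]
    # infinite-sites mutation influx at fresh sites
    n_mut = rng.poisson(2 * n_next * mu_hap)
    if n_mut:
        cols = np.zeros((2 * n_next, n_mut), dtype=np.uint8)
        cols[rng.integers(0, 2 * n_next, size=n_mut), np.arange(n_mut)] = 1
        H_next = np.concatenate([H_next, cols], axis=1)
        s_coef = np.concatenate([s_coef, sel.draw_s(n_mut, rng, rescale)])
    # prune fixed and lost sites
    if H_next.shape[1]:
        tot = H_next.sum(axis=0)
        keep = (tot > 0) & (tot < H_next.shape[0])
        if not keep.all():
            H_next = H_next[:, keep]
            s_coef = s_coef[keep]
    return np.ascontiguousarray(H_next), s_coef


def generate_pool_set(n_pools: int, dem: DemographyModel, sel: SelectionModel,
                      mu: float = 1.8e-8, L: int = 1500,
                      seed: int = 0, rescale: float = 1.0,
                      **kwargs) -> list[HaplotypePool]:
    """Independent haplotype pools with per-pool seeds spawned from ``seed``."""
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    seqs = np.random.SeedSequence(seed).spawn(n_pools)
    return [simulate_haplotype_pool(dem, sel, mu, L,
                                    np.random.default_rng(s),
                                    rescale=rescale, pool_id=i, **kwargs)
            for i, s in enumerate(seqs)]


def sample_individual(pool: HaplotypePool, rng: np.random.Generator):
    """Pair two uniformly drawn haplotypes; returns (hap1, hap2, dosage)."""
    i, j = rng.integers(0, pool.n_haplotypes, size=2)
    h1 = pool.haplotypes[i]
    h2 = pool.haplotypes[j]
    return h1, h2, h1.astype(np.int8) + h2.astype(np.int8)


def sample_haplotype_pairs(pool: HaplotypePool, n: int,
                           rng: np.random.Generator):
    """Vectorised draw of ``n`` individuals: (H1, H2) haplotype matrices."""
    idx = rng.integers(0, pool.n_haplotypes, size=(2, n))
    return pool.haplotypes[idx[0]], pool.haplotypes[idx[1]]


def load_site_frequencies(path: str) -> np.ndarray:
    """Read a one-column TSV of per-site minor-allele frequencies."""
    f = np.loadtxt(path, ndmin=1)
    if f.ndim != 1:
        raise ValueError("frequency file must hold a single column")
    if f.size and (((f <= 0) | (f > 0.5)).any()):
        raise ValueError("site frequencies must be in (0, 0.5]")
    return f


def sfs_genotype_generator(site_freqs, n: int,
                           rng: int | np.random.Generator = 0
                           ) -> GenotypeMatrix:
    """Unphased genotypes from per-site frequencies, sites independent.

    Each site's dosage is Binomial(2, f) -- Hardy-Weinberg within site,
    linkage equilibrium across sites.
    """
    rng = np.random.default_rng(rng)
    f = np.asarray(site_freqs, dtype=float)
    if f.size and (((f <= 0) | (f > 0.5)).any()):
        raise ValueError("site frequencies must be in (0, 0.5]")
    dosages = rng.binomial(2, f, size=(n, f.size)).astype(np.int8)
    return GenotypeMatrix(dosages=dosages,
                          site_ids=[f"s{i}" for i in range(f.size)],
                          site_maf=f)
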