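"""Disease-status assignment under linear log-odds models with ascertainment.

Case-control status is assigned from multi-site genotypes through a linear
log-odds (logistic) model: the disease log-odds of an individual is the
baseline log-odds plus the sum, over causal rare alleles carried, of the log
of the allele's effective odds ratio.  Four model kinds are supported:

* ``main_fixed`` -- every causal allele has the same OR (default 3.0).
* ``main_variable`` -- per-site ORs inversely related to MAF, spanning 2-20.
* ``within_gene`` -- a causal rare allele acts (OR 3) only in cis with the
  minor allele of one chosen common site on the same haplotype, emulating a
  promoter-variant x coding-variant interaction; requires phase.
* ``between_gene`` -- two unlinked genes: causal alleles in the high-risk
  gene 1 always act (OR 4); causal alleles in gene 2 act (OR 2) only when no
  causal gene-1 allele is present, emulating a shared-pathway epistasis.

Individuals are drawn from a haplotype pool and assigned affected status by a
Bernoulli draw on the model probability until fixed case and control quotas
are both met (ascertainment sampling).  Variant misclassification scenarios
act purely on the analyst's view of the data: phenotypes are always assigned
from the full causal set, and the analysis matrix afterwards drops a fraction
of causal sites or admits a fraction of non-causal sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, PhenotypeTable
from .popgen import HaplotypePool, sample_haplotype_pairs

MODEL_KINDS = ("main_fixed", "main_variable", "within_gene", "between_gene")


@dataclass
class PhenotypeModel:
    """Causal architecture mapping a genotype to disease probability."""

    kind: str = "main_fixed"
    causal_fraction: float = 0.5
    fixed_or: float = 3.0
    baseline_odds: float = 0.01
    or_map: str = "powerlaw"  # 'powerlaw' or 'reciprocal' inverse-MAF map
    or_range: tuple[float, float] = (2.0, 20.0)
    cis_or: float = 3.0  # within-gene: OR per causal allele in cis
    gene1_or: float = 4.0  # between-gene: high-risk gene
    gene2_or: float = 2.0  # between-gene: low-risk gene, silenced by gene 1

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0,1]")
        if self.baseline_odds <= 0:
            raise ValueError("baseline_odds must be positive")
        for v in (self.fixed_or, self.cis_or, self.gene1_or, self.gene2_or):
            if v <= 0:
                raise ValueError("odds ratios must be positive")


@dataclass
class ScenarioConfig:
    """One simulation-study cell: misclassification knobs and sampling sizes."""

    exclude_causal_fraction: float = 0.0
    include_noncausal_fraction: float = 0.0
    NA: int = 1000
    NU: int = 1000
    replicates: int = 300
    alpha: float = 0.01
    resamples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.exclude_causal_fraction, self.include_noncausal_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("misclassification fractions must be in [0,1]")
        if self.exclude_causal_fraction > 0 and self.include_noncausal_fraction > 0:
            raise ValueError(
                "at most one misclassification knob may be nonzero")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0,1]")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def assign_causal_sites(n_sites: int, fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Uniformly random causal subset of round(fraction * n_sites) sites."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0,1]")
    k = _round_half_up(fraction * n_sites)
    flags = np.zeros(n_sites, dtype=bool)
    if k:
        flags[rng.choice(n_sites, size=k, replace=False)] = True
    return flags


def main_effect_or(kind: str, maf, *, fixed_or: float = 3.0,
                   or_map: str = "powerlaw",
                   or_range: tuple[float, float] = (2.0, 20.0)):
    """Per-causal-allele odds ratio under a main-effects model.

    ``main_fixed`` returns the constant OR regardless of frequency.
    ``main_variable`` returns an OR inversely related to the MAF and clamped
    to ``or_range``.  Two inverse maps are available:

    * ``powerlaw`` (default): OR(f) = lo * (0.01/f)**(1/4), log-OR linear in
      -log10(f); it spans the whole range over MAF 1e-2 .. 1e-6 and keeps the
      bulk of sample-detectable variants (MAF ~ 1e-3..1e-2) at ORs of 2-4.
    * ``reciprocal``: OR(f) = lo * 0.01/f, reaching the upper clamp already
      at MAF = 1e-3; a much more aggressive enrichment profile.
    """
    maf = np.asarray(maf, dtype=float)
    if (maf <= 0).any():
        raise ValueError("MAF must be positive")
    if kind == "main_fixed":
        return np.broadcast_to(float(fixed_or), maf.shape).copy()
    if kind != "main_variable":
        raise ValueError("main_effect_or applies to main-effects kinds only")
    lo, hi = or_range
    if or_map == "powerlaw":
        raw = lo * (0.01 / maf) ** 0.25
    elif or_map == "reciprocal":
        raw = lo * 0.01 / maf
    else:
        raise ValueError(f"unknown or_map {or_map!r}")
    return np.clip(raw, lo, hi)


def site_log_ors(model: PhenotypeModel, maf: np.ndarray,
                 causal: np.ndarray) -> np.ndarray:
    """Per-site log odds ratios for the main-effects kinds (0 if non-causal)."""
    log_or = np.zeros(len(maf))
    if causal.any():
        ors = main_effect_or(model.kind, maf[causal], fixed_or=model.fixed_or,
                             or_map=model.or_map, or_range=model.or_range)
        log_or[causal] = np.log(ors)
    return log_or


def disease_probability(model: PhenotypeModel, *, dosage=None, phase=None,
                        maf=None, causal=None, common_site: int | None = None,
                        gene_split: int | None = None) -> np.ndarray:
    """Disease probability for one genotype or a batch of genotypes.

    Main-effects kinds need ``dosage`` (n x S or length-S), ``maf`` and
    ``causal`` flags.  ``within_gene`` needs ``phase`` (pair of haplotype
    matrices), ``causal`` flags and ``common_site`` (column index of the
    interacting common site, coded 1 = minor allele).  ``between_gene`` needs
    ``dosage`` and ``gene_split``: columns < split belong to gene 1.
    """
    b = model.baseline_odds
    if model.kind in ("main_fixed", "main_variable"):
        if dosage is None or maf is None or causal is None:
            raise ValueError("main-effects model needs dosage, maf and causal")
        dosage = np.atleast_2d(np.asarray(dosage))
        logodds = np.log(b) + dosage @ site_log_ors(model, np.asarray(maf),
                                                    np.asarray(causal))
    elif model.kind == "within_gene":
        if phase is None or causal is None or common_site is None:
            raise ValueError("within_gene model needs phase, causal, common_site")
        h1, h2 = (np.atleast_2d(np.asarray(h)) for h in phase)
        causal = np.asarray(causal, bool)
        # causal rare alleles count only on haplotypes carrying the common
        # site's minor allele (cis configuration)
        cis = (h1[:, causal].sum(axis=1) * h1[:, common_site]
               + h2[:, causal].sum(axis=1) * h2[:, common_site])
        logodds = np.log(b) + cis * np.log(model.cis_or)
    elif model.kind == "between_gene":
        if dosage is None or causal is None or gene_split is None:
            raise ValueError("between_gene model needs dosage, causal, gene_split")
        dosage = np.atleast_2d(np.asarray(dosage))
        causal = np.asarray(causal, bool)
        c1 = dosage[:, : gene_split][:, causal[:gene_split]].sum(axis=1)
        c2 = dosage[:, gene_split:][:, causal[gene_split:]].sum(axis=1)
        logodds = (np.log(b) + c1 * np.log(model.gene1_or)
                   + np.where(c1 == 0, c2 * np.log(model.gene2_or), 0.0))
    else:  # pragma: no cover
        raise ValueError(model.kind)
    p = 1.0 / (1.0 + np.exp(-np.asarray(logodds, dtype=float)))
    return p if p.size > 1 else float(p.reshape(-1)[0])


def ascertain_case_control(pool: HaplotypePool, model: PhenotypeModel,
                           NA: int, NU: int,
                           rng: int | np.random.Generator = 0, *,
                           causal: np.ndarray | None = None,
                           rare_maf: float = 0.01,
                           common_site: int | None = None,
                           batch: int = 20000, max_draws: int = 20_000_000
                           ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Sample individuals from a pool until NA cases and NU controls accrue.

    Rare sites are the pool sites with minor-allele frequency <= ``rare_maf``;
    causal flags (over those rare sites) default to a random
    ``model.causal_fraction`` subset.  The returned matrix is restricted to
    the rare sites (plus, for the within-gene model, the chosen common site
    as its last column, flagged non-rare) and keeps phase.
    """
    if NA < 1 or NU < 1:
        raise ValueError("NA and NU must be >= 1")
    rng = np.random.default_rng(rng)
    maf = pool.minor_freq()
    rare_idx = np.flatnonzero(maf <= rare_maf)
    if causal is None:
        causal = assign_causal_sites(len(rare_idx), model.causal_fraction, rng)
    causal = np.asarray(causal, bool)
    if len(causal) != len(rare_idx):
        raise ValueError("causal flags must cover the pool's rare sites")
    # orient haplotype coding to the minor allele
    flip = pool.site_freq > 0.5
    hap = np.where(flip, 1 - pool.haplotypes, pool.haplotypes).astype(np.uint8)

    if model.kind == "within_gene" and common_site is None:
        common_site = pick_common_interactor(pool, rng)

    kept_cases: list[np.ndarray] = []
    kept_ctrls: list[np.ndarray] = []
    n_cases = n_ctrls = 0
    drawn = 0
    cols = rare_idx if common_site is None else np.append(rare_idx, common_site)
    while n_cases < NA or n_ctrls < NU:
        if drawn >= max_draws:
            raise RuntimeError(
                f"ascertainment cap reached ({drawn} draws): case probability "
                "may be pathologically small")
        h1, h2 = sample_haplotype_pairs(pool, batch, rng)
        drawn += batch
        h1s, h2s = h1[:, cols], h2[:, cols]
        dos = (h1s + h2s).astype(np.int8)
        if model.kind == "within_gene":
            p = disease_probability(model, phase=(h1s, h2s),
                                    causal=np.append(causal, False),
                                    common_site=len(cols) - 1)
        else:
            p = disease_probability(model, dosage=dos[:, : len(rare_idx)],
                                    maf=maf[rare_idx], causal=causal)
        affected = rng.random(batch) < p
        block = np.concatenate([h1s[:, None, :], h2s[:, None, :]], axis=1)
        need_a = NA - n_cases
        if need_a > 0 and affected.any():
            take = np.flatnonzero(affected)[:need_a]
            kept_cases.append(block[take])
            n_cases += len(take)
        need_u = NU - n_ctrls
        if need_u > 0 and (~affected).any():
            take = np.flatnonzero(~affected)[:need_u]
            kept_ctrls.append(block[take])
            n_ctrls += len(take)

    stacked = np.concatenate(kept_cases + kept_ctrls, axis=0)
    h1_all, h2_all = stacked[:, 0, :], stacked[:, 1, :]
    status = np.concatenate([np.ones(NA, np.int8), np.zeros(NU, np.int8)])
    n_rare = len(rare_idx)
    is_rare = np.ones(len(cols), bool)
    is_causal = np.zeros(len(cols), bool)
    is_causal[:n_rare] = causal
    if common_site is not None:
        is_rare[-1] = False
    gm = GenotypeMatrix(
        dosages=(h1_all + h2_all).astype(np.int8),
        site_ids=[f"site{int(c)}" for c in cols],
        site_maf=maf[cols],
        is_rare=is_rare,
        is_causal=is_causal,
        phase=(h1_all.astype(np.int8), h2_all.astype(np.int8)),
    )
    return gm, PhenotypeTable(status=status)


def ascertain_between_gene(pool1: HaplotypePool, pool2: HaplotypePool,
                           model: PhenotypeModel, NA: int, NU: int,
                           rng: int | np.random.Generator = 0, *,
                           rare_maf: float = 0.01, batch: int = 20000,
                           max_draws: int = 20_000_000
                           ) -> tuple[GenotypeMatrix, PhenotypeTable, int]:
    """Two-unlinked-gene ascertainment for the between-gene epistasis model.

    Genotypes at the two genes are drawn from independent haplotype pools;
    causal alleles in high-risk gene 1 always act, causal alleles in low-risk
    gene 2 act only in individuals free of causal gene-1 alleles.  Returns
    the joint matrix (gene-1 columns first), phenotypes, and the gene split
    column index.
    """
    if model.kind != "between_gene":
        raise ValueError("model kind must be 'between_gene'")
    rng = np.random.default_rng(rng)
    mats, flags, mafs = [], [], []
    rare_idx = []
    for pool in (pool1, pool2):
        maf = pool.minor_freq()
        idx = np.flatnonzero(maf <= rare_maf)
        rare_idx.append(idx)
        causal = assign_causal_sites(len(idx), model.causal_fraction, rng)
        flags.append(causal)
        mafs.append(maf[idx])
    split = len(rare_idx[0])
    causal_all = np.concatenate(flags)

    kept_a, kept_u = [], []
    n_cases = n_ctrls = drawn = 0
    while n_cases < NA or n_ctrls < NU:
        if drawn >= max_draws:
            raise RuntimeError("ascertainment cap reached")
        parts = []
        for pool, idx in zip((pool1, pool2), rare_idx):
            flip = pool.site_freq[idx] > 0.5
            h1, h2 = sample_haplotype_pairs(pool, batch, rng)
            h1, h2 = h1[:, idx], h2[:, idx]
            dos = np.where(flip, 2 - (h1 + h2), h1 + h2)
            parts.append(dos.astype(np.int8))
        drawn += batch
        dos = np.concatenate(parts, axis=1)
        p = disease_probability(model, dosage=dos, causal=causal_all,
                                gene_split=split)
        affected = rng.random(batch) < np.atleast_1d(p)
        need_a = NA - n_cases
        if need_a > 0 and affected.any():
            take = np.flatnonzero(affected)[:need_a]
            kept_a.append(dos[take])
            n_cases += len(take)
        need_u = NU - n_ctrls
        if need_u > 0 and (~affected).any():
            take = np.flatnonzero(~affected)[:need_u]
            kept_u.append(dos[take])
            n_ctrls += len(take)
    dosages = np.concatenate(kept_a + kept_u, axis=0)
    status = np.concatenate([np.ones(NA, np.int8), np.zeros(NU, np.int8)])
    ids = [f"g1_site{int(c)}" for c in rare_idx[0]] + \
          [f"g2_site{int(c)}" for c in rare_idx[1]]
    gm = GenotypeMatrix(dosages=dosages, site_ids=ids,
                        site_maf=np.concatenate(mafs),
                        is_rare=np.ones(dosages.shape[1], bool),
                        is_causal=causal_all)
    return gm, PhenotypeTable(status=status), split


def apply_misclassification(gm: GenotypeMatrix, scenario: ScenarioConfig,
                            rng: int | np.random.Generator = 0
                            ) -> GenotypeMatrix:
    """Restrict the analysis matrix per the misclassification scenario.

    Keeps (1 - exclude_causal_fraction) of the causal sites and
    include_noncausal_fraction of the non-causal rare sites, each a uniform
    random subset; non-rare columns (e.g. an interacting common site) are
    always dropped from the analysis view.  Phenotypes must already have been
    assigned from the full causal set.
    """
    rng = np.random.default_rng(rng)
    if gm.is_causal is None or gm.is_rare is None:
        raise ValueError("matrix lacks causal/rarity flags")
    causal_idx = np.flatnonzero(gm.is_causal & gm.is_rare)
    noncausal_idx = np.flatnonzero(~gm.is_causal & gm.is_rare)
    n_keep_c = len(causal_idx) - _round_half_up(
        scenario.exclude_causal_fraction * len(causal_idx))
    n_keep_n = _round_half_up(
        scenario.include_noncausal_fraction * len(noncausal_idx))
    keep_c = rng.choice(causal_idx, size=n_keep_c, replace=False) \
        if n_keep_c else np.empty(0, int)
    keep_n = rng.choice(noncausal_idx, size=n_keep_n, replace=False) \
        if n_keep_n else np.empty(0, int)
    return gm.restrict_sites(np.sort(np.concatenate([keep_c, keep_n])))


def pick_common_interactor(pool: HaplotypePool,
                           rng: int | np.random.Generator = 0,
                           maf_threshold: float = 0.20) -> int:
    """Uniformly choose a pool site with minor-allele frequency > threshold."""
    rng = np.random.default_rng(rng)
    qualifying = np.flatnonzero(pool.minor_freq() > maf_threshold)
    if qualifying.size == 0:
        raise ValueError(
            f"no site with MAF > {maf_threshold}; regenerate the pool")
    return int(rng.choice(qualifying))
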