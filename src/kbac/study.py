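"""Experiment harness: association runs, type-I-error and power studies,
rare-variant summaries, and quartile dichotomization of quantitative traits.

Power and type-I studies follow the simulation design of the underlying
evaluation: haplotype pools are generated once; each replicate picks a pool
at random, ascertains a case-control sample under a log-odds phenotype
model, restricts the analysis matrix per the misclassification scenario and
to sites that are rare (MAF <= 1%) and polymorphic in the sample, and runs
the requested tests.  Empirical power is the fraction of replicates with
p <= alpha; its Monte Carlo standard error is sqrt(power*(1-power)/reps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparators import cmc_test, rve_test, wss_test
from .core import (TestResult, monte_carlo_pvalue, permutation_pvalue_from_tally)
from .covariates import ScoreTestSpec, kbac_score_test
from .data import (GenotypeMatrix, PhenotypeTable, filter_rare_sites,
                   tally_patterns)
from .phenotypes import (PhenotypeModel, ScenarioConfig, apply_misclassification,
                         ascertain_case_control)
from .popgen import HaplotypePool

METHODS = ("kbac", "kbac-mc", "kbac-score", "cmc", "wss", "rve")


@dataclass
class PowerStudyResult:
    """Empirical power per method for one scenario cell."""

    power: dict[str, float]
    replicates: int
    alpha: float
    seed: int
    p_values: pd.DataFrame | None = None

    def se(self, method: str) -> float:
        p = self.power[method]
        return float(np.sqrt(p * (1 - p) / self.replicates))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"method": m, "power": p, "se": self.se(m),
                 "replicates": self.replicates, "alpha": self.alpha,
                 "seed": self.seed} for m, p in self.power.items()]
        return pd.DataFrame(rows)


@dataclass
class RareVariantSummary:
    """Averages of the per-replicate rare-variant descriptive statistics."""

    carrier_freq_cases: float
    carrier_freq_controls: float
    mean_rare_sites: float
    mean_exclusive_sites: float
    multi_carrier_cases: float
    multi_carrier_controls: float

    @property
    def carrier_ratio(self) -> float:
        return self.carrier_freq_cases / self.carrier_freq_controls


def analysis_view(gm: GenotypeMatrix, maf_threshold: float = 0.01
                  ) -> GenotypeMatrix:
    """Restrict a matrix to sites rare (combined-sample MAF) and polymorphic."""
    gm = filter_rare_sites(gm, maf_threshold)
    poly = gm.dosages.sum(axis=0) > 0
    return gm.restrict_sites(poly) if not poly.all() else gm


def run_association(gm: GenotypeMatrix, ph: PhenotypeTable,
                    methods=("kbac",), kernel: str = "hypergeometric",
                    B: int = 5000, seed: int = 0, covariates=None,
                    sided: str = "two", n_genes: int = 1,
                    alpha: float = 0.05, maf_threshold: float = 0.01,
                    gene: str = "gene") -> pd.DataFrame:
    """Run the requested tests on one region; one result row per method.

    ``n_genes`` > 1 adds a Bonferroni-adjusted significance threshold column
    (alpha / n_genes) for exome-style multi-gene reporting.
    """
    if not methods:
        raise ValueError("empty method list")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {METHODS}")
    view = analysis_view(gm, maf_threshold)
    ss = np.random.SeedSequence(seed).spawn(len(methods))
    results: list[TestResult] = []
    for m, s in zip(methods, ss):
        rng = np.random.default_rng(s)
        if m == "kbac":
            t = tally_patterns(view, ph)
            res = permutation_pvalue_from_tally(t, kernel, sided, B, rng)
        elif m == "kbac-mc":
            t = tally_patterns(view, ph)
            res = monte_carlo_pvalue(t, kernel, sided, B, rng)
        elif m == "kbac-score":
            spec = ScoreTestSpec(covariate_names=list(covariates or []), B=B,
                                 seed=int(rng.integers(2**31)))
            res = kbac_score_test(view, ph, spec, kernel)
        elif m == "cmc":
            res = cmc_test(view, ph)
        elif m == "wss":
            res = wss_test(view, ph, B, rng, sided)
        else:
            res = rve_test(view, ph, B, rng)
        results.append(res)
    df = pd.DataFrame(
        [{"gene": gene, "method": r.method, "kernel": r.kernel,
          "sided": r.sided, "statistic": r.statistic, "p_value": r.p_value,
          "resamples": r.resamples, "seed": seed} for r in results])
    if n_genes > 1:
        df["bonferroni_alpha"] = alpha / n_genes
        df["significant_adjusted"] = df["p_value"] <= alpha / n_genes
    return df


def polymorphic_view(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop sites with no minor allele in the sample (they carry no signal)."""
    poly = gm.dosages.sum(axis=0) > 0
    return gm.restrict_sites(poly) if not poly.all() else gm


def simulate_replicate(pools: list[HaplotypePool], model: PhenotypeModel,
                       scenario: ScenarioConfig,
                       rng: np.random.Generator,
                       maf_threshold: float = 0.01):
    """One study replicate: (analysis matrix, phenotypes, full matrix).

    Rarity (MAF <= ``maf_threshold``) and causality are population-level
    properties of the pool, exactly as in the generative design; the analysis
    matrix is the scenario's included pool-rare sites pruned to those
    polymorphic in the sample, with no re-filtering by sample MAF.

    The within-gene interaction model needs a common (MAF > 20%) interactor
    site, so pool choice is restricted to qualifying pools (the regenerate-
    on-failure rule applied at the pool-set level).
    """
    if model.kind == "between_gene":
        from .phenotypes import ascertain_between_gene

        i, j = rng.choice(len(pools), size=2, replace=False) \
            if len(pools) > 1 else (0, 0)
        gm, ph, _ = ascertain_between_gene(pools[i], pools[j], model,
                                           scenario.NA, scenario.NU, rng,
                                           rare_maf=maf_threshold)
        gm_view = apply_misclassification(gm, scenario, rng)
        return polymorphic_view(gm_view), ph, gm
    if model.kind == "within_gene":
        eligible = [p for p in pools if (p.minor_freq() > 0.20).any()]
        if not eligible:
            raise ValueError("no pool has a common (MAF>20%) site; "
                             "generate more pools")
        pools = eligible
    pool = pools[rng.integers(len(pools))]
    gm, ph = ascertain_case_control(pool, model, scenario.NA, scenario.NU, rng,
                                    rare_maf=maf_threshold)
    gm_view = apply_misclassification(gm, scenario, rng)
    return polymorphic_view(gm_view), ph, gm


def run_power_study(pools: list[HaplotypePool], model: PhenotypeModel,
                    scenario: ScenarioConfig,
                    methods=("kbac", "wss", "cmc", "rve"),
                    kernel: str = "hypergeometric", sided: str = "two",
                    keep_pvalues: bool = False,
                    maf_threshold: float = 0.01) -> PowerStudyResult:
    """Empirical power of each method over ``scenario.replicates`` replicates.

    All methods are evaluated on the same replicates (paired comparison), and
    every replicate draws its own child generator from the master seed, so a
    given configuration is exactly reproducible.
    """
    if scenario.replicates < 1:
        raise ValueError("need at least one replicate")
    seqs = np.random.SeedSequence(scenario.seed).spawn(scenario.replicates)
    B = scenario.resamples
    pvals = {m: np.empty(scenario.replicates) for m in methods}
    for r, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        view, ph, _ = simulate_replicate(pools, model, scenario, rng,
                                         maf_threshold)
        for m in methods:
            if m == "kbac":
                t = tally_patterns(view, ph)
                res = permutation_pvalue_from_tally(t, kernel, sided, B, rng)
            elif m == "kbac-mc":
                t = tally_patterns(view, ph)
                res = monte_carlo_pvalue(t, kernel, sided, B, rng)
            elif m == "cmc":
                res = cmc_test(view, ph)
            elif m == "wss":
                res = wss_test(view, ph, B, rng, sided)
            elif m == "rve":
                res = rve_test(view, ph, B, rng)
            else:
                raise ValueError(f"unsupported method in power study: {m}")
            pvals[m][r] = res.p_value
    power = {m: float((pvals[m] <= scenario.alpha).mean()) for m in methods}
    frame = pd.DataFrame(pvals) if keep_pvalues else None
    return PowerStudyResult(power=power, replicates=scenario.replicates,
                            alpha=scenario.alpha, seed=scenario.seed,
                            p_values=frame)


def run_type1_study(pools: list[HaplotypePool], NA: int = 400, NU: int = 400,
                    replicates: int = 2000, B: int = 1000, M: int = 1000,
                    kernel: str = "hypergeometric", sided: str = "two",
                    seed: int = 0, maf_threshold: float = 0.01
                    ) -> pd.DataFrame:
    """Null p-values of permutation and Monte Carlo KBAC, replicate by replicate.

    Under the null every OR is 1, so a case-control sample is simply NA + NU
    exchangeable draws from a pool with arbitrary labels.  The returned frame
    has columns ``p_perm`` and ``p_mc``; QQ data and empirical rejection
    rates derive from it directly.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    from .popgen import sample_haplotype_pairs

    seqs = np.random.SeedSequence(seed).spawn(replicates)
    status = np.concatenate([np.ones(NA, np.int8), np.zeros(NU, np.int8)])
    ph = PhenotypeTable(status=status)
    out = np.empty((replicates, 2))
    for r, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        pool = pools[rng.integers(len(pools))]
        rare = np.flatnonzero(pool.minor_freq() <= maf_threshold)
        flip = pool.site_freq[rare] > 0.5
        h1, h2 = sample_haplotype_pairs(pool, NA + NU, rng)
        h1, h2 = h1[:, rare], h2[:, rare]
        dos = np.where(flip, 2 - (h1 + h2), h1 + h2).astype(np.int8)
        gm = GenotypeMatrix(dosages=dos,
                            site_ids=[f"s{i}" for i in range(dos.shape[1])])
        view = polymorphic_view(gm)
        t = tally_patterns(view, ph)
        out[r, 0] = permutation_pvalue_from_tally(t, kernel, sided, B, rng).p_value
        out[r, 1] = monte_carlo_pvalue(t, kernel, sided, M, rng).p_value
    return pd.DataFrame(out, columns=["p_perm", "p_mc"])


def empirical_alpha(pvalues: np.ndarray, alpha: float = 0.05) -> float:
    return float((np.asarray(pvalues) <= alpha).mean())


def summarize_one(gm: GenotypeMatrix, ph: PhenotypeTable) -> dict[str, float]:
    """The four descriptive statistics for a single replicate's matrix."""
    y = ph.status.astype(bool)
    dos = gm.dosages
    poly = dos.sum(axis=0) > 0
    dos = dos[:, poly]
    carrier = (dos > 0).any(axis=1)
    burden = dos.sum(axis=1)
    in_cases = (dos[y] > 0).any(axis=0)
    in_ctrls = (dos[~y] > 0).any(axis=0)
    ncar_a = carrier[y].sum()
    ncar_u = carrier[~y].sum()
    return {
        "carrier_freq_cases": carrier[y].mean() if y.any() else 0.0,
        "carrier_freq_controls": carrier[~y].mean() if (~y).any() else 0.0,
        "mean_rare_sites": float(dos.shape[1]),
        "mean_exclusive_sites": float((in_cases ^ in_ctrls).sum()),
        "multi_carrier_cases":
            float((burden[y] > 1).sum() / ncar_a) if ncar_a else 0.0,
        "multi_carrier_controls":
            float((burden[~y] > 1).sum() / ncar_u) if ncar_u else 0.0,
    }


def summarize_rare_variants(datasets) -> RareVariantSummary:
    """Average the per-replicate summaries over (gm, ph) pairs."""
    rows = [summarize_one(gm, ph) for gm, ph in datasets]
    if not rows:
        raise ValueError("need at least one replicate")
    df = pd.DataFrame(rows)
    return RareVariantSummary(**{k: float(df[k].mean()) for k in df.columns})


def quartile_case_control(ph: PhenotypeTable,
                          direction: str = "upper_is_case",
                          strata: np.ndarray | None = None
                          ) -> tuple[PhenotypeTable, np.ndarray]:
    """Dichotomize a quantitative trait into extreme-quartile case-control.

    Individuals at or beyond the upper empirical quartile of the trait become
    one class, those at or below the lower quartile the other, and the middle
    half is dropped.  Cutoffs are inclusive and computed within each stratum
    when ``strata`` labels are given (e.g. race x sex cells).  Returns the
    reduced phenotype table and the indices of retained individuals, for
    subsetting the paired genotype matrix.
    """
    if direction not in ("upper_is_case", "lower_is_case"):
        raise ValueError("direction must be 'upper_is_case' or 'lower_is_case'")
    trait = ph.quantitative_trait
    if trait is None:
        raise ValueError("phenotype table has no quantitative trait")
    trait = np.asarray(trait, float)
    if len(trait) < 8:
        raise ValueError("need at least 8 individuals")
    groups = (np.zeros(len(trait), int) if strata is None
              else np.asarray(strata))
    upper = np.zeros(len(trait), bool)
    lower = np.zeros(len(trait), bool)
    for g in np.unique(groups):
        mask = groups == g
        vals = trait[mask]
        if np.ptp(vals) == 0:
            raise ValueError("trait is constant within a stratum")
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        upper[mask] = vals >= q3
        lower[mask] = vals <= q1
    keep = np.flatnonzero(upper | lower)
    case_mask = upper[keep] if direction == "upper_is_case" else lower[keep]
    new = PhenotypeTable(
        status=case_mask.astype(np.int8),
        covariates=None if ph.covariates is None
        else ph.covariates.iloc[keep].reset_index(drop=True),
        quantitative_trait=trait[keep],
        sample_ids=None if ph.sample_ids is None
        else [ph.sample_ids[i] for i in keep])
    return new, keep
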