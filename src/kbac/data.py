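"""Genotype/phenotype containers and the multi-site genotype tally.

Case-control rare-variant data are held as a minor-allele dosage matrix
(individuals x sites, entries 0/1/2) with per-site metadata, plus a phenotype
table with binary affection status and optional numeric covariates.  The unit
of analysis for the adaptive-cluster test is not the single site but the
*multi-site genotype*: the full dosage vector of an individual over the rare
sites of a region.  :func:`tally_patterns` reduces a dataset to the counts of
each distinct multi-site genotype in cases and controls -- the sufficient
statistic for all downstream testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class GenotypeParseError(ValueError):
    """Raised when an input genotype file violates the expected format."""


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with per-site metadata.

    Attributes
    ----------
    dosages : (n_individuals, n_sites) int8 array with entries in {0, 1, 2}.
    site_ids : site identifiers, one per column.
    site_maf : minor-allele frequency per site (in the sample unless supplied
        externally); always in [0, 0.5].
    is_rare, is_causal, is_functional : optional per-site boolean flags.
    phase : optional pair of binary haplotype matrices summing to ``dosages``.
    sample_ids : optional individual identifiers, one per row.
    """

    dosages: np.ndarray
    site_ids: list[str]
    site_maf: np.ndarray | None = None
    is_rare: np.ndarray | None = None
    is_causal: np.ndarray | None = None
    is_functional: np.ndarray | None = None
    phase: tuple[np.ndarray, np.ndarray] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"dosage not in {{0,1,2}} at row {i}, column {j} "
                f"(site {self.site_ids[j]!r})"
            )
        if len(self.site_ids) != self.dosages.shape[1]:
            raise ValueError("site_ids length does not match dosage columns")
        if self.site_maf is None:
            self.site_maf = self.compute_maf()
        else:
            self.site_maf = np.asarray(self.site_maf, dtype=float)
        if self.phase is not None:
            h1, h2 = (np.asarray(h, dtype=np.int8) for h in self.phase)
            if not (np.isin(h1, (0, 1)).all() and np.isin(h2, (0, 1)).all()):
                raise ValueError("phase matrices must be binary")
            if not np.array_equal(h1 + h2, self.dosages):
                raise ValueError("phase matrices do not sum to dosages")
            self.phase = (h1, h2)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def compute_maf(self) -> np.ndarray:
        """Minor-allele frequency per site recomputed from the dosages."""
        if self.n_individuals == 0:
            return np.zeros(self.n_sites)
        f = self.dosages.sum(axis=0) / (2.0 * self.n_individuals)
        return np.minimum(f, 1.0 - f)

    def restrict_sites(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site columns (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)

        def take(a):
            return None if a is None else np.asarray(a)[index]

        phase = None
        if self.phase is not None:
            phase = (self.phase[0][:, index], self.phase[1][:, index])
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            site_ids=[self.site_ids[i] for i in index],
            site_maf=take(self.site_maf),
            is_rare=take(self.is_rare),
            is_causal=take(self.is_causal),
            is_functional=take(self.is_functional),
            phase=phase,
            sample_ids=self.sample_ids,
        )


@dataclass
class PhenotypeTable:
    """Binary affection status with optional covariates and quantitative trait."""

    status: np.ndarray
    covariates: pd.DataFrame | None = None
    quantitative_trait: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status values must be 0 (unaffected) or 1 (affected)")
        if self.covariates is not None:
            if len(self.covariates) != len(self.status):
                raise ValueError("covariate rows do not match status length")
            if self.covariates.isna().any().any():
                raise ValueError("covariates contain missing values")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.status) - self.status.sum())


@dataclass
class PatternTally:
    """Counts of distinct multi-site genotype patterns in cases and controls.

    ``patterns`` holds the k distinct non-wild-type dosage vectors (each has at
    least one rare allele), in lexicographic order.  For pattern i, ``n[i]``
    individuals carry it, of which ``nA[i]`` are affected and ``nU[i]``
    unaffected.  The all-zero (wild-type) pattern is tallied separately in
    ``n0/nA0/nU0``.
    """

    patterns: np.ndarray  # (k, n_sites) int8
    n: np.ndarray
    nA: np.ndarray
    nU: np.ndarray
    n0: int
    nA0: int
    nU0: int
    N: int
    NA: int
    NU: int

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.int8)
        for name in ("n", "nA", "nU"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if not np.array_equal(self.n, self.nA + self.nU):
            raise ValueError("n != nA + nU")
        if int(self.n.sum()) + self.n0 != self.N:
            raise ValueError("pattern counts do not sum to N")
        if self.NA + self.NU != self.N:
            raise ValueError("NA + NU != N")
        if self.k and (self.patterns.sum(axis=1) == 0).any():
            raise ValueError("a non-wild-type pattern is all zeros")

    @property
    def k(self) -> int:
        return len(self.n)


def read_genotype_matrix(path: str, dialect: str = "tsv", *,
                         missing_threshold: float = 0.0) -> GenotypeMatrix:
    """Read a genotype dosage matrix from a TSV table or a VCF file.

    TSV layout: header ``sample_id<TAB>site1<TAB>...``, one row per individual
    with integer dosages 0/1/2.  VCF: biallelic SNVs with GT fields; each site
    is oriented to its minor allele before dosages are computed, so MAF <= 0.5.

    Missing VCF genotypes up to ``missing_threshold`` (fraction per site) are
    imputed to the major allele (dosage 0); above the threshold an error is
    raised.  The default threshold of 0 makes any missingness an error.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, missing_threshold)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise GenotypeParseError(f"empty genotype file: {path}") from exc
    if df.shape[1] < 2:
        raise GenotypeParseError("genotype TSV needs a sample_id column and >=1 site")
    site_ids = list(df.columns[1:])
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1:]
    dosages = np.empty(raw.shape, dtype=np.int8)
    for j, col in enumerate(raw.columns):
        try:
            vals = raw[col].astype(int).to_numpy()
        except ValueError as exc:
            raise GenotypeParseError(
                f"non-integer dosage in column {col!r}") from exc
        if not np.isin(vals, (0, 1, 2)).all():
            i = int(np.flatnonzero(~np.isin(vals, (0, 1, 2)))[0])
            raise GenotypeParseError(
                f"dosage not in {{0,1,2}} at row {sample_ids[i]!r}, column {col!r}")
        dosages[:, j] = vals
    return GenotypeMatrix(dosages=dosages, site_ids=site_ids, sample_ids=sample_ids)


def _read_vcf(path: str, missing_threshold: float) -> GenotypeMatrix:
    import pysam

    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise GenotypeParseError(f"cannot read VCF {path}: {exc}") from exc
    sample_ids = list(vf.header.samples)
    if not sample_ids:
        raise GenotypeParseError("VCF contains no samples")
    site_ids: list[str] = []
    cols: list[np.ndarray] = []
    n = len(sample_ids)
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise GenotypeParseError(
                f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos}; "
                "split or filter multi-allelic sites first")
        alt_dose = np.zeros(n, dtype=float)
        missing = np.zeros(n, dtype=bool)
        for i, sample in enumerate(rec.samples.values()):
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                missing[i] = True
                continue
            alt_dose[i] = sum(1 for a in gt if a == 1)
        if missing.mean() > missing_threshold:
            raise GenotypeParseError(
                f"{missing.sum()} missing genotypes at {rec.chrom}:{rec.pos} "
                f"exceed threshold {missing_threshold}")
        # minor-allele orientation on observed genotypes
        obs = ~missing
        alt_f = alt_dose[obs].sum() / (2.0 * obs.sum()) if obs.sum() else 0.0
        dose = alt_dose if alt_f <= 0.5 else 2.0 - alt_dose
        dose[missing] = 0  # impute to major allele
        site_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        cols.append(dose.astype(np.int8))
    if not cols:
        raise GenotypeParseError(f"no usable variant records in {path}")
    return GenotypeMatrix(dosages=np.column_stack(cols), site_ids=site_ids,
                          sample_ids=sample_ids)


def read_phenotype_table(path: str) -> PhenotypeTable:
    """Read a phenotype TSV: ``sample_id, status[, trait][, covariates...]``."""
    df = pd.read_csv(path, sep="\t")
    if "status" not in df.columns:
        raise GenotypeParseError("phenotype TSV needs a 'status' column")
    trait = df["trait"].to_numpy(float) if "trait" in df.columns else None
    cov_cols = [c for c in df.columns
                if c not in ("sample_id", "status", "trait")]
    cov = df[cov_cols].astype(float) if cov_cols else None
    return PhenotypeTable(
        status=df["status"].to_numpy(),
        covariates=cov,
        quantitative_trait=trait,
        sample_ids=df["sample_id"].astype(str).tolist()
        if "sample_id" in df.columns else None,
    )


def filter_rare_sites(gm: GenotypeMatrix, maf_threshold: float = 0.01, *,
                      controls_only: np.ndarray | None = None) -> GenotypeMatrix:
    """Keep sites with MAF <= threshold (inclusive), preserving site order.

    MAF is computed in the combined sample by default, which keeps the filter
    symmetric under case/control label permutation.  Pass ``controls_only`` (a
    boolean control mask) to compute MAF among controls instead.

    An empty result (no site survives) is returned as a 0-column matrix;
    downstream tests treat it as "no rare variation" and report p = 1.
    """
    if not 0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in (0, 0.5]")
    if controls_only is not None:
        sub = gm.dosages[np.asarray(controls_only, bool)]
        denom = 2.0 * max(len(sub), 1)
        f = sub.sum(axis=0) / denom
        maf = np.minimum(f, 1 - f)
    else:
        maf = gm.compute_maf()
    return gm.restrict_sites(np.flatnonzero(maf <= maf_threshold))


def tally_patterns(gm: GenotypeMatrix, ph: PhenotypeTable) -> PatternTally:
    """Tally distinct multi-site genotypes into case/control counts.

    Patterns are keyed by the exact dosage vector over the matrix's sites and
    ordered lexicographically, so the result is invariant to individual order.
    """
    if gm.n_individuals != len(ph.status):
        raise ValueError(
            f"genotype rows ({gm.n_individuals}) != phenotype rows ({len(ph.status)})")
    NA, NU = ph.n_cases, ph.n_controls
    if NA == 0 or NU == 0:
        raise ValueError("degenerate phenotype: need at least one case and one control")
    N = gm.n_individuals
    if gm.n_sites == 0:
        return PatternTally(
            patterns=np.zeros((0, 0), np.int8), n=[], nA=[], nU=[],
            n0=N, nA0=NA, nU0=NU, N=N, NA=NA, NU=NU)
    uniq, inverse = np.unique(gm.dosages, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(uniq))
    case_counts = np.bincount(inverse, weights=ph.status, minlength=len(uniq)).astype(int)
    nonzero = uniq.sum(axis=1) > 0
    wt = np.flatnonzero(~nonzero)
    if len(wt):
        n0 = int(counts[wt[0]])
        nA0 = int(case_counts[wt[0]])
    else:
        n0 = nA0 = 0
    return PatternTally(
        patterns=uniq[nonzero],
        n=counts[nonzero],
        nA=case_counts[nonzero],
        nU=counts[nonzero] - case_counts[nonzero],
        n0=n0, nA0=nA0, nU0=n0 - nA0,
        N=N, NA=NA, NU=NU)


def write_genotype_matrix(gm: GenotypeMatrix, path: str) -> None:
    """Write the TSV genotype format read by :func:`read_genotype_matrix`."""
    ids = gm.sample_ids or [f"ind{i}" for i in range(gm.n_individuals)]
    df = pd.DataFrame(gm.dosages, columns=gm.site_ids, index=ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_phenotype_table(ph: PhenotypeTable, path: str) -> None:
    ids = ph.sample_ids or [f"ind{i}" for i in range(len(ph.status))]
    df = pd.DataFrame({"sample_id": ids, "status": ph.status})
    if ph.quantitative_trait is not None:
        df["trait"] = ph.quantitative_trait
    if ph.covariates is not None:
        df = pd.concat([df, ph.covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)
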