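"""Seeded simulators for cohorts, gene annotations, gene sets and base GWAS.

The generators reproduce the statistical structure the downstream stages
assume, at configurable scale:

* biallelic dosages with LD blocks (first-order autoregressive correlation
  on a latent Gaussian within a block, independence across blocks) and a
  uniform MAF spectrum within configurable bounds;
* a quantitative trait that is either a continuous latent score or a
  BIS-like bounded sum of 8 ordinal items each scored 1-4 (total 8-32,
  right-skewed by default);
* planted causal variants, each scaled so its marginal population variance
  explained equals a requested fraction;
* covariates emulating a clinical GWAS design (sex, genotyping batch, age,
  ancestry axes, an ordinal seizure-frequency category);
* gene annotations with per-chromosome sorted transcription start sites,
  GO-style gene sets, and an external "base" GWAS providing polygenic-score
  weights.

All randomness flows from the single integer seed in :class:`SimConfig`
through independent ``numpy`` sub-streams, so every output is bit-identical
across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "CohortData",
    "simulate_cohort",
    "simulate_annotation_and_sets",
    "simulate_base_gwas",
    "implied_adjacent_correlation",
]

#: default covariate generators: name -> (kind, params...)
DEFAULT_COVARIATE_SPEC: Mapping[str, tuple] = {
    "sex": ("bernoulli", 0.5),
    "batch": ("categorical", 4),
    "age": ("uniform", 18.0, 60.0),
    "ancestry": ("normal", 3),
    "seizure_freq": ("ordinal", 4),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror a small clinical GWAS of a bounded impulsivity score:
    a few hundred individuals, LD blocks of common variants, one or two
    planted variants each explaining ~10% of trait variance.
    """

    n_individuals: int = 324
    n_variants: int = 1000
    n_blocks: int = 50
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_spec: Sequence[tuple[int, float]] = ()
    covariate_spec: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_SPEC)
    )
    covariate_pve: float = 0.10
    phenotype_mode: str = "bis_like"
    include_x: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("n_individuals and n_variants must be positive")
        if not (1 <= self.n_blocks <= self.n_variants):
            raise ValueError("n_blocks must be in [1, n_variants]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        total_pve = sum(p for _, p in self.causal_spec)
        if total_pve + self.covariate_pve >= 1.0:
            raise ValueError(
                f"causal PVE ({total_pve:.3f}) + covariate PVE "
                f"({self.covariate_pve:.3f}) must sum to < 1"
            )
        for idx, p in self.causal_spec:
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"causal variant index {idx} out of range")
            if not (0.0 < p < 1.0):
                raise ValueError(f"causal PVE {p} must be in (0, 1)")
        if self.phenotype_mode not in ("continuous", "bis_like"):
            raise ValueError("phenotype_mode must be 'continuous' or 'bis_like'")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class CohortData:
    """Dosage matrix plus phenotype, covariates and per-variant metadata.

    ``dosages`` is individuals x variants with values in [0, 2]; missing
    entries are NaN.  ``variants`` has one row per column of ``dosages``
    with columns chrom, pos, ref, alt, maf, info_r2, call_rate.
    ``causal_effects`` records the planted per-dosage effect sizes (variant
    index -> beta) so that a base GWAS can share the causal architecture.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    phenotype: np.ndarray
    covariates: pd.DataFrame
    sex: np.ndarray
    causal_effects: dict[int, float] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "CohortData":
        return CohortData(
            dosages=self.dosages.copy(),
            variants=self.variants.copy(),
            phenotype=self.phenotype.copy(),
            covariates=self.covariates.copy(),
            sex=self.sex.copy(),
            causal_effects=dict(self.causal_effects),
        )


def _block_bounds(n_variants: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n_variants, n_blocks + 1).astype(int)
    return [(int(edges[b]), int(edges[b + 1])) for b in range(n_blocks)]


def _ar1_latent(rng: np.random.Generator, n_rows: int, width: int, rho: float) -> np.ndarray:
    """Stationary AR(1) Gaussian rows: z_j = rho z_{j-1} + sqrt(1-rho^2) eps."""
    z = rng.standard_normal((n_rows, width))
    if rho > 0.0:
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, width):
            z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    return z


def implied_adjacent_correlation(rho: float, maf_a: float, maf_b: float) -> float:
    """Genotype correlation implied by latent correlation ``rho``.

    Haplotype alleles are thresholded latent Gaussians, so the allele (and
    hence genotype) correlation is the tetrachoric-style quantity
    (P11 - pa*pb) / sqrt(pa qa pb qb) with P11 the bivariate-normal orthant
    probability at the two MAF thresholds.
    """
    ta = stats.norm.ppf(maf_a)
    tb = stats.norm.ppf(maf_b)
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
        [ta, tb]
    )
    denom = np.sqrt(maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
    return float((p11 - maf_a * maf_b) / denom)


_ALLELES = np.array(["A", "C", "G", "T"])


def _variant_table(
    rng: np.random.Generator,
    mafs: np.ndarray,
    blocks: list[tuple[int, int]],
    include_x: bool,
) -> pd.DataFrame:
    m = len(mafs)
    chroms = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    autosomes = [str(c) for c in range(1, 23)]
    per_chrom_offset: dict[str, int] = {}
    for b, (lo, hi) in enumerate(blocks):
        if include_x and b == len(blocks) - 1:
            chrom = "X"
        else:
            chrom = autosomes[b % len(autosomes)]
        start = per_chrom_offset.get(chrom, 0)
        width = hi - lo
        # 5 kb spacing within a block, 1 Mb gap between blocks on a chromosome
        pos[lo:hi] = start + 10_000 + 5_000 * np.arange(width)
        per_chrom_offset[chrom] = start + 1_000_000
        chroms[lo:hi] = chrom
    # transition-biased substitution model (Ts:Tv = 2:1, the genome-wide
    # norm), so strand-ambiguous A/T and G/C pairs arise at realistic rates
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}
    ref = _ALLELES[rng.integers(0, 4, size=m)]
    is_ts = rng.random(m) < 2.0 / 3.0
    tv_pick = rng.integers(0, 2, size=m)
    alt = np.array(
        [
            transition[r] if ts else transversions[r][k]
            for r, ts, k in zip(ref, is_ts, tv_pick)
        ],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": mafs,
            "info_r2": rng.uniform(0.7, 1.0, size=m),
            "call_rate": np.ones(m),
        }
    )


def _simulate_covariates(
    rng: np.random.Generator, n: int, spec: Mapping[str, tuple]
) -> tuple[pd.DataFrame, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    sex = np.full(n, "female", dtype=object)
    for name, desc in spec.items():
        kind = desc[0]
        if kind == "bernoulli":
            draw = rng.binomial(1, desc[1], size=n)
            cols[name] = draw.astype(float)
            if name == "sex":
                sex = np.where(draw == 1, "male", "female").astype(object)
        elif kind == "categorical":
            cols[name] = rng.integers(0, desc[1], size=n).astype(float)
        elif kind == "uniform":
            cols[name] = rng.uniform(desc[1], desc[2], size=n)
        elif kind == "normal":
            k = int(desc[1])
            draws = rng.standard_normal((n, k))
            for i in range(k):
                cols[f"pc{i + 1}" if name == "ancestry" else f"{name}{i + 1}"] = draws[:, i]
        elif kind == "ordinal":
            cols[name] = rng.integers(0, desc[1], size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    return pd.DataFrame(cols), sex


# Default BIS-like item cut quantiles: P(score 1..4) = 0.50, 0.30, 0.15, 0.05,
# giving the right-skewed bounded sum typical of impulsivity self-ratings.
BIS_ITEM_QUANTILES = (0.50, 0.80, 0.95)


def _bis_like_items(
    rng: np.random.Generator,
    latent: np.ndarray,
    n_items: int = 8,
    item_noise_sd: float = 1.0,
    quantiles: Sequence[float] = BIS_ITEM_QUANTILES,
) -> np.ndarray:
    """Cut latent + item noise into ordered 1..4 categories and sum."""
    latent_sd = float(np.sqrt(np.var(latent) + item_noise_sd**2))
    cuts = np.mean(latent) + latent_sd * stats.norm.ppf(np.asarray(quantiles))
    total = np.zeros(latent.shape[0], dtype=np.int64)
    for _ in range(n_items):
        item_latent = latent + item_noise_sd * rng.standard_normal(latent.shape[0])
        total += 1 + np.searchsorted(cuts, item_latent, side="right").astype(np.int64)
    return total


def simulate_cohort(config: SimConfig) -> CohortData:
    """Simulate genotype dosages, covariates and a trait from a seeded design.

    LD blocks are realised by thresholding a stationary AR(1) latent
    Gaussian into two haplotypes per individual, so genotypes are in Hardy-
    Weinberg proportions at the drawn MAF and adjacent variants within a
    block are correlated.  The trait is a linear combination of planted
    centred dosages (each scaled to its target marginal PVE), covariate
    effects totalling ``covariate_pve`` of the variance, and Gaussian noise;
    in ``bis_like`` mode the latent trait is discretised into 8 ordinal
    items scored 1-4 and summed to an 8-32 bounded score.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_geno, ss_meta, ss_cov, ss_noise, ss_items, ss_miss = root.spawn(6)
    rng_geno = np.random.default_rng(ss_geno)
    rng_meta = np.random.default_rng(ss_meta)
    rng_cov = np.random.default_rng(ss_cov)
    rng_noise = np.random.default_rng(ss_noise)
    rng_items = np.random.default_rng(ss_items)
    rng_miss = np.random.default_rng(ss_miss)

    n, m = config.n_individuals, config.n_variants
    mafs = rng_meta.uniform(config.maf_range[0], config.maf_range[1], size=m)
    blocks = _block_bounds(m, config.n_blocks)
    variants = _variant_table(rng_meta, mafs, blocks, config.include_x)
    covariates, sex = _simulate_covariates(rng_cov, n, config.covariate_spec)
    male = sex == "male"

    thresholds = stats.norm.ppf(mafs)
    dosages = np.empty((n, m), dtype=float)
    for lo, hi in blocks:
        width = hi - lo
        hap1 = _ar1_latent(rng_geno, n, width, config.rho) < thresholds[lo:hi]
        hap2 = _ar1_latent(rng_geno, n, width, config.rho) < thresholds[lo:hi]
        block_chrom = variants["chrom"].iloc[lo]
        if block_chrom == "X":
            # hemizygous males carry a single haplotype, coded 0/2 under
            # the X-inactivation convention; females are diploid as usual
            g = (hap1.astype(float) + hap2.astype(float))
            g[male] = 2.0 * hap1[male].astype(float)
            dosages[:, lo:hi] = g
        else:
            dosages[:, lo:hi] = hap1.astype(float) + hap2.astype(float)

    # phenotype: unit-variance latent scale
    genetic = np.zeros(n)
    causal_effects: dict[int, float] = {}
    for idx, target in config.causal_spec:
        p = mafs[idx]
        var_g = 2.0 * p * (1.0 - p)
        beta = np.sqrt(target / var_g)
        causal_effects[idx] = float(beta)
        g = dosages[:, idx]
        genetic += beta * (g - 2.0 * p)

    cov_effect = np.zeros(n)
    if config.covariate_pve > 0 and covariates.shape[1] > 0:
        z = covariates.to_numpy(dtype=float)
        sd = z.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=0)) / sd
        w = np.full(z.shape[1], np.sqrt(config.covariate_pve / z.shape[1]))
        cov_effect = z @ w

    noise_var = 1.0 - sum(p for _, p in config.causal_spec) - config.covariate_pve
    latent = genetic + cov_effect + np.sqrt(noise_var) * rng_noise.standard_normal(n)

    if config.phenotype_mode == "bis_like":
        phenotype = _bis_like_items(rng_items, latent).astype(float)
    else:
        phenotype = latent

    if config.missing_rate > 0:
        mask = rng_miss.random((n, m)) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan
        variants = variants.copy()
        variants["call_rate"] = 1.0 - mask.mean(axis=0)

    return CohortData(
        dosages=dosages,
        variants=variants,
        phenotype=phenotype,
        covariates=covariates,
        sex=sex,
        causal_effects=causal_effects,
    )


def simulate_annotation_and_sets(
    n_genes: int,
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_set: Sequence[str] | None = None,
    seed: int = 0,
    chroms: Sequence[str] = tuple(str(c) for c in range(1, 23)),
    max_tss: int = 2_000_000,
):
    """Simulate a gene annotation and a GO-style gene-set collection.

    Genes get unique ids ``G0001``..., are spread across ``chroms`` with
    strictly increasing TSS per chromosome, and random strands.  Sets are
    sampled without replacement from the gene universe; if ``planted_set``
    is given, its genes form the first set (id ``PLANTED``), letting
    end-to-end tests concentrate a set near configured causal variants.

    Returns ``(GenomeAnnotation, GeneSetCollection)``.
    """
    from endogwas.enrich import GenomeAnnotation, GeneSetCollection

    lo, hi = set_size_range
    if not (1 <= lo <= hi <= n_genes):
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi <= n_genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gene_ids = np.array([f"G{i:04d}" for i in range(1, n_genes + 1)], dtype=object)
    chrom_assign = np.sort(rng.integers(0, len(chroms), size=n_genes))
    tss = np.empty(n_genes, dtype=np.int64)
    for c in range(len(chroms)):
        idx = np.where(chrom_assign == c)[0]
        if idx.size:
            draws = rng.choice(np.arange(1, max_tss), size=idx.size, replace=False)
            tss[idx] = np.sort(draws)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": np.asarray(chroms, dtype=object)[chrom_assign],
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )
    annotation = GenomeAnnotation(genes)

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    if planted_set is not None:
        members = frozenset(planted_set)
        unknown = members - set(gene_ids)
        if unknown:
            raise ValueError(f"planted_set genes not in universe: {sorted(unknown)}")
        sets["PLANTED"] = ("planted enriched set", members)
    n_random = n_sets - len(sets)
    for s in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(gene_ids, size=size, replace=False))
        sets[f"SET{s + 1:03d}"] = (f"random set {s + 1}", members)
    collection = GeneSetCollection(sets=sets, universe=list(gene_ids))
    return annotation, collection


def simulate_base_gwas(
    cohort: CohortData,
    h2: float,
    seed: int = 0,
    n_base: int = 100_000,
) -> pd.DataFrame:
    """Simulate external base-GWAS summary statistics for PRS weighting.

    True standardized effects are proportional to the cohort's planted
    causal effects (or, if none were planted, spread infinitesimally over
    all variants), rescaled so the implied additive genetic variance equals
    ``h2``.  Reported betas carry the sampling noise of a quantitative
    GWAS of ``n_base`` individuals with unit trait variance.

    Returns a summary-statistics table (chrom, pos, ref, alt,
    effect_allele, beta, se, p, maf, n).
    """
    if not (0.0 <= h2 < 1.0):
        raise ValueError("h2 must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    v = cohort.variants
    mafs = v["maf"].to_numpy(dtype=float)
    var_g = 2.0 * mafs * (1.0 - mafs)
    m = len(v)

    beta_std = np.zeros(m)
    if h2 > 0:
        if cohort.causal_effects:
            for idx, b in cohort.causal_effects.items():
                beta_std[idx] = b * np.sqrt(var_g[idx])
            beta_std *= np.sqrt(h2 / np.sum(beta_std**2))
        else:
            beta_std = rng.normal(0.0, np.sqrt(h2 / m), size=m)
    beta_true = beta_std / np.sqrt(var_g)

    se = 1.0 / np.sqrt(n_base * var_g)
    beta_hat = beta_true + se * rng.standard_normal(m)
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "ref": v["ref"].to_numpy(),
            "alt": v["alt"].to_numpy(),
            "effect_allele": v["alt"].to_numpy(),
            "beta": beta_hat,
            "se": se,
            "p": p,
            "maf": mafs,
            "n": np.full(m, n_base, dtype=np.int64),
        }
    )
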