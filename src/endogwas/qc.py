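"""Variant- and sample-level quality control and phenotype transforms.

Filters follow the conventions of small-cohort array GWAS: variants and
individuals below 90% call rate are removed, post-imputation variants are
kept only above MAF 1% and imputation quality r2 0.4, variants out of
Hardy-Weinberg equilibrium at P < 1e-4 are flagged but retained, and a
maximal unrelated sample is chosen at kinship coefficient < 0.088.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import lgamma, log, exp

import numpy as np
from scipy import stats

from endogwas.synthetic_data import CohortData

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "apply_variant_filters",
    "select_unrelated",
    "inverse_normal_transform",
]


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.90
    hwe_p_flag: float = 1e-4
    min_maf: float = 0.01
    min_info_r2: float = 0.4
    kinship_threshold: float = 0.088

    def validate(self) -> None:
        for name in ("min_call_rate", "hwe_p_flag", "min_maf", "min_info_r2", "kinship_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QCReport:
    """Per-rule removal tallies plus retained index sets."""

    n_variants_in: int = 0
    n_individuals_in: int = 0
    removed_call_rate_variants: int = 0
    removed_maf: int = 0
    removed_info: int = 0
    removed_call_rate_individuals: int = 0
    hwe_flagged: list[int] = field(default_factory=list)
    retained_variants: list[int] = field(default_factory=list)
    retained_individuals: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_variants_in": self.n_variants_in,
                "n_individuals_in": self.n_individuals_in,
                "removed_call_rate_variants": self.removed_call_rate_variants,
                "removed_maf": self.removed_maf,
                "removed_info": self.removed_info,
                "removed_call_rate_individuals": self.removed_call_rate_individuals,
                "n_hwe_flagged": len(self.hwe_flagged),
                "hwe_flagged": list(map(int, self.hwe_flagged)),
                "n_variants_retained": len(self.retained_variants),
                "n_individuals_retained": len(self.retained_individuals),
            },
            indent=2,
        )


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the total genotype count ``n`` and the minor-allele count,
    and sums the probabilities of every attainable heterozygote count whose
    conditional probability does not exceed that of the observed
    configuration.  The conditional probability of ``h`` heterozygotes is

        P(h | n, n1) = n! / (n_AA! h! n_aa!) * 2^h * n1! * n2! / (2n)!

    with ``n1`` minor and ``n2`` major allele counts.  Exactness matters at
    flag levels like P < 1e-4 when alleles are rare.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_alt = 2 * n_hom_alt + n_het
    n1 = min(n_alt, 2 * n - n_alt)  # minor allele count
    n2 = 2 * n - n1
    if n1 == 0:
        return 1.0

    def log_prob(h: int) -> float:
        n_minor_hom = (n1 - h) // 2
        n_major_hom = n - h - n_minor_hom
        return (
            lgamma(n + 1)
            - lgamma(n_major_hom + 1)
            - lgamma(h + 1)
            - lgamma(n_minor_hom + 1)
            + h * log(2.0)
            + lgamma(n1 + 1)
            + lgamma(n2 + 1)
            - lgamma(2 * n + 1)
        )

    h_obs = n_het
    hs = range(n1 % 2, min(n1, n2) + 1, 2)
    logs = {h: log_prob(h) for h in hs}
    lp_obs = logs[h_obs]
    # sum probabilities <= observed, with slack for floating-point ties
    included = [lp for lp in logs.values() if lp <= lp_obs + 1e-12]
    if len(included) == len(logs):
        return 1.0
    return float(min(sum(exp(lp) for lp in included), 1.0))


def _hwe_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts from a dosage column (non-integers rounded)."""
    g = dosages[~np.isnan(dosages)]
    g = np.rint(g).astype(int)
    return int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))


def apply_variant_filters(
    cohort: CohortData, thresholds: QCThresholds | None = None
) -> tuple[CohortData, QCReport]:
    """Apply variant call-rate/MAF/info filters and the HWE flagging rule.

    Variants failing call rate, MAF or imputation-quality thresholds are
    removed; variants out of HWE at the flag level are retained but listed
    in the report.  Individuals whose dosage call rate falls below the
    threshold are removed.  Raises ``ValueError`` if nothing survives.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    thresholds.validate()
    v = cohort.variants
    n_ind, n_var = cohort.dosages.shape
    report = QCReport(n_variants_in=n_var, n_individuals_in=n_ind)

    call_rate = v["call_rate"].to_numpy(dtype=float)
    maf = v["maf"].to_numpy(dtype=float)
    info = v["info_r2"].to_numpy(dtype=float)

    fail_cr = call_rate < thresholds.min_call_rate
    fail_maf = ~fail_cr & (maf <= thresholds.min_maf)
    fail_info = ~fail_cr & ~fail_maf & (info <= thresholds.min_info_r2)
    keep_var = ~(fail_cr | fail_maf | fail_info)
    report.removed_call_rate_variants = int(fail_cr.sum())
    report.removed_maf = int(fail_maf.sum())
    report.removed_info = int(fail_info.sum())

    ind_call = 1.0 - np.mean(np.isnan(cohort.dosages), axis=1)
    keep_ind = ind_call >= thresholds.min_call_rate
    report.removed_call_rate_individuals = int((~keep_ind).sum())

    if not keep_var.any() or not keep_ind.any():
        raise ValueError("no variants or individuals survive QC filters")

    var_idx = np.where(keep_var)[0]
    ind_idx = np.where(keep_ind)[0]
    dosages = cohort.dosages[np.ix_(ind_idx, var_idx)]

    for j_out, j in enumerate(var_idx):
        counts = _hwe_counts(dosages[:, j_out])
        if sum(counts) == 0:
            continue
        if hwe_exact_test(*counts) < thresholds.hwe_p_flag:
            report.hwe_flagged.append(int(j))

    report.retained_variants = [int(j) for j in var_idx]
    report.retained_individuals = [int(i) for i in ind_idx]

    index_map = {int(old): new for new, old in enumerate(var_idx)}
    filtered = CohortData(
        dosages=dosages,
        variants=v.iloc[var_idx].reset_index(drop=True),
        phenotype=cohort.phenotype[ind_idx],
        covariates=cohort.covariates.iloc[ind_idx].reset_index(drop=True),
        sex=cohort.sex[ind_idx],
        causal_effects={
            index_map[i]: b for i, b in cohort.causal_effects.items() if i in index_map
        },
    )
    return filtered, report


def select_unrelated(kinship: np.ndarray, threshold: float = 0.088) -> list[int]:
    """Greedy maximal unrelated subset at the given kinship threshold.

    Repeatedly drops the individual with the most remaining kinship ties at
    or above the threshold (ties broken by the higher row index), until no
    retained pair is related.  Deterministic; returns retained row indices
    in ascending order.
    """
    k = np.asarray(kinship, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError("kinship matrix must be square")
    if not np.allclose(k, k.T, atol=1e-12, equal_nan=True):
        raise ValueError("kinship matrix must be symmetric")
    n = k.shape[0]
    adj = k >= threshold
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1).astype(int)
    while True:
        if degree[active].max(initial=0) == 0:
            break
        deg_masked = np.where(active, degree, -1)
        worst = int(np.max(np.where(deg_masked == deg_masked.max())[0]))
        active[worst] = False
        degree[adj[worst]] -= 1
        degree[worst] = 0
    return [int(i) for i in np.where(active)[0]]


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps rank r (average ranks for ties) of m non-missing values to
    ``Phi^{-1}((r - c) / (m - 2c + 1))`` with c = 3/8.  Missing (NaN)
    entries stay missing.  Raises if fewer than 3 non-missing values or if
    all non-missing values are identical.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    m = int(mask.sum())
    if m < 3:
        raise ValueError("need at least 3 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise ValueError("transform undefined for constant input")
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / (m - 2 * offset + 1))
    return out
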