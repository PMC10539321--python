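"""Phenotypic variance explained (partial r-squared) and detection power.

PVE of a SNP (or group of SNPs) is the proportion of the residual sum of
squares of the covariate-only regression that is removed when the SNP
dosages are added:  pve = (RSS_base - RSS_full) / RSS_base.

Power for a variant explaining a fraction ``pve`` of the (covariate-
adjusted) trait variance in ``n`` individuals is the upper-tail probability
of a 1-df noncentral chi-square with noncentrality
lambda = n * pve / (1 - pve) beyond the central critical value at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from endogwas.synthetic_data import CohortData

__all__ = ["PVEResult", "PowerSpec", "pve_partial_r2", "power_detect"]


@dataclass
class PVEResult:
    rss_base: float
    rss_full: float
    pve: float


@dataclass
class PowerSpec:
    n: int
    pve: float
    alpha: float
    ncp: float
    power: float


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def pve_partial_r2(
    cohort: CohortData,
    covariates: Sequence[str] = (),
    snp_group: Sequence[int] | None = None,
) -> PVEResult:
    """Partial r-squared of a variant group over the covariate-only model.

    ``snp_group`` gives column indices into the cohort's dosage matrix.
    Both models are fit on the same complete-case individuals (non-missing
    phenotype, covariates and every group dosage).  With a single variant
    and no covariates this equals the squared Pearson correlation between
    dosage and trait.
    """
    if not snp_group:
        raise ValueError("snp_group must be non-empty")
    for j in snp_group:
        if not (0 <= j < cohort.n_variants):
            raise ValueError(f"variant index {j} not in cohort")
    y = np.asarray(cohort.phenotype, dtype=float)
    covs = (
        cohort.covariates[list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((len(y), 0))
    )
    G = cohort.dosages[:, list(snp_group)].astype(float)
    keep = ~np.isnan(y) & ~np.isnan(G).any(axis=1)
    if covs.shape[1]:
        keep &= ~np.isnan(covs).any(axis=1)
    y, covs, G = y[keep], covs[keep], G[keep]
    n = y.shape[0]
    X_base = np.column_stack([np.ones(n), covs])
    if np.linalg.matrix_rank(X_base) < X_base.shape[1]:
        raise ValueError("base model is rank deficient")
    rss_base = _rss(y, X_base)
    rss_full = _rss(y, np.column_stack([X_base, G]))
    rss_full = min(rss_full, rss_base)
    pve = 0.0 if rss_base == 0 else (rss_base - rss_full) / rss_base
    return PVEResult(rss_base=rss_base, rss_full=rss_full, pve=pve)


def power_detect(n: int, pve: float, alpha: float) -> float:
    """Power to detect a variant explaining ``pve`` of trait variance.

    Uses the 1-df noncentral chi-square with lambda = n*pve/(1-pve); at
    pve = 0 the power equals alpha exactly.
    """
    if not (0.0 <= pve < 1.0):
        raise ValueError("pve must be in [0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    crit = stats.chi2.isf(alpha, df=1)
    ncp = n * pve / (1.0 - pve)
    if ncp == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def power_spec(n: int, pve: float, alpha: float) -> PowerSpec:
    """Full power computation record (n, pve, alpha, noncentrality, power)."""
    return PowerSpec(
        n=n,
        pve=pve,
        alpha=alpha,
        ncp=n * pve / (1.0 - pve),
        power=power_detect(n, pve, alpha),
    )
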