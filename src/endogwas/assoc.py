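"""Per-variant covariate-adjusted linear association.

Each variant is tested by ordinary least squares of the trait on alternate-
allele dosage plus an intercept and the configured covariates.  Two-sided
p-values come from the t distribution with n_used - (predictors) - 1 degrees
of freedom.  On chromosome X (non-pseudoautosomal), hemizygous males are
coded 0 for the reference allele and 2 for the alternate allele, under the
assumption of X-inactivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from endogwas.synthetic_data import CohortData
from endogwas.qc import inverse_normal_transform

__all__ = ["AssocConfig", "encode_dosage_x", "run_gwas"]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class AssocConfig:
    covariates: tuple[str, ...] = ()
    transform: str = "raw"  # "raw" or "int" (inverse normal transform)
    significance_threshold: float = 5e-8
    x_male_coding: bool = True
    missing_policy: str = "complete_case"  # or "mean_impute"

    def validate(self, cohort: CohortData) -> None:
        missing = [c for c in self.covariates if c not in cohort.covariates.columns]
        if missing:
            raise ValueError(f"covariates not in cohort: {missing}")
        if self.transform not in ("raw", "int"):
            raise ValueError("transform must be 'raw' or 'int'")
        if not (0.0 < self.significance_threshold < 1.0):
            raise ValueError("significance_threshold must be in (0, 1)")
        if self.missing_policy not in ("complete_case", "mean_impute"):
            raise ValueError("missing_policy must be 'complete_case' or 'mean_impute'")


def encode_dosage_x(genotype: int, sex: str, haploid: bool = False) -> int:
    """X-chromosome dosage coding: male ref -> 0, male alt -> 2.

    ``genotype`` counts alternate alleles: for ``haploid`` male calls it is
    0 or 1; diploid-style calls use 0/1/2.  A heterozygous male diploid call
    is an error (QC should have removed it).  Female codes pass through.
    """
    if sex == "female":
        if genotype not in (0, 1, 2):
            raise ValueError(f"invalid female genotype {genotype}")
        return genotype
    if sex != "male":
        raise ValueError(f"unknown sex {sex!r}")
    if haploid:
        if genotype not in (0, 1):
            raise ValueError(f"invalid haploid male genotype {genotype}")
        return 2 * genotype
    if genotype == 1:
        raise ValueError("heterozygous male X call")
    if genotype not in (0, 2):
        raise ValueError(f"invalid male X genotype {genotype}")
    return genotype


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    order = {str(c): c for c in range(1, 23)}
    order.update({"X": 23, "Y": 24, "MT": 25})
    return chrom.map(lambda c: order.get(str(c), 99))


def _ols_single(y: np.ndarray, g: np.ndarray, covs: np.ndarray):
    """OLS of y on [1, g, covs]; returns (beta_g, se_g, p, n)."""
    n = y.shape[0]
    X = np.column_stack([np.ones(n), g, covs])
    k = X.shape[1]
    if n <= k:
        return np.nan, np.nan, 1.0, n
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        return np.nan, np.nan, 1.0, n
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    var_beta = rss / df * xtx_inv[1, 1]
    if var_beta <= 0:
        return float(coef[1]), 0.0, _TINY, n
    se = float(np.sqrt(var_beta))
    t = coef[1] / se
    p = float(np.clip(2.0 * stats.t.sf(abs(t), df), _TINY, 1.0))
    return float(coef[1]), se, p, n


def run_gwas(cohort: CohortData, config: AssocConfig | None = None) -> pd.DataFrame:
    """Covariate-adjusted OLS association of every variant with the trait.

    Returns a summary-statistics table (chrom, pos, ref, alt, beta, se, p,
    n, maf) sorted by genomic position.  Monomorphic or rank-deficient
    variants get NaN beta/se and p = 1.  Individuals missing the phenotype
    or any covariate are dropped globally; missing dosages are handled per
    variant by the configured policy (complete case or mean imputation).
    """
    if config is None:
        config = AssocConfig()
    config.validate(cohort)

    y = np.asarray(cohort.phenotype, dtype=float)
    if np.all(np.isnan(y)):
        raise ValueError("all phenotype values are missing")
    if config.transform == "int":
        y = inverse_normal_transform(y)

    covs = (
        cohort.covariates[list(config.covariates)].to_numpy(dtype=float)
        if config.covariates
        else np.empty((len(y), 0))
    )
    keep = ~np.isnan(y)
    if covs.shape[1]:
        keep &= ~np.isnan(covs).any(axis=1)
    y = y[keep]
    covs = covs[keep]
    G = cohort.dosages[keep].astype(float)
    male = (cohort.sex[keep] == "male") if len(cohort.sex) else np.zeros(keep.sum(), bool)

    variants = cohort.variants
    is_x = variants["chrom"].astype(str).to_numpy() == "X"
    if config.x_male_coding and is_x.any() and male.any():
        gx = G[np.ix_(male, np.where(is_x)[0])]
        if np.any(gx == 1.0):
            raise ValueError("heterozygous male X call; run QC or disable x_male_coding")

    if config.missing_policy == "mean_impute" and np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = np.take(col_mean, idx[1])

    n, m = G.shape
    k_cov = covs.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pvals = np.ones(m)
    n_used = np.full(m, n, dtype=np.int64)
    maf = np.full(m, np.nan)

    has_missing = np.isnan(G).any(axis=0)
    complete_cols = np.where(~has_missing)[0]

    if complete_cols.size:
        # Frisch-Waugh: residualize trait and dosages on [1, covariates]
        # once, then per-variant simple regression on the residuals.
        X0 = np.column_stack([np.ones(n), covs])
        Q, _ = np.linalg.qr(X0)
        y_r = y - Q @ (Q.T @ y)
        Gc = G[:, complete_cols]
        G_r = Gc - Q @ (Q.T @ Gc)
        gg = np.einsum("ij,ij->j", G_r, G_r)
        gy = G_r.T @ y_r
        df = n - k_cov - 2
        ok = (gg > 1e-12) & (df > 0)
        b = np.where(ok, gy / np.where(gg > 0, gg, 1.0), np.nan)
        rss = (y_r @ y_r) - b**2 * gg
        rss = np.maximum(rss, 0.0)
        var_b = np.where(ok, rss / np.maximum(df, 1) / np.where(gg > 0, gg, 1.0), np.nan)
        s = np.sqrt(var_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(s > 0, b / s, np.inf)
        p = np.where(
            ok,
            np.clip(2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1)), _TINY, 1.0),
            1.0,
        )
        beta[complete_cols] = np.where(ok, b, np.nan)
        se[complete_cols] = np.where(ok, s, np.nan)
        pvals[complete_cols] = p
        f = Gc.mean(axis=0) / 2.0
        maf[complete_cols] = np.minimum(f, 1.0 - f)

    for j in np.where(has_missing)[0]:
        g = G[:, j]
        obs = ~np.isnan(g)
        if obs.sum() == 0:
            continue
        f = np.nanmean(g) / 2.0
        maf[j] = min(f, 1.0 - f)
        b, s, p, nj = _ols_single(y[obs], g[obs], covs[obs])
        beta[j], se[j], pvals[j], n_used[j] = b, s, p, nj

    out = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "ref": variants["ref"].to_numpy(),
            "alt": variants["alt"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": pvals,
            "n": n_used,
            "maf": maf,
        }
    )
    out = out.assign(_ck=_chrom_sort_key(out["chrom"]))
    out = out.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)
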