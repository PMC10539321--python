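"""Clumping-and-thresholding polygenic scores.

Index variants are chosen greedily by ascending p-value; variants on the
same chromosome within the physical window whose LD r-squared with an index
reaches the cut are pruned.  Retained variants below the p-value threshold
are weighted by their additive-scale effect, dosages are summed per
individual, and the scores are mean-centred before a covariate-adjusted
linear association with the trait.  With a family of several scores the
Bonferroni-corrected critical value (family alpha / number of scores) is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from endogwas.synthetic_data import CohortData
from endogwas.assoc import _ols_single

__all__ = ["ClumpParams", "ScoreModel", "ScoreResult", "ld_clump", "build_score", "associate_score"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ClumpParams:
    r2_threshold: float = 0.1
    window_kb: float = 250.0
    p_threshold: float = 1.0

    def validate(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class ScoreModel:
    """Clumped, thresholded per-variant weights on the additive scale."""

    weights: pd.DataFrame  # chrom, pos, ref, alt, effect_allele, weight


@dataclass
class ScoreResult:
    scores: np.ndarray  # centred per-individual scores
    beta: float
    se: float
    p: float
    n_used: int
    bonferroni_alpha: float


class LDReference:
    """Pairwise dosage r-squared computed lazily from reference genotypes.

    Variants are keyed by (chrom, pos); r2 is the squared Pearson
    correlation of (mean-imputed) dosage columns.
    """

    def __init__(self, dosages: np.ndarray, variants: pd.DataFrame):
        G = np.asarray(dosages, dtype=float)
        if np.isnan(G).any():
            col_mean = np.nanmean(G, axis=0)
            idx = np.where(np.isnan(G))
            G = G.copy()
            G[idx] = np.take(col_mean, idx[1])
        self._G = G - G.mean(axis=0)
        self._norm = np.sqrt(np.einsum("ij,ij->j", self._G, self._G))
        self._index = {
            (str(c), int(p)): j
            for j, (c, p) in enumerate(zip(variants["chrom"], variants["pos"]))
        }

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._index

    def r2(self, key_a: tuple[str, int], key_b: tuple[str, int]) -> float:
        a, b = self._index[key_a], self._index[key_b]
        denom = self._norm[a] * self._norm[b]
        if denom == 0:
            return 0.0
        r = float(self._G[:, a] @ self._G[:, b] / denom)
        return r * r


def ld_clump(
    stats: pd.DataFrame,
    ld: "LDReference | np.ndarray",
    params: ClumpParams | None = None,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Greedy LD clumping of p-value-ranked summary statistics.

    Repeatedly takes the remaining variant with the smallest p (ties by
    chromosome, then position) as an index and removes remaining variants on
    the same chromosome within ±window_kb whose r-squared with the index is
    at or above the threshold.  Only variants with p <= p_threshold are
    considered.  ``ld`` is an :class:`LDReference` or a square r2 matrix
    aligned with ``variants`` rows.  Output is independent of input row
    order.
    """
    if params is None:
        params = ClumpParams()
    params.validate()
    if isinstance(ld, np.ndarray):
        if variants is None:
            raise ValueError("a variant table is required with a raw r2 matrix")
        lookup = {
            (str(c), int(p)): j
            for j, (c, p) in enumerate(zip(variants["chrom"], variants["pos"]))
        }

        def r2_fn(a, b):
            return float(ld[lookup[a], lookup[b]])

        contains = lookup.__contains__
    else:
        r2_fn = ld.r2
        contains = ld.__contains__

    if len(stats) == 0:
        warnings.warn("empty summary statistics; empty clump", stacklevel=2)
        return stats.iloc[0:0]

    df = stats.copy()
    keys = list(zip(df["chrom"].astype(str), df["pos"].astype(int)))
    known = np.array([contains(k) for k in keys])
    if not known.all():
        warnings.warn(
            f"{int((~known).sum())} variant(s) absent from the LD source dropped",
            stacklevel=2,
        )
    df = df.loc[known]
    df = df.loc[df["p"] <= params.p_threshold]
    from endogwas.assoc import _chrom_sort_key

    df = df.assign(_ck=_chrom_sort_key(df["chrom"].astype(str)))
    df = df.sort_values(["p", "_ck", "pos"], kind="mergesort").drop(columns="_ck")

    window = params.window_kb * 1000.0
    alive = df.copy()
    index_rows = []
    while len(alive):
        idx_row = alive.iloc[0]
        index_rows.append(idx_row)
        key_i = (str(idx_row["chrom"]), int(idx_row["pos"]))
        same = (alive["chrom"].astype(str) == key_i[0]) & (
            (alive["pos"].astype(int) - key_i[1]).abs() <= window
        )
        prune = np.zeros(len(alive), dtype=bool)
        same_idx = np.where(same.to_numpy())[0]
        for pos_j in same_idx:
            row = alive.iloc[pos_j]
            key_j = (str(row["chrom"]), int(row["pos"]))
            if key_j == key_i or r2_fn(key_i, key_j) >= params.r2_threshold:
                prune[pos_j] = True
        alive = alive.iloc[~prune]
    out = pd.DataFrame(index_rows).reset_index(drop=True)
    out = out.assign(_ck=_chrom_sort_key(out["chrom"].astype(str)))
    return out.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck").reset_index(drop=True)


def build_score(model: ScoreModel | pd.DataFrame, cohort: CohortData) -> np.ndarray:
    """Centred additive polygenic score per individual.

    score_i = sum_j dosage_ij(effect allele) * w_j, then mean-centred.
    Effect alleles matching the cohort's alt allele use the dosage as is;
    those matching ref flip the weight sign (the flipped constant vanishes
    under centring).  Strand-ambiguous A/T and G/C variants are dropped
    with a warning; missing dosages contribute the in-sample mean dosage.
    """
    weights = model.weights if isinstance(model, ScoreModel) else model
    v = cohort.variants
    lookup = {
        (str(c), int(p)): j for j, (c, p) in enumerate(zip(v["chrom"], v["pos"]))
    }
    cols, w = [], []
    n_ambig = 0
    for _, row in weights.iterrows():
        key = (str(row["chrom"]), int(row["pos"]))
        j = lookup.get(key)
        if j is None:
            continue
        ref, alt = str(v["ref"].iloc[j]), str(v["alt"].iloc[j])
        if (ref, alt) in _AMBIGUOUS:
            n_ambig += 1
            continue
        eff = str(row["effect_allele"])
        weight = float(row.get("weight", row.get("beta")))
        if eff == alt:
            cols.append(j)
            w.append(weight)
        elif eff == ref:
            cols.append(j)
            w.append(-weight)
        # effect allele matching neither: unreconcilable, skipped
    if n_ambig:
        warnings.warn(f"{n_ambig} strand-ambiguous variant(s) dropped", stacklevel=2)
    if not cols:
        raise ValueError("no variants overlap between score model and cohort")
    G = cohort.dosages[:, cols].astype(float)
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = np.take(col_mean, idx[1])
    raw = G @ np.asarray(w)
    return raw - raw.mean()


def associate_score(
    scores: np.ndarray,
    cohort: CohortData,
    covariates: tuple[str, ...] = (),
    n_scores_in_family: int = 1,
) -> ScoreResult:
    """OLS of the trait on a polygenic score plus covariates.

    Reports the score's beta, SE and two-sided p, and the Bonferroni
    critical value 0.05 / n_scores_in_family for the score family.
    """
    s = np.asarray(scores, dtype=float)
    if np.nanstd(s) == 0:
        raise ValueError("constant score vector")
    y = np.asarray(cohort.phenotype, dtype=float)
    covs = (
        cohort.covariates[list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((len(y), 0))
    )
    keep = ~np.isnan(y) & ~np.isnan(s)
    if covs.shape[1]:
        keep &= ~np.isnan(covs).any(axis=1)
    beta, se, p, n_used = _ols_single(y[keep], s[keep], covs[keep])
    return ScoreResult(
        scores=s,
        beta=beta,
        se=se,
        p=p,
        n_used=n_used,
        bonferroni_alpha=0.05 / n_scores_in_family,
    )
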