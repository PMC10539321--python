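"""Readers and writers for the text dialects the pipeline exchanges.

Formats: VCF v4.2 (GT for hard calls, DS for fractional dosages; INFO
carries MAF/R2 so imputation metadata round-trips), phenotype/covariate TSV
(individual id first column), summary-statistics TSV, gene-model TSV
(gene_id, chrom, tss, strand), GMT gene sets, and a square kinship TSV.
Every TSV starts with a ``#`` dialect comment line; readers skip it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from endogwas.synthetic_data import CohortData
from endogwas.enrich import GenomeAnnotation, GeneSetCollection

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_summary_stats",
    "read_summary_stats",
    "write_gene_models",
    "read_gene_models",
    "write_gmt",
    "read_gmt",
    "write_kinship",
    "read_kinship",
    "write_cohort",
    "read_cohort",
]

_CHROM_ORDER = [str(c) for c in range(1, 23)] + ["X"]


def _individual_ids(n: int) -> list[str]:
    return [f"I{i:05d}" for i in range(1, n + 1)]


def write_vcf(cohort: CohortData, path: str | Path) -> None:
    """Write cohort genotypes as VCF v4.2 (GT if hard calls, else DS)."""
    G = cohort.dosages
    obs = G[~np.isnan(G)]
    hard = np.allclose(obs, np.rint(obs)) if obs.size else True
    ids = _individual_ids(cohort.n_individuals)
    v = cohort.variants
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">',
        '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality r2">',
    ]
    if hard:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    else:
        lines.append('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">')
    for chrom in _CHROM_ORDER:
        if (v["chrom"].astype(str) == chrom).any():
            lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids))

    order = sorted(
        range(len(v)),
        key=lambda j: (_CHROM_ORDER.index(str(v["chrom"].iloc[j])), int(v["pos"].iloc[j])),
    )
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in order:
        row = v.iloc[j]
        info = f"MAF={row['maf']:.6g};R2={row['info_r2']:.6g}"
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            f"var_{row['chrom']}_{int(row['pos'])}",
            str(row["ref"]),
            str(row["alt"]),
            ".",
            "PASS",
            info,
            "GT" if hard else "DS",
        ]
        col = G[:, j]
        if hard:
            fields += ["./." if np.isnan(d) else gt_code[int(round(d))] for d in col]
        else:
            fields += ["." if np.isnan(d) else f"{d:.4g}" for d in col]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read dosages and variant metadata from a VCF (GT or DS field).

    Returns ``(dosages, variants)`` with NaN for missing calls; variants
    has chrom, pos, ref, alt, maf, info_r2, call_rate columns (MAF/R2 from
    INFO when present, else recomputed from the data).
    """
    from cyvcf2 import VCF

    rows = []
    dosage_cols = []
    vcf = VCF(str(path))
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = ds[:, 0].astype(float)
            col[col < 0] = np.nan
        else:
            types = np.asarray(var.gt_types, dtype=float)  # 0 ref,1 het,2 unk,3 alt
            col = np.where(types == 3, 2.0, types)
            col[types == 2] = np.nan
        maf = var.INFO.get("MAF")
        r2 = var.INFO.get("R2")
        obs = col[~np.isnan(col)]
        if maf is None:
            f = obs.mean() / 2.0 if obs.size else np.nan
            maf = min(f, 1.0 - f)
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "maf": float(maf),
                "info_r2": float(r2) if r2 is not None else 1.0,
                "call_rate": float(len(obs)) / len(col) if len(col) else 0.0,
            }
        )
        dosage_cols.append(col)
    vcf.close()
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((0, 0))
    return dosages, pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: str | Path, dialect: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# endogwas {dialect} TSV\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_phenotypes(cohort: CohortData, path: str | Path) -> None:
    """Phenotype + sex + covariates, one row per individual."""
    df = pd.DataFrame({"individual_id": _individual_ids(cohort.n_individuals)})
    df["phenotype"] = cohort.phenotype
    df["sex_label"] = cohort.sex
    for col in cohort.covariates.columns:
        df[col] = cohort.covariates[col].to_numpy()
    _write_tsv(df, path, "phenotype/covariate")


def read_phenotypes(path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Returns (phenotype, sex labels, covariate table)."""
    df = _read_tsv(path)
    phen = df["phenotype"].to_numpy(dtype=float)
    sex = df["sex_label"].to_numpy(dtype=object)
    covs = df.drop(columns=["individual_id", "phenotype", "sex_label"])
    return phen, sex, covs


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(stats, path, "summary-statistics")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_gene_models(annotation: GenomeAnnotation, path: str | Path) -> None:
    _write_tsv(annotation.genes[["gene_id", "chrom", "tss", "strand"]], path, "gene-model")


def read_gene_models(path: str | Path) -> GenomeAnnotation:
    df = _read_tsv(path)
    df["chrom"] = df["chrom"].astype(str)
    return GenomeAnnotation(df)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    """GMT: one set per line (id, description, tab-separated members).

    The background universe is written as a trailing pseudo-set with id
    ``#UNIVERSE`` so a read round-trips the full collection.
    """
    lines = []
    for set_id, (desc, members) in sets.sets.items():
        lines.append("\t".join([set_id, desc] + sorted(members)))
    lines.append("\t".join(["#UNIVERSE", "background universe"] + list(sets.universe)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    uni = universe
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        set_id, desc, members = parts[0], parts[1], parts[2:]
        if set_id == "#UNIVERSE":
            uni = members
        else:
            sets[set_id] = (desc, frozenset(members))
    if uni is None:
        uni = sorted({g for _, m in sets.values() for g in m})
    return GeneSetCollection(sets=sets, universe=list(uni))


def write_kinship(kinship: np.ndarray, path: str | Path, ids: list[str] | None = None) -> None:
    n = kinship.shape[0]
    ids = ids or _individual_ids(n)
    df = pd.DataFrame(kinship, columns=ids)
    df.insert(0, "individual_id", ids)
    _write_tsv(df, path, "kinship-matrix")


def read_kinship(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = _read_tsv(path)
    ids = df["individual_id"].astype(str).tolist()
    return df.drop(columns="individual_id").to_numpy(dtype=float), ids


def write_cohort(cohort: CohortData, vcf_path: str | Path, pheno_path: str | Path) -> None:
    write_vcf(cohort, vcf_path)
    write_phenotypes(cohort, pheno_path)


def read_cohort(vcf_path: str | Path, pheno_path: str | Path) -> CohortData:
    dosages, variants = read_vcf(vcf_path)
    phen, sex, covs = read_phenotypes(pheno_path)
    if dosages.shape[0] != len(phen):
        raise ValueError("genotype and phenotype tables have different sample counts")
    return CohortData(
        dosages=dosages,
        variants=variants,
        phenotype=phen,
        covariates=covs,
        sex=sex,
    )
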