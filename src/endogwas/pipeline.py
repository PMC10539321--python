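"""Configuration and the seeded end-to-end runner.

``run_pipeline`` chains simulate -> qc -> assoc -> enrich / prs / pve on a
single configuration dictionary and a single integer seed, writing every
stage output as text under the output directory together with a JSON
manifest (seed, config hash, per-stage counts, completed stages).  All
stage randomness is derived from the global seed; two runs with the same
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from endogwas import io as egio
from endogwas.assoc import AssocConfig, run_gwas
from endogwas.enrich import (
    DEFAULT_PERMUTATIONS,
    DEFAULT_SELECTION_THRESHOLD,
    nearest_tss_map,
    permutation_calibrate,
)
from endogwas.prs import ClumpParams, LDReference, associate_score, build_score, ld_clump
from endogwas.pve_power import power_detect, pve_partial_r2
from endogwas.qc import QCThresholds, apply_variant_filters
from endogwas.synthetic_data import (
    SimConfig,
    simulate_annotation_and_sets,
    simulate_base_gwas,
    simulate_cohort,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

logger = logging.getLogger("endogwas")

#: packaged default configuration: a small clinical cohort with two planted
#: variants at the PVE fractions the power analysis is designed around.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_individuals": 324,
        "n_variants": 1000,
        "n_blocks": 50,
        "rho": 0.8,
        "maf_range": [0.05, 0.5],
        "causal_spec": [[100, 0.101], [500, 0.093]],
        "covariate_pve": 0.10,
        "phenotype_mode": "bis_like",
        "include_x": False,
        "missing_rate": 0.0,
    },
    "annotation": {
        "n_genes": 400,
        "n_sets": 20,
        "set_size_range": [5, 25],
        "plant_causal_set": True,
    },
    "qc": {
        "min_call_rate": 0.90,
        "hwe_p_flag": 1e-4,
        "min_maf": 0.01,
        "min_info_r2": 0.4,
        "kinship_threshold": 0.088,
    },
    "assoc": {
        "covariates": ["sex", "batch", "age", "pc1", "pc2", "pc3", "seizure_freq"],
        "transform": "raw",
        "significance_threshold": 5e-8,
        "x_male_coding": True,
        "missing_policy": "complete_case",
    },
    "enrich": {
        "threshold": DEFAULT_SELECTION_THRESHOLD,
        "permutations": DEFAULT_PERMUTATIONS,
    },
    "prs": {
        "base_h2": 0.3,
        "base_n": 100000,
        "r2_threshold": 0.1,
        "window_kb": 250.0,
        "p_threshold": 0.05,
        "covariates": ["age", "sex", "seizure_freq"],
        "n_scores_in_family": 5,
    },
    "power": {"pve": 0.12, "alpha": 5e-8},
}


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> dict:
    """Default config, optionally merged with a YAML/JSON file and overrides."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    return config


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run every stage in dependency order; return the manifest dict.

    Stage errors abort the run, but the manifest (with the stages completed
    so far) is still written to ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict[str, Any] = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "completed": [],
    }

    def finish() -> dict[str, Any]:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest

    try:
        # --- simulate ---------------------------------------------------
        sim = dict(config["simulate"])
        sim_config = SimConfig(
            n_individuals=int(sim["n_individuals"]),
            n_variants=int(sim["n_variants"]),
            n_blocks=int(sim["n_blocks"]),
            rho=float(sim["rho"]),
            maf_range=tuple(sim["maf_range"]),
            causal_spec=[(int(i), float(p)) for i, p in sim.get("causal_spec", [])],
            covariate_pve=float(sim.get("covariate_pve", 0.10)),
            phenotype_mode=sim.get("phenotype_mode", "bis_like"),
            include_x=bool(sim.get("include_x", False)),
            missing_rate=float(sim.get("missing_rate", 0.0)),
            seed=seed,
        )
        cohort = simulate_cohort(sim_config)
        egio.write_vcf(cohort, out / "cohort.vcf")
        egio.write_phenotypes(cohort, out / "phenotypes.tsv")
        manifest["stages"]["simulate"] = {
            "n_individuals": cohort.n_individuals,
            "n_variants": cohort.n_variants,
        }
        manifest["completed"].append("simulate")
        logger.info("simulate: %d individuals x %d variants", cohort.n_individuals, cohort.n_variants)

        ann_cfg = config["annotation"]
        annotation, _ = simulate_annotation_and_sets(
            n_genes=int(ann_cfg["n_genes"]),
            n_sets=int(ann_cfg["n_sets"]),
            set_size_range=tuple(ann_cfg["set_size_range"]),
            planted_set=None,
            seed=seed + 1,
        )
        planted = None
        if ann_cfg.get("plant_causal_set") and cohort.causal_effects:
            planted = sorted(
                {
                    g
                    for g in (
                        annotation.nearest_gene(
                            str(cohort.variants["chrom"].iloc[j]),
                            int(cohort.variants["pos"].iloc[j]),
                        )
                        for j in cohort.causal_effects
                    )
                    if g is not None
                }
            )
        annotation, sets = simulate_annotation_and_sets(
            n_genes=int(ann_cfg["n_genes"]),
            n_sets=int(ann_cfg["n_sets"]),
            set_size_range=tuple(ann_cfg["set_size_range"]),
            planted_set=planted,
            seed=seed + 1,
        )
        egio.write_gene_models(annotation, out / "gene_models.tsv")
        egio.write_gmt(sets, out / "gene_sets.gmt")
        manifest["stages"]["annotation"] = {"n_genes": len(annotation), "n_sets": len(sets.sets)}
        manifest["completed"].append("annotation")

        # --- qc ----------------------------------------------------------
        qc_cfg = config["qc"]
        thresholds = QCThresholds(
            min_call_rate=float(qc_cfg["min_call_rate"]),
            hwe_p_flag=float(qc_cfg["hwe_p_flag"]),
            min_maf=float(qc_cfg["min_maf"]),
            min_info_r2=float(qc_cfg["min_info_r2"]),
            kinship_threshold=float(qc_cfg["kinship_threshold"]),
        )
        cohort_qc, report = apply_variant_filters(cohort, thresholds)
        (out / "qc_report.json").write_text(report.to_json())
        manifest["stages"]["qc"] = {
            "variants_in": report.n_variants_in,
            "variants_out": len(report.retained_variants),
            "individuals_out": len(report.retained_individuals),
            "hwe_flagged": len(report.hwe_flagged),
        }
        manifest["completed"].append("qc")
        logger.info("qc: %d -> %d variants", report.n_variants_in, len(report.retained_variants))

        # --- assoc --------------------------------------------------------
        assoc_cfg = config["assoc"]
        covariates = tuple(
            c for c in assoc_cfg["covariates"] if c in cohort_qc.covariates.columns
        )
        gwas = run_gwas(
            cohort_qc,
            AssocConfig(
                covariates=covariates,
                transform=assoc_cfg.get("transform", "raw"),
                significance_threshold=float(assoc_cfg.get("significance_threshold", 5e-8)),
                x_male_coding=bool(assoc_cfg.get("x_male_coding", True)),
                missing_policy=assoc_cfg.get("missing_policy", "complete_case"),
            ),
        )
        egio.write_summary_stats(gwas, out / "gwas.tsv")
        manifest["stages"]["assoc"] = {
            "n_variants": int(len(gwas)),
            "n_genome_wide": int((gwas["p"] <= assoc_cfg.get("significance_threshold", 5e-8)).sum()),
        }
        manifest["completed"].append("assoc")

        # --- enrich --------------------------------------------------------
        en_cfg = config["enrich"]
        selected, assignment = nearest_tss_map(gwas, float(en_cfg["threshold"]), annotation)
        results = permutation_calibrate(
            gwas,
            float(en_cfg["threshold"]),
            annotation,
            sets,
            B=int(en_cfg["permutations"]),
            seed=seed + 2,
        )
        enrich_df = pd.DataFrame(
            [
                {
                    "set_id": r.set_id,
                    "k": r.k,
                    "K": r.K,
                    "n": r.n,
                    "N": r.N,
                    "fold": r.fold,
                    "p_hyper": r.p_hyper,
                    "p_perm": r.p_perm,
                    "B": r.B,
                }
                for r in results
            ]
        ).sort_values(["p_perm", "p_hyper", "set_id"], kind="mergesort")
        egio.write_summary_stats(assignment, out / "variant_to_gene.tsv")
        egio.write_summary_stats(enrich_df.reset_index(drop=True), out / "enrichment.tsv")
        manifest["stages"]["enrich"] = {
            "n_selected_genes": len(selected),
            "permutations": int(en_cfg["permutations"]),
        }
        manifest["completed"].append("enrich")

        # --- prs -------------------------------------------------------------
        prs_cfg = config["prs"]
        base = simulate_base_gwas(
            cohort_qc, h2=float(prs_cfg["base_h2"]), seed=seed + 3, n_base=int(prs_cfg["base_n"])
        )
        egio.write_summary_stats(base, out / "base_gwas.tsv")
        ld = LDReference(cohort_qc.dosages, cohort_qc.variants)
        clumped = ld_clump(
            base,
            ld,
            ClumpParams(
                r2_threshold=float(prs_cfg["r2_threshold"]),
                window_kb=float(prs_cfg["window_kb"]),
                p_threshold=float(prs_cfg["p_threshold"]),
            ),
        )
        score_weights = clumped.rename(columns={"beta": "weight"})
        scores = build_score(score_weights, cohort_qc)
        prs_covs = tuple(c for c in prs_cfg["covariates"] if c in cohort_qc.covariates.columns)
        score_result = associate_score(
            scores, cohort_qc, covariates=prs_covs,
            n_scores_in_family=int(prs_cfg["n_scores_in_family"]),
        )
        score_df = pd.DataFrame(
            {"individual_id": [f"I{i:05d}" for i in range(1, cohort_qc.n_individuals + 1)],
             "prs": scores}
        )
        egio.write_summary_stats(score_df, out / "prs_scores.tsv")
        (out / "prs_association.json").write_text(
            json.dumps(
                {
                    "beta": score_result.beta,
                    "se": score_result.se,
                    "p": score_result.p,
                    "n_used": score_result.n_used,
                    "n_variants_in_score": int(len(clumped)),
                    "bonferroni_alpha": score_result.bonferroni_alpha,
                },
                indent=2,
            )
        )
        manifest["stages"]["prs"] = {
            "n_clumped": int(len(clumped)),
            "bonferroni_alpha": score_result.bonferroni_alpha,
        }
        manifest["completed"].append("prs")

        # --- pve / power ---------------------------------------------------
        pve_entries = {}
        for j in sorted(cohort_qc.causal_effects):
            res = pve_partial_r2(cohort_qc, covariates=covariates, snp_group=[j])
            key = f"{cohort_qc.variants['chrom'].iloc[j]}:{int(cohort_qc.variants['pos'].iloc[j])}"
            pve_entries[key] = res.pve
        if len(cohort_qc.causal_effects) > 1:
            res = pve_partial_r2(
                cohort_qc, covariates=covariates, snp_group=sorted(cohort_qc.causal_effects)
            )
            pve_entries["combined"] = res.pve
        pw_cfg = config["power"]
        power = power_detect(
            cohort_qc.n_individuals, float(pw_cfg["pve"]), float(pw_cfg["alpha"])
        )
        (out / "pve_power.json").write_text(
            json.dumps(
                {
                    "pve": pve_entries,
                    "power": {
                        "n": cohort_qc.n_individuals,
                        "pve": pw_cfg["pve"],
                        "alpha": pw_cfg["alpha"],
                        "power": power,
                    },
                },
                indent=2,
            )
        )
        manifest["stages"]["pve_power"] = {"power": power, "n_pve_entries": len(pve_entries)}
        manifest["completed"].append("pve_power")
    except Exception as exc:  # abort but still write the manifest
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        finish()
        raise
    return finish()
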