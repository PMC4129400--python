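"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the stage chain

    simulate -> quantify -> covariates -> scan -> permfdr -> enrich -> concordance

from a single configuration mapping (typically loaded from YAML). Every
stage writes versioned tab-delimited outputs into the output directory and
registers them in a manifest carrying the seed, the effective parameters and
a checksum per artifact, so a rerun with the same configuration produces an
identical manifest. All randomness flows from the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import array_quant, covariates as cov_mod, enrichment, io, perm_fdr, qtl_map
from .datatypes import SimulationConfig
from .synthetic import simulate_cohort

log = logging.getLogger("pqtlkit")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "pqtlkit_out",
    "stages": {
        "simulate": True,
        "quantify": True,
        "covariates": True,
        "scan": True,
        "permfdr": True,
        "enrich": True,
        "concordance": True,
    },
    "simulate": {},  # SimulationConfig field overrides
    "quantify": {"snr_threshold": 3.0, "qc_mode": "quartile"},
    "scan": {"maf_min": 0.05, "hwe_alpha": 0.001, "window": 1_000_000},
    "permfdr": {"n_replicates": 3, "target_fdr": 0.20},
    "enrich": {"n_sets": 200, "bin_width": 0.05},
}

_STAGE_ORDER = [
    "simulate",
    "quantify",
    "covariates",
    "scan",
    "permfdr",
    "enrich",
    "concordance",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge(defaults: dict, overrides: dict) -> dict:
    out = dict(defaults)
    for k, v in (overrides or {}).items():
        if k not in defaults and k not in {"effects"}:
            if k not in {"seed", "out_dir", "stages"} and not isinstance(v, dict):
                raise ValueError(f"unknown configuration key {k!r}")
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = {**out[k], **v}
        else:
            out[k] = v
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None) -> dict:
    """Run the enabled stages; return the artifact manifest.

    Raises :class:`StageError` naming the failing stage. Disabled stages
    simply skip; downstream stages that need their outputs fail fast.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "stages": {}, "artifacts": {}}
    state: dict = {}

    def register(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "stage": stage,
            "sha256": _checksum(path),
        }

    for stage in _STAGE_ORDER:
        if not cfg["stages"].get(stage, False):
            log.info("stage %s disabled; skipping", stage)
            continue
        log.info("stage %s: start", stage)
        try:
            _run_stage(stage, cfg, state, out_dir, register)
        except StageError:
            raise
        except Exception as exc:  # halt with the stage name
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = "ok"
        log.info("stage %s: done", stage)

    manifest["parameters"] = {
        k: cfg[k] for k in ("quantify", "scan", "permfdr", "enrich")
    }
    if "cohort" in state:
        manifest["parameters"]["simulate"] = asdict(state["cohort"].config)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _require(state: dict, key: str, needed_by: str):
    if key not in state:
        raise RuntimeError(
            f"stage {needed_by!r} requires output {key!r} from a disabled or "
            "failed upstream stage"
        )
    return state[key]


def _run_stage(stage, cfg, state, out_dir, register) -> None:
    seed = int(cfg["seed"])
    if stage == "simulate":
        sim_cfg = SimulationConfig(**{"seed": seed, **cfg["simulate"]})
        cohort = simulate_cohort(sim_cfg)
        state["cohort"] = cohort
        io.write_dosage_table(cohort.genotypes, out_dir / "genotypes.tsv")
        io.write_feature_table(cohort.features, out_dir / "features.tsv")
        io.write_tsv(cohort.recomb_map, out_dir / "recomb_map.tsv", stage="simulate")
        io.write_gene_models_bed(cohort.gene_models, out_dir / "gene_models.bed")
        io.write_tsv(cohort.effects, out_dir / "true_effects.tsv", stage="simulate")
        for name in ("genotypes.tsv", "features.tsv", "recomb_map.tsv",
                     "gene_models.bed", "true_effects.tsv"):
            register(stage, name, out_dir / name)
        log.info("simulate: %d variants, %d features", cohort.genotypes.n_variants,
                 len(cohort.features))
    elif stage == "quantify":
        cohort = _require(state, "cohort", stage)
        matrix = array_quant.quantify(cohort.features, **cfg["quantify"])
        state["matrix"] = matrix
        io.write_protein_matrix(matrix, out_dir / "protein_matrix")
        register(stage, "protein_matrix.tsv", out_dir / "protein_matrix.tsv")
        register(stage, "protein_matrix.traits.tsv",
                 out_dir / "protein_matrix.traits.tsv")
        log.info("quantify: %d traits retained, %d dropped",
                 len(matrix.traits), matrix.dropped_traits["trait"].nunique())
    elif stage == "covariates":
        cohort = _require(state, "cohort", stage)
        matrix = _require(state, "matrix", stage)
        report, residuals = cov_mod.fit_covariate_model(matrix, cohort.covariates)
        svs = cov_mod.estimate_surrogate_variables(residuals, seed=seed)
        state["svs"] = svs
        io.write_tsv(report, out_dir / "covariate_report.tsv", stage="covariates")
        io.write_tsv(svs.svs.reset_index(), out_dir / "surrogate_variables.tsv",
                     stage="covariates")
        register(stage, "covariate_report.tsv", out_dir / "covariate_report.tsv")
        register(stage, "surrogate_variables.tsv",
                 out_dir / "surrogate_variables.tsv")
        log.info("covariates: %d significant SVs", svs.k)
    elif stage == "scan":
        cohort = _require(state, "cohort", stage)
        matrix = _require(state, "matrix", stage)
        sc = cfg["scan"]
        genotypes, filt = qtl_map.filter_genotypes(
            cohort.genotypes, maf_min=sc["maf_min"], hwe_alpha=sc["hwe_alpha"]
        )
        log.info("scan: genotype filter %s", filt)
        blocks = qtl_map.blocks_from_recomb_map(cohort.recomb_map)
        scan = qtl_map.association_scan(matrix.values, genotypes)
        best = qtl_map.select_block_best(scan, genotypes.variants, blocks)
        best = qtl_map.classify_cis_trans(
            best, genotypes.variants, cohort.gene_models, window=sc["window"]
        )
        state.update(genotypes_filtered=genotypes, blocks=blocks, best=best)
        io.write_tsv(best, out_dir / "associations_blockbest.tsv", stage="scan")
        register(stage, "associations_blockbest.tsv",
                 out_dir / "associations_blockbest.tsv")
        log.info("scan: %d block-best associations", len(best))
    elif stage == "permfdr":
        cohort = _require(state, "cohort", stage)
        matrix = _require(state, "matrix", stage)
        genotypes = _require(state, "genotypes_filtered", stage)
        blocks = _require(state, "blocks", stage)
        best = _require(state, "best", stage)
        pf = cfg["permfdr"]
        null = perm_fdr.build_permutation_null(
            matrix.values, genotypes, genotypes.variants, blocks,
            cohort.gene_models, n_replicates=pf["n_replicates"], seed=seed,
        )
        report = []
        hit_tables = []
        for stratum in ("cis", "trans"):
            thr, hits = perm_fdr.threshold_for_fdr(
                best, null, pf["target_fdr"], stratum
            )
            report.append((stratum, thr if thr is not None else np.nan, len(hits)))
            hits = hits.assign(stratum=stratum)
            hit_tables.append(hits)
        state["hits"] = pd.concat(hit_tables, ignore_index=True)
        io.write_tsv(
            pd.DataFrame(report, columns=["stratum", "p_threshold", "n_hits"]),
            out_dir / "fdr_thresholds.tsv", stage="permfdr",
        )
        io.write_tsv(state["hits"], out_dir / "significant_hits.tsv",
                     stage="permfdr")
        register(stage, "fdr_thresholds.tsv", out_dir / "fdr_thresholds.tsv")
        register(stage, "significant_hits.tsv", out_dir / "significant_hits.tsv")
        log.info("permfdr: %d significant hits", len(state["hits"]))
    elif stage == "enrich":
        genotypes = _require(state, "genotypes_filtered", stage)
        best = _require(state, "best", stage)
        qtl = best.loc[best["p"] < 1e-4, "variant_id"].unique()
        if len(qtl) == 0:
            log.info("enrich: no QTL variants at p<1e-4; skipping tests")
            return
        rng = np.random.default_rng(seed + 1)
        ann = pd.Series(
            rng.choice(enrichment.ANNOTATION_CLASSES, size=genotypes.n_variants),
            index=genotypes.variant_ids,
        )
        report = enrichment.annotation_enrichment(
            qtl, genotypes.variant_ids, ann
        )
        io.write_tsv(report, out_dir / "annotation_enrichment.tsv", stage="enrich")
        register(stage, "annotation_enrichment.tsv",
                 out_dir / "annotation_enrichment.tsv")
    elif stage == "concordance":
        cohort = _require(state, "cohort", stage)
        matrix = _require(state, "matrix", stage)
        from .concordance import interindividual_correlation

        mapping = cohort.gene_antibody_map
        mapping = mapping[mapping["antibody_id"].isin(matrix.traits)]
        report = interindividual_correlation(
            matrix.values, cohort.expression["rnaseq"],
            mapping[["antibody_id", "gene_id"]],
        )
        io.write_tsv(report, out_dir / "protein_mrna_concordance.tsv",
                     stage="concordance")
        register(stage, "protein_mrna_concordance.tsv",
                 out_dir / "protein_mrna_concordance.tsv")
        log.info("concordance: median rho %.3f", report.attrs["summary"]["median"])
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage}")
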