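"""End-to-end orchestration: simulate -> preprocess -> variance -> ewas ->
composite -> mediate -> index, with one global seed, per-stage substreams,
serialized intermediate artifacts and a content-hash manifest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from immunexpo import composite as composite_mod
from immunexpo import mediation as mediation_mod
from immunexpo import preprocess as preprocess_mod
from immunexpo import variance as variance_mod
from immunexpo.errors import ConfigError
from immunexpo.ewas import run_ewas
from immunexpo.indexes import compute_index, compute_weights, weights_to_table
from immunexpo.io import file_sha256, read_table, write_json, write_table
from immunexpo.synthetic import config_from_dict, generate_cohort

STAGES = ("simulate", "preprocess", "variance", "ewas", "composite",
          "mediate", "index")
_DEPENDS = {"preprocess": "simulate", "variance": "preprocess",
            "ewas": "preprocess", "composite": "preprocess",
            "mediate": "ewas", "index": "mediate"}


def validate_config(config: dict) -> list[str]:
    """Schema/range/dependency check; returns a list of problems (empty = ok)."""
    problems = []
    if "seed" not in config:
        problems.append("missing required field 'seed'")
    elif not isinstance(config["seed"], int):
        problems.append("'seed' must be an integer")
    stages = config.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            problems.append(f"unknown stage {s!r}")
    for s in stages:
        dep = _DEPENDS.get(s)
        if dep and dep not in stages and "input_dir" not in config:
            problems.append(f"stage {s!r} requires stage {dep!r} (or 'input_dir')")
    med = config.get("mediation", {})
    if med.get("n_boot", 1000) < 1:
        problems.append("'mediation.n_boot' must be positive")
    var = config.get("variance", {})
    if var.get("n_perm", 1000) < 1:
        problems.append("'variance.n_perm' must be positive")
    for path_key in ("input_dir",):
        if path_key in config and not Path(config[path_key]).exists():
            problems.append(f"'{path_key}' does not exist: {config[path_key]}")
    return problems


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0]) for s, c in zip(STAGES, children)}


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages in order; returns the artifact manifest.

    Each stage reads the previous stage's serialized outputs from ``outdir``.
    Failures abort with the failing stage named; completed artifacts are
    retained.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("config", "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    seeds = _stage_seeds(int(config["seed"]))
    artifacts: dict[str, str] = {}
    thresholds = {
        "skew_outlier_threshold": 2.15, "fdr_threshold": 0.05,
        "correlation_threshold_r": config.get("composite", {}).get("threshold_r", 0.2),
        "redundancy_r": 0.4, "knn_k": config.get("qc", {}).get("knn_k", 5),
        "n_perm": config.get("variance", {}).get("n_perm", 1000),
        "n_boot": config.get("mediation", {}).get("n_boot", 1000),
    }

    def record(name: str, path: Path):
        artifacts[name] = str(path.relative_to(outdir))

    current = None
    try:
        if "simulate" in stages:
            current = "simulate"
            syn = dict(config.get("synthetic", {}))
            syn.setdefault("seed", seeds["simulate"])
            bundle = generate_cohort(config_from_dict(syn))
            for name, path in bundle.write(outdir / "cohort").items():
                record(f"cohort/{name}", Path(path))
        cohort_dir = Path(config.get("input_dir", outdir / "cohort"))

        if "preprocess" in stages:
            current = "preprocess"
            pheno = read_table(cohort_dir / "phenotypes.tsv")
            expo = read_table(cohort_dir / "exposures.tsv")
            covars = read_table(cohort_dir / "covariates.tsv")
            omics = read_table(cohort_dir / "omics.tsv")
            qc = preprocess_mod.QCParams(**config.get("qc", {}))
            clean_pheno, report = preprocess_mod.preprocess_phenotypes(
                pheno, covars["sampling_day"].to_numpy(), qc)
            expo = preprocess_mod.exposure_inclusion_filter(expo)
            expo = pd.DataFrame(
                {c: preprocess_mod.standardize(expo[c].to_numpy(float))
                 for c in expo.columns}, index=expo.index)
            expo = preprocess_mod.knn_impute(expo, qc.knn_k)
            omics, _ = preprocess_mod.filter_detection(
                omics, qc.detection_min_fraction)
            omics, _ = preprocess_mod.clip_sd_outliers(omics, qc.sd_clip)
            omics = omics.fillna(omics.mean())
            pdir = outdir / "preprocessed"
            record("preprocessed/phenotypes",
                   write_table(clean_pheno, pdir / "phenotypes.tsv"))
            record("preprocessed/exposures",
                   write_table(expo, pdir / "exposures.tsv"))
            record("preprocessed/omics", write_table(omics, pdir / "omics.tsv"))
            record("preprocessed/covariates",
                   write_table(covars, pdir / "covariates.tsv"))
            record("preprocessed/qc_report",
                   write_table(report, pdir / "qc_report.tsv"))

        pdir = outdir / "preprocessed"
        if any(s in stages for s in ("variance", "ewas", "composite",
                                     "mediate", "index")):
            pheno = read_table(pdir / "phenotypes.tsv")
            expo = read_table(pdir / "exposures.tsv")
            covars = read_table(pdir / "covariates.tsv")
            omics = read_table(pdir / "omics.tsv")
            from immunexpo.ewas import covariate_design
            basic = covariate_design(covars)

        if "variance" in stages:
            current = "variance"
            vcfg = config.get("variance", {})
            resid = variance_mod.residualize_covariates(pheno, basic)
            dist = variance_mod.euclidean_distance(resid)
            comps = variance_mod.single_factor_scan(
                dist, expo, n_perm=vcfg.get("n_perm", 1000),
                seed=seeds["variance"])
            reps = variance_mod.screen_and_prune(comps, expo)
            table = variance_mod.components_table(comps)
            record("variance/single_factor",
                   write_table(table, outdir / "variance" / "single_factor.tsv"))
            if reps:
                multi = variance_mod.permanova(
                    dist, expo[reps], n_perm=vcfg.get("n_perm", 1000),
                    seed=seeds["variance"] + 1)
                record("variance/multivariate",
                       write_table(variance_mod.components_table(multi),
                                   outdir / "variance" / "multivariate.tsv"))
            write_json({"representatives": reps},
                       outdir / "variance" / "representatives.json")
            record("variance/representatives",
                   outdir / "variance" / "representatives.json")

        if "ewas" in stages:
            current = "ewas"
            ecfg = config.get("ewas", {})
            table = run_ewas(pheno, expo, covars,
                             season_coding=ecfg.get("season_coding", "month"))
            record("ewas/associations",
                   write_table(table.set_index("exposure"),
                               outdir / "ewas" / "associations.tsv"))

        if "composite" in stages:
            current = "composite"
            ccfg = config.get("composite", {})
            k, model = composite_mod.select_cluster_count(
                expo, k_start=ccfg.get("k_start", 2),
                threshold_r=ccfg.get("threshold_r", 0.2),
                alpha_bonf=ccfg.get("alpha_bonf", 0.05))
            cdir = outdir / "composite"
            record("composite/clusters",
                   write_table(model.clusters.to_frame(), cdir / "clusters.tsv"))
            record("composite/loadings",
                   write_table(pd.DataFrame({
                       "outer_weight": model.outer_weights,
                       "loading": model.loadings}), cdir / "loadings.tsv"))
            record("composite/scores",
                   write_table(model.scores, cdir / "lv_scores.tsv"))
            write_json({"k": k, "n_iterations": model.n_iterations,
                        "final_change": model.final_change},
                       cdir / "convergence.json")
            record("composite/convergence", cdir / "convergence.json")
            lv_ewas = composite_mod.composite_ewas(model, pheno, covars)
            record("composite/lv_associations",
                   write_table(lv_ewas.set_index("exposure"),
                               cdir / "lv_associations.tsv"))

        if "mediate" in stages:
            current = "mediate"
            mcfg = config.get("mediation", {})
            assoc = read_table(outdir / "ewas" / "associations.tsv")
            sig = assoc[assoc["significant"]]
            max_pairs = mcfg.get("max_pairs", 50)
            pairs = list(sig.sort_values("fdr_coef")
                         .head(max_pairs)
                         .reset_index()[["exposure", "phenotype"]]
                         .itertuples(index=False, name=None))
            resid_pheno = variance_mod.residualize_covariates(pheno, basic)
            resid_omics = variance_mod.residualize_covariates(omics, basic)
            records = mediation_mod.run_bidirectional_scan(
                pairs, expo, resid_pheno, resid_omics,
                n_boot=mcfg.get("n_boot", 1000), seed=seeds["mediate"])
            record("mediation/records",
                   write_table(records.set_index("exposure")
                               if len(records) else records,
                               outdir / "mediation" / "records.tsv"))

        if "index" in stages:
            current = "index"
            records = read_table(outdir / "mediation" / "records.tsv")
            records = records.reset_index()
            idir = outdir / "index"
            built = []
            classified = records[records["direction"].isin(["D1", "D2"])] \
                if len(records) else records
            for exposure_id in (classified["exposure"].unique()
                                if len(classified) else []):
                w = compute_weights(records, exposure_id)
                if len(w.prop_sum) == 0:
                    continue
                scores = compute_index(omics, w)
                record(f"index/{exposure_id}_weights",
                       write_table(weights_to_table(w).set_index("feature"),
                                   idir / f"{exposure_id}_weights.tsv"))
                record(f"index/{exposure_id}_scores",
                       write_table(scores.values.to_frame(),
                                   idir / f"{exposure_id}_scores.tsv"))
                built.append(exposure_id)
            write_json({"indexes": sorted(built)}, idir / "built.json")
            record("index/built", idir / "built.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "seed": int(config["seed"]),
        "stages": stages,
        "thresholds": thresholds,
        "files": {name: file_sha256(outdir / rel)
                  for name, rel in sorted(artifacts.items())},
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
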