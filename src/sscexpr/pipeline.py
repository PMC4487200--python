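"""End-to-end orchestration of the trial analysis.

One declarative config drives the full chain: synthetic-data generation
(or loading of user files), preprocessing, intrinsic-subset assignment,
responder classification, differential expression, enrichment, and the
clinical statistics.  Every stage writes its artifact to the output
directory and contributes counts to a JSON run report; a stage failure
halts the run with the report covering everything up to the failure.
The report's patient table carries the study's central join: responder
status, baseline subset call, and the baseline-to-post signature delta
per patient.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as cs
from . import diffexpr, enrichment, intrinsic, io, preprocess, simulate

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]

STAGES = ["simulate", "preprocess", "subtype", "improvers", "markers", "enrichment", "clinical", "join"]


def default_config() -> dict:
    """A complete, runnable config using the synthetic cohort."""
    return {
        "seed": 0,
        "output_dir": "sscexpr_run",
        "simulate": {"enabled": True},
        "inputs": {},
        "preprocess": {"max_missing_frac": 0.2, "knn_k": 10, "center": True},
        "subtype": {"signature": "inflammatory_signature"},
        "markers": {"alpha": 0.05},
        "enrichment": {"enabled": True, "n_perm": 1000, "weight": 1.0,
                       "min_size": 2, "max_size": 500, "ssgsea_alpha": 0.75},
        "clinical": {"interaction": False},
    }


def _counts(obj) -> dict:
    if isinstance(obj, pd.DataFrame):
        return {"n_rows": int(obj.shape[0]), "n_cols": int(obj.shape[1])}
    return {"n": len(obj)}


def run_pipeline(config: dict) -> dict:
    """Execute the analysis described by ``config``; return the run report."""
    cfg = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "config": cfg, "stages": {}, "warnings": []}

    def finish(stage: str, error: str | None = None) -> None:
        if error:
            report["stages"][stage] = {"status": "failed", "error": error}
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)

    stage = "simulate"
    try:
        # ---- inputs ------------------------------------------------------
        if cfg["simulate"].get("enabled", True):
            sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
            sim_cfg = simulate.SimulationConfig(seed=seed, **sim_kwargs)
            ref_expr, ref_labels, ref_truth = simulate.generate_reference_cohort(sim_cfg)
            trial = simulate.generate_trial_cohort(sim_cfg)
            expr, clin = trial["expression"], trial["clinical"]
            gene_sets = sim_cfg.signature_sets()
            io.write_expression(ref_expr, outdir / "reference_expression.tsv")
            io.write_expression(expr, outdir / "trial_expression.tsv")
            clin.to_csv(outdir / "clinical.csv", index=False)
            io.write_gmt(gene_sets, outdir / "signatures.gmt")
            pd.Series(ref_labels).to_csv(outdir / "reference_labels.csv", header=False)
            report["stages"][stage] = {"status": "ok", "truth_improvers": trial["truth"]["improver"],
                                       "truth_subsets": trial["truth"]["subsets"],
                                       **_counts(expr)}
            truth = trial["truth"]
        else:
            inputs = cfg["inputs"]
            expr = io.read_expression(inputs["expression"])
            ref_expr = io.read_expression(inputs["reference_expression"])
            ref_labels = io.read_labels(inputs["reference_labels"])
            clin = io.read_clinical_long(inputs["clinical"])
            gene_sets = io.read_gmt(inputs["gene_sets"]) if "gene_sets" in inputs else {}
            truth = None
            report["stages"][stage] = {"status": "skipped (user inputs)", **_counts(expr)}

        # ---- preprocess --------------------------------------------------
        stage = "preprocess"
        pp_cfg = preprocess.PreprocessConfig(**{
            k: v for k, v in cfg["preprocess"].items()
            if k in ("max_missing_frac", "knn_k", "collapse_rule", "center", "center_before_collapse")
        })
        annotation = None
        if cfg["preprocess"].get("annotation"):
            annotation = io.read_annotation(cfg["preprocess"]["annotation"])
        expr_p, pp_report = preprocess.run_preprocess(expr, annotation, pp_cfg)
        ref_p, _ = preprocess.run_preprocess(ref_expr, annotation, pp_cfg)
        io.write_expression(expr_p, outdir / "expression_processed.tsv")
        report["stages"][stage] = {"status": "ok", "report": pp_report, **_counts(expr_p)}

        # ---- subtype -----------------------------------------------------
        stage = "subtype"
        centroids = intrinsic.build_subset_centroids(ref_p, ref_labels)
        patient_samples = [c for c in expr_p.columns if c.endswith(("_base", "_post"))] or list(expr_p.columns)
        calls = intrinsic.assign_all_samples(expr_p, centroids, samples=patient_samples)
        calls.to_csv(outdir / "subset_calls.csv")
        sig_name = cfg["subtype"].get("signature")
        sig_scores = None
        if gene_sets and sig_name in gene_sets:
            sig_scores = intrinsic.score_signature(expr_p, gene_sets[sig_name],
                                                   samples=patient_samples, set_name=sig_name)
            sig_scores.to_csv(outdir / "signature_scores.csv")
        report["stages"][stage] = {"status": "ok", "calls": calls["call"].value_counts().to_dict()}

        # ---- improver classification ------------------------------------
        stage = "improvers"
        clin_locf = cs.apply_locf(clin)
        improvers = cs.classify_improver(clin_locf)
        improvers.to_csv(outdir / "improvers.csv")
        report["stages"][stage] = {
            "status": "ok",
            "n_improvers": int(improvers["improver"].sum()),
            "by_arm": improvers.groupby("arm")["improver"].sum().astype(int).to_dict(),
        }

        # ---- markers: baseline vs post in treated improvers --------------
        stage = "markers"
        imp_ids = improvers.index[improvers["improver"] & (improvers["arm"] == "abatacept")].tolist()
        markers_table = None
        if len(imp_ids) >= 2 and all(
            f"{p}_{s}" in expr_p.columns for p in imp_ids for s in ("base", "post")
        ):
            classes = diffexpr.ClassAssignment(
                classes={**{f"{p}_base": "A" for p in imp_ids}, **{f"{p}_post": "B" for p in imp_ids}},
                pairing={f"{p}_base": f"{p}_post" for p in imp_ids},
            )
            markers_table = diffexpr.two_class_marker_selection(
                expr_p, classes, paired=True, alpha=cfg["markers"]["alpha"])
            markers_table.to_csv(outdir / "markers_improver_base_vs_post.tsv", sep="\t", index=False)
            report["stages"][stage] = {
                "status": "ok",
                "n_significant": int(markers_table["significant"].sum()),
                "n_genes": int(markers_table.shape[0]),
            }
        else:
            report["stages"][stage] = {"status": "skipped (fewer than 2 treated improvers with expression)"}

        # ---- enrichment --------------------------------------------------
        stage = "enrichment"
        if cfg["enrichment"].get("enabled", True) and gene_sets and markers_table is not None:
            ecfg = cfg["enrichment"]
            classes = diffexpr.ClassAssignment(
                classes={**{f"{p}_base": "A" for p in imp_ids}, **{f"{p}_post": "B" for p in imp_ids}},
            )
            gsea_table = enrichment.gsea(
                expr_p, classes, gene_sets, n_perm=ecfg["n_perm"], weight=ecfg["weight"],
                min_size=ecfg["min_size"], max_size=ecfg["max_size"], seed=seed)
            gsea_out = gsea_table.drop(columns="core_enrichment")
            gsea_out.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
            proj = enrichment.ssgsea_project(expr_p, gene_sets, alpha=ecfg["ssgsea_alpha"])
            proj.to_csv(outdir / "ssgsea.tsv", sep="\t")
            report["stages"][stage] = {
                "status": "ok",
                "n_sets": int(gsea_table.shape[0]),
                "n_significant": int(gsea_table["significant"].sum()),
            }
        else:
            report["stages"][stage] = {"status": "skipped"}

        # ---- clinical statistics ----------------------------------------
        stage = "clinical"
        by_arm = improvers.groupby("arm")["improver"].agg(["sum", "count"])
        if {"abatacept", "placebo"} <= set(by_arm.index):
            a_imp, a_n = int(by_arm.loc["abatacept", "sum"]), int(by_arm.loc["abatacept", "count"])
            p_imp, p_n = int(by_arm.loc["placebo", "sum"]), int(by_arm.loc["placebo", "count"])
            fisher = cs.fisher_exact_2x2(a_imp, a_n - a_imp, p_imp, p_n - p_imp)
        else:
            fisher = {"p": float("nan"), "degenerate": True}
        mixed = cs.fit_mrss_mixed_model(clin_locf, interaction=cfg["clinical"].get("interaction", False))
        wilcoxon = {}
        for arm, grp in improvers.groupby("arm"):
            diffs = (grp["final_mrss"] - grp["baseline_mrss"]).to_numpy()
            if np.any(diffs != 0):
                wilcoxon[arm] = cs.wilcoxon_signed_rank(diffs)
        report["stages"][stage] = {
            "status": "ok",
            "fisher_improvers": fisher,
            "mixed_model": mixed,
            "wilcoxon_by_arm": wilcoxon,
        }

        # ---- per-patient join -------------------------------------------
        stage = "join"
        join = improvers.copy()
        base_ids = {p: f"{p}_base" for p in join.index}
        join["baseline_subset"] = [
            calls.loc[base_ids[p], "call"] if base_ids[p] in calls.index else None for p in join.index
        ]
        if sig_scores is not None:
            delta = {}
            for p in join.index:
                b, t = f"{p}_base", f"{p}_post"
                if b in sig_scores.index and t in sig_scores.index:
                    delta[p] = float(sig_scores.loc[t, "score"] - sig_scores.loc[b, "score"])
            join["signature_delta"] = pd.Series(delta)
        join.to_csv(outdir / "patient_join.csv")
        report["stages"][stage] = {"status": "ok", "table": join.reset_index().to_dict(orient="records")}
        if truth is not None:
            agree = np.mean([
                truth["subsets"][p] == join.loc[p, "baseline_subset"] for p in join.index
            ])
            report["stages"][stage]["subset_recovery_vs_truth"] = float(agree)
    except Exception as exc:  # noqa: BLE001 - report then surface
        finish(stage, error=f"{type(exc).__name__}: {exc}")
        raise

    finish("done")
    return report
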