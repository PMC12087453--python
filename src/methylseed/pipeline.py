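"""End-to-end orchestration of the methylation analysis stages.

Stage order: simulate → preprocess → sov_adjust → dm → enrich → stemness →
integrate → classify.  Each stage writes its artifacts plus a JSON manifest
(parameters, seed, sha256 checksums), so a rerun with the same config
produces byte-identical outputs.  Stage dependencies are validated before
any computation; a stage failure aborts the run with a FAILED marker file
but keeps earlier outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import io as msio
from .classifier import evaluate_transfer, roc_curve, select_markers, train_obesity_model
from .confounders import genomic_inflation, residualize, shuffled_null_lambda, sov_analysis
from .diffmeth import call_dm, exclude_dmr_cpgs, moderated_ttest, region_distribution
from .enrichment import (
    compare_groups_wilcoxon,
    enrich_pathways,
    map_cpgs_to_pathways,
    pathway_beta_score,
)
from .integration import gene_methyl_correlation, promoter_gene_beta
from .preprocess import ProbeMask, batch_adjust, beta_to_m, filter_probes
from .simulate import SimulationConfig, generate_external_cohort, simulate_all
from .stemness import compare_stemness, stemness_scores

STAGES = ("simulate", "preprocess", "sov_adjust", "dm", "enrich", "stemness", "integrate", "classify")
DEPENDS = {
    "preprocess": ["simulate"],
    "sov_adjust": ["preprocess"],
    "dm": ["sov_adjust"],
    "enrich": ["dm"],
    "stemness": ["preprocess"],
    "integrate": ["preprocess"],
    "classify": ["enrich"],
}

DEFAULT_CONFIG: dict = {
    "stages": {s: True for s in STAGES},
    "outdir": "methylseed_run",
    "seed": 0,
    "simulate": {},
    "thresholds": {
        "detection_alpha": 0.05,
        "dm_alpha": 0.05,
        "enrichment_alpha": 0.05,
        "pcc_enrichment": -0.2,
        "pcc_top": -0.3,
        "fc_cutoff": 1.5,
        "top_k": 5,
        "split": 0.8,
        "folds": 5,
    },
    "n_perm": 20,
    "external": {"n_pos": 50, "n_neg": 50, "shift": 0.2},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(config: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    stages = cfg["stages"]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage, deps in DEPENDS.items():
        if stages.get(stage):
            missing = [d for d in deps if not stages.get(d)]
            if missing:
                raise ValueError(f"stage {stage!r} requires disabled stage(s) {missing}")
    th = cfg["thresholds"]
    for key in ("detection_alpha", "dm_alpha", "enrichment_alpha"):
        if not 0 < th[key] < 1:
            raise ValueError(f"{key} must lie in (0,1)")
    if not 0 < th["split"] < 1:
        raise ValueError("split must lie in (0,1)")
    return cfg


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Run the enabled stages; returns the run report (also written as JSON)."""
    cfg = validate_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": cfg["seed"]}
    ctx: dict = {}
    for stage in STAGES:
        if not cfg["stages"].get(stage):
            continue
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            summary = _RUNNERS[stage](cfg, ctx, stage_dir)
        except Exception as exc:
            (stage_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            msio.write_json(report, out / "run_report.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        files = sorted(p for p in stage_dir.iterdir() if p.name != "manifest.json")
        manifest = {
            "stage": stage,
            "seed": cfg["seed"],
            "parameters": cfg.get(stage, {}),
            "thresholds": cfg["thresholds"],
            "outputs": {p.name: _sha256(p) for p in files},
        }
        msio.write_json(manifest, stage_dir / "manifest.json")
        report["stages"][stage] = {"status": "ok", **summary}
    msio.write_json(report, out / "run_report.json")
    return report


def _stage_simulate(cfg: dict, ctx: dict, outdir: Path) -> dict:
    sim_cfg = SimulationConfig(**{**cfg.get("simulate", {}), "seed": cfg["seed"]})
    cohort = simulate_all(sim_cfg)
    ctx["cohort"] = cohort
    msio.write_matrix(cohort.beta, outdir / "beta.tsv")
    msio.write_metadata(cohort.metadata, cohort.factor_types, outdir / "metadata.csv")
    msio.write_annotation(cohort.annotation, outdir / "annotation.tsv")
    msio.write_gmt(cohort.pathways, outdir / "pathways.gmt")
    msio.write_bed(cohort.dmr_track.intervals, outdir / "gestational_dmrs.bed")
    msio.write_matrix(cohort.expression, outdir / "expression.tsv")
    msio.write_json(
        {
            "truth_cpg": cohort.truth_cpg,
            "truth_genes": cohort.truth_genes,
            "truth_pathways": cohort.truth_pathways,
            "dmr_probes": sorted(cohort.dmr_probes),
        },
        outdir / "truth.json",
    )
    return {"n_probes": cohort.beta.shape[0], "n_samples": cohort.beta.shape[1]}


def _stage_preprocess(cfg: dict, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    mask = ProbeMask()  # synthetic runs carry no mask files; CLI wires real ones
    filtered, rep = filter_probes(cohort.beta, mask, cfg["thresholds"]["detection_alpha"])
    m = beta_to_m(filtered)
    m_adj = batch_adjust(m, cohort.metadata.loc[m.columns, "batch"])
    ctx["beta_filtered"] = filtered
    ctx["m_adj"] = m_adj
    msio.write_matrix(m_adj, outdir / "m_adjusted.tsv")
    msio.write_json(rep.to_dict(), outdir / "filter_report.json")
    return {"probes_in": rep.n_in, "probes_out": rep.n_out}


def _stage_sov_adjust(cfg: dict, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    m_adj = ctx["m_adj"]
    factors = ["group"] + [
        c for c in cohort.metadata.columns if c not in ("group", "batch")
    ]
    sov = sov_analysis(m_adj, cohort.metadata, factors, cohort.factor_types)
    resid = residualize(m_adj, cohort.metadata, sov.selected, cohort.factor_types)
    ctx["m_resid"] = resid
    groups = cohort.metadata.loc[m_adj.columns, "group"]
    lam_pre = genomic_inflation(moderated_ttest(m_adj, groups)["p_raw"]).lambda_
    lam_post = genomic_inflation(moderated_ttest(resid, groups)["p_raw"]).lambda_
    null = shuffled_null_lambda(resid, cohort.metadata, n_perm=cfg["n_perm"], seed=cfg["seed"] + 10)
    sov.to_frame().to_csv(outdir / "sov.tsv", sep="\t", index=False, float_format="%.10g")
    msio.write_matrix(resid, outdir / "m_resid.tsv")
    msio.write_json(
        {
            "lambda_unadjusted": lam_pre,
            "lambda_adjusted": lam_post,
            "lambda_null_median": null.lambda_,
            "null_lambdas": null.null_lambdas,
        },
        outdir / "inflation.json",
    )
    return {"confounders": sov.selected, "lambda_adjusted": lam_post}


def _stage_dm(cfg: dict, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    groups = cohort.metadata.loc[ctx["m_resid"].columns, "group"]
    res = moderated_ttest(ctx["m_resid"], groups)
    res = call_dm(res, alpha=cfg["thresholds"]["dm_alpha"])
    res, dmr_log = exclude_dmr_cpgs(res, cohort.dmr_track, cohort.annotation)
    ctx["dm"] = res
    sig = res.index[res["direction"] != "none"]
    summary = {
        "n_hyper": int((res["direction"] == "hyper").sum()),
        "n_hypo": int((res["direction"] == "hypo").sum()),
        **dmr_log,
    }
    if len(sig):
        dist = region_distribution(set(sig), cohort.annotation)
        summary["island_fraction"] = dist["island"]["proportions"]["Island"]
        msio.write_json(dist, outdir / "feature_distribution.json")
    table = res.sort_values(["p_adj", "log2FC"], ascending=[True, False], key=lambda s: s.abs() if s.name == "log2FC" else s, kind="mergesort")
    table.to_csv(outdir / "dm.tsv", sep="\t", index_label="probe_id", float_format="%.10g")
    msio.write_json(summary, outdir / "dm_summary.json")
    return summary


def _stage_enrich(cfg: dict, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    res = ctx["dm"]
    universes, universe = map_cpgs_to_pathways(cohort.annotation, cohort.pathways, "promoter")
    sig = set(res.index[res["direction"] == "hyper"])
    table = enrich_pathways(sig, universes, universe, alpha=cfg["thresholds"]["enrichment_alpha"])
    ctx["enrichment"] = table
    ctx["universes"] = universes
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    groups = cohort.metadata.loc[cohort.beta.columns, "group"].to_numpy()
    rows = []
    for pw in table["pathway"]:
        if table.set_index("pathway").loc[pw, "K"] == 0:
            continue
        score = pathway_beta_score(ctx["beta_filtered"], universes, pw)
        _, p = compare_groups_wilcoxon(score.to_numpy(), groups)
        rows.append({"pathway": pw, "wilcoxon_p": p, **{s: v for s, v in score.items()}})
    pd.DataFrame(rows).to_csv(outdir / "pathway_scores.tsv", sep="\t", index=False, float_format="%.10g")
    top = table[table["significant"]]
    return {"n_significant_pathways": int(table["significant"].sum()), "top": list(top["pathway"].head(5))}


def _stage_stemness(cfg: dict, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    scores = stemness_scores(ctx["beta_filtered"])
    groups = cohort.metadata.loc[scores.entropy.index, "group"]
    test = compare_stemness(scores, groups)
    frame = scores.to_frame()
    frame["group"] = groups
    frame.to_csv(outdir / "stemness.tsv", sep="\t", index_label="sample_id", float_format="%.10g")
    msio.write_json(test, outdir / "stemness_test.json")
    return {"wilcoxon_p": test["p"], "higher_group": test["higher_group"]}


def _stage_integrate(cfg: dict, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    gene_beta, counts = promoter_gene_beta(ctx["beta_filtered"], cohort.annotation)
    rows = gene_methyl_correlation(
        gene_beta, cohort.expression, cohort.metadata["group"]
    )
    rows["n_probes"] = counts.reindex(rows.index)
    rows.to_csv(outdir / "gene_correlation.tsv", sep="\t", float_format="%.10g")
    ctx["gene_correlation"] = rows
    return {
        "n_genes": int(rows.shape[0]),
        "n_enrichment_set": int(rows["selected_enrichment"].sum()),
        "n_top_set": int(rows["selected_top"].sum()),
        "mean_pcc": float(rows["pcc"].mean()),
    }


def _stage_classify(cfg: dict, ctx: dict, outdir: Path) -> dict:
    cohort = ctx["cohort"]
    th = cfg["thresholds"]
    panel = select_markers(
        ctx["dm"], ctx["enrichment"], cohort.annotation, cohort.pathways,
        top_k=th["top_k"], alpha=th["dm_alpha"],
    )
    X = ctx["beta_filtered"].loc[panel.markers].T
    labels = cohort.metadata.loc[X.index, "group"]
    model, cv_m, hold_m = train_obesity_model(
        X, labels, split=th["split"], folds=th["folds"], seed=cfg["seed"] + 20
    )
    ext = cfg["external"]
    ext_beta, ext_labels = generate_external_cohort(
        panel.markers, ext["n_pos"], ext["n_neg"], shift=ext["shift"], seed=cfg["seed"] + 21
    )
    transfer = evaluate_transfer(model, ext_beta, ext_labels, panel, dataset="synthetic_external")
    scores = model.predict_proba(ext_beta.loc[panel.markers].T.to_numpy())[:, 1]
    points, auc = roc_curve(scores, ext_labels.to_numpy())
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(
        outdir / "roc.tsv", sep="\t", index=False, float_format="%.10g"
    )
    metrics = pd.DataFrame([cv_m.to_dict(), hold_m.to_dict(), transfer.to_dict()])
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    panel.provenance.to_csv(outdir / "marker_panel.tsv", sep="\t", float_format="%.10g")
    msio.write_json(
        {
            "markers": panel.markers,
            "hyperparameters": {"n_estimators": 500, "max_features": "sqrt"},
            "seed": cfg["seed"] + 20,
            "holdout_balanced_accuracy": hold_m.balanced_accuracy,
            "transfer_balanced_accuracy": transfer.balanced_accuracy,
            "transfer_auc": auc,
        },
        outdir / "model_card.json",
    )
    return {
        "n_markers": len(panel),
        "holdout_balanced_accuracy": hold_m.balanced_accuracy,
        "transfer_balanced_accuracy": transfer.balanced_accuracy,
    }


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "sov_adjust": _stage_sov_adjust,
    "dm": _stage_dm,
    "enrich": _stage_enrich,
    "stemness": _stage_stemness,
    "integrate": _stage_integrate,
    "classify": _stage_classify,
}
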