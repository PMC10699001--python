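"""Staged, resumable orchestration of the full analysis.

Stage order: load/transform -> regulator clustering -> one-vs-rest DE ->
overlap DEGs -> univariate Cox screen -> PCA score -> score grouping ->
associations (burden, immune signatures, survival) -> drug-sensitivity
transfer -> Lasso-Cox risk model.  Every stage persists its outputs under
the run directory and echoes its parameters into the machine-readable
RunReport, so any paper-gap default is auditable.  Re-running with the same
config and seed reproduces the report byte for byte.
"""

from __future__ import annotations

import difflib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, genomics, mixture, score as scoring, simulate, survival as surv
from .catalog import load_regulator_catalog, signature_registry
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    log2_fpkm_transform,
    read_clinical,
    read_expression,
    read_gmt,
    read_maf,
    read_seg,
    toy_arm_table,
    toy_genome,
    write_clinical,
    write_expression,
    write_maf,
    write_seg,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_status", "STAGES"]

logger = logging.getLogger("m6atlas")

STAGES = (
    "inputs",
    "cluster",
    "deg",
    "screen",
    "score",
    "associations",
    "drugs",
    "risk_model",
)

KNOWN_KEYS = {
    "seed": "random seed (mandatory)",
    "outdir": "output directory",
    "simulate": "synthetic-cohort parameters (dict) or true",
    "expression": "expression TSV path",
    "expression_scale": "raw_fpkm or log2p1",
    "clinical": "clinical TSV path",
    "seg": "SEG file path",
    "maf": "MAF file path",
    "gmt": "GMT file path (overrides the built-in signature registry)",
    "samples": "optional sample-id subset to analyze",
    "cluster": "clustering parameters (k_min, k_max, structures, n_init, scale)",
    "deg": "DE parameters (alpha, min_abs_log2fc, min_contrasts, de_scale)",
    "score": "scoring parameters (scale, k_range)",
    "lasso": "lasso parameters (n_folds, n_lambda, lambda_min_ratio)",
    "drugs": "drug model parameters (n_lines, n_genes, noise_sd)",
    "horizons": "tdAUC horizons in days",
    "resume": "reuse persisted stage outputs when present",
}

SIMULATE_KEYS = {f.name for f in __import__("dataclasses").fields(simulate.SimulationConfig)}


class PipelineConfig(dict):
    """A validated pipeline configuration (plain dict semantics)."""


def validate_config(cfg: dict) -> list[str]:
    """Return a list of issues; an empty list means the config is runnable."""
    issues = []
    for key in cfg:
        if key not in KNOWN_KEYS:
            hint = difflib.get_close_matches(key, KNOWN_KEYS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            issues.append(f"unknown config key {key!r}{suffix}")
    if "seed" not in cfg:
        issues.append("missing required key 'seed'")
    if "outdir" not in cfg:
        issues.append("missing required key 'outdir'")
    sim = cfg.get("simulate")
    if sim:
        if isinstance(sim, dict):
            for key in sim:
                if key not in SIMULATE_KEYS:
                    hint = difflib.get_close_matches(key, SIMULATE_KEYS, n=1)
                    suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
                    issues.append(f"unknown simulate key {key!r}{suffix}")
    else:
        for key in ("expression", "clinical"):
            if key not in cfg:
                issues.append(f"missing required key {key!r} (no simulate preset given)")
            elif not Path(cfg[key]).exists():
                issues.append(f"{key} file does not exist: {cfg[key]}")
        for key in ("seg", "maf", "gmt"):
            if key in cfg and not Path(cfg[key]).exists():
                issues.append(f"{key} file does not exist: {cfg[key]}")
    return issues


def stage_status(outdir: str | Path) -> dict[str, str]:
    """Per-stage state ('done' / 'pending') judged from persisted artifacts."""
    outdir = Path(outdir)
    return {
        stage: "done" if (outdir / stage / ".done").exists() else "pending"
        for stage in STAGES
    }


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, 10) if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (pd.Series,)):
        return _sanitize(obj.to_dict())
    return obj


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / ".done").write_text("done\n")


def _finish(stage_dir: Path, report: dict, stage: str, fragment: dict) -> None:
    fragment = _sanitize(fragment)
    report["stages"][stage] = fragment
    (stage_dir / "stage_report.json").write_text(
        json.dumps(fragment, indent=2, sort_keys=True)
    )
    _mark_done(stage_dir)


def _resumable(cfg, stage_dir: Path, report: dict, stage: str) -> bool:
    """True when a completed stage can be reloaded instead of recomputed."""
    frag = stage_dir / "stage_report.json"
    if cfg.get("resume") and (stage_dir / ".done").exists() and frag.exists():
        report["stages"][stage] = json.loads(frag.read_text())
        logger.info("stage %s: resumed from %s", stage, stage_dir)
        return True
    return False


def run_pipeline(cfg: dict) -> dict:
    """Run every stage in order; returns (and persists) the RunReport dict.

    Any stage error aborts with the stage name; the partial report is
    persisted as ``report.partial.json`` in the run directory.
    """
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "stages": {}, "warnings": []}

    current = "inputs"
    try:
        ctx = _stage_inputs(cfg, seed, outdir, report)
        for current in STAGES[1:]:
            globals()[f"_stage_{current}"](cfg, seed, outdir, report, ctx)
    except Exception as exc:
        (outdir / "report.partial.json").write_text(
            json.dumps(_sanitize(report), indent=2, sort_keys=True)
        )
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(_sanitize(report), indent=2, sort_keys=True) + "\n"
    )
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_inputs(cfg, seed, outdir, report) -> dict:
    stage_dir = outdir / "inputs"
    stage_dir.mkdir(exist_ok=True)
    sim = cfg.get("simulate")
    truth = None
    if sim:
        params = dict(sim) if isinstance(sim, dict) else {}
        params.setdefault("seed", seed)
        sim_cfg = simulate.SimulationConfig(**params)
        X, clinical, segs, muts, truth = simulate.generate_cohort(sim_cfg)
        write_expression(X, stage_dir / "expression.tsv")
        write_clinical(clinical, stage_dir / "clinical.tsv")
        write_seg(segs, stage_dir / "segments.seg")
        write_maf(muts, stage_dir / "mutations.maf")
        report["stages"]["inputs"] = {
            "mode": "simulate",
            "params": _sanitize(sim_cfg.__dict__),
            "n_samples": len(X.sample_ids),
            "n_genes": len(X.gene_ids),
        }
    else:
        X = read_expression(cfg["expression"], cfg.get("expression_scale", "log2p1"))
        if X.scale_tag == "raw_fpkm":
            X = log2_fpkm_transform(X)
        clinical = read_clinical(cfg["clinical"])
        segs = read_seg(cfg["seg"]) if "seg" in cfg else None
        muts = read_maf(cfg["maf"]) if "maf" in cfg else None
        report["stages"]["inputs"] = {
            "mode": "files",
            "n_samples": len(X.sample_ids),
            "n_genes": len(X.gene_ids),
        }
    if cfg.get("samples"):
        keep = [s for s in X.sample_ids if s in set(cfg["samples"])]
        X = ExpressionMatrix(X.values[keep], X.scale_tag)
        clinical = ClinicalTable(clinical.data.loc[keep])
        report["stages"]["inputs"]["n_samples_after_filter"] = len(keep)
    gene_sets = read_gmt(cfg["gmt"]) if "gmt" in cfg else None
    _mark_done(stage_dir)
    return {
        "X": X,
        "clinical": clinical,
        "segs": segs,
        "muts": muts,
        "truth": truth,
        "gene_sets": gene_sets,
    }


def _stage_cluster(cfg, seed, outdir, report, ctx) -> None:
    stage_dir = outdir / "cluster"
    stage_dir.mkdir(exist_ok=True)
    if _resumable(cfg, stage_dir, report, "cluster"):
        ctx["labels"] = pd.read_csv(stage_dir / "assignment.tsv", sep="\t",
                                    index_col=0)["label"]
        ctx["labels"].index = ctx["labels"].index.astype(str)
        return
    params = dict(cfg.get("cluster") or {})
    k_min = int(params.get("k_min", 1))
    k_max = int(params.get("k_max", 6))
    structures = tuple(params.get("structures", mixture.STRUCTURES))
    n_init = int(params.get("n_init", 4))
    scale = bool(params.get("scale", True))
    X = ctx["X"]
    catalog = load_regulator_catalog()
    panel = [g for g in catalog.symbols if g in X.values.index]
    M = X.values.loc[panel].to_numpy(float).T  # samples x genes
    if scale:
        M = (M - M.mean(axis=0)) / np.where(M.std(axis=0) > 0, M.std(axis=0), 1.0)
    model, assignment, bic_table = mixture.select_model(
        M,
        k_range=range(k_min, k_max + 1),
        structures=structures,
        seed=seed,
        n_init=n_init,
        sample_ids=X.sample_ids,
    )
    assignment.labels.to_csv(stage_dir / "assignment.tsv", sep="\t")
    bic_table.to_csv(stage_dir / "bic_table.tsv", sep="\t", index=False)
    ctx["labels"] = assignment.labels
    _finish(stage_dir, report, "cluster", {
        "params": {
            "k_range": [k_min, k_max],
            "structures": list(structures),
            "n_init": n_init,
            "scale": scale,
            "panel_size": len(panel),
        },
        "selected_k": model.K,
        "selected_structure": model.covariance_structure,
        "bic": model.bic,
        "cluster_sizes": _sanitize(assignment.sizes()),
    })


def _stage_deg(cfg, seed, outdir, report, ctx) -> None:
    stage_dir = outdir / "deg"
    stage_dir.mkdir(exist_ok=True)
    if _resumable(cfg, stage_dir, report, "deg"):
        text = (stage_dir / "overlap_degs.txt").read_text()
        ctx["overlap"] = {g for g in text.split() if g}
        return
    params = dict(cfg.get("deg") or {})
    alpha = float(params.get("alpha", 0.05))
    fc = float(params.get("min_abs_log2fc", 1.0))
    min_contrasts = params.get("min_contrasts")
    de_scale = params.get("de_scale", "log2p1")
    Xde = ctx["X"]
    if de_scale == "raw_fpkm":
        # literal raw-scale DE; not recommended (see docs/methods.md)
        Xde = ExpressionMatrix(2.0 ** Xde.values - 1.0, scale_tag="raw_fpkm")
    elif de_scale != "log2p1":
        raise ValueError(f"unknown de_scale {de_scale!r}")
    stats_by_contrast = de.moderated_stats(Xde, ctx["labels"])
    sets_primary, sets_half = [], []
    counts = {}
    for name, stat in stats_by_contrast.items():
        table = de.call_degs(stat, alpha, fc)
        table.to_csv(stage_dir / f"{name}.tsv", sep="\t")
        s1 = set(table.index[table["passes"]])
        s2 = de.deg_set(stat, alpha, 0.5)
        sets_primary.append(s1)
        sets_half.append(s2)
        counts[name] = {"n_deg_fc1": len(s1), "n_deg_fc0.5": len(s2)}
    overlap = de.overlap_degs(
        sets_primary, min_contrasts=int(min_contrasts) if min_contrasts else None
    )
    if not overlap:
        report["warnings"].append("overlap DEG set is empty")
    (stage_dir / "overlap_degs.txt").write_text("\n".join(sorted(overlap)) + "\n")
    ctx["overlap"] = overlap
    _finish(stage_dir, report, "deg", {
        "params": {"alpha": alpha, "min_abs_log2fc": fc,
                   "min_contrasts": min_contrasts, "de_scale": de_scale},
        "per_contrast": counts,
        "n_overlap_degs": len(overlap),
        "n_overlap_degs_fc0.5": len(de.overlap_degs(sets_half)),
    })


def _stage_screen(cfg, seed, outdir, report, ctx) -> None:
    stage_dir = outdir / "screen"
    stage_dir.mkdir(exist_ok=True)
    if _resumable(cfg, stage_dir, report, "screen"):
        text = (stage_dir / "significant_genes.txt").read_text()
        ctx["significant"] = {g for g in text.split() if g}
        return
    table, significant = surv.univariate_screen(
        ctx["X"], ctx["clinical"], sorted(ctx["overlap"])
    )
    table.to_csv(stage_dir / "cox_screen.tsv", sep="\t")
    (stage_dir / "significant_genes.txt").write_text("\n".join(sorted(significant)) + "\n")
    ctx["significant"] = significant
    _finish(stage_dir, report, "screen", {
        "n_screened": len(table),
        "n_significant": len(significant),
    })


def _stage_score(cfg, seed, outdir, report, ctx) -> None:
    stage_dir = outdir / "score"
    stage_dir.mkdir(exist_ok=True)
    if _resumable(cfg, stage_dir, report, "score"):
        table = pd.read_csv(stage_dir / "m6ascore.tsv", sep="\t", index_col=0)
        table.index = table.index.astype(str)
        genes = (stage_dir / "signature_genes.txt").read_text().split()
        result = scoring.M6AScoreResult(
            scores=table["m6ascore"],
            projections=table[["PC1", "PC2"]],
            signature_genes=genes,
            score_group=table["score_group"],
        )
        ctx["score_result"] = result
        ctx["signature_genes"] = genes
        return
    params = dict(cfg.get("score") or {})
    genes = scoring.select_signature_genes(ctx["overlap"], ctx["significant"])
    proj = scoring.pca_signature(ctx["X"], genes, scale=bool(params.get("scale", False)))
    result = scoring.compute_m6ascore(proj)
    groups, model = scoring.score_groups(result.scores, seed=seed)
    result.score_group = groups
    out = proj.projections.copy()
    out["m6ascore"] = result.scores
    out["score_group"] = groups
    out.to_csv(stage_dir / "m6ascore.tsv", sep="\t", index_label="sample_id")
    (stage_dir / "signature_genes.txt").write_text("\n".join(genes) + "\n")
    ctx["score_result"] = result
    ctx["signature_genes"] = genes
    _finish(stage_dir, report, "score", {
        "n_signature_genes": len(genes),
        "explained_variance_ratio": _sanitize(proj.explained_variance_ratio),
        "score_group_sizes": _sanitize(groups.value_counts().sort_index()),
        "score_group_k": model.K,
    })


def _stage_associations(cfg, seed, outdir, report, ctx) -> None:
    stage_dir = outdir / "associations"
    stage_dir.mkdir(exist_ok=True)
    if _resumable(cfg, stage_dir, report, "associations"):
        return
    X = ctx["X"]
    burden = None
    if ctx["segs"] is not None and ctx["muts"] is not None:
        bt = genomics.burden_table(
            ctx["segs"], ctx["muts"], toy_arm_table(toy_genome()), X.sample_ids
        )
        burden = bt.data
        burden.to_csv(stage_dir / "burden.tsv", sep="\t", index_label="sample_id")
    sets = ctx["gene_sets"] if ctx["gene_sets"] is not None else signature_registry(True)
    sig = genomics.signature_scores(X, sets)
    sig.to_csv(stage_dir / "signature_scores.tsv", sep="\t", index_label="sample_id")
    assoc = scoring.score_associations(
        ctx["score_result"],
        burden_table=burden,
        signature_scores=sig,
        clinical=ctx["clinical"],
        cluster_labels=ctx["labels"],
    )
    assoc.pop("km_curves", None)
    ctx["signature_scores"] = sig
    ctx["burden"] = burden
    _finish(stage_dir, report, "associations", assoc)


def _stage_drugs(cfg, seed, outdir, report, ctx) -> None:
    stage_dir = outdir / "drugs"
    stage_dir.mkdir(exist_ok=True)
    if _resumable(cfg, stage_dir, report, "drugs"):
        return
    params = dict(cfg.get("drugs") or {})
    X = ctx["X"]
    if ctx["truth"] is not None:
        panel_genes = sorted(ctx["truth"].planted_deg_genes)[: int(params.get("n_genes", 40))]
    else:
        panel_genes = sorted(ctx.get("signature_genes", X.gene_ids[:40]))[:40]
    cell_expr, ic50, _ = simulate.generate_cell_line_panel(
        n_lines=int(params.get("n_lines", 150)),
        noise_sd=float(params.get("noise_sd", 0.5)),
        seed=seed + 7,
        gene_names=panel_genes,
    )
    result = ctx["score_result"]
    out = {}
    preds = {}
    for drug in ic50.columns:
        model = genomics.train_drug_model(cell_expr, ic50, drug, seed=seed)
        pred = genomics.predict_ic50(model, X)
        preds[drug] = pred
        shared = pred.index.intersection(result.score_group.index)
        H, df, p = surv.kruskal_wallis(
            pred[shared].to_numpy(), result.score_group[shared].to_numpy()
        )
        out[drug] = {"penalty": model.penalty, "kruskal_H": H, "kruskal_p": p}
    pd.DataFrame(preds).to_csv(stage_dir / "predicted_ic50.tsv", sep="\t", index_label="sample_id")
    _finish(stage_dir, report, "drugs", out)


def _stage_risk_model(cfg, seed, outdir, report, ctx) -> None:
    stage_dir = outdir / "risk_model"
    stage_dir.mkdir(exist_ok=True)
    if _resumable(cfg, stage_dir, report, "risk_model"):
        return
    params = dict(cfg.get("lasso") or {})
    horizons = list(cfg.get("horizons", [365, 730, 1095]))
    genes = ctx["signature_genes"]
    path = surv.lasso_cox(
        ctx["X"],
        ctx["clinical"],
        genes,
        n_folds=int(params.get("n_folds", 10)),
        seed=seed,
        n_lambda=int(params.get("n_lambda", 100)),
        lambda_min_ratio=float(params.get("lambda_min_ratio", 0.05)),
    )
    path.coefs.to_csv(stage_dir / "lasso_path.tsv", sep="\t")
    aucs: dict[str, float | None] = {}
    model_info: dict = {}
    try:
        model = surv.risk_model(path, ctx["X"], ctx["clinical"], horizons=horizons)
        model.scores.to_frame().join(model.groups).to_csv(
            stage_dir / "risk_scores.tsv", sep="\t", index_label="sample_id"
        )
        clin = ClinicalTable(ctx["clinical"].data.loc[model.groups.index])
        chi2, dfree, p = surv.logrank_test(clin, model.groups)
        model_info = {
            "model_genes": model.genes,
            "coefficients": _sanitize(model.coefficients),
            "cutpoint": model.cutpoint,
            "td_auc": _sanitize(model.td_auc),
            "logrank_risk_groups": {"chi2": chi2, "df": dfree, "p": p},
        }
        (stage_dir / "risk_model.json").write_text(
            json.dumps(_sanitize(model_info), indent=2, sort_keys=True)
        )
    except ValueError as exc:
        report["warnings"].append(f"risk model: {exc}")
        model_info = {"error": str(exc)}
    _finish(stage_dir, report, "risk_model", {
        "params": {
            "n_candidates": len(genes),
            "n_folds": int(params.get("n_folds", 10)),
            "horizons": horizons,
        },
        "selected_lambda": path.selected_lambda,
        "n_active": len(path.active_genes),
        **model_info,
    })
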