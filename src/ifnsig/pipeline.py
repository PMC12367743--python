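"""End-to-end orchestration: simulate or load a cohort, then run
DEG -> clustering -> enrichment -> signature scoring -> clinical stats,
writing a directory of TSVs plus a machine-readable run manifest.

Configuration is a plain mapping (round-trips through YAML); every output
byte is determined by ``(config, seed)``. Each stage consumes only
in-memory products of earlier stages or the original inputs, and any
stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

import ifnsig
from ifnsig import clinical_stats, clustering, deg_analysis, enrichment, ifn_signature
from ifnsig.io_formats import (
    read_expression,
    read_gmt,
    read_metadata,
    read_survival,
)
from ifnsig.synthetic_data import default_study_design, generate_cohort

__all__ = ["PipelineError", "default_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config(seed: int = 0) -> dict:
    """The default configuration: simulate the 6-patient design."""
    return {
        "seed": seed,
        "simulate": {"n_genes": 500, "noise_sd": 0.25},
        "deg": {
            "fc_threshold": 1.0,
            "p_threshold": 0.05,
            "min_mean_expression": 1.0,
            "grouping": "outcome_union",
        },
        "clustering": {"distance": "correlation", "linkage": "average", "k": 2},
        "enrichment": {"direction": "down", "tau": 0.25, "ora_group": "survivor"},
        "signature": {
            "sets": ["ifn_type_I", "ifn_type_II", "ifn_type_III"],
            "ddof": 1,
        },
    }


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def _load_inputs(config: Mapping[str, Any]):
    if "inputs" in config:
        paths = config["inputs"]
        expr = read_expression(paths["expression"])
        meta = read_metadata(paths["metadata"])
        gene_sets = read_gmt(paths["gmt"], paths.get("signs"))
        clinical = (
            pd.read_csv(paths["clinical"], sep="\t", dtype={"patient_id": str})
            if "clinical" in paths
            else None
        )
        survival = read_survival(paths["survival"]) if "survival" in paths else None
        meta.bind(expr)
        return expr, meta, gene_sets, clinical, survival
    sim = dict(config.get("simulate", {}))
    design = default_study_design(
        n_genes=int(sim.get("n_genes", 500)),
        noise_sd=float(sim.get("noise_sd", 0.25)),
        seed=int(config.get("seed", 0)),
    )
    cohort = generate_cohort(design)
    return (
        cohort.expression,
        cohort.metadata,
        cohort.gene_sets,
        cohort.clinical,
        cohort.survival,
    )


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run every stage and write the results bundle under *outdir*.

    Returns a dict of in-memory stage products (also written as TSVs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    stage = "inputs"
    try:
        expr, meta, gene_sets, clinical, survival = _load_inputs(config)
        logger.info(
            "inputs: %d genes x %d samples, %d gene sets",
            expr.n_genes,
            expr.n_samples,
            len(gene_sets.sets),
        )
        results["expression"] = expr
        results["metadata"] = meta
        results["gene_sets"] = gene_sets

        stage = "deg"
        deg_cfg = dict(config.get("deg", {}))
        fc = deg_analysis.per_patient_log2fc(expr, meta)
        fc_threshold = float(deg_cfg.get("fc_threshold", 1.0))
        p_threshold = deg_cfg.get("p_threshold", 0.05)
        floor = float(deg_cfg.get("min_mean_expression", 1.0))
        deg_all = deg_analysis.call_degs(
            fc,
            fc_threshold=fc_threshold,
            p_threshold=p_threshold,
            expr=expr,
            min_mean_expression=floor,
        )
        results["fold_changes"] = fc
        results["deg_table"] = deg_all
        _write_tsv(fc.to_frame().reset_index(names="gene_id"), outdir / "fold_changes.tsv")
        _write_tsv(deg_all, outdir / "deg_table.tsv")
        logger.info(
            "deg: %d genes tested, %d DEGs (joint)", len(deg_all), int(deg_all["is_deg"].sum())
        )

        grouping = deg_cfg.get("grouping", "outcome_union")
        outcome_of = meta.patient_attr("outcome")
        group_tables: dict[str, pd.DataFrame] = {}
        if grouping == "outcome_union":
            for outcome in sorted(set(outcome_of.values())):
                members = [p for p in fc.patient_ids if outcome_of[p] == outcome]
                if len(members) < 2:
                    continue
                table = deg_analysis.call_degs(
                    fc,
                    patients=members,
                    fc_threshold=fc_threshold,
                    p_threshold=p_threshold,
                    expr=expr,
                    min_mean_expression=floor,
                )
                group_tables[outcome] = table
                _write_tsv(table, outdir / f"deg_{outcome}.tsv")
            cluster_genes = sorted(
                set().union(
                    *(
                        set(t.loc[t["is_deg"], "gene_id"])
                        for t in group_tables.values()
                    )
                )
            )
        elif grouping == "all":
            cluster_genes = sorted(deg_all.loc[deg_all["is_deg"], "gene_id"])
        else:
            raise ValueError(f"unknown deg grouping {grouping!r}")
        results["deg_group_tables"] = group_tables
        results["cluster_genes"] = cluster_genes

        stage = "clustering"
        clu_cfg = dict(config.get("clustering", {}))
        dendro = clustering.cluster_patients(
            fc,
            cluster_genes,
            distance=clu_cfg.get("distance", "correlation"),
            linkage=clu_cfg.get("linkage", "average"),
        )
        concordance = clustering.outcome_concordance(
            dendro, meta, k=int(clu_cfg.get("k", 2))
        )
        results["dendrogram"] = dendro
        results["concordance"] = concordance
        (outdir / "dendrogram.newick").write_text(clustering.to_newick(dendro) + "\n")
        assign = pd.DataFrame(
            {
                "patient_id": list(concordance["assignment"]),
                "cluster": list(concordance["assignment"].values()),
            }
        )
        _write_tsv(assign, outdir / "clusters.tsv")
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "labeling": "outcome",
                        "ari": concordance["ari_outcome"],
                    },
                    {"labeling": "arm", "ari": concordance["ari_arm"]},
                ]
            ),
            outdir / "concordance.tsv",
        )
        logger.info(
            "clustering: %d genes, ARI(outcome)=%.3f ARI(arm)=%.3f",
            len(cluster_genes),
            concordance["ari_outcome"],
            concordance["ari_arm"],
        )

        stage = "enrichment"
        enr_cfg = dict(config.get("enrichment", {}))
        direction = enr_cfg.get("direction", "down")
        ora_group = enr_cfg.get("ora_group", "survivor")
        source = group_tables.get(ora_group, deg_all)
        degs = source.loc[
            source["is_deg"] & (source["direction"] == direction), "gene_id"
        ]
        universe = source["gene_id"]
        ora = enrichment.overrepresentation(degs, gene_sets, universe)
        results["enrichment"] = ora
        _write_tsv(ora, outdir / f"enrichment_{direction}.tsv")

        tau = float(enr_cfg.get("tau", 0.25))
        sv_scores = enrichment.set_variation_scores(expr, gene_sets, tau=tau)
        results["set_variation_scores"] = sv_scores
        _write_tsv(sv_scores, outdir / "set_variation_scores.tsv")
        comparisons = []
        for name in gene_sets.names():
            try:
                rep = enrichment.compare_set_scores(sv_scores, meta, name)
            except ValueError as exc:
                logger.warning("set score comparison skipped for %r: %s", name, exc)
                continue
            comparisons.append(
                {
                    "set_name": name,
                    "arm_a": rep["arms"][0],
                    "arm_b": rep["arms"][1],
                    "t": rep["t"],
                    "dof": rep["dof"],
                    "p_value": rep["p_value"],
                    "mean_delta_a": rep["mean_delta"][rep["arms"][0]],
                    "mean_delta_b": rep["mean_delta"][rep["arms"][1]],
                }
            )
        results["set_score_comparisons"] = pd.DataFrame(comparisons)
        _write_tsv(results["set_score_comparisons"], outdir / "set_score_comparisons.tsv")

        stage = "ifn_signature"
        sig_cfg = dict(config.get("signature", {}))
        set_names = sig_cfg.get("sets") or list(gene_sets.names())
        centered = ifn_signature.batch_center(expr, meta)
        nonconstant = centered.values.std(axis=1, ddof=1) > 0
        if not nonconstant.all():
            keep = [g for g, ok in zip(centered.gene_ids, nonconstant) if ok]
            frame = centered.to_frame().loc[keep]
            from ifnsig.io_formats import ExpressionMatrix

            centered = ExpressionMatrix.from_frame(frame)
        z = ifn_signature.zscore(centered, ddof=int(sig_cfg.get("ddof", 1)))
        sub_sets = {n: gene_sets.sets[n] for n in set_names if n in gene_sets.sets}
        from ifnsig.io_formats import GeneSetCollection

        sig_collection = GeneSetCollection(sets=sub_sets, signs=dict(gene_sets.signs))
        scores = ifn_signature.signature_scores(z, sig_collection)
        dynamics = ifn_signature.score_dynamics(scores, meta)
        results["signature_scores"] = scores
        results["signature_dynamics"] = dynamics
        _write_tsv(scores, outdir / "signature_scores.tsv")
        _write_tsv(dynamics["trajectories"], outdir / "signature_deltas.tsv")
        _write_tsv(dynamics["by_outcome"], outdir / "signature_deltas_by_outcome.tsv")

        outcome_rows = []
        plot_frames = []
        for name in set_names:
            if name not in gene_sets.sets:
                continue
            rep = ifn_signature.compare_fc_by_outcome(fc, meta, gene_sets.sets[name])
            a, b = rep["groups"]
            outcome_rows.append(
                {
                    "set_name": name,
                    "group_a": a,
                    "group_b": b,
                    "mean_a": rep["mean"][a],
                    "mean_b": rep["mean"][b],
                    "sd_a": rep["sd"][a],
                    "sd_b": rep["sd"][b],
                    "t": rep["t"],
                    "dof": rep["dof"],
                    "p_value": rep["p_value"],
                    "n_genes": rep["n_genes"],
                }
            )
            pf = rep["plot_data"].copy()
            pf.insert(0, "set_name", name)
            plot_frames.append(pf)
        results["fc_outcome_comparison"] = pd.DataFrame(outcome_rows)
        _write_tsv(results["fc_outcome_comparison"], outdir / "fc_outcome_comparison.tsv")
        if plot_frames:
            _write_tsv(pd.concat(plot_frames), outdir / "fc_violin_data.tsv")

        stage = "clinical_stats"
        if clinical is not None:
            surv = None
            if survival is not None:
                surv = survival.rename(columns={"arm": "group"})
                if "group" not in surv.columns:
                    raise ValueError("survival table needs a 'group' column")
            report = clinical_stats.table2_report(clinical, surv, group_col="arm")
            results["clinical_report"] = report
            _write_tsv(report, outdir / "clinical_report.tsv")
        else:
            logger.info("no clinical table provided; clinical stage skipped")

        stage = "manifest"
        manifest = {
            "config": json.loads(json.dumps(dict(config), default=str)),
            "config_sha256": _config_hash(config),
            "seed": int(config.get("seed", 0)),
            "package_version": ifnsig.__version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        results["manifest"] = manifest
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        raise PipelineError(stage, exc) from exc
    return results
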