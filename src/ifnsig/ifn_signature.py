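"""Signed z-score signature scoring and its pre/post dynamics.

The score for a signed gene set on a sample is ``sum_g c_g * z(g, s)``
where ``z`` is the genewise z-score (row-standardised across all scored
samples, sample sd with the n-1 denominator by default) computed after
per-batch mean-centering when the samples span more than one batch, and
``c_g`` is the set's +1/-1 coefficient for gene ``g`` (+1 unless the
collection says otherwise).

Also provided: per-patient score trajectories (pre, post, delta,
direction) and a genewise fold-change comparison between outcome groups
(Welch's t over the set's genewise group-mean log2 fold changes - the
unit of that test is the gene, matching violin-plot style summaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ifnsig.clinical_stats import welch_t
from ifnsig.deg_analysis import FoldChangeMatrix
from ifnsig.io_formats import ExpressionMatrix, GeneSetCollection, SampleMetadata

__all__ = [
    "batch_center",
    "zscore",
    "ZScoreMatrix",
    "signature_score",
    "signature_scores",
    "score_deltas",
    "score_dynamics",
    "compare_fc_by_outcome",
]

logger = logging.getLogger(__name__)


def batch_center(expr: ExpressionMatrix, meta: SampleMetadata) -> ExpressionMatrix:
    """Subtract each batch's per-gene mean; identity for single-batch input."""
    meta.bind(expr)
    batch_of = meta.attr_of_sample("batch")
    batches = {batch_of[s] for s in expr.sample_ids}
    if len(batches) <= 1:
        return expr
    values = expr.values.copy()
    cols_by_batch: dict[str, list[int]] = {}
    for j, s in enumerate(expr.sample_ids):
        cols_by_batch.setdefault(batch_of[s], []).append(j)
    for cols in cols_by_batch.values():
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)


@dataclass(frozen=True)
class ZScoreMatrix:
    """Row-standardised matrix: each gene has mean 0, sd 1 across samples."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.z.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def zscore(expr: ExpressionMatrix, ddof: int = 1) -> ZScoreMatrix:
    """Genewise z-scores across samples (sample sd, n-1 denominator).

    ``ddof=0`` switches to the population denominator for sensitivity
    analysis. Zero-variance genes are an error listing the offenders;
    callers may prefilter.
    """
    values = expr.values
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    sds = values.std(axis=1, ddof=ddof)
    if np.any(sds == 0):
        bad = [g for g, s in zip(expr.gene_ids, sds) if s == 0]
        raise ValueError(
            f"{len(bad)} zero-variance gene(s) cannot be z-scored: {bad[:10]}"
        )
    z = (values - values.mean(axis=1, keepdims=True)) / sds[:, None]
    return ZScoreMatrix(expr.gene_ids, expr.sample_ids, z)


def signature_score(
    z: ZScoreMatrix,
    genes: tuple[str, ...] | list[str],
    collection: GeneSetCollection | None = None,
) -> pd.Series:
    """Signed sum of set-gene z-scores per sample.

    Genes missing from the matrix are skipped with a warning; an empty
    intersection is an error. Sign coefficients come from *collection*
    (default +1 for every gene).
    """
    gene_pos = {g: i for i, g in enumerate(z.gene_ids)}
    present = [g for g in genes if g in gene_pos]
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        logger.warning(
            "%d signature gene(s) absent from matrix and skipped: %s",
            len(missing),
            missing[:10],
        )
    if not present:
        raise ValueError("no signature gene is present in the z-score matrix")
    rows = [gene_pos[g] for g in present]
    coeff = np.array(
        [collection.sign_of(g) if collection is not None else 1 for g in present],
        dtype=float,
    )
    scores = coeff @ z.z[rows]
    return pd.Series(scores, index=list(z.sample_ids), name="score")


def signature_scores(
    z: ZScoreMatrix, collection: GeneSetCollection
) -> pd.DataFrame:
    """Tidy per sample x set score table for every set in the collection."""
    rows = []
    for name, genes in collection.sets.items():
        s = signature_score(z, genes, collection)
        for sid, val in s.items():
            rows.append({"sample_id": sid, "set_name": name, "score": float(val)})
    return pd.DataFrame(rows)


def score_deltas(scores: pd.DataFrame, meta: SampleMetadata) -> pd.DataFrame:
    """Per patient x set (pre, post, delta) for patients with both timepoints."""
    by_key = {
        (r["sample_id"], r["set_name"]): r["score"] for _, r in scores.iterrows()
    }
    set_names = list(dict.fromkeys(scores["set_name"]))
    rows = []
    for pid in meta.paired_patients():
        pre_id = meta.sample_for(pid, "pre")
        post_id = meta.sample_for(pid, "post")
        for name in set_names:
            if (pre_id, name) not in by_key or (post_id, name) not in by_key:
                continue
            pre = by_key[(pre_id, name)]
            post = by_key[(post_id, name)]
            rows.append(
                {
                    "patient_id": pid,
                    "set_name": name,
                    "pre": pre,
                    "post": post,
                    "delta": post - pre,
                }
            )
    return pd.DataFrame(rows)


def score_dynamics(
    scores: pd.DataFrame,
    meta: SampleMetadata,
    flat_tolerance: float = 0.0,
) -> dict:
    """Per-patient score trajectories plus by-outcome delta summaries.

    Returns ``{"trajectories": DataFrame, "by_outcome": DataFrame}``;
    trajectories carry a direction label in {up, down, flat} (flat when
    ``|delta| <= flat_tolerance``).
    """
    deltas = score_deltas(scores, meta)
    outcome_of = meta.patient_attr("outcome")
    if deltas.empty:
        return {"trajectories": deltas, "by_outcome": pd.DataFrame()}
    deltas = deltas.copy()
    deltas["outcome"] = [outcome_of[p] for p in deltas["patient_id"]]
    deltas["direction"] = np.where(
        np.abs(deltas["delta"]) <= flat_tolerance,
        "flat",
        np.where(deltas["delta"] > 0, "up", "down"),
    )
    summary = (
        deltas.groupby(["set_name", "outcome"])["delta"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_delta", "std": "sd_delta", "count": "n"})
    )
    return {"trajectories": deltas, "by_outcome": summary}


def compare_fc_by_outcome(
    fc: FoldChangeMatrix,
    meta: SampleMetadata,
    genes: tuple[str, ...] | list[str],
) -> dict:
    """Welch's t over genewise group-mean log2 fold changes by outcome.

    For every set gene, the group value is the mean per-patient log2FC
    within the outcome group; the two gene-level vectors are compared
    with Welch's two-sample t. The genewise values are returned for
    violin-style plotting.
    """
    outcome_of = meta.patient_attr("outcome")
    groups: dict[str, list[int]] = {}
    for i, pid in enumerate(fc.patient_ids):
        groups.setdefault(outcome_of[pid], []).append(i)
    if len(groups) != 2:
        raise ValueError(f"need both outcome groups, found {sorted(groups)}")
    gene_pos = {g: i for i, g in enumerate(fc.gene_ids)}
    present = [g for g in genes if g in gene_pos]
    if len(present) < 2:
        raise ValueError("need >= 2 set genes in the matrix for a variance estimate")
    rows = [gene_pos[g] for g in present]
    (name_a, cols_a), (name_b, cols_b) = sorted(groups.items())
    means_a = fc.values[np.ix_(rows, cols_a)].mean(axis=1)
    means_b = fc.values[np.ix_(rows, cols_b)].mean(axis=1)
    t, dof, p = welch_t(means_a, means_b)
    plot_data = pd.DataFrame(
        {
            "gene_id": present * 2,
            "outcome": [name_a] * len(present) + [name_b] * len(present),
            "mean_log2fc": np.concatenate([means_a, means_b]),
        }
    )
    return {
        "groups": (name_a, name_b),
        "t": t,
        "dof": dof,
        "p_value": p,
        "mean": {name_a: float(means_a.mean()), name_b: float(means_b.mean())},
        "sd": {
            name_a: float(means_a.std(ddof=1)),
            name_b: float(means_b.std(ddof=1)),
        },
        "n_genes": len(present),
        "plot_data": plot_data,
    }
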