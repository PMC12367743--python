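"""Per-patient pre/post fold changes and threshold-based DEG calling.

Expression is already log2-scale, so a patient's fold change is simply
``post - pre`` per gene. Group-level calling uses a two-sided one-sample
t-test of the per-patient differences against zero (the natural paired
test for a pre/post design); a Welch two-sample variant on the raw pre
vs post groups is available for sensitivity analysis. A gene is a DEG
when ``|group mean log2FC| >= fc_threshold`` and ``p < p_threshold``
(defaults 1 and 0.05). Benjamini-Hochberg q-values are reported as an
extra column but play no role in the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ifnsig.io_formats import ExpressionMatrix, SampleMetadata

__all__ = ["FoldChangeMatrix", "per_patient_log2fc", "call_degs", "bh_qvalues"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Genes x patients matrix of per-patient log2 fold changes (post - pre)."""

    gene_ids: tuple[str, ...]
    patient_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.patient_ids)):
            raise ValueError("fold-change matrix shape mismatch")
        if not np.all(np.isfinite(values)):
            raise ValueError("fold-change values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.patient_ids)
        )

    def subset_patients(self, patient_ids: Sequence[str]) -> "FoldChangeMatrix":
        idx = {p: i for i, p in enumerate(self.patient_ids)}
        cols = [idx[p] for p in patient_ids]
        return FoldChangeMatrix(self.gene_ids, tuple(patient_ids), self.values[:, cols])


def per_patient_log2fc(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    strict: bool = False,
) -> FoldChangeMatrix:
    """Compute post - pre log2 fold change per gene for every paired patient.

    Patients lacking a timepoint are excluded with a warning, or rejected
    when ``strict`` is set.
    """
    meta.bind(expr)
    sample_idx = expr.sample_index()
    patients = []
    cols = []
    for pid in meta.patient_ids:
        pre = meta.sample_for(pid, "pre")
        post = meta.sample_for(pid, "post")
        if pre is None or post is None:
            msg = f"patient {pid!r} lacks a {'pre' if pre is None else 'post'} sample"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; excluded from fold-change matrix", msg)
            continue
        cols.append(expr.values[:, sample_idx[post]] - expr.values[:, sample_idx[pre]])
        patients.append(pid)
    if not patients:
        raise ValueError("no patient has both pre and post samples")
    return FoldChangeMatrix(expr.gene_ids, tuple(patients), np.column_stack(cols))


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def call_degs(
    fc: FoldChangeMatrix,
    patients: Sequence[str] | None = None,
    fc_threshold: float = 1.0,
    p_threshold: float | None = 0.05,
    expr: ExpressionMatrix | None = None,
    min_mean_expression: float = 1.0,
    test: str = "paired",
    meta: SampleMetadata | None = None,
) -> pd.DataFrame:
    """Call DEGs over a patient group from per-patient fold changes.

    Parameters
    ----------
    fc : FoldChangeMatrix
        Per-patient log2 fold changes.
    patients : sequence of str, optional
        Subset of patients defining the analysis group (default: all).
    fc_threshold, p_threshold : float
        The DEG filter: ``|mean log2FC| >= fc_threshold`` and
        ``p < p_threshold``. Pass ``p_threshold=None`` for a
        fold-change-only call (no test; required when only one patient
        is available).
    expr, min_mean_expression : optional low-expression prefilter
        When *expr* is given, genes whose mean log2 expression across all
        its samples falls below ``min_mean_expression`` are dropped
        before testing.
    test : {"paired", "welch"}
        ``paired``: one-sample t of per-patient differences against 0.
        ``welch``: Welch two-sample t of post vs pre expression values
        (requires *expr* and *meta*), offered for sensitivity analysis.

    Returns
    -------
    DataFrame with columns gene_id, group_log2fc, p_value, q_value,
    is_deg, direction, n_patients, zero_variance.
    """
    if patients is None:
        patients = fc.patient_ids
    else:
        missing = [p for p in patients if p not in fc.patient_ids]
        if missing:
            raise ValueError(f"patients absent from fold-change matrix: {missing}")
    sub = fc.subset_patients(patients)
    n = len(patients)
    if p_threshold is not None and n < 2:
        raise ValueError(
            "a p-value needs >= 2 patients; use fold-change-only mode "
            "(p_threshold=None) for a single patient"
        )

    gene_ids = np.asarray(sub.gene_ids)
    values = sub.values
    keep = np.ones(len(gene_ids), dtype=bool)
    if expr is not None:
        mean_expr = expr.values.mean(axis=1)
        by_id = dict(zip(expr.gene_ids, mean_expr))
        keep = np.array([by_id.get(g, np.inf) >= min_mean_expression for g in gene_ids])
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "low-expression prefilter removed %d/%d genes (floor %.3g)",
                n_dropped,
                len(gene_ids),
                min_mean_expression,
            )
    gene_ids = gene_ids[keep]
    values = values[keep]

    mean_fc = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if n >= 2 else np.zeros(len(gene_ids))
    zero_var = (sd == 0) & (mean_fc != 0) if n >= 2 else np.zeros(len(gene_ids), bool)

    if p_threshold is None:
        pvals = np.full(len(gene_ids), np.nan)
        passes_p = np.ones(len(gene_ids), dtype=bool)
    elif test == "paired":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_1samp(values, popmean=0.0, axis=1)
        pvals = np.asarray(res.pvalue, dtype=float)
        # zero-variance nonzero-mean genes: p is 0/undefined; flag, do not pass
        pvals = np.where(zero_var, np.nan, pvals)
        pvals = np.where((sd == 0) & (mean_fc == 0), 1.0, pvals)
        passes_p = np.where(np.isnan(pvals), False, pvals < p_threshold)
    elif test == "welch":
        if expr is None or meta is None:
            raise ValueError("welch test requires expr and meta")
        pre_ids = [meta.sample_for(p, "pre") for p in patients]
        post_ids = [meta.sample_for(p, "post") for p in patients]
        sample_idx = expr.sample_index()
        pre = expr.values[:, [sample_idx[s] for s in pre_ids]]
        post = expr.values[:, [sample_idx[s] for s in post_ids]]
        gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
        rows = [gene_pos[g] for g in gene_ids]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(post[rows], pre[rows], axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
        passes_p = np.where(np.isnan(pvals), False, pvals < p_threshold)
    else:
        raise ValueError(f"unknown test {test!r}")

    qvals = np.full(len(gene_ids), np.nan)
    finite = ~np.isnan(pvals)
    if finite.any():
        qvals[finite] = bh_qvalues(pvals[finite])

    is_deg = (np.abs(mean_fc) >= fc_threshold) & passes_p
    direction = np.where(mean_fc > 0, "up", np.where(mean_fc < 0, "down", "flat"))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group_log2fc": mean_fc,
            "p_value": pvals,
            "q_value": qvals,
            "is_deg": is_deg,
            "direction": direction,
            "n_patients": n,
            "zero_variance": zero_var,
        }
    )
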