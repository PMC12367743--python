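"""Overrepresentation analysis and a per-sample rank random-walk set score.

``overrepresentation`` tests a (direction-filtered) gene list against a
gene-set collection with the exact hypergeometric upper tail, computed in
integer arithmetic (``math.comb``) so small-instance results are exact.

``set_variation_scores`` provides a single-sample enrichment statistic:
genes are ranked within each sample by descending genewise z-score; the
walk accumulates ``|z|**tau``-weighted hits over set members against
uniform misses over non-members and reports the summed difference (the
integral form). It is a documented stand-in for kernel-based GSVA, not a
re-implementation of it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import numpy as np
import pandas as pd

from ifnsig.clinical_stats import welch_t
from ifnsig.io_formats import ExpressionMatrix, GeneSetCollection, SampleMetadata

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "overrepresentation",
    "rank_walk_statistic",
    "set_variation_scores",
    "compare_set_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int  # k
    set_size: int  # K (within universe)
    list_size: int  # n
    universe_size: int  # N
    p_value: float


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact.

    ``N`` population size, ``K`` marked items, ``n`` draws, ``k`` observed
    marked draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    denom = math.comb(N, n)
    num = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    )
    return float(Fraction(num, denom))


def overrepresentation(
    deg_list: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of *deg_list* in each gene set.

    Sets are intersected with the universe before testing; sets with zero
    genes left in the universe are skipped. Results are sorted ascending
    by p-value with ties broken by set name; a BH q-value column is
    appended.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    deg = list(dict.fromkeys(deg_list))
    outside = [g for g in deg if g not in uni]
    if outside:
        raise ValueError(f"DEG list contains genes outside the universe: {outside[:5]}")
    if not deg:
        logger.warning("empty DEG list: returning empty enrichment table")
        return pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p_value", "q_value"]
        )
    N = len(universe)
    n = len(deg)
    deg_set = set(deg)
    rows = []
    for name, genes in collection.sets.items():
        members = [g for g in genes if g in uni]
        K = len(members)
        if K == 0:
            logger.info("set %r has no genes in the universe; skipped", name)
            continue
        k = sum(1 for g in members if g in deg_set)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p_value", "q_value"]
        )
    table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(
        drop=True
    )
    from ifnsig.deg_analysis import bh_qvalues

    table["q_value"] = bh_qvalues(table["p_value"].to_numpy())
    return table


def rank_walk_statistic(
    z: np.ndarray, is_member: np.ndarray, tau: float = 0.25
) -> float:
    """Summed hit-miss walk over a ranking of one sample's z-scores.

    Genes are ranked by descending ``z``; ``P_hit`` accumulates
    ``|z|**tau`` over set members (normalised by the member total) and
    ``P_miss`` accumulates uniformly over non-members. Returns
    ``sum_i (P_hit(i) - P_miss(i))``. With ``tau = 0`` the statistic is a
    pure rank statistic with maximum ``N/2`` (set at the top of the
    ranking) and minimum ``-N/2``.
    """
    z = np.asarray(z, dtype=float)
    is_member = np.asarray(is_member, dtype=bool)
    if z.shape != is_member.shape or z.ndim != 1:
        raise ValueError("z and is_member must be 1-D arrays of equal length")
    N = z.size
    K = int(is_member.sum())
    if K == 0:
        raise ValueError("set has no members in the ranking")
    if K == N:
        raise ValueError("set covers every gene: walk is degenerate")
    order = np.argsort(-z, kind="stable")
    member_sorted = is_member[order]
    weights = np.abs(z[order]) ** tau
    hit_weights = np.where(member_sorted, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:  # all member weights zero (e.g. z == 0 at tau > 0)
        hit_weights = member_sorted.astype(float)
        total = float(K)
    p_hit = np.cumsum(hit_weights) / total
    p_miss = np.cumsum(~member_sorted) / (N - K)
    return float(np.sum(p_hit - p_miss))


def set_variation_scores(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    tau: float = 0.25,
    meta: SampleMetadata | None = None,
) -> pd.DataFrame:
    """Per sample x gene set walk scores.

    Genewise z-scores are computed across all samples of *expr*; each set
    must have between 1 and N-1 member genes present in the matrix.
    Returns a tidy frame with columns sample_id, set_name, score.
    """
    values = expr.values
    sds = values.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = [g for g, s in zip(expr.gene_ids, sds) if s == 0]
        raise ValueError(f"zero-variance genes cannot be z-scored: {bad[:5]}")
    z = (values - values.mean(axis=1, keepdims=True)) / sds[:, None]
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    masks = {}
    for name, genes in collection.sets.items():
        mask = np.zeros(expr.n_genes, dtype=bool)
        present = [gene_pos[g] for g in genes if g in gene_pos]
        if not present:
            raise ValueError(f"set {name!r} has no genes in the expression matrix")
        if len(present) == expr.n_genes:
            raise ValueError(f"set {name!r} covers every gene: walk is degenerate")
        mask[present] = True
        masks[name] = mask
    rows = []
    for j, sid in enumerate(expr.sample_ids):
        for name, mask in masks.items():
            rows.append(
                {
                    "sample_id": sid,
                    "set_name": name,
                    "score": rank_walk_statistic(z[:, j], mask, tau=tau),
                }
            )
    return pd.DataFrame(rows)


def compare_set_scores(
    scores: pd.DataFrame,
    meta: SampleMetadata,
    set_name: str,
) -> dict:
    """Welch t-test of per-patient (post - pre) score deltas between arms."""
    sub = scores[scores["set_name"] == set_name]
    if sub.empty:
        raise ValueError(f"no scores for set {set_name!r}")
    by_sample = dict(zip(sub["sample_id"], sub["score"]))
    arm_of = meta.patient_attr("arm")
    deltas: dict[str, list[float]] = {}
    for pid in meta.paired_patients():
        pre = by_sample.get(meta.sample_for(pid, "pre"))
        post = by_sample.get(meta.sample_for(pid, "post"))
        if pre is None or post is None:
            raise ValueError(f"patient {pid!r} lacks a pre or post score")
        deltas.setdefault(arm_of[pid], []).append(post - pre)
    if len(deltas) != 2:
        raise ValueError(f"expected 2 arms, found {sorted(deltas)}")
    (arm_a, xs), (arm_b, ys) = sorted(deltas.items())
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each arm needs >= 2 patients with paired scores")
    t, dof, p = welch_t(xs, ys)
    return {
        "set_name": set_name,
        "arms": (arm_a, arm_b),
        "t": t,
        "dof": dof,
        "p_value": p,
        "mean_delta": {arm_a: float(np.mean(xs)), arm_b: float(np.mean(ys))},
        "n": {arm_a: len(xs), arm_b: len(ys)},
    }
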