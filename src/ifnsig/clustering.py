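"""Hierarchical clustering of per-patient fold-change profiles.

Default distance is ``1 - Pearson correlation`` across the selected gene
set with average linkage (the usual transcriptomic heatmap convention);
Euclidean and Ward are available by flag. The flat two-group cut is
compared against outcome and treatment-arm labels with the adjusted Rand
index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from ifnsig.deg_analysis import FoldChangeMatrix
from ifnsig.io_formats import SampleMetadata

__all__ = ["Dendrogram", "cluster_patients", "outcome_concordance", "to_newick"]

_LINKAGES = ("average", "complete", "single", "ward")
_DISTANCES = ("correlation", "euclidean")


@dataclass(frozen=True)
class Dendrogram:
    """An agglomerative tree over patients.

    ``merges`` is the scipy-style linkage matrix: row ``i`` merges nodes
    ``merges[i, 0]`` and ``merges[i, 1]`` (leaves are ``0..n-1``, internal
    nodes ``n+i``) at height ``merges[i, 2]``.
    """

    leaf_labels: tuple[str, ...]
    merges: np.ndarray
    distance: str
    linkage: str

    def __post_init__(self) -> None:
        merges = np.asarray(self.merges, dtype=float)
        object.__setattr__(self, "merges", merges)
        n = len(self.leaf_labels)
        if merges.shape[0] != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def cut(self, k: int) -> dict[str, int]:
        """Flat assignment of each leaf to one of ``k`` clusters (1-based)."""
        if k > len(self.leaf_labels):
            raise ValueError("k exceeds number of leaves")
        flat = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.leaf_labels, (int(c) for c in flat)))


def cluster_patients(
    fc: FoldChangeMatrix,
    deg_genes: Sequence[str],
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of patient columns restricted to *deg_genes*."""
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if len(fc.patient_ids) < 2:
        raise ValueError("need >= 2 patients to cluster")
    deg_genes = list(deg_genes)
    if not deg_genes:
        raise ValueError("deg_genes must be nonempty")
    gene_pos = {g: i for i, g in enumerate(fc.gene_ids)}
    missing = [g for g in deg_genes if g not in gene_pos]
    if missing:
        raise ValueError(f"genes absent from fold-change matrix: {missing[:5]}")
    rows = sorted(gene_pos[g] for g in deg_genes)  # gene-order invariance
    profiles = fc.values[rows].T  # patients x genes

    if distance == "correlation":
        sds = profiles.std(axis=1)
        flat = np.flatnonzero(sds == 0)
        if flat.size:
            names = [fc.patient_ids[i] for i in flat]
            raise ValueError(
                f"zero-variance patient profile under correlation distance: {names}"
            )
        dmat = pdist(profiles, metric="correlation")
    else:
        dmat = pdist(profiles, metric="euclidean")
    dmat = np.clip(dmat, 0.0, None)
    merges = hierarchy.linkage(dmat, method=linkage)
    return Dendrogram(tuple(fc.patient_ids), merges, distance, linkage)


def outcome_concordance(
    dendrogram: Dendrogram,
    meta: SampleMetadata,
    k: int = 2,
) -> dict:
    """Cut the tree into *k* clusters and compare against outcome and arm.

    Returns a dict with the flat assignment, cross-tabulations and the
    adjusted Rand index for both labellings.
    """
    assignment = dendrogram.cut(k)
    outcome_of = meta.patient_attr("outcome")
    arm_of = meta.patient_attr("arm")
    patients = list(dendrogram.leaf_labels)
    clusters = [assignment[p] for p in patients]
    outcomes = [outcome_of[p] for p in patients]
    arms = [arm_of[p] for p in patients]
    report = {
        "k": k,
        "assignment": assignment,
        "ari_outcome": float(adjusted_rand_score(outcomes, clusters)),
        "ari_arm": float(adjusted_rand_score(arms, clusters)),
        "crosstab_outcome": pd.crosstab(
            pd.Series(outcomes, name="outcome"), pd.Series(clusters, name="cluster")
        ),
        "crosstab_arm": pd.crosstab(
            pd.Series(arms, name="arm"), pd.Series(clusters, name="cluster")
        ),
    }
    return report


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialise the dendrogram as a Newick string with branch lengths."""
    n = len(dendrogram.leaf_labels)
    merges = dendrogram.merges
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {i: dendrogram.leaf_labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(merges):
        a, b = int(a), int(b)
        la = heights[a]
        lb = heights[b]
        node_id = n + i
        nodes[node_id] = (
            f"({nodes[a]}:{h - la:.10g},{nodes[b]}:{h - lb:.10g})"
        )
        heights[node_id] = float(h)
    return nodes[2 * n - 2] + ";"
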