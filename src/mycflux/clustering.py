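"""Hierarchical clustering of transcriptional response profiles.

Genes are grouped into response archetypes from concatenated log2-response
features (RNAPII densities over promoter / gene body / TES plus synthesis
rates), the agglomerative tree is cut at k clusters, undersized clusters
are removed (kept in the output with an explicit "removed" label rather
than deleted), and cluster-mean profiles are extracted for compartment-model
inference.  PCA summarizes the response structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .polii import ClusterProfile
from .signal import ResponseMatrix, SignalTable

__all__ = [
    "ClusterAssignment",
    "build_feature_matrix",
    "hierarchical_clusters",
    "pca_explained_variance",
    "cluster_profiles",
]

REMOVED = 0  # label used for genes in undersized clusters


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels (1..k by decreasing size; 0 = removed)."""

    labels: pd.Series
    k: int
    min_cluster_size: int
    metric: str
    method: str

    @property
    def removed_genes(self) -> np.ndarray:
        return self.labels.index[self.labels == REMOVED].to_numpy(dtype=object)

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != REMOVED].value_counts().sort_index()


def build_feature_matrix(
    responses: list[ResponseMatrix],
    baseline: np.ndarray | None = None,
) -> pd.DataFrame:
    """Concatenate response matrices into one genes x features matrix.

    Each input block is scaled to unit overall variance so that assays with
    different dynamic ranges contribute comparably to distances.  Baseline
    (untreated-intensity) columns, if given, are appended standardized but
    are conventionally excluded from clustering distances by the caller.
    """
    if not responses:
        raise ValueError("no response matrices given")
    ref = responses[0].gene_ids
    blocks, cols = [], []
    for rm in responses:
        if rm.gene_ids.shape != ref.shape or np.any(rm.gene_ids != ref):
            raise ValueError("response matrices must share the gene list")
        sd = float(rm.values.std())
        blocks.append(rm.values / (sd if sd > 1e-12 else 1.0))
        cols.extend(rm.feature_labels)
    if baseline is not None:
        b = np.atleast_2d(np.asarray(baseline, float))
        b = b.T if b.shape[0] != ref.size else b
        sd = b.std(axis=0)
        blocks.append((b - b.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0))
        cols.extend(f"baseline_{i}" for i in range(b.shape[1]))
    return pd.DataFrame(
        np.concatenate(blocks, axis=1), index=pd.Index(ref, name="gene_id"), columns=cols
    )


def hierarchical_clusters(
    matrix,
    k: int = 14,
    min_cluster_size: int = 30,
    metric: str = "euclidean",
    method: str = "ward",
) -> ClusterAssignment:
    """Agglomerative clustering cut at ``k``, removing undersized clusters.

    Labels are renumbered 1..k in decreasing cluster-size order (ties by
    the smaller original label, so the result is deterministic); clusters
    below ``min_cluster_size`` get the ``removed`` label 0.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    n = df.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    Z = linkage(df.to_numpy(), method=method, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    mapping = {}
    nxt = 1
    for c in order:
        if counts[c] >= min_cluster_size:
            mapping[c] = nxt
            nxt += 1
        else:
            mapping[c] = REMOVED
    labels = pd.Series([mapping[c] for c in raw], index=df.index, name="cluster")
    return ClusterAssignment(labels, k, min_cluster_size, metric, method)


def pca_explained_variance(matrix, n_components: int | None = None):
    """Centered PCA: per-component explained-variance fractions and scores.

    Returns ``(fractions, scores)`` with components ordered by decreasing
    variance; fractions over all components sum to 1.
    """
    X = np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    if float(X.std()) <= 1e-15:
        raise ValueError("zero-variance matrix")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return pca.explained_variance_ratio_, scores


def cluster_profiles(
    assignment: ClusterAssignment,
    tables: dict,
    min_genes: int = 1,
) -> list[ClusterProfile]:
    """Cluster-mean Pr/Gb/Te/k1 trajectories for compartment-model fitting.

    ``tables`` maps ``{"Pr": SignalTable, "Gb": ..., "Te": ..., "k1": array}``
    (SignalTables are replicate-averaged; ``k1`` may be a plain
    genes x timepoints array).  Genes labeled removed are excluded; clusters
    left empty are dropped with a warning.
    """
    import warnings

    first = tables["Pr"]
    gene_ids = first.gene_ids if isinstance(first, SignalTable) else None
    times = first.grid.as_array() if isinstance(first, SignalTable) else None

    def as_matrix(x):
        return x.values.mean(axis=2) if isinstance(x, SignalTable) else np.asarray(x, float)

    mats = {name: as_matrix(tab) for name, tab in tables.items()}
    if gene_ids is None:
        raise ValueError("tables['Pr'] must be a SignalTable")
    labels = assignment.labels.reindex(gene_ids)
    if labels.isna().any():
        raise ValueError("assignment does not cover the table genes")
    profiles = []
    for cid in sorted(set(labels) - {REMOVED}):
        m = (labels == cid).to_numpy()
        if m.sum() < min_genes:
            warnings.warn(f"cluster {cid} empty after exclusions; dropped")
            continue
        profiles.append(
            ClusterProfile(
                cluster_id=int(cid),
                times=times,
                Pr=mats["Pr"][m].mean(axis=0),
                Gb=mats["Gb"][m].mean(axis=0),
                Te=mats["Te"][m].mean(axis=0),
                k1=mats["k1"][m].mean(axis=0),
                n_genes=int(m.sum()),
            )
        )
    return profiles
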