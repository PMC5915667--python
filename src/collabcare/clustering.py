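"""Trace clustering of care trajectories.

Patients are grouped by the similarity of their discipline sequences:
agglomerative clustering (complete linkage by default) on a normalized
edit distance, cut so that members of one cluster never differ by more
than the similarity threshold (default 15%). Clusters smaller than
``ceil(outlier_fraction * n)`` (default 3%) are pooled into a single
outlier group, which is excluded from pattern classification but kept
for outcome statistics.

The distance is normalized Levenshtein — edit distance divided by the
longer sequence length — computed with edlib. It is pluggable through
``cluster_traces(distance=...)`` so alternative trace dissimilarities can
be swapped in without touching the clustering itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster import hierarchy

from .network import CollaborativeNetwork, DisciplineLog, NetworkMetrics, build_network, network_metrics

logger = logging.getLogger(__name__)

OUTLIER_GROUP_ID = "outliers"


@dataclass(frozen=True)
class ClusteringConfig:
    similarity_threshold: float = 0.15
    outlier_fraction: float = 0.03
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must be in (0, 1]")
        if not 0.0 < self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TraceCluster:
    cluster_id: str
    member_ids: frozenset[str]
    is_outlier_group: bool = False


def trace_distance(seq_a, seq_b) -> float:
    """Normalized Levenshtein distance between two discipline sequences.

    Edit distance (substitutions, insertions, deletions at unit cost)
    divided by the length of the longer sequence: 0 iff identical, 1 when
    nothing aligns. Symmetric. Empty sequences are an error.
    """
    a, b = "".join(seq_a), "".join(seq_b)
    if not a or not b:
        raise ValueError("trace_distance requires non-empty sequences")
    if a == b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return d / max(len(a), len(b))


def _condensed_distances(sequences: list[tuple[str, ...]], distance) -> np.ndarray:
    """Condensed pairwise matrix; identical sequences share one computation."""
    keys = ["".join(s) for s in sequences]
    uniq = sorted(set(keys))
    index = {k: i for i, k in enumerate(uniq)}
    u = len(uniq)
    ud = np.zeros((u, u))
    for i in range(u):
        for j in range(i + 1, u):
            ud[i, j] = ud[j, i] = distance(uniq[i], uniq[j])
    n = len(keys)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        ki = index[keys[i]]
        for j in range(i + 1, n):
            out[k] = ud[ki, index[keys[j]]]
            k += 1
    return out


def min_cluster_size(n_patients: int, outlier_fraction: float) -> int:
    """Smallest admissible cluster: ceil(outlier_fraction * n)."""
    return math.ceil(outlier_fraction * n_patients)


def cluster_traces(
    log: DisciplineLog,
    config: ClusteringConfig = ClusteringConfig(),
    distance=trace_distance,
) -> list[TraceCluster]:
    """Cluster patients by trace similarity; pool undersized groups.

    Deterministic for a given log: patients are processed in lexicographic
    id order and clusters are labeled C01, C02, ... by decreasing size
    (ties by smallest member id). The outlier group is always present,
    possibly empty, with id ``"outliers"``.
    """
    pids = log.patients
    n = len(pids)
    if n == 0:
        raise ValueError("cannot cluster an empty log")
    if n == 1:
        logger.warning("fewer than 2 patients: returning a single cluster")
        return [
            TraceCluster("C01", frozenset(pids)),
            TraceCluster(OUTLIER_GROUP_ID, frozenset(), is_outlier_group=True),
        ]
    seqs = [log.sequences[p] for p in pids]
    condensed = _condensed_distances(seqs, distance)
    z = hierarchy.linkage(condensed, method=config.linkage)
    labels = hierarchy.fcluster(z, t=config.similarity_threshold, criterion="distance")

    groups: dict[int, list[str]] = {}
    for pid, lab in zip(pids, labels):
        groups.setdefault(int(lab), []).append(pid)

    min_size = min_cluster_size(n, config.outlier_fraction)
    kept = [g for g in groups.values() if len(g) >= min_size]
    outliers = [pid for g in groups.values() if len(g) < min_size for pid in g]
    kept.sort(key=lambda g: (-len(g), min(g)))
    clusters = [
        TraceCluster(f"C{i:02d}", frozenset(g)) for i, g in enumerate(kept, start=1)
    ]
    clusters.append(TraceCluster(OUTLIER_GROUP_ID, frozenset(outliers), is_outlier_group=True))
    return clusters


def cut_cluster_count(log: DisciplineLog, threshold: float, linkage: str = "complete",
                      distance=trace_distance) -> int:
    """Number of clusters in the raw dendrogram cut (before outlier pooling)."""
    pids = log.patients
    if len(pids) < 2:
        return len(pids)
    condensed = _condensed_distances([log.sequences[p] for p in pids], distance)
    z = hierarchy.linkage(condensed, method=linkage)
    return len(set(hierarchy.fcluster(z, t=threshold, criterion="distance")))


def cluster_networks(
    clusters: list[TraceCluster], log: DisciplineLog
) -> dict[str, tuple[CollaborativeNetwork, NetworkMetrics]]:
    """Per-cluster collaborative network and indices (outlier group included)."""
    out: dict[str, tuple[CollaborativeNetwork, NetworkMetrics]] = {}
    for cluster in clusters:
        if not cluster.member_ids:
            continue
        net = build_network(log.subset(cluster.member_ids))
        out[cluster.cluster_id] = (net, network_metrics(net))
    return out
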