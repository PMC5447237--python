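"""Landmark generation: score partition, Jaccard kNN graphs, communities.

Events confidently matching one table type (score > 1/2) are grouped per
type; events confidently matching nothing go to an "unknown" pool.  Each
group is clustered by modularity-maximizing community detection on a
30-nearest-neighbour graph whose edge weights are the Jaccard similarity
of the two endpoints' neighbour sets (the construction popularized for
cytometry by graph-based phenotyping tools).  Every sufficiently large
community contributes one landmark: its coordinate mean, labelled with the
group's cell type (or ``unknown:<i>`` for the unknown pool).  Landmarks
are the boundary conditions of the downstream random-walker classifier.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import GraphError, ParameterError
from .preprocessing import EventMatrix
from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Undirected weighted graph over point indices ``0..n_nodes-1``.

    Edges are stored once with ``i < j``; weights are nonnegative and
    self-loops are forbidden.
    """

    n_nodes: int
    edges: np.ndarray = field(repr=False)    # (E, 2) int, i < j
    weights: np.ndarray = field(repr=False)  # (E,)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise GraphError("edge/weight length mismatch")
        if len(self.edges):
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise GraphError("self-loops are not allowed")
            if (self.weights < 0).any():
                raise GraphError("negative edge weight")
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise GraphError("edge endpoint out of range")
            # canonical order i < j, one record per edge
            lo = self.edges.min(axis=1)
            hi = self.edges.max(axis=1)
            self.edges = np.column_stack([lo, hi])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_sparse(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        mat = sp.coo_matrix(
            (
                np.concatenate([self.weights, self.weights]),
                (np.concatenate([i, j]), np.concatenate([j, i])),
            ),
            shape=(self.n_nodes, self.n_nodes),
        )
        return mat.tocsr()

    def to_igraph(self) -> ig.Graph:
        graph = ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])
        graph.es["weight"] = list(self.weights)
        return graph

    def total_weight(self) -> float:
        return float(self.weights.sum())


def _knn_indices(points: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours per row, self excluded, sorted by distance."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(points))).fit(points)
    idx = nn.kneighbors(points, return_distance=False)
    rows = []
    for i, row in enumerate(idx):
        row = row[row != i][:k]
        rows.append(row)
    return np.asarray(rows)


def build_jaccard_graph(points: np.ndarray, k: int = 30) -> NeighborGraph:
    """30-NN graph (Euclidean) weighted by neighbour-set Jaccard similarity.

    For every ordered kNN relation ``j in NN_k(i)`` the undirected edge
    ``(i, j)`` receives weight ``|N(i) & N(j)| / |N(i) | N(j)|`` where
    ``N(i) = NN_k(i) | {i}`` is the point's closed neighbourhood (the point
    itself plus its k nearest neighbours) — including the point makes two
    duplicated points with otherwise identical neighbours score weight 1,
    as identical neighbourhoods should.  Zero-weight edges are dropped.
    ``k`` is clamped to ``n - 1`` (with a warning) when the point set is
    small.

    Raises
    ------
    GraphError
        With fewer than 2 points.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise GraphError(f"need at least 2 points to build a graph, got {n}")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    k_eff = min(k, n - 1)
    if k_eff < k:
        logger.warning("clamping k from %d to %d for %d points", k, k_eff, n)
    nbrs = _knn_indices(points, k_eff)  # (n, k_eff)

    # closed-neighbourhood membership matrix: each row marks NN_k(i) and i
    membership = sp.csr_matrix(
        (
            np.ones(n * k_eff),
            (np.repeat(np.arange(n), k_eff), nbrs.ravel()),
        ),
        shape=(n, n),
    ) + sp.identity(n, format="csr")
    src = np.repeat(np.arange(n), k_eff)
    dst = nbrs.ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    pairs = np.unique(np.column_stack([lo, hi]), axis=0)
    # shared-neighbour counts only for candidate pairs
    shared = sp.csr_matrix(membership @ membership.T)
    inter = np.asarray(shared[pairs[:, 0], pairs[:, 1]]).ravel()
    union = 2.0 * (k_eff + 1) - inter
    weights = inter / union
    keep = weights > 0
    return NeighborGraph(n_nodes=n, edges=pairs[keep], weights=weights[keep])


def modularity(graph: NeighborGraph, assignment) -> float:
    """Newman modularity Q of a community assignment.

    ``Q = (1/2m) * sum_ij (W_ij - s_i s_j / 2m) delta(c_i, c_j)`` with
    ``s_i`` the weighted degree and ``2m`` the total weight of the
    (symmetric) adjacency.  The all-in-one-community assignment has
    ``Q = 0`` exactly.

    Raises
    ------
    GraphError
        If the assignment does not cover every node or total weight is 0.
    """
    assignment = np.asarray(assignment)
    if assignment.shape != (graph.n_nodes,):
        raise GraphError("assignment must label every node")
    two_m = 2.0 * graph.total_weight()
    if two_m == 0:
        raise GraphError("modularity undefined for a graph of zero total weight")
    adj = graph.to_sparse()
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    same = assignment[i] == assignment[j]
    intra = 2.0 * graph.weights[same].sum()  # both (i,j) and (j,i)
    null = sum(
        degrees[assignment == label].sum() ** 2 for label in np.unique(assignment)
    ) / two_m
    return float((intra - null) / two_m)


def detect_communities(graph: NeighborGraph, seed: int = 0) -> np.ndarray:
    """Greedy modularity maximization (Leiden refinement of Louvain).

    Deterministic given ``seed``; disconnected components are handled
    independently by the optimizer.  The returned assignment is guaranteed
    to score at least as well as the all-singleton and all-in-one
    baselines (falling back to all-in-one if the heuristic somehow does
    worse, which would imply Q < 0).

    Raises
    ------
    GraphError
        On an empty graph.
    """
    if graph.n_nodes == 0:
        raise GraphError("cannot detect communities on an empty graph")
    if graph.n_edges == 0:
        return np.arange(graph.n_nodes)
    g = graph.to_igraph()
    partition = leidenalg.find_partition(
        g,
        leidenalg.ModularityVertexPartition,
        weights="weight",
        seed=seed,
        n_iterations=-1,  # iterate until no further improvement
    )
    labels = np.asarray(partition.membership, dtype=int)
    if modularity(graph, labels) < 0.0:  # all-in-one baseline has Q = 0
        logger.warning("community detection below trivial baseline; merging")
        labels = np.zeros(graph.n_nodes, dtype=int)
    return labels


@dataclass
class ScorePartition:
    """Disjoint grouping of events by confident score."""

    by_type: dict[str, np.ndarray]      # type name -> event indices
    unknown: np.ndarray                 # indices with unknown score > threshold
    unassigned: np.ndarray              # indices exceeding no threshold
    overlap_count: int                  # events above threshold for >1 type

    def sizes(self) -> dict[str, int]:
        out = {t: len(ix) for t, ix in self.by_type.items()}
        out["unknown"] = len(self.unknown)
        out["(unassigned)"] = len(self.unassigned)
        return out


def partition_by_score(
    scores: ScoreMatrix, threshold: float = 0.5
) -> ScorePartition:
    """Split events into per-type subsets, an unknown pool and a remainder.

    An event joins the subset of its *argmax* type when that type's score
    exceeds ``threshold`` (if several types exceed it the argmax wins and
    the overlap counter is incremented — subsets must be disjoint because
    they become unambiguous boundary labels).  Events whose unknown score
    exceeds the threshold join the unknown pool; events exceeding no
    threshold are left unassigned and are only classified downstream by
    the random walker.
    """
    type_scores = scores.type_scores
    unknown_scores = scores.unknown_scores
    n = len(unknown_scores)
    if type_scores.shape[1]:
        best = np.argmax(type_scores, axis=1)
        best_score = type_scores[np.arange(n), best]
    else:
        best = np.zeros(n, dtype=int)
        best_score = np.zeros(n)
    above = type_scores > threshold
    overlap = int(np.sum(above.sum(axis=1) > 1))
    if overlap:
        logger.info(
            "%d events exceeded the threshold for multiple types; "
            "assigned to their argmax type",
            overlap,
        )
    in_type = best_score > threshold
    in_unknown = (~in_type) & (unknown_scores > threshold)
    unassigned = ~(in_type | in_unknown)
    by_type = {
        ctype: np.flatnonzero(in_type & (best == j))
        for j, ctype in enumerate(scores.cell_types)
    }
    return ScorePartition(
        by_type=by_type,
        unknown=np.flatnonzero(in_unknown),
        unassigned=np.flatnonzero(unassigned),
        overlap_count=overlap,
    )


@dataclass
class LandmarkSet:
    """Labelled cluster centres acting as classification boundary points."""

    points: np.ndarray = field(repr=False)  # (L, n_markers)
    labels: list[str]                       # table type or "unknown:<i>"
    member_counts: np.ndarray = field(repr=False)
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.member_counts = np.asarray(self.member_counts, dtype=int)
        if len(self.labels) != len(self.points):
            raise ValueError("one label per landmark required")

    @property
    def n_landmarks(self) -> int:
        return len(self.labels)

    @property
    def class_names(self) -> list[str]:
        seen: list[str] = []
        for label in self.labels:
            if label not in seen:
                seen.append(label)
        return seen

    def to_csv(self, path=None):
        import pandas as pd

        frame = pd.DataFrame(self.points, columns=self.marker_names or None)
        frame.insert(0, "label", self.labels)
        frame.insert(1, "member_count", self.member_counts)
        return frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, source) -> "LandmarkSet":
        import pandas as pd

        frame = pd.read_csv(source)
        markers = [c for c in frame.columns if c not in ("label", "member_count")]
        return cls(
            points=frame[markers].to_numpy(dtype=float),
            labels=[str(x) for x in frame["label"]],
            member_counts=frame["member_count"].to_numpy(dtype=int),
            marker_names=markers,
        )


def extract_landmarks(
    events: EventMatrix,
    partition: ScorePartition,
    k: int = 30,
    min_cluster_size: int = 10,
    seed: int = 0,
) -> LandmarkSet:
    """Cluster each score subset and emit community means as landmarks.

    Per subset: build the ``k``-NN Jaccard graph on the subset's events,
    run community detection, and emit every community of at least
    ``min_cluster_size`` events as one landmark (its coordinate mean).
    Type subsets label their landmarks with the type; unknown-pool
    communities get labels ``unknown:1``, ``unknown:2``, ... in decreasing
    size order.  Subsets or communities below ``min_cluster_size`` are
    dropped with a warning (a dropped type will be absent from the
    classifier's class list).
    """
    points_out: list[np.ndarray] = []
    labels_out: list[str] = []
    counts_out: list[int] = []

    groups: list[tuple[str, np.ndarray]] = list(partition.by_type.items())
    groups.append(("unknown", partition.unknown))

    unknown_communities: list[tuple[np.ndarray, int]] = []
    for name, indices in groups:
        if len(indices) == 0:
            continue
        if len(indices) < max(min_cluster_size, 2):
            logger.warning(
                "subset %r has only %d events (< %d); no landmark emitted",
                name, len(indices), min_cluster_size,
            )
            continue
        subset = events.values[indices]
        graph = build_jaccard_graph(subset, k=k)
        communities = detect_communities(graph, seed=seed)
        for community in np.unique(communities):
            members = indices[communities == community]
            if len(members) < min_cluster_size:
                logger.info(
                    "dropping community of %d events (< %d) in subset %r",
                    len(members), min_cluster_size, name,
                )
                continue
            centre = events.values[members].mean(axis=0)
            if name == "unknown":
                unknown_communities.append((centre, len(members)))
            else:
                points_out.append(centre)
                labels_out.append(name)
                counts_out.append(len(members))

    # number unknown clusters by decreasing size for stable, readable labels
    unknown_communities.sort(key=lambda item: -item[1])
    for rank, (centre, size) in enumerate(unknown_communities, start=1):
        points_out.append(centre)
        labels_out.append(f"unknown:{rank}")
        counts_out.append(size)

    if not points_out:
        raise GraphError("no landmarks could be generated from any subset")
    return LandmarkSet(
        points=np.vstack(points_out),
        labels=labels_out,
        member_counts=np.asarray(counts_out),
        marker_names=list(events.marker_names),
    )


def cluster_majority_baseline(
    events: EventMatrix,
    reference_labels,
    k: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Unsupervised-clustering baseline: cluster, then vote with references.

    Communities are detected on the full data's ``k``-NN Jaccard graph and
    every event inherits the most frequent reference label of its
    community (majority ties resolve to the lexicographically smallest
    label and are logged).
    """
    reference_labels = np.asarray(reference_labels, dtype=object)
    if len(reference_labels) != events.n_events:
        raise ParameterError("one reference label per event required")
    graph = build_jaccard_graph(events.values, k=k)
    communities = detect_communities(graph, seed=seed)
    out = np.empty(events.n_events, dtype=object)
    n_ties = 0
    for community in np.unique(communities):
        mask = communities == community
        labels, counts = np.unique(reference_labels[mask].astype(str), return_counts=True)
        top = counts.max()
        winners = sorted(labels[counts == top])
        if len(winners) > 1:
            n_ties += 1
        out[mask] = winners[0]
    if n_ties:
        logger.info("majority vote: %d community ties broken lexicographically", n_ties)
    return out
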