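"""Random-walker classification as a discrete Laplace boundary-value problem.

The probability that a random walker started at event ``x`` first reaches a
landmark of class ``c`` is a harmonic function on the graph: at every
non-landmark node it equals the weighted average of its neighbours' values,

    P(x | c) = sum_y W_xy P(y | c) / sum_y W_xy,

with boundary conditions ``P(l | c) = 1`` at landmarks of class ``c`` and 0
at landmarks of other classes.  Solving one sparse linear system per class
gives soft memberships for every event; the argmax is the label.  Because
the boundary indicator vectors sum to one at every landmark, linearity
makes the solution row-stochastic, and the maximum principle keeps every
interior value strictly inside (0, 1).

The graph is a 10-nearest-neighbour graph over the union of event points
and landmark points, with Gaussian-kernel edge weights by default so that
nearer neighbours dominate the walk.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .errors import ComputeError, GraphError, ParameterError
from .landmarks import LandmarkSet, NeighborGraph, extract_landmarks, partition_by_score
from .marker_table import MarkerTable, validate_against_panel
from .preprocessing import EventMatrix, pool_replicates, unpool
from .scoring import fit_marker_models, score_events

logger = logging.getLogger(__name__)


def build_walk_graph(
    events: EventMatrix,
    landmarks: LandmarkSet,
    k: int = 10,
    weighted: bool = True,
) -> tuple[NeighborGraph, np.ndarray]:
    """kNN graph over events plus landmarks, for the walker.

    Landmark points join the construction as ordinary points (appended
    after the events).  The directed kNN relation is symmetrized by edge
    union.  With ``weighted=True`` the edge weight is
    ``exp(-d^2 / sigma^2)`` with ``sigma`` the mean distance to the k-th
    neighbour over all points; otherwise all edges weigh 1.

    Returns
    -------
    (graph, landmark_nodes)
        The graph over ``n_events + n_landmarks`` nodes and the node
        indices of the landmarks.

    Raises
    ------
    GraphError
        If any connected component contains no landmark (the walker could
        never be absorbed there) — a sign that ``k`` is too small or a
        population has no landmark.
    """
    if landmarks.n_landmarks == 0:
        raise GraphError("at least one landmark is required")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    points = np.vstack([events.values, landmarks.points])
    n = len(points)
    k_eff = min(k, n - 1)
    if k_eff < k:
        logger.warning("clamping walk-graph k from %d to %d", k, k_eff)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    # drop self (first occurrence per row), keep k_eff neighbours
    rows_i, rows_j, rows_d = [], [], []
    for i in range(n):
        mask = idx[i] != i
        rows_i.append(np.full(mask.sum(), i)[:k_eff])
        rows_j.append(idx[i][mask][:k_eff])
        rows_d.append(dist[i][mask][:k_eff])
    src = np.concatenate(rows_i)
    dst = np.concatenate(rows_j)
    d = np.concatenate(rows_d)

    if weighted:
        kth = np.array([rd[-1] if len(rd) else 0.0 for rd in rows_d])
        sigma = float(kth.mean())
        if sigma <= 0:
            logger.warning("zero kNN bandwidth (duplicate points); unweighted edges")
            w = np.ones_like(d)
        else:
            w = np.exp(-(d**2) / sigma**2)
    else:
        w = np.ones_like(d)

    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    order = np.lexsort((hi, lo))
    pairs = np.column_stack([lo, hi])[order]
    w = w[order]
    keep = np.ones(len(pairs), dtype=bool)
    keep[1:] = (np.diff(pairs[:, 0]) != 0) | (np.diff(pairs[:, 1]) != 0)
    graph = NeighborGraph(n_nodes=n, edges=pairs[keep], weights=w[keep])

    landmark_nodes = np.arange(events.n_events, n)
    n_comp, comp = connected_components(graph.to_sparse(), directed=False)
    if n_comp > 1:
        landmark_comps = set(comp[landmark_nodes])
        for c in range(n_comp):
            if c not in landmark_comps:
                size = int((comp == c).sum())
                raise GraphError(
                    f"connected component of {size} node(s) contains no "
                    "landmark; increase k or check landmark generation"
                )
    return graph, landmark_nodes


@dataclass
class HarmonicSolution:
    """First-arrival probabilities ``P(x | c)`` for every node and class."""

    probs: np.ndarray = field(repr=False)  # (n_nodes, n_classes)
    class_names: list[str]
    landmark_nodes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[1] != len(self.class_names):
            raise ValueError("one probability column per class required")

    def event_probs(self, n_events: int) -> np.ndarray:
        """Rows for the event nodes (landmarks are appended after events)."""
        return self.probs[:n_events]


def solve_harmonic(
    graph: NeighborGraph,
    landmark_nodes: np.ndarray,
    landmark_labels: list[str],
    class_names: list[str] | None = None,
    residual_tol: float = 1e-8,
) -> HarmonicSolution:
    """Solve the Laplace boundary-value problem for every class.

    One sparse symmetric system ``L_uu P_u = W_ub B_c`` per class, sharing
    a single LU factorization.  After solving, the harmonic property
    ``|P(x|c) - weighted neighbour mean|`` is verified to ``residual_tol``
    at every interior node.

    Raises
    ------
    GraphError
        If a component has no landmark.
    ComputeError
        If the system is singular or the residual check fails.
    """
    landmark_nodes = np.asarray(landmark_nodes, dtype=int)
    if len(landmark_nodes) != len(landmark_labels):
        raise ParameterError("one label per landmark node required")
    if class_names is None:
        class_names = []
        for label in landmark_labels:
            if label not in class_names:
                class_names.append(label)
    class_index = {c: i for i, c in enumerate(class_names)}

    n = graph.n_nodes
    adjacency = graph.to_sparse()
    n_comp, comp = connected_components(adjacency, directed=False)
    if set(comp) - set(comp[landmark_nodes]):
        raise GraphError("a connected component contains no landmark")

    is_boundary = np.zeros(n, dtype=bool)
    is_boundary[landmark_nodes] = True
    interior = np.flatnonzero(~is_boundary)

    # boundary indicator matrix B: landmarks x classes
    indicator = np.zeros((len(landmark_nodes), len(class_names)))
    for row, label in enumerate(landmark_labels):
        indicator[row, class_index[label]] = 1.0

    probs = np.zeros((n, len(class_names)))
    probs[landmark_nodes] = indicator

    if len(interior):
        degrees = np.asarray(adjacency.sum(axis=1)).ravel()
        lap = sp.diags(degrees) - adjacency
        lap_uu = lap[interior][:, interior].tocsc()
        w_ub = adjacency[interior][:, landmark_nodes]
        rhs = w_ub @ indicator
        try:
            lu = spla.splu(lap_uu)
            solution = lu.solve(np.asarray(rhs))  # all class columns at once
        except RuntimeError as exc:
            raise ComputeError(f"harmonic system is singular: {exc}") from exc
        probs[interior] = solution

        # verify the weighted-average (harmonic) property per interior node
        neighbour_avg = adjacency[interior] @ probs / degrees[interior][:, None]
        residual = np.abs(probs[interior] - neighbour_avg).max() if len(interior) else 0
        if residual > residual_tol:
            raise ComputeError(
                f"harmonic residual {residual:.2e} exceeds {residual_tol:.0e}"
            )
        # clip solver-level noise; values are provably within [0, 1]
        np.clip(probs, 0.0, 1.0, out=probs)

    return HarmonicSolution(
        probs=probs, class_names=list(class_names), landmark_nodes=landmark_nodes
    )


def assign_labels(solution: HarmonicSolution, n_events: int | None = None) -> np.ndarray:
    """Argmax class per node (ties to the lowest class index, logged)."""
    probs = solution.probs if n_events is None else solution.event_probs(n_events)
    winners = np.argmax(probs, axis=1)
    n_tied = int(np.sum((probs == probs.max(axis=1, keepdims=True)).sum(1) > 1))
    if n_tied:
        logger.info("assign_labels: %d exact ties broken by class order", n_tied)
    names = np.asarray(solution.class_names, dtype=object)
    return names[winners]


def estimate_frequencies(labels, class_universe: list[str]):
    """Normalized label counts over a declared class universe.

    Classes absent from ``labels`` appear with frequency 0; labels outside
    the universe raise.
    """
    from .evaluation import FrequencyHistogram

    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ParameterError("cannot estimate frequencies from zero events")
    unknown_labels = set(str(x) for x in labels) - set(class_universe)
    if unknown_labels:
        raise ParameterError(f"labels outside the class universe: {unknown_labels}")
    counts = np.array([(labels == c).sum() for c in class_universe], dtype=float)
    return FrequencyHistogram(classes=list(class_universe), freqs=counts / counts.sum())


@dataclass
class PipelineResult:
    """Everything the multi-replicate pipeline produces."""

    labels: dict[str, np.ndarray]          # sample id -> per-event labels
    probs: dict[str, np.ndarray]           # sample id -> (n_events, n_classes)
    frequencies: dict[str, object]         # sample id -> FrequencyHistogram
    landmarks: LandmarkSet
    models: object                         # MarkerModels
    class_names: list[str]
    diagnostics: dict


def run_pipeline(samples: list[EventMatrix], table: MarkerTable, config=None) -> PipelineResult:
    """Full pipeline: pooled landmarks, then per-replicate classification.

    Marker models, scores and landmarks are computed once on the pooled
    matrix so every replicate is classified against a common set of
    boundary conditions; each replicate then gets its own walk graph
    (its events plus the shared landmarks), harmonic solve, labels and
    frequency histogram.  Input events are assumed to already be on the
    transformed (arcsinh) scale.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    t0 = time.perf_counter()
    pooled = pool_replicates(samples)
    validate_against_panel(table, pooled.marker_names, strict=True)

    models = fit_marker_models(pooled, seed=cfg.seed)
    scores = score_events(pooled, table, models)
    partition = partition_by_score(scores, threshold=cfg.threshold)
    landmarks = extract_landmarks(
        pooled,
        partition,
        k=cfg.jaccard_knn,
        min_cluster_size=cfg.min_cluster_size,
        seed=cfg.seed,
    )
    t_landmarks = time.perf_counter()
    logger.info(
        "landmark stage: %d landmarks (%s) in %.1fs",
        landmarks.n_landmarks, landmarks.class_names, t_landmarks - t0,
    )

    class_names = landmarks.class_names
    labels_out: dict[str, np.ndarray] = {}
    probs_out: dict[str, np.ndarray] = {}
    freqs_out: dict[str, object] = {}
    per_sample = unpool(pooled)
    for sid, sample in per_sample.items():
        graph, landmark_nodes = build_walk_graph(
            sample, landmarks, k=cfg.walk_knn, weighted=cfg.weighted_walk
        )
        solution = solve_harmonic(
            graph, landmark_nodes, landmarks.labels, class_names=class_names
        )
        labels = assign_labels(solution, n_events=sample.n_events)
        labels_out[sid] = labels
        probs_out[sid] = solution.event_probs(sample.n_events)
        freqs_out[sid] = estimate_frequencies(labels, class_universe=class_names)
        logger.info("classified sample %r (%d events)", sid, sample.n_events)

    return PipelineResult(
        labels=labels_out,
        probs=probs_out,
        frequencies=freqs_out,
        landmarks=landmarks,
        models=models,
        class_names=class_names,
        diagnostics={
            "overlap_count": partition.overlap_count,
            "n_unassigned": len(partition.unassigned),
            "subset_sizes": partition.sizes(),
            "landmark_seconds": t_landmarks - t0,
            "total_seconds": time.perf_counter() - t0,
        },
    )
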