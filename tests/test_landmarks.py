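import itertools

import numpy as np
import pytest

import cytomark as cm
from cytomark.errors import GraphError
from cytomark.landmarks import NeighborGraph, ScorePartition
from .conftest import make_events


def brute_force_knn_sets(points: np.ndarray, k: int) -> list[set]:
    """Independent neighbourhood oracle: full distance matrix; each set is
    the point itself plus its k nearest neighbours (closed neighbourhood)."""
    dists = np.linalg.norm(points[:, None] - points[None], axis=-1)
    np.fill_diagonal(dists, np.inf)
    return [
        set(np.argsort(row, kind="stable")[:k]) | {i}
        for i, row in enumerate(dists)
    ]


def brute_force_modularity(graph: NeighborGraph, assignment) -> float:
    """Direct double-sum evaluation of Q over all ordered node pairs."""
    adjacency = graph.to_sparse().toarray()
    degrees = adjacency.sum(axis=1)
    two_m = adjacency.sum()
    q = 0.0
    for i in range(graph.n_nodes):
        for j in range(graph.n_nodes):
            if assignment[i] == assignment[j]:
                q += adjacency[i, j] - degrees[i] * degrees[j] / two_m
    return q / two_m


def all_partitions(items):
    """Every set partition of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for idx in range(len(smaller)):
            yield smaller[:idx] + [[first] + smaller[idx]] + smaller[idx + 1:]
        yield [[first]] + smaller


def exhaustive_best_modularity(graph: NeighborGraph) -> float:
    best = -np.inf
    for partition in all_partitions(range(graph.n_nodes)):
        labels = np.empty(graph.n_nodes, dtype=int)
        for community, members in enumerate(partition):
            labels[members] = community
        best = max(best, cm.modularity(graph, labels))
    return best


def clique_pair_graph(size: int, weight: float = 1.0) -> NeighborGraph:
    """Two ``size``-cliques joined by a single bridge edge."""
    edges, weights = [], []
    for offset in (0, size):
        for i, j in itertools.combinations(range(offset, offset + size), 2):
            edges.append((i, j))
            weights.append(weight)
    edges.append((0, size))
    weights.append(weight)
    return NeighborGraph(n_nodes=2 * size, edges=np.array(edges), weights=np.array(weights))


class TestJaccardGraph:
    def test_weights_match_hand_enumeration_on_line(self):
        """6 points on a line, k=2: weights equal the neighbour-set Jaccard
        of the brute-force kNN sets."""
        points = np.array([[0.0], [1.0], [2.1], [3.3], [4.6], [6.0]])
        k = 2
        graph = cm.build_jaccard_graph(points, k=k)
        sets = brute_force_knn_sets(points, k)
        got = {(i, j): w for (i, j), w in zip(map(tuple, graph.edges), graph.weights)}
        # every kNN relation with nonzero overlap must appear with the right weight
        for i in range(6):
            for j in sets[i] - {i}:
                lo, hi = min(i, j), max(i, j)
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                if inter:
                    assert got[(lo, hi)] == pytest.approx(inter / union)
                else:
                    assert (lo, hi) not in got
        # and no edge outside the kNN relation
        for lo, hi in got:
            assert hi in sets[lo] or lo in sets[hi]

    def test_duplicated_points_weight_one(self):
        # 0 and 1 are duplicates: identical closed neighbourhoods -> weight 1
        points = np.array([[5.0], [5.0], [4.0], [6.5], [30.0], [40.0]])
        graph = cm.build_jaccard_graph(points, k=2)
        sets = brute_force_knn_sets(points, 2)
        assert sets[0] == sets[1]
        weights = {tuple(e): w for e, w in zip(map(tuple, graph.edges), graph.weights)}
        assert weights[(0, 1)] == pytest.approx(1.0)

    def test_disjoint_neighbor_sets_no_edge(self):
        # two tight, far-apart triplets: no cross edges at k=2
        points = np.vstack([np.zeros((3, 2)) + [[0, 0], [0.1, 0], [0, 0.1]],
                            np.zeros((3, 2)) + [[90, 90], [90.1, 90], [90, 90.1]]])
        graph = cm.build_jaccard_graph(points, k=2)
        left = graph.edges < 3
        assert (left.all(axis=1) | (~left).all(axis=1)).all()

    def test_small_inputs(self):
        with pytest.raises(GraphError):
            cm.build_jaccard_graph(np.array([[0.0]]), k=2)
        graph = cm.build_jaccard_graph(np.array([[0.0], [1.0], [2.0]]), k=30)
        assert graph.n_nodes == 3  # k clamped, no crash


class TestModularity:
    def test_all_in_one_is_zero(self):
        graph = clique_pair_graph(3)
        assert cm.modularity(graph, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_matches_direct_summation(self, rng):
        graph = clique_pair_graph(3, weight=1.0)
        assignment = np.array([0, 0, 0, 1, 1, 1])
        assert cm.modularity(graph, assignment) == pytest.approx(
            brute_force_modularity(graph, assignment)
        )
        # and on a random weighted graph with a random assignment
        edges = np.array(list(itertools.combinations(range(7), 2)))
        keep = rng.random(len(edges)) < 0.6
        graph = NeighborGraph(7, edges[keep], rng.random(keep.sum()))
        assignment = rng.integers(0, 3, size=7)
        assert cm.modularity(graph, assignment) == pytest.approx(
            brute_force_modularity(graph, assignment)
        )

    def test_relabelling_invariance(self):
        graph = clique_pair_graph(3)
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([5, 5, 5, 2, 2, 2])
        assert cm.modularity(graph, a) == pytest.approx(cm.modularity(graph, b))

    def test_zero_weight_graph_errors(self):
        graph = NeighborGraph(3, np.array([[0, 1]]), np.array([0.0]))
        with pytest.raises(GraphError):
            cm.modularity(graph, np.zeros(3, dtype=int))


class TestDetectCommunities:
    def test_two_cliques_found_exactly(self):
        graph = clique_pair_graph(5)
        labels = cm.detect_communities(graph, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:5])) == 1 and len(np.unique(labels[5:])) == 1

    @pytest.mark.parametrize("builder", [
        lambda: clique_pair_graph(4),
        lambda: NeighborGraph(
            6,
            np.array(list(itertools.combinations(range(6), 2))),
            np.ones(15),
        ),  # K6: no split improves on one community
        lambda: clique_pair_graph(3, weight=0.5),
    ])
    def test_attains_exhaustive_optimum(self, builder):
        graph = builder()
        labels = cm.detect_communities(graph, seed=0)
        assert cm.modularity(graph, labels) >= exhaustive_best_modularity(graph) - 1e-9

    def test_k6_single_community(self):
        edges = np.array(list(itertools.combinations(range(6), 2)))
        graph = NeighborGraph(6, edges, np.ones(15))
        labels = cm.detect_communities(graph, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_given_seed(self):
        graph = clique_pair_graph(5)
        a = cm.detect_communities(graph, seed=3)
        b = cm.detect_communities(graph, seed=3)
        assert np.array_equal(a, b)

    def test_empty_graph_errors(self):
        with pytest.raises(GraphError):
            cm.detect_communities(NeighborGraph(0, np.empty((0, 2)), np.empty(0)))


class TestPartitionByScore:
    def scores(self, rows, types=("A", "B")):
        rows = np.asarray(rows, dtype=float)
        unknown = 1 - rows.max(axis=1, keepdims=True)
        return cm.ScoreMatrix(np.hstack([rows, unknown]), list(types))

    def test_rules(self):
        scores = self.scores([
            [0.9, 0.1],    # -> A
            [0.2, 0.3],    # unknown score 0.7 -> unknown pool
            [0.6, 0.55],   # both above: argmax A, overlap counted
            [0.45, 0.48],  # nothing above 0.5, unknown 0.52 -> unknown pool
            [0.5, 0.5],    # exactly at threshold: unassigned
        ])
        part = cm.partition_by_score(scores)
        assert list(part.by_type["A"]) == [0, 2]
        assert list(part.by_type["B"]) == []
        assert list(part.unknown) == [1, 3]
        assert list(part.unassigned) == [4]
        assert part.overlap_count == 1

    def test_exact_partition_property(self, rng):
        rows = rng.random((500, 3)) * rng.choice([0.4, 1.0], size=(500, 1))
        scores = self.scores(rows, types=("A", "B", "C"))
        part = cm.partition_by_score(scores)
        pieces = [ix for ix in part.by_type.values()] + [part.unknown, part.unassigned]
        combined = np.concatenate(pieces)
        assert len(combined) == 500
        assert len(np.unique(combined)) == 500


class TestExtractLandmarks:
    def make_partition(self, by_type, unknown=()):
        return ScorePartition(
            by_type={t: np.asarray(ix, dtype=int) for t, ix in by_type.items()},
            unknown=np.asarray(unknown, dtype=int),
            unassigned=np.array([], dtype=int),
            overlap_count=0,
        )

    def test_single_blob_landmarks_at_center(self, rng):
        """Community detection may split a homogeneous blob into several
        communities; all their landmarks must sit inside the blob and their
        member-weighted mean must match the sample mean."""
        points = rng.normal(5.0, 0.5, size=(200, 3))
        events = make_events(points, ["a", "b", "c"])
        part = self.make_partition({"T": np.arange(200)})
        lm = cm.extract_landmarks(events, part, k=15, seed=0)
        assert set(lm.labels) == {"T"}
        assert np.abs(lm.points - 5.0).max() < 3 * 0.5  # all within the blob
        weighted = np.average(lm.points, axis=0, weights=lm.member_counts)
        se = 0.5 / np.sqrt(200)
        assert np.abs(weighted - points.mean(axis=0)).max() < 3 * se + 1e-9

    def test_two_blobs_both_represented(self, rng):
        """Two well-separated blobs: every landmark lies in one blob, no
        landmark falls between them, and both blobs get at least one."""
        blob1 = rng.normal(0.0, 0.3, size=(100, 2))
        blob2 = rng.normal(8.0, 0.3, size=(100, 2))
        events = make_events(np.vstack([blob1, blob2]), ["a", "b"])
        part = self.make_partition({"T": np.arange(200)})
        lm = cm.extract_landmarks(events, part, k=15, seed=0)
        assert set(lm.labels) == {"T"}
        near1 = np.abs(lm.points - blob1.mean(axis=0)).max(axis=1) < 1.0
        near2 = np.abs(lm.points - blob2.mean(axis=0)).max(axis=1) < 1.0
        assert (near1 | near2).all()
        assert near1.any() and near2.any()

    def test_empty_unknown_subset_ok(self, rng):
        events = make_events(rng.normal(size=(50, 2)), ["a", "b"])
        part = self.make_partition({"T": np.arange(50)}, unknown=())
        lm = cm.extract_landmarks(events, part, k=10, seed=0)
        assert all(not l.startswith("unknown") for l in lm.labels)

    def test_tiny_subset_dropped_with_no_landmark(self, rng):
        events = make_events(rng.normal(size=(60, 2)), ["a", "b"])
        part = self.make_partition({"T": np.arange(50), "S": np.arange(50, 55)})
        lm = cm.extract_landmarks(events, part, k=10, min_cluster_size=10, seed=0)
        assert "S" not in lm.labels

    def test_landmark_csv_roundtrip(self, rng, tmp_path):
        events = make_events(rng.normal(size=(60, 2)), ["m1", "m2"])
        part = self.make_partition({"T": np.arange(60)})
        lm = cm.extract_landmarks(events, part, k=10, seed=0)
        path = tmp_path / "landmarks.csv"
        lm.to_csv(path)
        again = cm.LandmarkSet.from_csv(path)
        assert again.labels == lm.labels
        np.testing.assert_allclose(again.points, lm.points)
        assert again.marker_names == ["m1", "m2"]


class TestClusterMajorityBaseline:
    def test_perfect_clusters_reproduce_reference(self, rng):
        blob1 = rng.normal(0.0, 0.3, size=(80, 2))
        blob2 = rng.normal(9.0, 0.3, size=(80, 2))
        events = make_events(np.vstack([blob1, blob2]), ["a", "b"])
        reference = np.array(["X"] * 80 + ["Y"] * 80, dtype=object)
        labels = cm.cluster_majority_baseline(events, reference, k=15, seed=0)
        assert np.array_equal(labels, reference)

    def test_majority_rule(self, rng):
        # one tight blob whose reference is 60/40: all events get the majority
        points = rng.normal(0.0, 0.2, size=(100, 2))
        events = make_events(points, ["a", "b"])
        reference = np.array(["A"] * 60 + ["B"] * 40, dtype=object)
        labels = cm.cluster_majority_baseline(events, reference, k=30, seed=0)
        assert set(labels) == {"A"}
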