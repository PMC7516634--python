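"""Synthetic learning environments with controlled statistical structure.

Two generative models produce 31-feature, 4-class classification data:

* a *binary tree* model in which a ±1 value diffuses from the root down a
  depth-``D`` tree with a stochastic left/right flip (probability ``epsilon``),
  yielding hierarchically correlated features;
* an *independent clusters* model in which nodes of a spatial graph are
  annealed into disjoint groups; a sample activates one group, whose nodes
  take their topological order as feature value, giving a block-diagonal
  feature covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    AnnealingFailure,
    DegenerateGeometryError,
    InvalidConfigurationError,
    InvalidSampleError,
)

__all__ = [
    "TreeConfig",
    "ClustersConfig",
    "SpatialGraph",
    "Dataset",
    "generate_tree_sample",
    "tree_class_label",
    "generate_tree_dataset",
    "build_spatial_graph",
    "temperature_schedule",
    "anneal_edges",
    "direct_and_order",
    "generate_clusters_dataset",
    "covariance_matrix",
    "write_dataset_csv",
    "read_dataset_csv",
]


# ---------------------------------------------------------------------------
# Configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeConfig:
    """Parameters of the binary-tree generative model.

    ``depth`` levels give ``2**depth - 1`` features (depth 5 -> 31).
    ``flip_threshold`` is the probability epsilon that the +1 value flips to
    the right child instead of being inherited by the left child.
    ``distinction_level`` sets how deep the +1 path identifies the class;
    level 2 yields four classes.
    """

    depth: int = 5
    flip_threshold: float = 0.3
    distinction_level: int = 2
    n_samples: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise InvalidConfigurationError("tree depth must be >= 2")
        if not 0.0 <= self.flip_threshold <= 1.0:
            raise InvalidConfigurationError("flip_threshold must lie in [0, 1]")
        if self.distinction_level < 1:
            raise InvalidConfigurationError("distinction_level must be >= 1")
        if self.distinction_level + 1 > self.depth:
            raise InvalidConfigurationError(
                "distinction_level + 1 must not exceed the tree depth"
            )

    @property
    def n_features(self) -> int:
        return 2 ** self.depth - 1

    @property
    def n_classes(self) -> int:
        return 2 ** self.distinction_level


@dataclass(frozen=True)
class ClustersConfig:
    """Parameters of the independent-clusters generative model."""

    n_nodes: int = 31
    n_groups: int = 4
    max_schedule_steps: int = 200
    spread: float = 0.08
    n_samples: int = 4000
    seed: int = 0
    max_geometry_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise InvalidConfigurationError("n_groups must be >= 2")
        if self.n_groups > self.n_nodes:
            raise InvalidConfigurationError("n_groups cannot exceed n_nodes")
        if self.n_nodes < 2 * self.n_groups:
            raise InvalidConfigurationError("every group needs >= 2 nodes")
        if self.spread <= 0:
            raise InvalidConfigurationError("spread must be positive")
        if self.max_schedule_steps < 2:
            raise InvalidConfigurationError("max_schedule_steps must be >= 2")


@dataclass
class SpatialGraph:
    """Undirected spatial graph: 2-D node coordinates, Euclidean edge lengths
    and a group label per node."""

    graph: nx.Graph  # nodes carry 'pos' and 'group'; edges carry 'length'

    @property
    def positions(self) -> dict[int, np.ndarray]:
        return {n: np.asarray(d["pos"]) for n, d in self.graph.nodes(data=True)}

    @property
    def groups(self) -> dict[int, int]:
        return {n: d["group"] for n, d in self.graph.nodes(data=True)}

    def edge_lengths(self) -> np.ndarray:
        return np.array([d["length"] for _, _, d in self.graph.edges(data=True)])

    def copy(self) -> "SpatialGraph":
        return SpatialGraph(self.graph.copy())


@dataclass
class Dataset:
    """Design matrix plus integer class labels."""

    matrix: np.ndarray
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise InvalidConfigurationError("matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise InvalidConfigurationError("labels length must match sample count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else int(self.labels.max()) + 1


# ---------------------------------------------------------------------------
# Binary tree environment
# ---------------------------------------------------------------------------

def generate_tree_sample(config: TreeConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one ±1 feature vector from the binary-tree diffusion model.

    The tree is stored as a linear array: children of node ``i`` sit at
    ``2*i + 1`` (left) and ``2*i + 2`` (right).  The root is uniform on
    {−1, +1}.  The root's +1 child is deterministic (+1 root promotes the
    left child, −1 root the right child); below that, each +1 node passes
    +1 to its left child with probability ``1 − epsilon`` and to its right
    child otherwise.  Every node in a −1 node's subtree is −1.
    """
    if config.depth < 2:
        raise InvalidConfigurationError("tree depth must be >= 2")
    n = config.n_features
    values = -np.ones(n, dtype=int)
    root = 1 if rng.random() < 0.5 else -1
    values[0] = root
    # deterministic step at level 2
    plus_child = 1 if root == 1 else 2
    values[plus_child] = 1
    # stochastic diffusion from level 2 downward
    node = plus_child
    while 2 * node + 1 < n:
        left, right = 2 * node + 1, 2 * node + 2
        if rng.random() > config.flip_threshold:
            values[left] = 1
            node = left
        else:
            values[right] = 1
            node = right
    return values


def _level_slices(depth: int) -> list[range]:
    """Index ranges of each tree level, 1-based levels."""
    return [range(2 ** (l - 1) - 1, 2 ** l - 1) for l in range(1, depth + 1)]


def tree_class_label(features: np.ndarray, distinction_level: int) -> int:
    """Class of a tree sample from the +1 path down to ``distinction_level + 1``.

    The label encodes the root sign (high bit) followed by the left/right
    outcome at every +1 node on levels ``2 .. distinction_level``: outcome 0
    when the left child inherited +1 (no flip), 1 when the right child did.
    For ``distinction_level = 2`` this is the fixed enumeration
    (+1/no-flip, +1/flip, −1/no-flip, −1/flip) -> (0, 1, 2, 3).
    """
    features = np.asarray(features)
    n = len(features)
    depth = int(np.log2(n + 1))
    if 2 ** depth - 1 != n:
        raise InvalidSampleError("feature vector length is not 2**D - 1")
    if distinction_level + 1 > depth:
        raise InvalidConfigurationError("distinction_level + 1 exceeds tree depth")
    for level in _level_slices(depth)[1:]:
        if int(np.sum(features[list(level)] == 1)) != 1:
            raise InvalidSampleError(
                "malformed tree sample: each level below the root must hold "
                "exactly one +1 node"
            )
    if features[0] == 1:
        label = 0
        node = 1
    else:
        label = 1
        node = 2
    # follow the +1 path, recording flip outcomes at levels 2..distinction_level
    for _ in range(2, distinction_level + 1):
        left, right = 2 * node + 1, 2 * node + 2
        if features[left] == 1:
            label = label * 2 + 0
            node = left
        else:
            label = label * 2 + 1
            node = right
    return int(label)


def generate_tree_dataset(config: TreeConfig) -> Dataset:
    """Sample ``config.n_samples`` labelled instances of the tree environment."""
    rng = np.random.default_rng(config.seed)
    rows = np.empty((config.n_samples, config.n_features), dtype=float)
    labels = np.empty(config.n_samples, dtype=int)
    for i in range(config.n_samples):
        sample = generate_tree_sample(config, rng)
        rows[i] = sample
        labels[i] = tree_class_label(sample, config.distinction_level)
    names = [f"tree_class_{c}" for c in range(config.n_classes)]
    return Dataset(rows, labels, names)


# ---------------------------------------------------------------------------
# Independent clusters environment
# ---------------------------------------------------------------------------

_UNIT_SQUARE_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


def _group_sizes(n_nodes: int, n_groups: int) -> list[int]:
    base, extra = divmod(n_nodes, n_groups)
    return [base + (1 if g < extra else 0) for g in range(n_groups)]


def _group_centers(n_groups: int, rng: np.random.Generator) -> np.ndarray:
    if n_groups <= 4:
        return _UNIT_SQUARE_CORNERS[:n_groups].copy()
    # beyond four groups, place extra centers on a circle around the square
    extra = n_groups - 4
    angles = 2 * np.pi * np.arange(extra) / extra
    ring = 0.5 + 1.2 * np.column_stack([np.cos(angles), np.sin(angles)])
    return np.vstack([_UNIT_SQUARE_CORNERS, ring])


def build_spatial_graph(config: ClustersConfig, rng: np.random.Generator) -> SpatialGraph:
    """Scatter nodes around well-separated group centers; complete graph with
    Euclidean edge lengths."""
    if config.n_groups < 2:
        raise InvalidConfigurationError("n_groups must be >= 2")
    centers = _group_centers(config.n_groups, rng)
    sizes = _group_sizes(config.n_nodes, config.n_groups)
    g = nx.Graph()
    node = 0
    for group, size in enumerate(sizes):
        for _ in range(size):
            pos = centers[group] + rng.normal(0.0, config.spread, size=2)
            g.add_node(node, pos=tuple(pos), group=group)
            node += 1
    for u in g.nodes:
        pu = np.asarray(g.nodes[u]["pos"])
        for v in g.nodes:
            if v <= u:
                continue
            length = float(np.linalg.norm(pu - np.asarray(g.nodes[v]["pos"])))
            g.add_edge(u, v, length=length)
    return SpatialGraph(g)


def temperature_schedule(graph: SpatialGraph, n_steps: int) -> np.ndarray:
    """Equally spaced temperatures from 1/longest-edge up to 1/shortest-edge."""
    lengths = graph.edge_lengths()
    if lengths.size == 0:
        raise InvalidConfigurationError("graph has no edges")
    if n_steps < 2:
        raise InvalidConfigurationError("n_steps must be >= 2")
    if np.any(lengths <= 0):
        raise DegenerateGeometryError("zero-length edge: coincident nodes")
    t0 = 1.0 / lengths.max()
    tf = 1.0 / lengths.min()
    return np.linspace(t0, tf, n_steps)


def anneal_edges(
    graph: SpatialGraph, schedule: Iterable[float], n_groups: int
) -> SpatialGraph:
    """Delete edges of length >= 1/T along the rising temperature schedule.

    Stops at the first step after which the surviving graph splits into
    exactly ``n_groups`` connected components none of which is a single
    node.  Raises :class:`AnnealingFailure` if the schedule is exhausted
    without reaching that state.
    """
    work = graph.copy()
    g = work.graph

    def _done() -> bool:
        comps = list(nx.connected_components(g))
        return len(comps) == n_groups and all(len(c) >= 2 for c in comps)

    if _done():
        return work
    for temperature in schedule:
        threshold = 1.0 / temperature
        doomed = [
            (u, v) for u, v, d in g.edges(data=True) if d["length"] >= threshold
        ]
        g.remove_edges_from(doomed)
        if _done():
            return work
    raise AnnealingFailure(
        f"schedule exhausted without reaching {n_groups} non-singleton components"
    )


def direct_and_order(
    group_graph: nx.Graph, root: int
) -> tuple[dict[int, int], nx.DiGraph]:
    """Assign topological orders within one connected group and direct edges.

    The root gets order 1; every other node gets 1 + its unweighted graph
    distance from the root.  Each edge points from the lower-order endpoint
    to the higher-order endpoint; order ties point from the lower to the
    higher node id.  The root therefore has in-degree 0.
    """
    if not nx.is_connected(group_graph):
        raise InvalidSampleError("group subgraph must be connected")
    dist = nx.single_source_shortest_path_length(group_graph, root)
    orders = {node: 1 + d for node, d in dist.items()}
    directed = nx.DiGraph()
    directed.add_nodes_from(group_graph.nodes(data=True))
    for u, v, data in group_graph.edges(data=True):
        if orders[u] < orders[v] or (orders[u] == orders[v] and u < v):
            directed.add_edge(u, v, **data)
        else:
            directed.add_edge(v, u, **data)
    return orders, directed


def _annealed_groups(
    config: ClustersConfig, rng: np.random.Generator
) -> tuple[SpatialGraph, dict[int, int]]:
    """Build geometry, anneal, and compute topological orders; retries the
    geometry on annealing failure."""
    last_error: Exception | None = None
    for _ in range(config.max_geometry_retries):
        spatial = build_spatial_graph(config, rng)
        schedule = temperature_schedule(spatial, config.max_schedule_steps)
        try:
            annealed = anneal_edges(spatial, schedule, config.n_groups)
        except AnnealingFailure as err:  # new geometry draw and retry
            last_error = err
            continue
        orders: dict[int, int] = {}
        centers = {
            g: np.mean(
                [annealed.positions[n] for n, gr in annealed.groups.items() if gr == g],
                axis=0,
            )
            for g in range(config.n_groups)
        }
        for comp in nx.connected_components(annealed.graph):
            sub = annealed.graph.subgraph(comp)
            group = annealed.graph.nodes[next(iter(comp))]["group"]
            center = centers[group]
            root = min(
                comp,
                key=lambda n: (
                    float(np.linalg.norm(annealed.positions[n] - center)),
                    n,
                ),
            )
            comp_orders, _ = direct_and_order(sub, root)
            orders.update(comp_orders)
        return annealed, orders
    raise AnnealingFailure(
        f"no geometry produced {config.n_groups} groups after "
        f"{config.max_geometry_retries} retries"
    ) from last_error


def generate_clusters_dataset(config: ClustersConfig) -> Dataset:
    """Sample the independent-clusters environment.

    Every sample picks one group uniformly at random; features of nodes in
    the chosen group equal their topological order, all other features are
    −1.  The label is the group index, so exactly ``n_groups`` distinct row
    patterns occur.
    """
    rng = np.random.default_rng(config.seed)
    annealed, orders = _annealed_groups(config, rng)
    groups = annealed.groups
    patterns = -np.ones((config.n_groups, config.n_nodes), dtype=float)
    for node, order in orders.items():
        patterns[groups[node], node] = order
    labels = rng.integers(0, config.n_groups, size=config.n_samples)
    matrix = patterns[labels]
    names = [f"cluster_group_{g}" for g in range(config.n_groups)]
    return Dataset(matrix, labels, names)


# ---------------------------------------------------------------------------
# Diagnostics and I/O
# ---------------------------------------------------------------------------

def covariance_matrix(dataset: Dataset) -> np.ndarray:
    """Sample covariance across features (features as variables)."""
    if dataset.n_samples < 2:
        raise InvalidConfigurationError("covariance needs at least 2 samples")
    return np.cov(dataset.matrix, rowvar=False)


def write_dataset_csv(dataset: Dataset, path: str | Path) -> None:
    """One sample per row; header ``f0..fN,label``."""
    frame = pd.DataFrame(
        dataset.matrix, columns=[f"f{j}" for j in range(dataset.n_features)]
    )
    frame["label"] = dataset.labels
    frame.to_csv(path, index=False)


def read_dataset_csv(path: str | Path, class_names: list[str] | None = None) -> Dataset:
    frame = pd.read_csv(path)
    labels = frame.pop("label").to_numpy(dtype=int)
    return Dataset(frame.to_numpy(dtype=float), labels, class_names or [])
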