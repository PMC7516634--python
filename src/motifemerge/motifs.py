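"""Network motif mining: ESU enumeration, canonical labeling, null models,
and Z-score significance profiles.

The miner counts every weakly connected induced k-node subgraph of a
directed graph exactly once (ESU ordered-extension enumeration), groups the
counts by isomorphism class via exhaustive canonical labeling (exact for
k <= 5, at most 120 permutations), builds a degree-preserving null ensemble
by double-edge switch randomization, and scores each class with

    Z = (N_real - <N_random>) / sigma_random.

Edge *colors* (the strong/mild weight categories) can be included in the
isomorphism classification, which is the weighted-analysis mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .graph_extraction import CATEGORY_COLORS

__all__ = [
    "MotifCensus",
    "NullModelConfig",
    "ProfileEntry",
    "SignificanceProfile",
    "canonical_code",
    "canonical_matrix",
    "decode_matrix",
    "skeleton_code",
    "enumerate_connected_subgraphs",
    "brute_force_census",
    "switch_randomize",
    "null_census_ensemble",
    "z_scores",
    "profile_delta",
    "top_motifs",
    "census_to_frame",
    "profile_to_frame",
    "profile_to_csv",
]

_PERMUTATIONS: dict[int, list[tuple[int, ...]]] = {
    k: list(itertools.permutations(range(k))) for k in range(1, 6)
}

#: base of the positional code: 0/1 uncolored, 0..3 colored (0 = no edge,
#: otherwise 1 + color).
_BASE = {False: 2, True: 4}


# ---------------------------------------------------------------------------
# Canonical labeling (exact, exhaustive over <= 5! permutations)
# ---------------------------------------------------------------------------

def _encode(matrix: np.ndarray, base: int) -> int:
    code = 0
    for value in matrix.ravel():
        code = code * base + int(value)
    return code


_canon_cache: dict[tuple[int, bool, tuple[int, ...]], int] = {}


def canonical_code(adjacency: np.ndarray, colored: bool = False) -> int:
    """Permutation-invariant integer identifying the isomorphism class.

    ``adjacency`` is a k x k integer matrix: entry 0 means no arc; in
    colored mode a present arc carries ``1 + color`` (1 mild, 2 strongly
    positive, 3 strongly negative), in uncolored mode 1.  The code is the
    minimum over all k! simultaneous row/column permutations of the
    row-major base-``B`` number, B = 2 (uncolored) or 4 (colored).
    """
    adjacency = np.asarray(adjacency, dtype=np.int64)
    k = adjacency.shape[0]
    if k > 5:
        raise InvalidConfigurationError("canonical labeling supports k <= 5")
    base = _BASE[colored]
    raw = tuple(adjacency.ravel().tolist())
    key = (k, colored, raw)
    cached = _canon_cache.get(key)
    if cached is not None:
        return cached
    best = None
    for perm in _PERMUTATIONS[k]:
        permuted = adjacency[np.ix_(perm, perm)]
        code = _encode(permuted, base)
        if best is None or code < best:
            best = code
    _canon_cache[key] = best  # type: ignore[assignment]
    return best  # type: ignore[return-value]


def canonical_matrix(code: int, k: int, colored: bool = False) -> np.ndarray:
    """Decode a canonical code back into its k x k representative matrix."""
    return decode_matrix(code, k, colored)


def decode_matrix(code: int, k: int, colored: bool = False) -> np.ndarray:
    base = _BASE[colored]
    digits = np.zeros(k * k, dtype=np.int64)
    for pos in range(k * k - 1, -1, -1):
        digits[pos] = code % base
        code //= base
    return digits.reshape(k, k)


def skeleton_code(code: int, k: int) -> int:
    """Uncolored canonical code of a colored class's underlying digraph."""
    matrix = decode_matrix(code, k, colored=True)
    return canonical_code((matrix > 0).astype(np.int64), colored=False)


def adjacency_string(code: int, k: int, colored: bool = False) -> str:
    """Row-major digit string of the canonical representative."""
    return "".join(str(d) for d in decode_matrix(code, k, colored).ravel())


# ---------------------------------------------------------------------------
# Subgraph enumeration
# ---------------------------------------------------------------------------

@dataclass
class MotifCensus:
    """Occurrence counts of connected induced k-subgraphs per canonical code."""

    k: int
    colored: bool
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _graph_arrays(graph: nx.DiGraph, colored: bool
                  ) -> tuple[list[int], dict[int, int], np.ndarray]:
    """Relabel nodes to 0..n-1; dense adjacency with color codes."""
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=np.int64)
    for u, v, data in graph.edges(data=True):
        if colored:
            adj[index[u], index[v]] = 1 + CATEGORY_COLORS[data.get("category",
                                                                   "mild")]
        else:
            adj[index[u], index[v]] = 1
    return nodes, index, adj


def _subgraph_code(adj: np.ndarray, nodes: tuple[int, ...],
                   colored: bool) -> int:
    sub = adj[np.ix_(nodes, nodes)]
    return canonical_code(sub, colored)


def enumerate_connected_subgraphs(graph: nx.DiGraph, k: int,
                                  colored: bool = False) -> MotifCensus:
    """ESU census of weakly connected induced k-node subgraphs.

    Every such subgraph is visited exactly once via the ordered-extension
    scheme: starting from each node v, the extension set only ever admits
    exclusive neighbors with a label greater than v.
    """
    if not 1 <= k <= 5:
        raise InvalidConfigurationError("k must be between 1 and 5")
    if nx.number_of_selfloops(graph):
        raise InvalidConfigurationError("graph must be simple (no self-loops)")
    census = MotifCensus(k=k, colored=colored)
    n = graph.number_of_nodes()
    if k > n:
        return census
    _, index, adj = _graph_arrays(graph, colored)
    # undirected neighborhoods over integer labels
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, j in zip(*np.nonzero(adj)):
        neighbors[i].add(int(j))
        neighbors[j].add(int(i))

    counts = census.counts

    def extend(sub: list[int], ext: set[int], v: int,
               closed: set[int]) -> None:
        if len(sub) == k:
            code = _subgraph_code(adj, tuple(sub), colored)
            counts[code] = counts.get(code, 0) + 1
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            # exclusive neighbors of w: not in sub and not adjacent to sub
            new_ext = ext | {u for u in neighbors[w]
                             if u > v and u not in closed}
            extend(sub + [w], new_ext, v, closed | neighbors[w])
        return

    for v in range(n):
        ext = {u for u in neighbors[v] if u > v}
        extend([v], ext, v, {v} | neighbors[v])
    return census


def brute_force_census(graph: nx.DiGraph, k: int,
                       colored: bool = False) -> MotifCensus:
    """All-subsets reference census (oracle for ESU; O(C(n, k)))."""
    census = MotifCensus(k=k, colored=colored)
    nodes, _, adj = _graph_arrays(graph, colored)
    n = len(nodes)
    und = ((adj > 0) | (adj > 0).T).astype(np.int64)
    for subset in itertools.combinations(range(n), k):
        sub_und = und[np.ix_(subset, subset)]
        g = nx.from_numpy_array(sub_und)
        if not nx.is_connected(g):
            continue
        code = _subgraph_code(adj, subset, colored)
        census.counts[code] = census.counts.get(code, 0) + 1
    return census


# ---------------------------------------------------------------------------
# Null model: degree-preserving switch randomization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullModelConfig:
    """Randomized-replica ensemble settings."""

    n_replicas: int = 1000
    swaps_per_edge: int = 3
    mode: Literal["layer_preserving", "global"] = "layer_preserving"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise InvalidConfigurationError(
                "n_replicas must be >= 2 for a defined standard deviation"
            )
        if self.swaps_per_edge < 0:
            raise InvalidConfigurationError("swaps_per_edge must be >= 0")
        if self.mode not in ("layer_preserving", "global"):
            raise InvalidConfigurationError(f"unknown null mode {self.mode!r}")


def switch_randomize(graph: nx.DiGraph, config: NullModelConfig,
                     rng: np.random.Generator) -> nx.DiGraph:
    """One randomized replica via double-edge swaps (a->b, c->d) => (a->d, c->b).

    Swaps that would create a self-loop or duplicate an existing edge are
    rejected; in ``layer_preserving`` mode a swap is also rejected unless
    both new edges join consecutive layers.  In- and out-degrees of every
    node are preserved exactly.  Edge attributes travel with the source
    half of each rewired edge.
    """
    edges = [(u, v, dict(d)) for u, v, d in graph.edges(data=True)]
    n_edges = len(edges)
    replica = graph.copy()
    if n_edges < 2:
        return replica
    layer_mode = config.mode == "layer_preserving"
    layers = {n: d.get("layer") for n, d in graph.nodes(data=True)}
    if layer_mode and any(l is None for l in layers.values()):
        raise InvalidConfigurationError(
            "layer_preserving null model needs a 'layer' attribute on every node"
        )
    present = {(u, v) for u, v, _ in edges}
    attempts = config.swaps_per_edge * n_edges
    for _ in range(attempts):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b, ab_data = edges[i]
        c, d, cd_data = edges[j]
        if a == d or c == b:          # would create a self-loop
            continue
        if (a, d) in present or (c, b) in present:   # duplicate
            continue
        if layer_mode and (layers[d] != layers[a] + 1
                           or layers[b] != layers[c] + 1):
            continue
        present.discard((a, b))
        present.discard((c, d))
        present.add((a, d))
        present.add((c, b))
        edges[i] = (a, d, ab_data)
        edges[j] = (c, b, cd_data)
    replica.remove_edges_from(list(replica.edges))
    for u, v, data in edges:
        replica.add_edge(u, v, **data)
    return replica


def null_census_ensemble(graph: nx.DiGraph, k: int, config: NullModelConfig,
                         colored: bool = False
                         ) -> dict[int, tuple[float, float]]:
    """Per-class (mean, sample sd) of counts over the randomized ensemble.

    Classes absent from a replica contribute a zero count; classes that
    appear only in replicas are retained (they carry N_real = 0 when
    scored).
    """
    rng = np.random.default_rng(config.seed)
    replica_counts: list[dict[int, int]] = []
    codes: set[int] = set()
    for _ in range(config.n_replicas):
        replica = switch_randomize(graph, config, rng)
        census = enumerate_connected_subgraphs(replica, k, colored)
        replica_counts.append(census.counts)
        codes.update(census.counts)
    out: dict[int, tuple[float, float]] = {}
    for code in codes:
        values = np.array([c.get(code, 0) for c in replica_counts], dtype=float)
        out[code] = (float(values.mean()), float(values.std(ddof=1)))
    return out


# ---------------------------------------------------------------------------
# Significance profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileEntry:
    n_real: int
    mean_random: float
    sd_random: float
    z: float | None  # None where sigma_random = 0 (Z undefined)


@dataclass
class SignificanceProfile:
    """Non-normalized per-class Z-scores for one network."""

    k: int
    colored: bool
    entries: dict[int, ProfileEntry] = field(default_factory=dict)

    def defined(self) -> dict[int, float]:
        return {c: e.z for c, e in self.entries.items() if e.z is not None}


def z_scores(census: MotifCensus,
             ensemble: dict[int, tuple[float, float]]) -> SignificanceProfile:
    """Z = (N_real - <N_random>) / sigma_random per isomorphism class.

    Classes whose null standard deviation is zero get an undefined Z and
    are excluded from profile plots and deltas.
    """
    profile = SignificanceProfile(k=census.k, colored=census.colored)
    for code in set(census.counts) | set(ensemble):
        n_real = census.counts.get(code, 0)
        mean, sd = ensemble.get(code, (0.0, 0.0))
        z = (n_real - mean) / sd if sd > 0 else None
        profile.entries[code] = ProfileEntry(n_real, mean, sd, z)
    return profile


def profile_delta(before: SignificanceProfile,
                  after: SignificanceProfile) -> dict[int, float | None]:
    """Per-class Z_after − Z_before; undefined on either side stays undefined.

    A class entirely absent from one profile counts as Z = 0 there.
    """
    if before.k != after.k or before.colored != after.colored:
        raise InvalidConfigurationError(
            "profiles must share k and coloring mode to be compared"
        )
    deltas: dict[int, float | None] = {}
    for code in set(before.entries) | set(after.entries):
        zb = before.entries[code].z if code in before.entries else 0.0
        za = after.entries[code].z if code in after.entries else 0.0
        deltas[code] = None if zb is None or za is None else za - zb
    return deltas


def top_motifs(profile: SignificanceProfile, n: int,
               mode: Literal["most_significant", "most_typical"]
               = "most_significant") -> list[tuple[int, float]]:
    """Ranked (code, Z) list, one representative per isomorphic group.

    In colored analysis, classes sharing an uncolored skeleton form one
    group: ``most_significant`` keeps the member of largest |Z|,
    ``most_typical`` the member whose Z is closest to the group mean.
    Ranking is by |Z| descending, ties by canonical code ascending.
    """
    defined = profile.defined()
    if not defined:
        return []
    if profile.colored:
        groups: dict[int, list[int]] = {}
        for code in defined:
            groups.setdefault(skeleton_code(code, profile.k), []).append(code)
    else:
        groups = {code: [code] for code in defined}
    chosen: list[tuple[int, float]] = []
    for members in groups.values():
        if mode == "most_significant":
            pick = min(members, key=lambda c: (-abs(defined[c]), c))
        elif mode == "most_typical":
            mean_z = float(np.mean([defined[c] for c in members]))
            pick = min(members, key=lambda c: (abs(defined[c] - mean_z), c))
        else:
            raise InvalidConfigurationError(f"unknown ranking mode {mode!r}")
        chosen.append((pick, defined[pick]))
    chosen.sort(key=lambda item: (-abs(item[1]), item[0]))
    return chosen[:n]


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def census_to_frame(census: MotifCensus) -> pd.DataFrame:
    rows = [
        {
            "k": census.k,
            "canonical_code": code,
            "adjacency_string": adjacency_string(code, census.k, census.colored),
            "Nreal": count,
        }
        for code, count in sorted(census.counts.items())
    ]
    return pd.DataFrame(rows,
                        columns=["k", "canonical_code", "adjacency_string",
                                 "Nreal"])


def profile_to_frame(profile: SignificanceProfile) -> pd.DataFrame:
    rows = []
    for code, e in sorted(profile.entries.items()):
        rows.append({
            "k": profile.k,
            "canonical_code": code,
            "adjacency_string": adjacency_string(code, profile.k,
                                                 profile.colored),
            "Nreal": e.n_real,
            "mean_random": e.mean_random,
            "sd_random": e.sd_random,
            "Z": e.z if e.z is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=["k", "canonical_code",
                                       "adjacency_string", "Nreal",
                                       "mean_random", "sd_random", "Z"])


def profile_to_csv(profile: SignificanceProfile, path: str | Path) -> None:
    profile_to_frame(profile).to_csv(path, index=False)
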