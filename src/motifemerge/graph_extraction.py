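"""From trained parameters to a layered directed graph of strong connections.

A single Gaussian is fitted to the pooled connection weights of all layers;
weights whose fitted density exceeds ``c`` times the density peak form the
*exclusion zone* (the near-zero bulk) and are dropped.  The survivors become
directed edges of a layered graph whose nodes are the network's units, with
each edge categorized as strongly positive, strongly negative, or mild
relative to the fitted distribution.

The default cutoff ``c = 0.26`` is calibrated so that for Normal-initialized
weights (sigma = 0.1) the mean absolute retained weight is 0.206: the
truncated half-normal mean equation ``E[|w| : |w| > t] = 0.206`` solves at
``t = 1.642 sigma``, and ``c = exp(-t^2 / 2 sigma^2) = 0.26``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .errors import DegenerateFitError, InvalidConfigurationError
from .mlp import MLPParameters

__all__ = [
    "PruneConfig",
    "RetainedWeight",
    "CATEGORY_COLORS",
    "COLOR_CATEGORIES",
    "fit_gaussian",
    "exclusion_halfwidth",
    "calibrate_cutoff",
    "prune",
    "categorize",
    "model_to_graph",
    "layer_offsets",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]

#: FANMOD-style integer edge colors.
CATEGORY_COLORS = {"mild": 0, "strong_positive": 1, "strong_negative": 2}
COLOR_CATEGORIES = {v: k for k, v in CATEGORY_COLORS.items()}


@dataclass(frozen=True)
class PruneConfig:
    """Density cutoff ``c`` (larger c -> smaller exclusion zone) and the
    strong/mild category boundary in units of the fitted sigma."""

    cutoff: float = 0.26
    strong_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise InvalidConfigurationError("cutoff c must lie strictly in (0, 1)")
        if self.strong_multiplier <= 0:
            raise InvalidConfigurationError("strong_multiplier must be positive")


class RetainedWeight(NamedTuple):
    source: int
    target: int
    weight: float
    category: str


def fit_gaussian(weights: Iterable[float]) -> tuple[float, float]:
    """Maximum-likelihood Normal fit (mean, std) of pooled weights."""
    w = np.asarray(list(weights) if not isinstance(weights, np.ndarray) else weights,
                   dtype=float).ravel()
    if w.size < 2 or np.unique(w).size < 2:
        raise DegenerateFitError("need at least 2 distinct weights to fit")
    return float(w.mean()), float(w.std())


def exclusion_halfwidth(sigma: float, c: float) -> float:
    """Half-width of the exclusion band: |w - mu| <= sigma*sqrt(2 ln(1/c)).

    A weight is excluded iff the fitted Gaussian density at w is at least
    ``c`` times the peak density.
    """
    if not 0.0 < c < 1.0:
        raise InvalidConfigurationError("cutoff c must lie strictly in (0, 1)")
    if sigma <= 0:
        raise DegenerateFitError("sigma must be positive")
    return float(sigma * np.sqrt(2.0 * np.log(1.0 / c)))


def calibrate_cutoff(target_mean_abs: float, sigma: float) -> float:
    """Cutoff c such that retained |weights| of a centred Normal(0, sigma)
    average ``target_mean_abs``.

    Solves the truncated half-normal mean equation
    ``sigma * phi(a) / (1 - Phi(a)) = target`` for ``a = t/sigma`` and
    returns ``c = exp(-a^2/2)``.
    """
    if target_mean_abs <= sigma * stats.norm.pdf(0) / stats.norm.sf(0):
        raise InvalidConfigurationError(
            "target mean must exceed the untruncated half-normal mean"
        )
    f = lambda a: sigma * stats.norm.pdf(a) / stats.norm.sf(a) - target_mean_abs
    a = optimize.brentq(f, 1e-9, 20.0)
    return float(np.exp(-0.5 * a * a))


def categorize(weight: float, mu: float, sigma: float,
               strong_multiplier: float) -> str:
    if weight > mu + strong_multiplier * sigma:
        return "strong_positive"
    if weight < mu - strong_multiplier * sigma:
        return "strong_negative"
    return "mild"


def layer_offsets(layer_sizes: tuple[int, ...]) -> list[int]:
    """Starting node id of each layer under contiguous layer-major numbering."""
    return [int(o) for o in np.concatenate([[0], np.cumsum(layer_sizes)[:-1]])]


def prune(params: MLPParameters, config: PruneConfig) -> list[RetainedWeight]:
    """Weights outside the exclusion zone as (source, target, weight, category).

    Node ids are contiguous by layer (inputs first).  Biases are not part
    of the graph: motifs concern connectivity between units.
    """
    mu, sigma = fit_gaussian(params.all_weights())
    half = exclusion_halfwidth(sigma, config.cutoff)
    offsets = layer_offsets(params.layer_sizes)
    retained: list[RetainedWeight] = []
    for li, w in enumerate(params.weights):
        keep = np.abs(w - mu) > half
        for i, j in zip(*np.nonzero(keep)):
            value = float(w[i, j])
            retained.append(RetainedWeight(
                offsets[li] + int(i),
                offsets[li + 1] + int(j),
                value,
                categorize(value, mu, sigma, config.strong_multiplier),
            ))
    return retained


def model_to_graph(params: MLPParameters, config: PruneConfig) -> nx.DiGraph:
    """Layered digraph of retained connections, oriented input -> output.

    All units appear as nodes (with a ``layer`` attribute) even when every
    one of their connections was pruned.
    """
    sizes = params.layer_sizes
    offsets = layer_offsets(sizes)
    g = nx.DiGraph()
    for layer, (size, off) in enumerate(zip(sizes, offsets)):
        for i in range(size):
            g.add_node(off + i, layer=layer)
    for rec in prune(params, config):
        g.add_edge(rec.source, rec.target, weight=rec.weight,
                   category=rec.category)
    return g


# ---------------------------------------------------------------------------
# Edge-list and GraphML I/O
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.DiGraph, path: str | Path,
                    colored: bool = True) -> None:
    """FANMOD dialect: one ``source target [color]`` line per edge."""
    lines = []
    for u, v, data in sorted(graph.edges(data=True)):
        if colored:
            color = CATEGORY_COLORS[data.get("category", "mild")]
            lines.append(f"{u} {v} {color}")
        else:
            lines.append(f"{u} {v}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_edge_list(path: str | Path) -> nx.DiGraph:
    """Read a whitespace-separated integer edge list, optional color column."""
    g = nx.DiGraph()
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        u, v = int(parts[0]), int(parts[1])
        if len(parts) >= 3:
            g.add_edge(u, v, category=COLOR_CATEGORIES[int(parts[2])])
        else:
            g.add_edge(u, v)
    return g


def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
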