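"""Weighted graph measures of a covariance network.

Conventions (fixed defaults, see each function):

- shortest-path edge length = 1 / weight ("inverse-weight"; alternatives
  "one-minus" = 1 - w and "neg-log" = -ln w are available everywhere a
  ``distance`` argument is accepted);
- weighted clustering is the Onnela geometric-mean form with max-weight
  normalization;
- local efficiency of a node is the global efficiency of its neighbor-induced
  subgraph keeping original weights;
- characteristic path length averages finite distances only (unreachable
  pairs are excluded and their count logged);
- assortativity correlates endpoint *degrees* (edge counts) over the directed
  edge list; zero degree variance or < 2 edges yields NaN, never 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, fields
from typing import Union

import numpy as np

from .network import ConnectivityMatrix

__all__ = [
    "NetworkMeasures",
    "MEASURE_NAMES",
    "distances",
    "global_efficiency",
    "local_efficiency",
    "mean_clustering",
    "characteristic_path_length",
    "strength_degree",
    "assortativity",
    "all_measures",
]

logger = logging.getLogger(__name__)

DISTANCE_CONVENTIONS = ("inverse-weight", "one-minus", "neg-log")

MEASURE_NAMES = (
    "global_efficiency",
    "local_efficiency",
    "mean_clustering_coefficient",
    "characteristic_path_length",
    "average_strength",
    "average_degree",
    "assortative_coefficient",
)

WeightsLike = Union[np.ndarray, ConnectivityMatrix]


@dataclass(frozen=True)
class NetworkMeasures:
    """Scalar summary measures of one weighted network.

    ``assortative_coefficient`` is NaN when undefined (regular graphs, < 2
    edges); ``characteristic_path_length`` is ``inf`` when no pair is
    reachable.
    """

    global_efficiency: float
    local_efficiency: float
    mean_clustering_coefficient: float
    characteristic_path_length: float
    average_strength: float
    average_degree: float
    assortative_coefficient: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in MEASURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}

    def to_record(self) -> dict[str, str]:
        """Delimited-text-friendly dict; undefined values rendered as 'NA'."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = "NA" if math.isnan(v) else f"{v:.12g}"
        return out


def _weights(w: WeightsLike) -> np.ndarray:
    if isinstance(w, ConnectivityMatrix):
        return w.weights
    m = np.asarray(w, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {m.shape}")
    return m


def _edge_lengths(w: np.ndarray, distance: str) -> np.ndarray:
    if distance not in DISTANCE_CONVENTIONS:
        raise ValueError(
            f"unknown distance convention {distance!r}; choose from {DISTANCE_CONVENTIONS}"
        )
    pos = w > 0
    lengths = np.zeros_like(w)
    with np.errstate(divide="ignore", over="ignore"):
        if distance == "inverse-weight":
            lengths[pos] = 1.0 / w[pos]
        elif distance == "one-minus":
            lengths[pos] = 1.0 - w[pos]
        else:  # neg-log
            lengths[pos] = -np.log(w[pos])
    return lengths


def distances(w: WeightsLike, *, distance: str = "inverse-weight") -> np.ndarray:
    """Exact pairwise shortest-path distances; unreachable pairs are +inf.

    Edges with zero weight are absent. ``d[i, i] = 0`` and the matrix is
    symmetric.
    """
    m = _weights(w)
    lengths = _edge_lengths(m, distance)
    d = np.where(m > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    # Floyd-Warshall, row-vectorized; exact for non-negative lengths and
    # faster than sparse-graph routines at covariance-network sizes (< ~200)
    for k in range(d.shape[0]):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def _geff_from_dist(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d[off]), 0.0, 1.0 / np.where(d[off] == 0, np.inf, d[off]))
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(w: WeightsLike, *, distance: str = "inverse-weight") -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    return _geff_from_dist(distances(w, distance=distance))


def local_efficiency(w: WeightsLike, *, distance: str = "inverse-weight") -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph.

    Neighbors are nodes with positive weight to ``i``; the subgraph keeps the
    original weights. Nodes with fewer than 2 neighbors contribute 0.
    """
    m = _weights(w)
    n = m.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(m[i] > 0)
        if nb.size < 2:
            continue
        sub = m[np.ix_(nb, nb)]
        total += _geff_from_dist(distances(sub, distance=distance))
    return total / n


def mean_clustering(w: WeightsLike) -> float:
    """Onnela weighted clustering, averaged over nodes.

    C_i = [1 / (k_i (k_i - 1))] * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) with
    w' = w / max(w); nodes with degree < 2 contribute 0. An all-zero matrix
    returns 0 with a warning.
    """
    m = _weights(w)
    wmax = m.max()
    if wmax == 0:
        warnings.warn("all-zero weight matrix: clustering defined as 0", UserWarning,
                      stacklevel=2)
        return 0.0
    cube = np.cbrt(m / wmax)
    triples = np.diag(cube @ cube @ cube)  # sum over ordered (j, h) closing a triangle
    k = (m > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, triples / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean())


def characteristic_path_length(
    w: WeightsLike, *, distance: str = "inverse-weight"
) -> float:
    """Mean shortest-path distance over reachable ordered pairs.

    Unreachable pairs are excluded (count logged); if no pair is reachable
    the result is ``inf``.
    """
    d = distances(w, distance=distance)
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    finite = np.isfinite(off)
    excluded = int((~finite).sum())
    if excluded:
        logger.info("characteristic_path_length: excluded %d unreachable pairs", excluded)
    if not finite.any():
        return float("inf")
    return float(off[finite].mean())


def strength_degree(w: WeightsLike) -> tuple[float, float]:
    """(average node strength, average node degree)."""
    m = _weights(w)
    return float(m.sum(axis=1).mean()), float((m > 0).sum(axis=1).mean())


def assortativity(w: WeightsLike, *, use_strength: bool = False) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Each unordered positive-weight edge contributes both orientations. With
    ``use_strength=True`` the endpoint attribute is node strength instead of
    degree (non-default variant). Returns NaN when < 2 edges or the endpoint
    attribute has zero variance.
    """
    m = _weights(w)
    i_idx, j_idx = np.where(np.triu(m, k=1) > 0)
    if i_idx.size < 2:
        return float("nan")
    attr = m.sum(axis=1) if use_strength else (m > 0).sum(axis=1).astype(float)
    x = np.concatenate([attr[i_idx], attr[j_idx]])
    y = np.concatenate([attr[j_idx], attr[i_idx]])
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def all_measures(w: WeightsLike, *, distance: str = "inverse-weight") -> NetworkMeasures:
    """All seven measures computed on one matrix (single distance pass)."""
    m = _weights(w)
    d = distances(m, distance=distance)
    strength, degree = strength_degree(m)
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    finite = np.isfinite(off)
    cpl = float(off[finite].mean()) if finite.any() else float("inf")
    return NetworkMeasures(
        global_efficiency=_geff_from_dist(d),
        local_efficiency=local_efficiency(m, distance=distance),
        mean_clustering_coefficient=mean_clustering(m),
        characteristic_path_length=cpl,
        average_strength=strength,
        average_degree=degree,
        assortative_coefficient=assortativity(m),
    )
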