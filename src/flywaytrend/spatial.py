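"""Relative neighborhood graphs and Moran's I autocorrelation tests.

The diagnostic of the trend pipeline: connect survey points by a relative
neighborhood graph (RNG), attach per-point values (site slopes, predicted
random effects) and test them for spatial autocorrelation with the
Cliff-Ord Moran statistic.  An RNG joins p and q iff no third point r is
strictly closer to both of them than they are to each other:

    edge(p, q)  <=>  no r with max(d(p,r), d(q,r)) < d(p,q)

The RNG contains the minimum spanning tree (hence is connected) and is a
subgraph of the Delaunay triangulation, a property the construction
exploits by screening Delaunay edges only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError
from scipy.stats import norm

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """Moran's I is undefined (zero variance in the values)."""


@dataclass
class NeighborGraph:
    """Undirected proximity graph over labelled points."""

    ids: list
    coords: np.ndarray               # (n, 2)
    edges: list[tuple[int, int]]     # index pairs, i < j, sorted

    @property
    def n(self) -> int:
        return len(self.ids)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class SpatialWeights:
    """Sparse nonnegative spatial weight matrix with zero diagonal."""

    ids: list
    matrix: sp.csr_matrix
    style: str  # "binary" | "row-standardized"

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    null: str          # "randomization" | "normality"
    alternative: str   # "greater" | "two-sided" | "less"


def _candidate_edges(coords: np.ndarray) -> list[tuple[int, int]]:
    """Delaunay edges when available, otherwise all pairs."""
    n = len(coords)
    if n >= 4:
        try:
            tri = Delaunay(coords)
            edges = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = int(simplex[a]), int(simplex[b])
                        edges.add((min(i, j), max(i, j)))
            return sorted(edges)
        except QhullError:
            pass  # degenerate layout (e.g. collinear points)
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def relative_neighborhood_graph(coords, ids=None, jitter: float = 1e-6,
                                seed: int = 0) -> NeighborGraph:
    """Build the relative neighborhood graph of a point set.

    Duplicate coordinates (sites closer than the floating-point resolution,
    which do occur in winter-count schemes) are jittered by a Normal
    perturbation of SD ``jitter`` meters before construction; ties in the
    strict-inequality blocker test do not remove edges.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 2:
        raise ValueError("need >= 2 two-dimensional points")
    if ids is None:
        ids = list(range(len(coords)))

    _, inverse, counts = np.unique(coords, axis=0, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        ndup = int((counts[inverse] > 1).sum())
        logger.warning("jittering %d duplicate coordinates by %.2g", ndup, jitter)
        rng = np.random.default_rng(seed)
        dup_mask = counts[inverse] > 1
        coords = coords.copy()
        coords[dup_mask] += rng.normal(0.0, jitter, size=(ndup, 2))

    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    edges = []
    # strict inequality with a relative guard so exact geometric ties
    # (equilateral configurations) do not block an edge through rounding
    for i, j in _candidate_edges(coords):
        cut = dist[i, j] * (1.0 - 1e-12)
        if not np.any((dist[i] < cut) & (dist[j] < cut)):
            edges.append((i, j))
    return NeighborGraph(ids=list(ids), coords=coords, edges=edges)


def to_weights(graph: NeighborGraph, style: str = "row-standardized") -> SpatialWeights:
    """Convert a graph to a binary or row-standardized weight matrix."""
    if style not in ("binary", "row-standardized"):
        raise ValueError(f"unknown weight style {style!r}")
    n = graph.n
    rows = [i for i, j in graph.edges] + [j for i, j in graph.edges]
    cols = [j for i, j in graph.edges] + [i for i, j in graph.edges]
    data = np.ones(len(rows))
    w = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    if style == "row-standardized":
        deg = np.asarray(w.sum(axis=1)).ravel()
        isolated = deg == 0
        if isolated.any():
            logger.warning("%d isolated nodes left with zero weight rows", isolated.sum())
        scale = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, deg))
        w = sp.diags(scale) @ w
    return SpatialWeights(ids=graph.ids, matrix=w.tocsr(), style=style)


def morans_i(values, weights: SpatialWeights) -> float:
    """Moran's I statistic.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    """
    x = np.asarray(values, dtype=float)
    if x.shape != (weights.n,):
        raise ValueError("values length must match weight matrix order")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0.0:
        raise UndefinedStatisticError("Moran's I undefined for constant values")
    w = weights.matrix
    s0 = w.sum()
    return float(len(x) / s0 * (z @ (w @ z)) / ss)


def _moments(weights: SpatialWeights, x: np.ndarray, null: str):
    """Cliff-Ord closed-form E[I] and Var[I] under the chosen null."""
    w = weights.matrix
    n = weights.n
    s0 = w.sum()
    wt = w.T.tocsr()
    s1 = 0.5 * ((w + wt).power(2)).sum()
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = ((row + col) ** 2).sum()
    e = -1.0 / (n - 1)
    if null == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e * e
    elif null == "randomization":
        z = x - x.mean()
        b2 = n * (z ** 4).sum() / (z ** 2).sum() ** 2
        var = (
            n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
            - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e * e
    else:
        raise ValueError(f"unknown null {null!r}")
    return e, float(var)


def morans_test(values, weights: SpatialWeights, null: str = "randomization",
                alternative: str = "greater") -> MoranResult:
    """Moran test with Gaussian approximation of (I - E[I]) / sqrt(Var[I])."""
    x = np.asarray(values, dtype=float)
    if weights.n < 4:
        raise ValueError("Moran test requires n >= 4")
    if alternative not in ("greater", "two-sided", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    i_stat = morans_i(x, weights)
    e, var = _moments(weights, x, null)
    z = (i_stat - e) / np.sqrt(var)
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2 * norm.sf(abs(z)))
    return MoranResult(I=i_stat, expected=e, variance=var, z=float(z),
                       p_value=p, null=null, alternative=alternative)


def graph_to_edge_csv(graph: NeighborGraph, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(graph.ids[i], graph.ids[j]) for i, j in graph.edges],
        columns=["from_id", "to_id"],
    ).to_csv(path, index=False)
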