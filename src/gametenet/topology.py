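"""Topological statistics: degree, centralities, path lengths, power-law fit.

These are the metrics used to call essential proteins in protein-interaction
networks.  Betweenness centrality (BC) is normalized to [0, 1] by
``(n-1)(n-2)/2``; closeness centrality (CC) is the reciprocal of a node's
mean shortest-path distance to the nodes reachable from it (isolated nodes
report 0).  Both conventions match the network-analysis tooling commonly
used on such networks, and keep printed values comparable with published
hub/bottleneck tables.  Shortest paths are unweighted.

The scale-free check fits ``log10 P(k)`` against ``log10 k`` by ordinary
least squares, where ``P(k)`` is the fraction of positive-degree nodes of
degree ``k``; the slope is the degree exponent and the coefficient of
determination measures how linear the log-log decay is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import Network, ProteinRecord, ValidationError, annotation_index

__all__ = [
    "PowerLawFit",
    "PathStats",
    "degrees",
    "betweenness",
    "closeness",
    "path_stats",
    "fit_power_law",
    "centrality_table",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares log-log fit of a degree distribution.

    ``exponent`` is the slope (negative for scale-free decay), ``intercept``
    the log10 intercept, ``r_squared`` the coefficient of determination of
    the regression, ``n_points`` the number of distinct degrees fitted.
    """

    exponent: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PathStats:
    """Shortest-path histogram over connected unordered node pairs.

    ``characteristic_path_length`` is the count-weighted mean path length;
    it is ``None`` (explicitly undefined) when the network has no connected
    pair at all.  Unreachable pairs are excluded rather than given a penalty
    distance, so the statistic stays finite on disconnected networks.
    """

    histogram: dict[int, int]
    characteristic_path_length: float | None

    @property
    def n_pairs(self) -> int:
        return sum(self.histogram.values())


def degrees(net: Network) -> dict[str, int]:
    """Number of incident edges per node; isolated nodes report 0."""
    return {n: d for n, d in net.degree()}


def betweenness(net: Network) -> dict[str, float]:
    """Normalized betweenness centrality.

    BC(v) is the sum over unordered pairs ``s != t != v`` of the fraction of
    shortest s-t paths passing through v, divided by ``(n-1)(n-2)/2``.
    Unreachable pairs contribute 0.  Networks with fewer than 3 nodes have
    no interior pairs, so every value is 0.
    """
    n = net.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in net.nodes}
    return nx.betweenness_centrality(net, normalized=True)


def closeness(net: Network) -> dict[str, float]:
    """Component-restricted closeness centrality.

    CC(v) = 1 / mean distance from v to the nodes reachable from v;
    isolated nodes report 0.  Values lie in [0, 1].
    """
    out: dict[str, float] = {}
    for v in net.nodes:
        dist = nx.single_source_shortest_path_length(net, v)
        total = sum(dist.values())
        reachable = len(dist) - 1
        out[v] = reachable / total if total > 0 else 0.0
    return out


def path_stats(net: Network) -> PathStats:
    """Histogram of shortest-path lengths and the characteristic path length."""
    hist: dict[int, int] = {}
    for _, dist in nx.all_pairs_shortest_path_length(net):
        for d in dist.values():
            if d >= 1:
                hist[d] = hist.get(d, 0) + 1
    hist = {d: c // 2 for d, c in sorted(hist.items())}  # unordered pairs
    total = sum(hist.values())
    if total == 0:
        return PathStats(histogram={}, characteristic_path_length=None)
    cpl = sum(d * c for d, c in hist.items()) / total
    return PathStats(histogram=hist, characteristic_path_length=cpl)


def fit_power_law(deg: Mapping[str, int]) -> PowerLawFit:
    """Ordinary least-squares log-log fit of the degree distribution.

    ``P(k)`` is computed as the fraction of positive-degree nodes having
    degree ``k`` (one point per observed degree, no binning; degree-0 nodes
    are excluded because ``log 0`` is undefined).  The regression is
    ``log10 P(k) = intercept + exponent * log10 k``.

    Raises
    ------
    ValidationError
        If fewer than two distinct positive degrees are observed.
    """
    positive = [d for d in deg.values() if d > 0]
    ks, counts = np.unique(positive, return_counts=True)
    if len(ks) < 2:
        raise ValidationError(
            "power-law fit needs at least 2 distinct positive degrees, "
            f"got {len(ks)}"
        )
    p = counts / counts.sum()
    x = np.log10(ks.astype(float))
    y = np.log10(p)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # flat distribution: the constant model is exact
        r2 = 1.0 if math.isclose(ss_res, 0.0, abs_tol=1e-24) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerLawFit(
        exponent=float(slope),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=int(len(ks)),
    )


def centrality_table(
    net: Network, annotations: Sequence[ProteinRecord] | None = None
) -> pd.DataFrame:
    """Per-node degree, betweenness and closeness as a DataFrame.

    Columns: ``accession``, ``gene_symbol``, ``degree``, ``betweenness``,
    ``closeness``; one row per network node, sorted by degree descending
    then accession.  When annotations are given, gene symbols are joined in;
    otherwise the accession doubles as the symbol.
    """
    deg = degrees(net)
    bc = betweenness(net)
    cc = closeness(net)
    idx = annotation_index(annotations) if annotations is not None else {}
    rows = [
        {
            "accession": v,
            "gene_symbol": idx[v].gene_symbol if v in idx else v,
            "degree": deg[v],
            "betweenness": bc[v],
            "closeness": cc[v],
        }
        for v in net.nodes
    ]
    df = pd.DataFrame(
        rows, columns=["accession", "gene_symbol", "degree", "betweenness", "closeness"]
    )
    return df.sort_values(
        ["degree", "betweenness", "accession"], ascending=[False, False, True]
    ).reset_index(drop=True)
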