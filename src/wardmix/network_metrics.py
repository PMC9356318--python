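"""Network-level measures and their association with hospital size.

Degree, density, diameter, betweenness, closeness and modularity summarize
a monthly (or otherwise windowed) contact network.  Path-based measures
(diameter, betweenness, closeness) are computed on the largest connected
component of the simple unweighted graph, since windowed networks may be
disconnected.  Modularity uses greedy modularity maximization on the
weighted graph; the community-detection algorithm is recorded in the
result so runs remain comparable.

The size association is fit as a Gaussian-family identity-link GLM
(ordinary least squares), with the slope rescaled per 100 patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import statsmodels.api as sm

from wardmix.contact_network import ContactNetwork

MODULARITY_METHOD = "greedy_modularity_weighted"


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    mean_degree: float
    sd_degree: float
    density: float
    diameter: int  # of the largest connected component
    mean_betweenness: float  # unnormalized, largest component
    mean_closeness: float  # in [0, 1], largest component
    modularity: float | None  # None (flagged) when the graph has no edges
    modularity_method: str = MODULARITY_METHOD

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegressionResult:
    """OLS slope per 100 patients with its 95% CI and two-sided p."""

    slope_per_100: float
    ci95: tuple[float, float]
    p_value: float
    n: int

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.slope_per_100 <= hi or math.isnan(self.p_value)):
            raise ValueError("CI does not bracket the slope")


def compute_metrics(network: ContactNetwork | nx.Graph) -> NetworkMetrics:
    """Compute all network-level measures for one contact network.

    Degree-based measures use the simple unweighted graph; modularity uses
    edge weights.  A single-node graph has density and diameter 0; a graph
    with no edges reports modularity as None.
    """
    g = network.graph if isinstance(network, ContactNetwork) else network
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("network must have at least one node")
    m = g.number_of_edges()

    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_degree = 2.0 * m / n
    sd_degree = float(degrees.std(ddof=0)) if n > 0 else 0.0
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0

    if m == 0:
        diameter = 0
        mean_betweenness = 0.0
        mean_closeness = 0.0
        modularity = None
    else:
        lcc_nodes = max(nx.connected_components(g), key=len)
        lcc = g.subgraph(lcc_nodes)
        diameter = nx.diameter(lcc)
        bc = nx.betweenness_centrality(lcc, normalized=False)
        mean_betweenness = float(np.mean(list(bc.values())))
        cc = nx.closeness_centrality(lcc)
        mean_closeness = float(np.mean(list(cc.values())))
        communities = nx.community.greedy_modularity_communities(g, weight="weight")
        modularity = float(
            nx.community.modularity(g, communities, weight="weight")
        )

    return NetworkMetrics(
        n_nodes=n,
        n_edges=m,
        mean_degree=mean_degree,
        sd_degree=sd_degree,
        density=density,
        diameter=diameter,
        mean_betweenness=mean_betweenness,
        mean_closeness=mean_closeness,
        modularity=modularity,
    )


def metric_size_regression(
    records: Iterable[tuple[float, float]] | Sequence[tuple[float, float]],
) -> RegressionResult:
    """Regress a network metric on hospital size (unique patients).

    Fits metric ~ intercept + size by OLS and reports the slope rescaled
    per 100 patients, its t-based 95% CI and two-sided p-value.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 (size, metric) records")
    sizes = np.array([r[0] for r in records], dtype=float)
    values = np.array([r[1] for r in records], dtype=float)
    if np.allclose(sizes, sizes[0]):
        raise ValueError("degenerate design: all hospital sizes equal")

    x = sm.add_constant(sizes)
    fit = sm.OLS(values, x).fit()
    slope = fit.params[1] * 100.0
    lo, hi = fit.conf_int(alpha=0.05)[1] * 100.0
    p = float(fit.pvalues[1])
    scale = 1.0 + float(np.mean(values**2))
    if math.isnan(p) or fit.ssr <= 1e-16 * len(records) * scale:
        # zero residual variance up to floating fuzz: noise-free line
        # (p -> 0) or constant response (slope -> 0, p -> 1)
        degenerate_zero = abs(slope) <= 1e-9 * math.sqrt(scale)
        p = 1.0 if degenerate_zero else 0.0
        if degenerate_zero:
            slope = 0.0
        lo = hi = slope
    return RegressionResult(
        slope_per_100=float(slope), ci95=(float(lo), float(hi)), p_value=p,
        n=len(records),
    )
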