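"""Construction and bookkeeping of the N-1 signed dynamic networks DN-t.

Network DN-t is built from time points ``T_t`` and ``T_t+1``: for every
canonical feature pair whose ratio's effective range up- or downshifts with
``|NOR| >= tau``, an edge joins the two features — red (+) for upshifts,
green (-) for downshifts.  Nested/identical range changes never create
edges.  Every retained feature is a node of every network (isolates
included) so degree tables are comparable across networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import TimeSeriesDataset
from .errors import AtsdnetError
from .ratio_dynamics import GAMMA, TAU, pairwise_nor, sample_probability


@dataclass
class DynamicNetwork:
    """Signed NOR-weighted graph over features between T_t and T_t+1."""

    t: int
    graph: nx.Graph
    tau: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, int, float]]:
        """Canonical edge list: (i, j, sign, nor) with i < j in node order."""
        order = {f: k for k, f in enumerate(self.graph.nodes)}
        out = []
        for a, b, d in self.graph.edges(data=True):
            i, j = (a, b) if order[a] < order[b] else (b, a)
            out.append((i, j, d["sign"], d["nor"]))
        out.sort(key=lambda e: (order[e[0]], order[e[1]]))
        return out

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_i": i, "node_j": j, "t": self.t,
             "sign": "red" if s > 0 else "green", "nor": v}
            for i, j, s, v in self.edges()
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "t", "sign", "nor"])

    def write_edges(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(
    ds: TimeSeriesDataset,
    features: list[str] | None = None,
    t: int = 1,
    tau: float = TAU,
    gamma: float = GAMMA,
    group: str | None = "model",
) -> DynamicNetwork:
    """Build DN-t from the samples at ``T_t`` and ``T_t+1``.

    The disease-course networks are built from the model group by default;
    pass ``group=None`` to pool all samples.  The sample probability of
    each time point is its share of the two-point window, so equal sample
    sets give ``p = 0.5`` on both sides.
    """
    n = ds.n_timepoints
    if not 1 <= t < n:
        raise IndexError(f"network index t={t} must satisfy 1 <= t < N={n}")
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    features = list(features) if features is not None else ds.feature_names
    idx = [ds.feature_names.index(f) for f in features]

    Xa = ds.values_at(t, group)[:, idx]
    Xb = ds.values_at(t + 1, group)[:, idx]
    p_a = sample_probability(Xa.shape[0], Xb.shape[0])
    i_idx, j_idx, values = pairwise_nor(Xa, Xb, p_a, gamma=gamma)

    g = nx.Graph(t=t, tau=tau)
    g.add_nodes_from(features)
    hits = np.flatnonzero(~np.isnan(values) & (np.abs(values) >= tau))
    for k in hits:
        v = float(values[k])
        g.add_edge(features[i_idx[k]], features[j_idx[k]], sign=1 if v > 0 else -1, nor=v)
    return DynamicNetwork(t=t, graph=g, tau=tau)


def network_series(
    ds: TimeSeriesDataset,
    features: list[str] | None = None,
    tau: float = TAU,
    gamma: float = GAMMA,
    group: str | None = "model",
) -> list[DynamicNetwork]:
    """All N-1 networks DN-1 .. DN-(N-1) along the N time points."""
    n = ds.n_timepoints
    if n < 2:
        raise AtsdnetError(f"need >= 2 time points to build networks, got N={n}")
    return [
        build_network(ds, features=features, t=t, tau=tau, gamma=gamma, group=group)
        for t in range(1, n)
    ]


def degree_stats(networks: list[DynamicNetwork]) -> pd.DataFrame:
    """Per-network node degrees plus the accumulated degree over all networks.

    Rows are features (node order of the first network), columns are the
    network indices ``t`` plus ``"accumulated"``.
    """
    if not networks:
        raise AtsdnetError("need at least one network")
    nodes = list(networks[0].graph.nodes)
    table = pd.DataFrame(index=nodes)
    for net in networks:
        deg = dict(net.graph.degree())
        table[net.t] = [deg.get(f, 0) for f in nodes]
    table["accumulated"] = table.sum(axis=1)
    return table
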