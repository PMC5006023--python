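"""Early-warning subset extraction from the dynamic networks.

Two independent read-outs of the N-1 signed networks:

* **Dynamic concentration** — ratios whose edge keeps the same colour in
  every network of the pre-onset window ``DN-i`` (``s - N_e <= i < s - 1``),
  i.e. a persistent monotone disturbance ahead of the onset point ``T_s``.
* **Topological structure** — the network with the most edges marks the key
  transition of the time course; the ratios incident to its top-k
  highest-degree nodes are extracted.

The two subsets can then be combined by union or intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from .data_model import StageDesign
from .dynamic_network import DynamicNetwork, degree_stats
from .errors import AtsdnetError, DesignError

Pair = tuple[str, str]


@dataclass(frozen=True)
class FeatureSubset:
    """A set of canonical feature-ratio pairs with provenance."""

    pairs: frozenset[Pair]
    provenance: Literal["concentration", "topology", "intersection", "union"]
    evidence: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[Pair]:
        return sorted(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"node_i": i, "node_j": j, "provenance": self.provenance}
             for i, j in self.sorted_pairs()]
        )


def _canonical_edge(net: DynamicNetwork, a: str, b: str) -> Pair:
    order = {f: k for k, f in enumerate(net.graph.nodes)}
    return (a, b) if order[a] < order[b] else (b, a)


def dynamic_concentration(
    networks: list[DynamicNetwork], design: StageDesign
) -> FeatureSubset:
    """Ratios whose edge keeps the same sign in every window network.

    The window is ``design.concentration_window()``; with the onset at
    ``T_s = 7`` and ``N_e = 3`` it is ``{DN-4, DN-5}``.  An edge absent
    from any window network, or flipping colour, is excluded.
    """
    window = design.concentration_window()
    if not window:
        raise DesignError("concentration window is empty")
    by_t = {net.t: net for net in networks}
    missing = [t for t in window if t not in by_t]
    if missing:
        raise DesignError(f"window networks DN-{missing} not supplied")

    signs: dict[Pair, int] = {}
    first = by_t[window[0]]
    for i, j, s, _ in first.edges():
        signs[(i, j)] = s
    for t in window[1:]:
        net = by_t[t]
        current = {(i, j): s for i, j, s, _ in net.edges()}
        signs = {
            pair: s for pair, s in signs.items()
            if current.get(pair) == s
        }
    return FeatureSubset(
        pairs=frozenset(signs),
        provenance="concentration",
        evidence={"window": window, "signs": signs},
    )


def topological_structure(
    networks: list[DynamicNetwork], k: int = 1
) -> FeatureSubset:
    """Ratios incident to the top-k degree nodes of the max-edge network.

    The network with the most edges is the key transition (earliest t wins
    a tie, with a warning).  Its nodes are ranked by degree descending;
    degree ties break by (1) larger accumulated degree over all networks,
    (2) canonical feature order.  All edges of the top-k nodes in that
    network form the subset.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = [net.n_edges for net in networks]
    if max(counts, default=0) == 0:
        raise AtsdnetError("all networks are empty; no key transition exists")
    best = max(counts)
    ties = [net.t for net, c in zip(networks, counts) if c == best]
    if len(ties) > 1:
        warnings.warn(
            f"networks DN-{ties} tie at {best} edges; using the earliest", stacklevel=2
        )
    key = next(net for net in networks if net.n_edges == best)

    acc = degree_stats(networks)["accumulated"]
    order = {f: i for i, f in enumerate(key.graph.nodes)}
    deg = dict(key.graph.degree())
    ranked = sorted(
        key.graph.nodes,
        key=lambda f: (-deg.get(f, 0), -int(acc[f]), order[f]),
    )
    top = ranked[:k]

    pairs = {
        _canonical_edge(key, a, b)
        for node in top
        for a, b in key.graph.edges(node)
    }
    return FeatureSubset(
        pairs=frozenset(pairs),
        provenance="topology",
        evidence={
            "network_t": key.t,
            "edge_count": best,
            "top_nodes": top,
            "degrees": {f: deg.get(f, 0) for f in top},
        },
    )


def combine(
    s1: FeatureSubset,
    s2: FeatureSubset,
    mode: Literal["intersection", "union"] = "intersection",
) -> FeatureSubset:
    """Set-combine two feature subsets; empty intersections warn, not fail."""
    if mode == "intersection":
        pairs = s1.pairs & s2.pairs
        if not pairs:
            warnings.warn("intersection of feature subsets is empty", stacklevel=2)
    elif mode == "union":
        pairs = s1.pairs | s2.pairs
    else:
        raise ValueError(f"mode must be 'intersection' or 'union', got {mode!r}")
    return FeatureSubset(
        pairs=frozenset(pairs),
        provenance=mode,
        evidence={"parents": (s1.provenance, s2.provenance)},
    )
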