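"""Probability and information estimators behind the MI and NSI indices.

The scoring model treats "pair (x, y) is connected" as an event L¹_xy and
ranks candidate links by the negative conditional self-information of that
event given observed structural features.  Everything needed to evaluate a
score is estimated once per training graph and cached in :class:`InfoModel`:

* a degree-based **prior** connection probability
      p(L¹_xy) = 1 − C(M − k_x, k_y) / C(M, k_y),
  the chance that at least one of k_y link endpoints drawn without
  replacement from the M training links lands on one of x's k_x endpoints;
* a per-node **conditional** — the Laplace-smoothed clustering statistic
  c_z = (N_Δz + 1) / (N_Δz + N_Λz + 2), where N_Δz / N_Λz count the
  connected / disconnected node pairs having z as a common neighbor;
* a per-edge conditional built the same way from the pairs an edge bridges
  between its endpoints' neighborhoods.

Information is measured in bits (base-2 logarithms); rankings are invariant
to the base, which only rescales every term by one positive constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Hashable, Iterable, Sequence, Tuple

from .graph import Graph, Pair, common_neighbors, neighbors, node_pair

Node = Hashable


def prior_connect_probability_raw(M: int, k_x: int, k_y: int) -> float:
    """Unclamped prior p(L¹_xy) = 1 − C(M − k_x, k_y) / C(M, k_y).

    Symmetric in (k_x, k_y) and non-decreasing in each degree; 0 when either
    degree is 0 and 1 when k_y > M − k_x (pigeonhole).
    """
    if k_x < 0 or k_y < 0:
        raise ValueError(f"negative degree (k_x={k_x}, k_y={k_y})")
    if k_x > M or k_y > M:
        raise ValueError(f"degree exceeds link count M={M} (k_x={k_x}, k_y={k_y})")
    if M == 0:
        return 0.0
    denom = math.comb(M, k_y)
    return 1.0 - math.comb(M - k_x, k_y) / denom


def self_information(p: float) -> float:
    """−log₂ p, the surprise of an event of probability p, in bits."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p}")
    return -math.log2(p)


@dataclass(frozen=True)
class NodeConditional:
    """Clustering statistic of one node z acting as a common neighbor.

    ``n_connected`` (N_Δz) and ``n_disconnected`` (N_Λz) count the connected
    and disconnected pairs among z's neighbors; ``c`` is the Laplace-smoothed
    fraction connected, strictly inside (0, 1).
    """

    n_connected: int
    n_disconnected: int
    c: float


@dataclass(frozen=True)
class LinkConditional:
    """Bridging statistic of one training edge {u, v}.

    The edge bridges the node pairs {(m, n) : m ∈ Γ(u)\\{v}, n ∈ Γ(v)\\{u},
    m ≠ n}; ``c`` is the smoothed fraction of bridged pairs that are
    themselves connected, and ``mean_prior_info`` the average prior
    self-information over the bridged pairs (0 when none exist).
    """

    n_connected: int
    n_disconnected: int
    c: float
    mean_prior_info: float


def fit_node_conditionals(g: Graph) -> Dict[Node, NodeConditional]:
    """Clustering statistics for every node of degree ≥ 2.

    Nodes of degree < 2 cannot be common neighbors and receive no entry.
    N_Δz + N_Λz = C(k_z, 2) by construction.
    """
    out: Dict[Node, NodeConditional] = {}
    for z in g.nodes:
        k = g.degree(z)
        if k < 2:
            continue
        nbrs = neighbors(g, z)
        n_conn = sum(1 for m, n in combinations(nbrs, 2) if g.has_edge(m, n))
        n_pairs = k * (k - 1) // 2
        n_dis = n_pairs - n_conn
        out[z] = NodeConditional(n_conn, n_dis, (n_conn + 1) / (n_pairs + 2))
    return out


def _bridged_pairs(g: Graph, u: Node, v: Node) -> set:
    gx = neighbors(g, u) - {v}
    gy = neighbors(g, v) - {u}
    return {node_pair(m, n) for m in gx for n in gy if m != n}


def fit_link_conditionals(
    g: Graph, prior_info: "callable" = None
) -> Dict[Pair, LinkConditional]:
    """Bridging statistics for every training edge.

    ``prior_info(pair) -> bits`` supplies the prior self-information used for
    the bridged-pair average; when omitted the averages are set to 0 (the
    counts and c are independent of it).
    """
    out: Dict[Pair, LinkConditional] = {}
    for edge in g.edges:
        u, v = edge
        bridged = _bridged_pairs(g, u, v)
        n_conn = sum(1 for m, n in bridged if g.has_edge(m, n))
        n_dis = len(bridged) - n_conn
        c = (n_conn + 1) / (len(bridged) + 2)
        if bridged and prior_info is not None:
            mean_info = sum(prior_info(p) for p in bridged) / len(bridged)
        else:
            mean_info = 0.0
        out[edge] = LinkConditional(n_conn, n_dis, c, mean_info)
    return out


@dataclass(frozen=True)
class InfoModel:
    """Per-graph cache of everything the information indices evaluate.

    Fit once on a training graph; scoring then only combines cached terms
    with the structural queries (common neighbors, cross links).
    """

    graph: Graph
    M: int
    degree: Dict[Node, int]
    node_stats: Dict[Node, NodeConditional]
    link_stats: Dict[Pair, LinkConditional]
    p_floor: float
    _node_mean_prior: Dict[Node, float] = field(default_factory=dict, repr=False)

    @classmethod
    def fit(cls, g: Graph, p_floor: float | None = None) -> "InfoModel":
        """Estimate all priors and conditionals from a training graph.

        ``p_floor`` clamps prior probabilities into [p_floor, 1 − p_floor] so
        every self-information stays finite even for degree-0 nodes (which
        appear when probe removal isolates a node); the default
        1 / (2(M + 1)) preserves the ordering "smaller degree ⇒ larger prior
        information".
        """
        M = g.number_of_edges()
        if p_floor is None:
            p_floor = 1.0 / (2.0 * (M + 1))
        if not 0.0 < p_floor < 0.5:
            raise ValueError(f"p_floor must lie in (0, 0.5), got {p_floor}")
        degree = {x: g.degree(x) for x in g.nodes}
        model = cls(g, M, degree, {}, {}, p_floor)
        node_stats = fit_node_conditionals(g)
        link_stats = fit_link_conditionals(g, prior_info=model.prior_information)
        node_mean = {
            z: (
                sum(
                    model.prior_information(node_pair(m, n))
                    for m, n in combinations(neighbors(g, z), 2)
                )
                / (degree[z] * (degree[z] - 1) // 2)
            )
            for z in node_stats
        }
        object.__setattr__(model, "node_stats", node_stats)
        object.__setattr__(model, "link_stats", link_stats)
        object.__setattr__(model, "_node_mean_prior", node_mean)
        return model

    # -- priors ----------------------------------------------------------
    def prior_probability(self, pair: Pair) -> float:
        """Clamped prior connection probability of a candidate pair."""
        x, y = pair
        p = prior_connect_probability_raw(self.M, self.degree[x], self.degree[y])
        return min(max(p, self.p_floor), 1.0 - self.p_floor)

    def prior_information(self, pair: Pair) -> float:
        """I(L¹_xy) = −log₂ p(L¹_xy), in bits."""
        return self_information(self.prior_probability(pair))

    # -- node (common-neighbor) feature ---------------------------------
    def node_conditional_information(self, z: Node) -> float:
        """−log₂ c_z: residual surprise of a connection given common neighbor z."""
        try:
            stats = self.node_stats[z]
        except KeyError:
            raise ValueError(
                f"node {z!r} has degree < 2 and no conditional estimate"
            ) from None
        return -math.log2(stats.c)

    def node_information_gain(self, z: Node) -> float:
        """Evidence contributed by common neighbor z, in bits.

        Mean prior self-information over z's neighbor pairs minus the
        conditional information −log₂ c_z.  Negative for low-clustering
        neighbors — sharing such a neighbor is evidence *against* a link.
        """
        return self._node_mean_prior[z] - self.node_conditional_information(z)

    # -- link (cross-link) feature --------------------------------------
    def link_information_gain(self, edge: Pair) -> float:
        """Evidence contributed by one cross link, in bits (0 if it bridges nothing)."""
        stats = self.link_stats[edge]
        if stats.n_connected + stats.n_disconnected == 0:
            return 0.0
        return stats.mean_prior_info - (-math.log2(stats.c))

    # -- debugging -------------------------------------------------------
    def to_report(self) -> dict:
        """JSON-serializable dump of all cached counts and conditionals."""
        return {
            "M": self.M,
            "p_floor": self.p_floor,
            "nodes": {
                str(z): {
                    "degree": self.degree[z],
                    "n_connected": s.n_connected,
                    "n_disconnected": s.n_disconnected,
                    "c": s.c,
                }
                for z, s in self.node_stats.items()
            },
            "links": {
                f"{u}|{v}": {
                    "n_connected": s.n_connected,
                    "n_disconnected": s.n_disconnected,
                    "c": s.c,
                    "mean_prior_info": s.mean_prior_info,
                }
                for (u, v), s in self.link_stats.items()
            },
        }


def combine(
    prior_info: float,
    gains_per_feature: Sequence[Tuple[float, Iterable[float]]],
) -> float:
    """Weighted multi-feature likelihood score.

    With per-feature conditional information
    I(L¹|Ω_i) = prior_info − Σ_{ω∈Ω_i} gain(ω) (independence expansion),
    returns  s = −Σ_i λ_i · I(L¹|Ω_i).  Higher means more likely.  Linear in
    each λ_i; scaling all weights rescales all scores, leaving every ranking
    unchanged.
    """
    weights = [w for w, _ in gains_per_feature]
    if any(w < 0 for w in weights):
        raise ValueError("feature weights must be nonnegative")
    if not any(w > 0 for w in weights):
        raise ValueError("at least one feature weight must be positive")
    score = 0.0
    for w, gains in gains_per_feature:
        score -= w * (prior_info - sum(gains))
    return score
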