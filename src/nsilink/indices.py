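"""The seven similarity indices under one contract: higher score = more likely.

Structural baselines (CN, AA, RA, PA, LP) read the training graph directly;
the information indices (MI, NSI) read a fitted :class:`~nsilink.info.InfoModel`.
``score_all`` evaluates any of them over all candidate pairs and returns a
:class:`ScoreTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, TextIO

from .graph import Graph, Pair, candidate_pairs, common_neighbors, cross_links, walk_counts
from .info import InfoModel, combine

#: default weight ratio λ = λ₂/λ₁ between cross-link and common-neighbor
#: information in NSI; 0.1 gives reasonable accuracy across network types.
DEFAULT_LAMBDA = 0.1
#: default weight of length-3 paths in the local-path index.
DEFAULT_EPSILON = 0.001

INDEX_NAMES = ("CN", "AA", "RA", "PA", "LP", "MI", "NSI")


def score_cn(g: Graph, pair: Pair) -> float:
    """Common Neighbors: |Γ(x) ∩ Γ(y)|."""
    return float(len(common_neighbors(g, pair)))


def score_aa(g: Graph, pair: Pair) -> float:
    """Adamic–Adar: Σ_z 1/ln k_z over common neighbors (natural log)."""
    return sum(1.0 / math.log(g.degree(z)) for z in common_neighbors(g, pair))


def score_ra(g: Graph, pair: Pair) -> float:
    """Resource Allocation: Σ_z 1/k_z over common neighbors."""
    return sum(1.0 / g.degree(z) for z in common_neighbors(g, pair))


def score_pa(g: Graph, pair: Pair) -> float:
    """Preferential Attachment: k_x · k_y."""
    x, y = pair
    return float(g.degree(x) * g.degree(y))


def score_lp(g: Graph, pair: Pair, epsilon: float = DEFAULT_EPSILON) -> float:
    """Local Path: (A²)_xy + ε·(A³)_xy.  Reduces to CN at ε = 0."""
    if epsilon < 0:
        raise ValueError(f"epsilon must be nonnegative, got {epsilon}")
    s = float(walk_counts(g, pair, 2))
    if epsilon:
        s += epsilon * walk_counts(g, pair, 3)
    return s


def score_mi(model: InfoModel, pair: Pair) -> float:
    """Mutual-Information index: common-neighbor feature only.

    s = −I(L¹_xy) + Σ_{z ∈ CN} gain(z), i.e. the single-feature case of the
    weighted combination rule at λ = 1.
    """
    gains = [model.node_information_gain(z) for z in common_neighbors(model.graph, pair)]
    return combine(model.prior_information(pair), [(1.0, gains)])


def score_nsi(model: InfoModel, pair: Pair, lam: float = DEFAULT_LAMBDA) -> float:
    """Neighbor Set Information index.

    Combines the common-neighbor feature (weight 1) with the cross-link
    feature (weight λ):

        s = −(1 + λ)·I(L¹_xy) + Σ_{z ∈ CN} gain(z) + λ·Σ_{l ∈ cross} gain(l)

    λ is the ratio λ₂/λ₁ of the two feature weights; λ = 0 discards the
    cross-link feature (and then ranks identically to MI up to the shared
    prior term).
    """
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    g = model.graph
    node_gains = [model.node_information_gain(z) for z in common_neighbors(g, pair)]
    link_gains = [model.link_information_gain(e) for e in cross_links(g, pair)]
    return combine(
        model.prior_information(pair), [(1.0, node_gains), (lam, link_gains)]
    )


@dataclass
class ScoreTable:
    """Scores for every candidate pair of one training graph under one index."""

    entries: Dict[Pair, float]
    index_name: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, pair: Pair) -> float:
        return self.entries[pair]

    def ranked(self) -> list:
        """(pair, score) sorted by descending score, then lexicographic pair."""
        return sorted(
            self.entries.items(),
            key=lambda kv: (-kv[1], str(kv[0][0]), str(kv[0][1])),
        )

    def write_csv(self, sink: TextIO) -> None:
        """Columns node_a, node_b, score; descending score, repr floats."""
        sink.write("node_a,node_b,score\n")
        for (a, b), s in self.ranked():
            sink.write(f"{a},{b},{s!r}\n")


def score_all(
    g: Graph,
    index: str,
    params: Mapping[str, float] | None = None,
    pairs: Iterable[Pair] | None = None,
    model: InfoModel | None = None,
) -> ScoreTable:
    """Score all candidate pairs (or a supplied pair list) under one index.

    ``params`` may carry ``lam`` (NSI) and ``epsilon`` (LP).  A pre-fitted
    ``model`` is reused for MI/NSI; otherwise one is fitted from ``g``.
    Deterministic given the graph and parameters.
    """
    params = dict(params or {})
    name = index.upper()
    if name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}; choose from {INDEX_NAMES}")
    if pairs is None:
        pairs = candidate_pairs(g)
    if name in ("MI", "NSI") and model is None:
        model = InfoModel.fit(g)

    if name == "CN":
        fn = lambda p: score_cn(g, p)
    elif name == "AA":
        fn = lambda p: score_aa(g, p)
    elif name == "RA":
        fn = lambda p: score_ra(g, p)
    elif name == "PA":
        fn = lambda p: score_pa(g, p)
    elif name == "LP":
        eps = params.setdefault("epsilon", DEFAULT_EPSILON)
        fn = lambda p: score_lp(g, p, eps)
    elif name == "MI":
        fn = lambda p: score_mi(model, p)
    else:  # NSI
        lam = params.setdefault("lam", DEFAULT_LAMBDA)
        fn = lambda p: score_nsi(model, p, lam)

    entries = {p: fn(p) for p in pairs}
    return ScoreTable(entries, name, params)
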