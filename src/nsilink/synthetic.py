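"""Seeded graph generators, a tie-breaking fixture, and brute-force oracles.

Everything the test suite needs is generated here, so the package is fully
testable without downloading any network data.  ``reference_scores``
recomputes every index with naive exhaustive loops, structurally independent
of the main code paths, and serves as the oracle the fast implementations
are checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import networkx as nx
import numpy as np

from .graph import Graph, Pair, node_pair

MODELS = ("erdos_renyi", "barabasi_albert", "watts_strogatz")


@dataclass(frozen=True)
class GeneratorSpec:
    """A named random-graph model plus its parameters and seed.

    erdos_renyi: params (n, p); barabasi_albert: (n, m);
    watts_strogatz: (n, k, beta).  The seed fixes the output exactly.
    """

    model: str
    params: dict
    seed: int = 0


def generate(spec: GeneratorSpec) -> Graph:
    """Generate a simple undirected graph from a spec, deterministically per seed."""
    p = dict(spec.params)
    n = p.get("n", 0)
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got n={n}")
    if spec.model == "erdos_renyi":
        prob = p["p"]
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {prob}")
        g = nx.gnp_random_graph(n, prob, seed=spec.seed)
    elif spec.model == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, p["m"], seed=spec.seed)
    elif spec.model == "watts_strogatz":
        beta = p["beta"]
        if not 0.0 <= beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {beta}")
        g = nx.watts_strogatz_graph(n, p["k"], beta, seed=spec.seed)
    else:
        raise ValueError(f"unknown model {spec.model!r}; choose from {MODELS}")
    return Graph(nodes=g.nodes, edges=g.edges)


def erdos_renyi(n: int, p: float, seed: int) -> Graph:
    return generate(GeneratorSpec("erdos_renyi", {"n": n, "p": p}, seed))


def barabasi_albert(n: int, m: int, seed: int) -> Graph:
    return generate(GeneratorSpec("barabasi_albert", {"n": n, "m": m}, seed))


def watts_strogatz(n: int, k: int, beta: float, seed: int) -> Graph:
    return generate(GeneratorSpec("watts_strogatz", {"n": n, "k": k, "beta": beta}, seed))


def lp_tie_fixture() -> Tuple[Graph, Pair, Pair]:
    """A graph on which LP cannot separate two candidate pairs but NSI can.

    Returns (graph, pair_a, pair_b).  Both pairs have exactly two common
    neighbors and exactly one length-3 path, so LP assigns them equal scores
    for every ε.  The two halves of the graph are degree-for-degree
    identical; they differ only in that pair_a's common neighbors each sit
    on a triangle (clustering 1/6) while pair_b's have clustering 0.  NSI
    therefore scores pair_a strictly above pair_b for every λ ≥ 0 — shared
    neighbors that cluster are stronger evidence of a link.
    """
    edges = [
        # half A: pair (a1, a2); common neighbors au, av cluster via t-triangles
        ("a1", "au"), ("a1", "av"), ("a2", "au"), ("a2", "av"),
        ("a1", "ap1"), ("ap1", "ap2"), ("ap2", "a2"),      # the length-3 path
        ("au", "at1"), ("au", "at2"), ("at1", "at2"),       # triangle at au
        ("av", "at3"), ("av", "at4"), ("at3", "at4"),       # triangle at av
        # half B: pair (b1, b2); common neighbors bu, bv do not cluster
        ("b1", "bu"), ("b1", "bv"), ("b2", "bu"), ("b2", "bv"),
        ("b1", "bp1"), ("bp1", "bp2"), ("bp2", "b2"),
        ("bu", "bs1"), ("bu", "bs2"),
        ("bv", "bs3"), ("bv", "bs4"),
        # pendants keep the s-nodes' degrees equal to the t-nodes'
        ("bs1", "br1"), ("bs2", "br2"), ("bs3", "br3"), ("bs4", "br4"),
    ]
    return Graph(edges=edges), node_pair("a1", "a2"), node_pair("b1", "b2")


def prior_probability_oracle(M: int, k_x: int, k_y: int, trials: int,
                             seed: int) -> float:
    """Monte-Carlo estimate of the degree-based prior connection probability.

    Each trial draws k_y of M link slots uniformly without replacement and
    checks whether at least one lands among a fixed set of k_x slots; the
    returned fraction estimates p(L¹_xy).  Independent of the closed-form
    combinatorial prior it validates.
    """
    if not (0 <= k_x <= M and 0 <= k_y <= M):
        raise ValueError(f"degrees must lie in [0, M={M}], got ({k_x}, {k_y})")
    if trials < 1:
        raise ValueError(f"trials must be ≥ 1, got {trials}")
    if k_x == 0 or k_y == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    # column argsort of uniforms = one uniform permutation per trial
    perms = np.argsort(rng.random((trials, M)), axis=1)
    chosen = perms[:, :k_y]
    hits = (chosen < k_x).any(axis=1)
    return float(hits.mean())


# ---------------------------------------------------------------------------
# Naive re-implementations used as oracles
# ---------------------------------------------------------------------------

def _naive_adj(g: Graph) -> Dict:
    adj: Dict = {x: set() for x in g.nodes}
    for u, v in g.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _naive_prior_info(M: int, adj: Dict, x, y) -> float:
    kx, ky = len(adj[x]), len(adj[y])
    p = 1.0 - math.comb(M - kx, ky) / math.comb(M, ky)
    floor = 1.0 / (2.0 * (M + 1))
    p = min(max(p, floor), 1.0 - floor)
    return -math.log2(p)


def reference_scores(g: Graph, pair: Pair) -> Dict[str, float]:
    """All seven index scores for one pair via exhaustive loops.

    Intended for graphs of ≤ 50 nodes; everything (common neighbors, paths,
    clustering counts, bridged pairs, priors) is recomputed from the raw
    edge set with nested loops, independently of the main code paths.
    """
    x, y = pair
    adj = _naive_adj(g)
    nodes = sorted(adj, key=str)
    M = g.number_of_edges()

    cn = [z for z in nodes if z in adj[x] and z in adj[y]]
    out: Dict[str, float] = {}
    out["CN"] = float(len(cn))
    out["AA"] = sum(1.0 / math.log(len(adj[z])) for z in cn)
    out["RA"] = sum(1.0 / len(adj[z]) for z in cn)
    out["PA"] = float(len(adj[x]) * len(adj[y]))

    paths2 = sum(1 for z in nodes if z in adj[x] and z in adj[y])
    paths3 = sum(
        1
        for u in nodes
        for v in nodes
        if u in adj[x] and v in adj[u] and y in adj[v]
    )
    out["LP"] = paths2 + 0.001 * paths3
    out["LP_paths2"] = float(paths2)
    out["LP_paths3"] = float(paths3)

    def node_gain(z) -> float:
        nbrs = sorted(adj[z], key=str)
        n_conn = n_dis = 0
        infos = []
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                m, n = nbrs[i], nbrs[j]
                if n in adj[m]:
                    n_conn += 1
                else:
                    n_dis += 1
                infos.append(_naive_prior_info(M, adj, m, n))
        c = (n_conn + 1) / (n_conn + n_dis + 2)
        return sum(infos) / len(infos) - (-math.log2(c))

    prior = _naive_prior_info(M, adj, x, y)
    out["MI"] = -prior + sum(node_gain(z) for z in cn)

    # cross links: edges with one endpoint in each punctured neighborhood
    crosses = []
    for u, v in g.edges:
        a_side = {z for z in adj[x] if z != y}
        b_side = {z for z in adj[y] if z != x}
        if (u in a_side and v in b_side) or (v in a_side and u in b_side):
            crosses.append((u, v))

    def link_gain(u, v) -> float:
        left = [m for m in adj[u] if m != v]
        right = [n for n in adj[v] if n != u]
        pairs = {node_pair(m, n) for m in left for n in right if m != n}
        if not pairs:
            return 0.0
        n_conn = sum(1 for m, n in pairs if n in adj[m])
        c = (n_conn + 1) / (len(pairs) + 2)
        mean_info = sum(_naive_prior_info(M, adj, m, n) for m, n in pairs) / len(pairs)
        return mean_info - (-math.log2(c))

    lam = 0.1
    out["NSI"] = (
        -(1 + lam) * prior
        + sum(node_gain(z) for z in cn)
        + lam * sum(link_gain(u, v) for u, v in crosses)
    )
    return out
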