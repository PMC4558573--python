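"""Train/probe splitting, AUC, Precision@L, and the repeated benchmark runner.

Protocol: the observed links E are partitioned at random into a training set
E^T (shown to the predictor) and a probe set E^P (the "missing" links).  AUC
is the probability that a random probe link outscores a random non-existent
link (a pair in U − E), ties counting one half; Precision@L is the fraction
of probe links among the L top-ranked candidates.  All randomness flows
from explicit integer seeds, so every run is exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .graph import Graph, Pair, node_pair
from .indices import ScoreTable, score_all
from .info import InfoModel

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Raised when a metric is undefined (empty probe or negative class)."""


@dataclass(frozen=True)
class SplitResult:
    """A random partition of observed links into training and probe sets.

    The training graph keeps every original node, so probe removal may leave
    degree-0 nodes; predictors must tolerate them.
    """

    train: Graph
    probe: frozenset
    seed: int
    fraction: float

    def sorted_probe(self) -> list:
        return sorted(self.probe, key=lambda e: (str(e[0]), str(e[1])))


def split_train_probe(g: Graph, fraction: float, seed: int) -> SplitResult:
    """Uniform random split with |E^T| = round(fraction · |E|).

    Deterministic for a fixed (graph, fraction, seed).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    edges = sorted(g.edges, key=lambda e: (str(e[0]), str(e[1])))
    if not edges:
        raise ValueError("graph has no edges to split")
    n_train = round(fraction * len(edges))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    train_edges = [edges[i] for i in perm[:n_train]]
    probe = frozenset(edges[i] for i in perm[n_train:])
    train = Graph(nodes=g.nodes, edges=train_edges)
    return SplitResult(train, probe, seed, fraction)


def _positives_negatives(scores: ScoreTable, split: SplitResult):
    """Probe scores and non-existent (U − E) scores from one table."""
    pos = [scores.entries[p] for p in split.sorted_probe()]
    probe = split.probe
    neg_pairs = [p for p in scores.entries if p not in probe]
    neg_pairs.sort(key=lambda e: (str(e[0]), str(e[1])))
    neg = [scores.entries[p] for p in neg_pairs]
    if not pos:
        raise EvaluationError("empty probe set: AUC undefined")
    if not neg:
        raise EvaluationError("no non-existent pairs: AUC undefined")
    return np.asarray(pos), np.asarray(neg)


def auc_sampled(scores: ScoreTable, split: SplitResult, n: int = 100_000,
                seed: int = 0) -> float:
    """Sampled AUC: (n′ + 0.5·n″) / n over n random probe-vs-non-existent
    comparisons drawn independently with replacement."""
    if n < 1:
        raise ValueError(f"need at least one comparison, got n={n}")
    pos, neg = _positives_negatives(scores, split)
    rng = np.random.default_rng(seed)
    ps = pos[rng.integers(len(pos), size=n)]
    ns = neg[rng.integers(len(neg), size=n)]
    return float((np.count_nonzero(ps > ns) + 0.5 * np.count_nonzero(ps == ns)) / n)


def auc_exact(scores: ScoreTable, split: SplitResult) -> float:
    """Exact rank-based AUC over all probe × non-existent comparisons.

    Computed from mid-ranks (Mann–Whitney form), which credits each tie
    exactly one half; ``auc_sampled`` converges to this value.
    """
    pos, neg = _positives_negatives(scores, split)
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def precision_at(scores: ScoreTable, split: SplitResult, L: int = 100,
                 tie_seed: int = 0) -> float:
    """Precision@L: fraction of the L top-scored candidates that are probe links.

    Ties are broken by a seeded random shuffle ahead of a stable sort, so
    label order never biases the ranking.  If L exceeds the number of
    candidates, all candidates are used (with a logged warning).
    """
    if L < 1:
        raise ValueError(f"L must be positive, got {L}")
    items = list(scores.entries.items())
    items.sort(key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    rng = np.random.default_rng(tie_seed)
    rng.shuffle(items)
    items.sort(key=lambda kv: -kv[1])  # stable: shuffled order breaks ties
    if L > len(items):
        logger.warning("L=%d exceeds %d candidates; using all", L, len(items))
        L = len(items)
    top = items[:L]
    hits = sum(1 for pair, _ in top if pair in split.probe)
    return hits / L


@dataclass
class BenchmarkResult:
    """Mean ± sd of each metric for each index over repeated random splits."""

    results: Dict[str, Dict[str, Tuple[float, float, int]]]
    metadata: Dict[str, object] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "metadata": self.metadata,
            "results": {
                idx: {m: {"mean": v[0], "sd": v[1], "reps": v[2]}
                      for m, v in metrics.items()}
                for idx, metrics in self.results.items()
            },
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    def to_table(self) -> str:
        """Text table with ``mean(sd×10⁴)`` cells, e.g. ``0.697(52)``."""
        metrics = sorted({m for v in self.results.values() for m in v})
        lines = ["index\t" + "\t".join(metrics)]
        for idx in sorted(self.results):
            cells = []
            for m in metrics:
                mean, sd, _ = self.results[idx][m]
                cells.append(f"{round(mean, 3)}({round(sd * 1e4):d})")
            lines.append(idx + "\t" + "\t".join(cells))
        return "\n".join(lines)


def run_benchmark(
    g: Graph,
    indices: Mapping[str, Mapping[str, float]] | Sequence[str],
    fraction: float = 0.9,
    reps: int = 100,
    base_seed: int = 0,
    metrics: Sequence[str] = ("auc", "precision"),
    auc_method: str = "sampled",
    auc_samples: int = 100_000,
    top_l: int = 100,
) -> BenchmarkResult:
    """Repeatedly split, score, and evaluate each index.

    Repetition r uses split seed ``base_seed + r``; metric sampling seeds are
    derived from (base_seed, r), so an identical call is bit-reproducible.
    The per-rep information model is fitted once on the training graph and
    shared by MI and NSI.
    """
    if reps < 1:
        raise ValueError(f"reps must be ≥ 1, got {reps}")
    if isinstance(indices, Mapping):
        index_specs = {k: dict(v or {}) for k, v in indices.items()}
    else:
        index_specs = {name: {} for name in indices}
    values: Dict[str, Dict[str, list]] = {
        idx: {m: [] for m in metrics} for idx in index_specs
    }
    for r in range(reps):
        split = split_train_probe(g, fraction, base_seed + r)
        model = None
        if any(idx.upper() in ("MI", "NSI") for idx in index_specs):
            model = InfoModel.fit(split.train)
        for idx, params in index_specs.items():
            try:
                table = score_all(split.train, idx, params, model=model)
                for m in metrics:
                    if m == "auc":
                        if auc_method == "exact":
                            v = auc_exact(table, split)
                        else:
                            v = auc_sampled(
                                table, split, auc_samples,
                                seed=np.random.default_rng(
                                    [base_seed, r, 1]).integers(2**31),
                            )
                    elif m == "precision":
                        v = precision_at(
                            table, split, top_l,
                            tie_seed=np.random.default_rng(
                                [base_seed, r, 2]).integers(2**31),
                        )
                    else:
                        raise ValueError(f"unknown metric {m!r}")
                    values[idx][m].append(v)
            except EvaluationError:
                raise
            except Exception as exc:  # pragma: no cover - context for debugging
                raise RuntimeError(
                    f"benchmark repetition failed (index={idx}, seed={base_seed + r})"
                ) from exc
    results = {
        idx: {
            m: (float(np.mean(vs)), float(np.std(vs)), reps)
            for m, vs in per.items()
        }
        for idx, per in values.items()
    }
    metadata = {
        "fraction": fraction,
        "reps": reps,
        "base_seed": base_seed,
        "auc_method": auc_method,
        "auc_samples": auc_samples,
        "top_l": top_l,
        "indices": index_specs,
    }
    return BenchmarkResult(results, metadata)
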