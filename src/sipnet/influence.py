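"""Strongest-influence-path probabilities and greedy seed selection.

The influence of a node on another is the Strongest Influence Path (SIP)
value: the maximum over all connecting paths of the product of edge
probabilities.  Because every weight lies in (0, 1], maximizing the product
is a shortest-path problem on costs ``-log(weight)``, all nonnegative, so
SIP values come from a single Dijkstra search per source; the probability is
then re-multiplied along the returned path so products are not perturbed by
the log transform.  Unreachable pairs have SIP 0 and ``sip(u, u) = 1``.

Seed selection is the greedy heuristic for influence maximization under
SIP: pick the single node with the highest influence on the eligible
targets, then repeatedly add the candidate whose inclusion gives the
highest combined influence of the seed set on the remaining targets.
"Combined" influence of several seeds on one target aggregates their SIP
values with a noisy-OR (``1 - prod(1 - sigma)``, treating paths from
different seeds as independent) by default, or a plain maximum.  Node
colors (gene/disease) restrict which nodes may serve as sources or targets,
supporting queries such as "the k genes most closely related to this
disease set".

Exhaustive brute-force oracles (simple-path enumeration for SIP, subset
search for seed sets) are provided for small graphs; the exact problem is
intractable at scale, which is what the greedy heuristic is for.

The suite-relevance score is a reconstruction: summing, over a disease
suite, the combined influence of a gene suite on each disease is the
simplest scalar consistent with ranking (gene suite, disease suite) pairs,
but no authoritative formula exists, so the aggregator stays configurable.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .cooccurrence import CoocGraph
from .errors import NodeNotFoundError, OracleCapError, ValidationError

__all__ = [
    "InfluenceConfig",
    "SeedResult",
    "SuiteRelevance",
    "sip",
    "sip_from",
    "node_influence",
    "set_influence",
    "select_seeds_greedy",
    "query_influencers",
    "suite_relevance",
    "brute_force_sip",
    "brute_force_seeds",
    "seed_result_to_json",
    "write_rank_table",
]

AGGREGATORS = ("noisy_or", "max")


@dataclass(frozen=True)
class InfluenceConfig:
    """Knobs of the seed-selection problem.

    ``aggregator`` combines per-seed SIP values on a target; ``source_color``
    and ``target_color`` restrict eligibility by node class ("all" disables
    the restriction); ``num_seeds`` is the seed-set size s.
    """

    aggregator: str = "noisy_or"
    target_color: str = "all"
    source_color: str = "all"
    num_seeds: int = 1

    def __post_init__(self) -> None:
        if self.aggregator not in AGGREGATORS:
            raise ValidationError(f"unknown aggregator {self.aggregator!r}")
        if self.num_seeds < 1:
            raise ValidationError("num_seeds must be >= 1")


@dataclass
class SeedResult:
    """Ordered seeds with the combined influence recorded after each addition."""

    seeds: list[str]
    influence_trace: list[float]
    final_influence: float
    config: InfluenceConfig


@dataclass
class SuiteRelevance:
    gene_suite: frozenset[str]
    disease_suite: frozenset[str]
    relevance: float


# ---------------------------------------------------------------------------
# SIP
# ---------------------------------------------------------------------------

def _neg_log(u: str, v: str, data: Mapping[str, float]) -> float:
    return -math.log(data["weight"])


def sip_from(graph: CoocGraph, source: str) -> dict[str, float]:
    """SIP probability from ``source`` to every reachable node (one search).

    Nodes missing from the result are unreachable (SIP 0); the source maps
    to 1.0.
    """
    g = graph.graph
    if source not in g:
        raise NodeNotFoundError(source)
    _, paths = nx.single_source_dijkstra(g, source, weight=_neg_log)
    probs: dict[str, float] = {}
    for node, path in paths.items():
        p = 1.0
        for a, b in zip(path, path[1:]):
            p *= g.edges[a, b]["weight"]
        probs[node] = p
    return probs


def sip(graph: CoocGraph, source: str, dest: str) -> float:
    """Maximum product of edge probabilities over paths from source to dest."""
    if dest not in graph.graph:
        raise NodeNotFoundError(dest)
    return sip_from(graph, source).get(dest, 0.0)


def _combine(values: Iterable[float], aggregator: str) -> float:
    values = list(values)
    if aggregator == "noisy_or":
        q = 1.0
        for v in values:
            q *= 1.0 - v
        return 1.0 - q
    return max(values, default=0.0)


def _eligible_targets(graph: CoocGraph, target_color: str) -> set[str]:
    return set(graph.nodes_of_color(target_color))


def node_influence(graph: CoocGraph, u: str,
                   config: InfluenceConfig = InfluenceConfig(),
                   exclude: Iterable[str] = ()) -> float:
    """Influence of a single node: the sum of its SIP probabilities over all
    eligible targets (color-matched, not the node itself, not excluded)."""
    probs = sip_from(graph, u)
    targets = _eligible_targets(graph, config.target_color) - {u} - set(exclude)
    return sum(probs.get(v, 0.0) for v in targets)


def set_influence(graph: CoocGraph, seeds: Iterable[str],
                  config: InfluenceConfig = InfluenceConfig()) -> float:
    """Combined influence of a seed set on the other eligible nodes.

    For each eligible target outside the set, the per-seed SIP values are
    aggregated (noisy-OR or max) and the aggregates are summed.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValidationError("seed set must be non-empty")
    for s in seeds:
        if s not in graph.graph:
            raise NodeNotFoundError(s)
    per_seed = {s: sip_from(graph, s) for s in seeds}
    targets = _eligible_targets(graph, config.target_color) - set(seeds)
    return sum(
        _combine((per_seed[s].get(v, 0.0) for s in seeds), config.aggregator)
        for v in targets
    )


# ---------------------------------------------------------------------------
# greedy selection
# ---------------------------------------------------------------------------

def _sip_matrix(graph: CoocGraph, sources: Sequence[str],
                index: Mapping[str, int]) -> np.ndarray:
    m = np.zeros((len(sources), len(index)))
    for row, u in enumerate(sources):
        for v, p in sip_from(graph, u).items():
            m[row, index[v]] = p
    return m


def _greedy(graph: CoocGraph, sources: Sequence[str], target_mask: np.ndarray,
            index: Mapping[str, int], k: int, aggregator: str,
            exclude_seeds_from_targets: bool) -> tuple[list[str], list[float]]:
    """Core greedy loop shared by whole-graph selection and fixed-target
    queries.  ``sources`` must be lexicographically sorted; ties at every
    argmax then resolve to the smallest node id."""
    M = _sip_matrix(graph, sources, index)
    n = len(index)
    seed_rows: list[int] = []
    seeds: list[str] = []
    trace: list[float] = []
    # running aggregate per target: product of (1 - sip) for noisy-OR,
    # best sip so far for max
    q = np.ones(n)
    best = np.zeros(n)
    seed_mask = np.zeros(n, dtype=bool)

    for _ in range(k):
        best_row, best_val = -1, -np.inf
        for row in range(len(sources)):
            if row in seed_rows:
                continue
            if aggregator == "noisy_or":
                vals = 1.0 - q * (1.0 - M[row])
            else:
                vals = np.maximum(best, M[row])
            mask = target_mask & ~seed_mask
            if exclude_seeds_from_targets:
                mask = mask.copy()
                mask[index[sources[row]]] = False
            total = float(vals[mask].sum())
            if total > best_val:
                best_row, best_val = row, total
        u = sources[best_row]
        seed_rows.append(best_row)
        seeds.append(u)
        seed_mask[index[u]] = exclude_seeds_from_targets
        q *= 1.0 - M[best_row]
        best = np.maximum(best, M[best_row])
        trace.append(best_val)
    return seeds, trace


def select_seeds_greedy(graph: CoocGraph,
                        config: InfluenceConfig) -> SeedResult:
    """Greedy seed selection over the whole graph.

    The first seed is the node with the highest single-node influence; each
    later iteration adds the eligible source whose inclusion maximizes the
    combined influence of the enlarged set on the remaining eligible
    targets.  Deterministic: ties break lexicographically by node id.
    """
    sources = graph.nodes_of_color(config.source_color)
    if config.num_seeds > len(sources):
        raise ValidationError(
            f"requested {config.num_seeds} seeds but only {len(sources)} "
            f"eligible source nodes"
        )
    nodes = sorted(graph.graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    targets = _eligible_targets(graph, config.target_color)
    target_mask = np.array([v in targets for v in nodes], dtype=bool)
    seeds, trace = _greedy(graph, sources, target_mask, index,
                           config.num_seeds, config.aggregator,
                           exclude_seeds_from_targets=True)
    return SeedResult(seeds, trace, trace[-1], config)


def query_influencers(graph: CoocGraph, fixed_targets: Iterable[str], k: int,
                      source_color: str = "gene",
                      aggregator: str = "noisy_or") -> SeedResult:
    """Greedy selection of the k sources most closely related to a fixed
    target set (e.g. the genes most related to a disease set, or vice versa
    with colors swapped).  Influence is summed over the fixed targets only."""
    fixed_targets = set(fixed_targets)
    for t in fixed_targets:
        if t not in graph.graph:
            raise NodeNotFoundError(t)
    if k < 1:
        raise ValidationError("k must be >= 1")
    sources = [s for s in graph.nodes_of_color(source_color)
               if s not in fixed_targets]
    if k > len(sources):
        raise ValidationError(
            f"requested {k} influencers but only {len(sources)} candidate sources"
        )
    nodes = sorted(graph.graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    target_mask = np.array([v in fixed_targets for v in nodes], dtype=bool)
    config = InfluenceConfig(aggregator=aggregator, source_color=source_color,
                             target_color="all", num_seeds=k)
    seeds, trace = _greedy(graph, sources, target_mask, index, k, aggregator,
                           exclude_seeds_from_targets=False)
    return SeedResult(seeds, trace, trace[-1], config)


def suite_relevance(graph: CoocGraph, gene_suite: Iterable[str],
                    disease_suite: Iterable[str],
                    aggregator: str = "noisy_or") -> SuiteRelevance:
    """Relevance of a gene suite to a disease suite: the sum over diseases of
    the combined influence of the gene suite on that disease."""
    gene_suite = frozenset(gene_suite)
    disease_suite = frozenset(disease_suite)
    if gene_suite & disease_suite:
        raise ValidationError("gene and disease suites must be disjoint")
    for n in gene_suite | disease_suite:
        if n not in graph.graph:
            raise NodeNotFoundError(n)
    per_gene = {g: sip_from(graph, g) for g in sorted(gene_suite)}
    relevance = sum(
        _combine((per_gene[g].get(d, 0.0) for g in sorted(gene_suite)), aggregator)
        for d in disease_suite
    )
    return SuiteRelevance(gene_suite, disease_suite, relevance)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _check_cap(graph: CoocGraph, cap: int) -> None:
    n = graph.graph.number_of_nodes()
    if n > cap:
        raise OracleCapError(
            f"brute force refused: graph has {n} nodes, oracle cap is {cap}"
        )


def brute_force_sip(graph: CoocGraph, source: str, dest: str,
                    cap: int = 10) -> float:
    """Exact SIP by exhaustive simple-path enumeration (small graphs only)."""
    _check_cap(graph, cap)
    g = graph.graph
    if source not in g or dest not in g:
        raise NodeNotFoundError(source if source not in g else dest)
    if source == dest:
        return 1.0
    best = 0.0
    for path in nx.all_simple_paths(g, source, dest):
        p = 1.0
        for a, b in zip(path, path[1:]):
            p *= g.edges[a, b]["weight"]
        best = max(best, p)
    return best


def brute_force_seeds(graph: CoocGraph, config: InfluenceConfig,
                      cap: int = 10) -> tuple[list[str], float]:
    """Exact best seed set by exhaustive subset search (small graphs only).

    Ties resolve to the lexicographically smallest subset.
    """
    _check_cap(graph, cap)
    sources = graph.nodes_of_color(config.source_color)
    if config.num_seeds > len(sources):
        raise ValidationError("num_seeds exceeds eligible sources")
    best_set: list[str] = []
    best_val = -math.inf
    for subset in itertools.combinations(sources, config.num_seeds):
        val = set_influence(graph, subset, config)
        if val > best_val:
            best_set, best_val = list(subset), val
    return best_set, best_val


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def _graph_digest(graph: CoocGraph) -> str:
    h = hashlib.sha256()
    for n in sorted(graph.graph.nodes):
        h.update(f"{n}:{graph.color(n)};".encode())
    for u, v in sorted(map(sorted, graph.graph.edges)):
        h.update(f"{u}-{v}:{graph.graph.edges[u, v]['weight']!r};".encode())
    return h.hexdigest()[:16]


def seed_result_to_json(result: SeedResult, graph: CoocGraph) -> str:
    payload = {
        "seeds": result.seeds,
        "influence_trace": result.influence_trace,
        "final_influence": result.final_influence,
        "config": {
            "aggregator": result.config.aggregator,
            "source_color": result.config.source_color,
            "target_color": result.config.target_color,
            "num_seeds": result.config.num_seeds,
        },
        "graph_digest": _graph_digest(graph),
    }
    return json.dumps(payload, indent=2)


def write_rank_table(result: SeedResult, graph: CoocGraph,
                     path: str | Path) -> None:
    """Rank table: rank, node, color, marginal gain, cumulative influence."""
    lines = ["rank\tnode\tcolor\tmarginal_gain\tcumulative_influence"]
    prev = 0.0
    for rank, (node, cum) in enumerate(zip(result.seeds, result.influence_trace),
                                       start=1):
        lines.append(f"{rank}\t{node}\t{graph.color(node)}\t"
                     f"{cum - prev:.6g}\t{cum:.6g}")
        prev = cum
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
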