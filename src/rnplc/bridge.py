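"""Life-cycle bridge scores: betweenness-style shortest-path statistics.

For bait sets S1, S2 of two mRNA life-cycle steps, the pairwise bridge
score of node v is

    score_{S1,S2}(v) = (1/N) * sum_{s in S1, t in S2} sigma_{s,t|v} / sigma_{s,t}

where sigma_{s,t} counts shortest s-t paths, sigma_{s,t|v} those passing
through v as an interior node, and N is the number of (s, t) pairs
(unreachable pairs contribute 0 but stay in N). The all-steps score sums
the fractions over every step pair and divides by N', the total pair count.
The balanced variant rescales each step pair by a = 1000 / #pairs(S1, S2)
and divides by N'' = 1000 x #step-pairs, which makes it exactly the
unweighted mean of the pairwise scores (the 1000 factors cancel).

Path counting is a hand-rolled breadth-first layered count (one BFS per
bait); a brute-force oracle enumerating all shortest paths is provided for
verification on small graphs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping

import networkx as nx

BALANCE_FACTOR = 1000.0


@dataclass
class BridgeScores:
    """Per-node scores for every step pair plus all-steps variants."""

    pairwise: dict[tuple[str, str], dict[Hashable, float]]
    all_steps: dict[Hashable, float]
    balanced: dict[Hashable, float]
    normalizers: dict[tuple[str, str], int]
    n_prime: int
    n_double_prime: float


def _bfs_counts(adj: Mapping, source) -> tuple[dict, dict]:
    """(distance, number-of-shortest-paths) maps from one source."""
    dist = {source: 0}
    sigma = {source: 1.0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0.0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def shortest_path_counts(graph: nx.Graph, s, t) -> tuple[float, dict]:
    """sigma_{s,t} and per-node interior path counts sigma_{s,t|v}.

    v is interior: v not in {s, t}. Unreachable (s, t) gives sigma = 0 and
    an all-zero map.
    """
    if s not in graph or t not in graph:
        raise KeyError(f"node absent from graph: {s!r} or {t!r}")
    adj = {u: list(graph.neighbors(u)) for u in graph.nodes}
    ds, ss = _bfs_counts(adj, s)
    dt, st = _bfs_counts(adj, t)
    through = {v: 0.0 for v in graph.nodes}
    if t not in ds:
        return 0.0, through
    d = ds[t]
    for v in graph.nodes:
        if v in (s, t):
            continue
        if v in ds and v in dt and ds[v] + dt[v] == d:
            through[v] = ss[v] * st[v]
    return float(ss[t]), through


def _pair_fractions(graph: nx.Graph, sources: list) -> dict:
    """Cache one BFS per distinct endpoint."""
    adj = {u: list(graph.neighbors(u)) for u in graph.nodes}
    return {s: _bfs_counts(adj, s) for s in sources}


def _accumulate(graph, cache, s, t) -> dict:
    ds, ss = cache[s]
    dt, st = cache[t]
    out = {}
    if t not in ds:
        return out
    d = ds[t]
    denom = ss[t]
    for v in graph.nodes:
        if v in (s, t):
            continue
        if v in ds and v in dt and ds[v] + dt[v] == d:
            out[v] = (ss[v] * st[v]) / denom
    return out


def bridge_score_pairwise(graph: nx.Graph, s1: set, s2: set) -> dict:
    """Per-node score for one pair of step bait sets (N includes unreachable
    pairs; s = t pairs are excluded)."""
    if not s1 or not s2:
        raise ValueError("empty step set")
    missing = (set(s1) | set(s2)) - set(graph.nodes)
    if missing:
        raise KeyError(f"step baits absent from graph: {sorted(missing)}")
    cache = _pair_fractions(graph, sorted(set(s1) | set(s2)))
    scores = {v: 0.0 for v in graph.nodes}
    n_pairs = 0
    for s in sorted(s1):
        for t in sorted(s2):
            if s == t:
                continue
            n_pairs += 1
            for v, frac in _accumulate(graph, cache, s, t).items():
                scores[v] += frac
    if n_pairs == 0:
        raise ValueError("no (s, t) pairs between the step sets")
    return {v: x / n_pairs for v, x in scores.items()}


def bridge_score_all_steps(
    graph: nx.Graph, step_assignment: Mapping[Hashable, str]
) -> BridgeScores:
    """All three score variants over every unordered pair of life-cycle steps.

    ``step_assignment`` maps baits to steps; nodes with step "unknown" (or
    absent from the mapping) remain ordinary graph nodes but anchor no step
    set. Requires >= 2 steps with at least one bait present in the graph.
    """
    steps: dict[str, set] = {}
    for node, step in step_assignment.items():
        if step and step != "unknown" and node in graph:
            steps.setdefault(step, set()).add(node)
    if len(steps) < 2:
        raise ValueError("need >= 2 life-cycle steps with baits in the graph")
    step_names = sorted(steps)
    endpoints = sorted(set().union(*steps.values()))
    cache = _pair_fractions(graph, endpoints)

    pairwise: dict[tuple[str, str], dict] = {}
    normalizers: dict[tuple[str, str], int] = {}
    raw_sums: dict[tuple[str, str], dict] = {}
    for a, b in combinations(step_names, 2):
        sums = {v: 0.0 for v in graph.nodes}
        n_pairs = 0
        for s in sorted(steps[a]):
            for t in sorted(steps[b]):
                if s == t:
                    continue
                n_pairs += 1
                for v, frac in _accumulate(graph, cache, s, t).items():
                    sums[v] += frac
        if n_pairs == 0:
            continue
        raw_sums[(a, b)] = sums
        normalizers[(a, b)] = n_pairs
        pairwise[(a, b)] = {v: x / n_pairs for v, x in sums.items()}

    n_prime = sum(normalizers.values())
    n_step_pairs = len(normalizers)
    n_double_prime = BALANCE_FACTOR * n_step_pairs
    all_steps = {v: 0.0 for v in graph.nodes}
    balanced = {v: 0.0 for v in graph.nodes}
    for key, sums in raw_sums.items():
        a_factor = BALANCE_FACTOR / normalizers[key]
        for v, x in sums.items():
            all_steps[v] += x
            balanced[v] += a_factor * x
    all_steps = {v: x / n_prime for v, x in all_steps.items()}
    balanced = {v: x / n_double_prime for v, x in balanced.items()}
    return BridgeScores(
        pairwise=pairwise,
        all_steps=all_steps,
        balanced=balanced,
        normalizers=normalizers,
        n_prime=n_prime,
        n_double_prime=n_double_prime,
    )


def brute_force_bridge_oracle(
    graph: nx.Graph, step_assignment: Mapping[Hashable, str], max_nodes: int = 12
) -> BridgeScores:
    """Literal-summation oracle: enumerate every shortest path.

    Independent route: path enumeration delegates to
    networkx.all_shortest_paths rather than the BFS-counting code above.
    Restricted to small graphs.
    """
    if graph.number_of_nodes() > max_nodes:
        raise ValueError("graph too large for the brute-force oracle")
    steps: dict[str, set] = {}
    for node, step in step_assignment.items():
        if step and step != "unknown" and node in graph:
            steps.setdefault(step, set()).add(node)
    if len(steps) < 2:
        raise ValueError("need >= 2 life-cycle steps with baits in the graph")

    def fractions(s, t) -> dict:
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            return {}
        sigma = len(paths)
        out: dict = {}
        for path in paths:
            for v in path[1:-1]:
                out[v] = out.get(v, 0) + 1
        return {v: c / sigma for v, c in out.items()}

    step_names = sorted(steps)
    pairwise: dict[tuple[str, str], dict] = {}
    normalizers: dict[tuple[str, str], int] = {}
    raw: dict[tuple[str, str], dict] = {}
    for a, b in combinations(step_names, 2):
        sums = {v: 0.0 for v in graph.nodes}
        n_pairs = 0
        for s in sorted(steps[a]):
            for t in sorted(steps[b]):
                if s == t:
                    continue
                n_pairs += 1
                for v, frac in fractions(s, t).items():
                    sums[v] += frac
        if n_pairs == 0:
            continue
        raw[(a, b)] = sums
        normalizers[(a, b)] = n_pairs
        pairwise[(a, b)] = {v: x / n_pairs for v, x in sums.items()}

    n_prime = sum(normalizers.values())
    n_double_prime = BALANCE_FACTOR * len(normalizers)
    all_steps = {
        v: sum(raw[k][v] for k in raw) / n_prime for v in graph.nodes
    }
    balanced = {
        v: sum((BALANCE_FACTOR / normalizers[k]) * raw[k][v] for k in raw) / n_double_prime
        for v in graph.nodes
    }
    return BridgeScores(
        pairwise=pairwise,
        all_steps=all_steps,
        balanced=balanced,
        normalizers=normalizers,
        n_prime=n_prime,
        n_double_prime=n_double_prime,
    )


def top_bridge_nodes(scores: Mapping[Hashable, float], frac: float = 0.03) -> list:
    """Nodes in the top ``frac`` of the score distribution, best first."""
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    k = max(1, int(round(frac * len(ranked))))
    return [v for v, _ in ranked[:k]]
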