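"""Independent brute-force oracles used by the test suite.

Kept deliberately primitive (exact rational arithmetic, explicit BFS)
and independent of the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def exact_binom_two_sided(a: int, b: int, line_lib: int, baseline_lib: int) -> Fraction:
    """Two-sided minimum-likelihood binomial tail by full enumeration.

    Exact rational arithmetic: conditional on t = a + b, outcome x has
    probability C(t, x) pi^x (1-pi)^(t-x) with pi = line_lib / (line_lib
    + baseline_lib); the p-value sums every outcome whose probability is
    <= the observed one (exact comparison).
    """
    t = a + b
    if t == 0:
        return Fraction(1)
    pi = Fraction(line_lib, line_lib + baseline_lib)
    probs = [comb(t, x) * pi**x * (1 - pi) ** (t - x) for x in range(t + 1)]
    observed = probs[a]
    return sum((p for p in probs if p <= observed), Fraction(0))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct enumeration."""
    denom = comb(N, n)
    total = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return Fraction(total, denom)


def connected_components_bfs(nodes: list, edges: list[tuple]) -> list[frozenset]:
    """Connected components by explicit breadth-first traversal."""
    adj: dict = {v: set() for v in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen: set = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        comp = {start}
        while queue:
            cur = queue.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    queue.append(nxt)
        comps.append(frozenset(comp))
    return comps


def degrees_from_edges(edges: list[tuple]) -> dict:
    deg: dict = {}
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    return deg
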