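"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available —
quadratic scans, transitive closure, exact enumeration — without calling
the code paths it is checking.
"""

from __future__ import annotations

import math

import numpy as np


def window_for(strand: str, tss: int, w_up: int, w_down: int) -> tuple[int, int]:
    """Promoter window arithmetic, written out independently."""
    if strand == "+":
        lo, hi = tss - w_up, tss + w_down
        if w_down == 0:
            hi = tss + 1
    else:
        lo, hi = tss - w_down + 1, tss + w_up + 1
        if w_down == 0:
            lo = tss
    return max(lo, 0), hi


def brute_force_assignment(peaks, genes, w_up: int, w_down: int) -> set[tuple[str, int]]:
    """All (gene_id, peak_index) pairs by an all-pairs overlap scan.

    ``peaks``: list of (chrom, start, end); ``genes``: list of
    (gene_id, chrom, strand, tss).
    """
    hits = set()
    for gene_id, gchrom, strand, tss in genes:
        lo, hi = window_for(strand, tss, w_up, w_down)
        for idx, (pchrom, start, end) in enumerate(peaks):
            if pchrom == gchrom and start < hi and lo < end:
                hits.add((gene_id, idx))
    return hits


def brute_force_assignment_vec(peaks, genes, w_up: int, w_down: int) -> set[tuple[str, int]]:
    """Same all-pairs scan, vectorised per chromosome for large instances."""
    hits = set()
    chroms = {c for c, _, _ in peaks} | {c for _, c, _, _ in genes}
    for chrom in chroms:
        pk = [(i, s, e) for i, (c, s, e) in enumerate(peaks) if c == chrom]
        gn = [(g, st, t) for g, c, st, t in genes if c == chrom]
        if not pk or not gn:
            continue
        idx = np.array([i for i, _, _ in pk])
        starts = np.array([s for _, s, _ in pk])
        ends = np.array([e for _, _, e in pk])
        for gene_id, strand, tss in gn:
            lo, hi = window_for(strand, tss, w_up, w_down)
            mask = (starts < hi) & (lo < ends)
            for i in idx[mask]:
                hits.add((gene_id, int(i)))
    return hits


def scc_by_transitive_closure(n_nodes: int, edges: set[tuple[int, int]]) -> list[frozenset[int]]:
    """SCC partition via boolean-matrix reachability closure (<= ~12 nodes)."""
    reach = np.eye(n_nodes, dtype=bool)
    for u, v in edges:
        reach[u, v] = True
    for _ in range(n_nodes):
        reach = reach | (reach @ reach)
    mutual = reach & reach.T
    comps = {frozenset(np.flatnonzero(mutual[i]).tolist()) for i in range(n_nodes)}
    return sorted(comps, key=lambda c: min(c))


def hypergeom_upper_tail(n_universe: int, n_a: int, n_b: int, k_min: int) -> float:
    """P(overlap >= k_min) by exact combinatorial enumeration."""
    total = math.comb(n_universe, n_b)
    acc = 0
    for k in range(k_min, min(n_a, n_b) + 1):
        if n_b - k <= n_universe - n_a:
            acc += math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k)
    return acc / total


def all_topological_levels(n_nodes: int, edges: set[tuple[int, int]]) -> dict[int, tuple[int, int]]:
    """(level_min, level_max) per node of a DAG by longest-path definitions,
    computed by exhaustive DFS over all simple paths (tiny graphs only)."""
    succ = {i: [] for i in range(n_nodes)}
    pred = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        succ[u].append(v)
        pred[v].append(u)

    def longest_from(node, nxt):
        best = 0
        for m in nxt[node]:
            best = max(best, 1 + longest_from(m, nxt))
        return best

    down = {i: longest_from(i, succ) for i in range(n_nodes)}
    up = {i: longest_from(i, pred) for i in range(n_nodes)}
    height = max((up[i] + down[i] for i in range(n_nodes)), default=0) + 1
    return {i: (up[i], (height - 1) - down[i]) for i in range(n_nodes)}
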