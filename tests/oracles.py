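"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a different algorithmic route than
the implementation under test: shortest-path search instead of tabular
DP, exhaustive enumeration instead of traceback, subset enumeration
instead of graph alignment.
"""

from __future__ import annotations

import heapq
import itertools

from phasebench.gap_params import AffineParams


def dijkstra_affine(ref: str, alt: str, p: AffineParams) -> float:
    """Minimum affine alignment penalty by shortest-path search over the
    (i, j, state) lattice."""
    n, m = len(ref), len(alt)
    start = (0, 0, "M")
    dist = {start: 0.0}
    heap = [(0.0, 0, 0, "M")]
    best = float("inf")
    while heap:
        d, i, j, s = heapq.heappop(heap)
        if d > dist.get((i, j, s), float("inf")):
            continue
        if i == n and j == m:
            best = min(best, d)
            continue
        moves = []
        if i < n and j < m:
            cost = p.m if ref[i] == alt[j] else p.x
            moves.append((i + 1, j + 1, "M", cost))
        if i < n:
            moves.append((i + 1, j, "D", p.e if s == "D" else p.o + p.e))
        if j < m:
            moves.append((i, j + 1, "I", p.e if s == "I" else p.o + p.e))
        for ni, nj, ns, c in moves:
            nd = d + c
            if nd < dist.get((ni, nj, ns), float("inf")):
                dist[(ni, nj, ns)] = nd
                heapq.heappush(heap, (nd, ni, nj, ns))
    return best


def enumerate_alignments(ref: str, alt: str):
    """Yield every alignment as an op string over M/X/D/I (tiny inputs)."""
    n, m = len(ref), len(alt)

    def rec(i: int, j: int, ops: list[str]):
        if i == n and j == m:
            yield "".join(ops)
            return
        if i < n and j < m:
            op = "M" if ref[i] == alt[j] else "X"
            yield from rec(i + 1, j + 1, ops + [op])
        if i < n:
            yield from rec(i + 1, j, ops + ["D"])
        if j < m:
            yield from rec(i, j + 1, ops + ["I"])

    yield from rec(0, 0, [])


def op_string_penalty(ops: str, p: AffineParams) -> float:
    """Penalty of an explicit op string, pricing each gap run as o + n*e."""
    total = 0.0
    i = 0
    while i < len(ops):
        op = ops[i]
        j = i
        while j < len(ops) and ops[j] == op:
            j += 1
        run = j - i
        if op == "M":
            total += p.m * run
        elif op == "X":
            total += p.x * run
        else:
            total += p.gap_cost(run)
        i = j
    return total


def exhaustive_min_penalty(ref: str, alt: str, p: AffineParams) -> float:
    return min(op_string_penalty(ops, p) for ops in enumerate_alignments(ref, alt))


def op_string_ed_de(ops: str) -> tuple[int, int]:
    ed = de = 0
    prev = None
    for op in ops:
        if op == "X":
            ed += 1
            de += 1
        elif op in "DI":
            ed += 1
            if op != prev:
                de += 1
        prev = op
    return ed, de


def min_2de_ed(a: str, b: str) -> int:
    """Brute-force global minimum of 2*DE + ED over all alignments."""
    return min(2 * d + e for ops in enumerate_alignments(a, b)
               for e, d in [op_string_ed_de(ops)])


def brute_force_phase_cost(categories, switch_cost=1.0, phase_error_cost=1.0):
    """Minimum switch+phase-error cost over all 2^k state assignments."""
    k = len(categories)
    best = float("inf")
    for states in itertools.product("XY", repeat=k):
        cost = 0.0
        for a, b in zip(states, states[1:]):
            if a != b:
                cost += switch_cost
        for s, c in zip(states, categories):
            if c is not None and c != s:
                cost += phase_error_cost
        best = min(best, cost)
    return best


def brute_force_reach(ref_w: str, alt_w: str, cluster_ref_len: int,
                      budget: float, p: AffineParams) -> int:
    """Furthest off-diagonal reference offset by exhaustive path search.

    Explores every partial alignment path from the window start, with
    affine gap state, skipping match steps that would land on the final
    main diagonal beyond the cluster span, and pruning at the penalty
    budget.  Mirrors the reach semantics with an independent search.
    """
    n, m = len(ref_w), len(alt_w)
    delta = m - n
    best = [min(cluster_ref_len, n)]
    seen: dict[tuple, float] = {}

    def rec(i: int, j: int, state: str, cost: float) -> None:
        if cost > budget:
            return
        key = (i, j, state)
        if seen.get(key, float("inf")) <= cost:
            return
        seen[key] = cost
        best[0] = max(best[0], i)
        if i < n and j < m:
            is_match = ref_w[i] == alt_w[j]
            blocked = is_match and (i + 1) > cluster_ref_len \
                and (j + 1) - (i + 1) == delta
            if not blocked:
                rec(i + 1, j + 1, "M", cost + (p.m if is_match else p.x))
        if i < n:
            rec(i + 1, j, "D", cost + (p.e if state == "D" else p.o + p.e))
        if j < m:
            rec(i, j + 1, "I", cost + (p.e if state == "I" else p.o + p.e))

    rec(0, 0, "M", 0.0)
    return best[0]


def brute_force_graph_distance(window: str, truth_seq: str, query_variants,
                               lev) -> int:
    """Minimum edit distance over all subsets of query variants taken."""
    from phasebench.vcf_io import apply_variants

    best = None
    for k in range(len(query_variants) + 1):
        for subset in itertools.combinations(query_variants, k):
            subset = sorted(subset, key=lambda v: (v.start, v.end))
            try:
                seq = apply_variants(window, list(subset))
            except ValueError:
                continue
            d = lev(truth_seq, seq)
            best = d if best is None else min(best, d)
    return best
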