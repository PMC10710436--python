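"""Affine-gap global alignment (Gotoh) with deterministic traceback.

The alignment model has three states per cell: M (match/substitution),
D (deletion, consumes a reference base) and I (insertion, consumes a
query base).  A gap of length n costs ``o + n*e``; the first gap base
costs ``o + e``.

Tie-breaking is fully deterministic so that equal-penalty optima always
yield the same variant representation: during traceback from the final
cell, match/substitution is preferred over deletion over insertion, and
continuing a gap is preferred over opening a new one.  Because traceback
runs end-to-start, preferring the diagonal pushes gaps as far left as
possible, matching conventional left-shifted VCF normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gap_params import AffineParams

INF = float("inf")


@dataclass
class AlignmentPath:
    """Run-length encoded edit path anchored at (ref offset 0, query offset 0).

    ``ops`` is a list of (op, length) with op in {'M', 'X', 'D', 'I'}:
    match, substitution, deletion (ref-only) and insertion (query-only).
    """

    ops: list[tuple[str, int]]
    penalty: float

    def expand(self) -> str:
        return "".join(op * n for op, n in self.ops)

    def ref_len(self) -> int:
        return sum(n for op, n in self.ops if op in "MXD")

    def query_len(self) -> int:
        return sum(n for op, n in self.ops if op in "MXI")

    def recompute_penalty(self, p: AffineParams) -> float:
        """Re-derive the penalty from the operations (invariant check)."""
        total = 0.0
        for op, n in self.ops:
            if op == "M":
                total += p.m * n
            elif op == "X":
                total += p.x * n
            else:
                total += p.gap_cost(n)
        return total


def _compress(ops: list[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return runs


def align_affine(ref_seq: str, alt_seq: str, p: AffineParams) -> AlignmentPath:
    """Minimum-penalty global alignment of ``alt_seq`` against ``ref_seq``."""
    n, m = len(ref_seq), len(alt_seq)
    oe = p.o + p.e

    # Cost matrices per state; python floats, windows are small.
    M = [[INF] * (m + 1) for _ in range(n + 1)]
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    I = [[INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = p.o + i * p.e
    for j in range(1, m + 1):
        I[0][j] = p.o + j * p.e

    for i in range(1, n + 1):
        ri = ref_seq[i - 1]
        Mi, Di, Ii = M[i], D[i], I[i]
        Mp, Dp, Ip = M[i - 1], D[i - 1], I[i - 1]
        for j in range(1, m + 1):
            sub = p.m if ri == alt_seq[j - 1] else p.x
            Mi[j] = min(Mp[j - 1], Dp[j - 1], Ip[j - 1]) + sub
            Di[j] = min(Mp[j] + oe, Dp[j] + p.e, Ip[j] + oe)
            Ii[j] = min(Mi[j - 1] + oe, Ii[j - 1] + p.e, Di[j - 1] + oe)
        Di[0] = p.o + i * p.e if i else INF
    # fix column 0 for I rows (only row 0 can end in insertion at j=0)

    # Traceback.  State preference: M > D > I; within a gap state prefer
    # continuing the gap, then the diagonal state.
    i, j = n, m
    if n == 0 and m == 0:
        return AlignmentPath([], 0.0)
    cands = [(M[i][j], "M"), (D[i][j], "D"), (I[i][j], "I")]
    best = min(c[0] for c in cands)
    state = next(s for c, s in cands if c == best)
    penalty = best
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            is_match = ref_seq[i - 1] == alt_seq[j - 1]
            sub = p.m if is_match else p.x
            ops.append("M" if is_match else "X")
            cur = M[i][j]
            i, j = i - 1, j - 1
            # compare with the same operation order as the forward pass
            for prev_cost, prev_state in ((M[i][j], "M"), (D[i][j], "D"), (I[i][j], "I")):
                if prev_cost + sub == cur:
                    state = prev_state
                    break
            else:  # pragma: no cover - forward/backward mismatch
                raise AssertionError("traceback failed in match state")
        elif state == "D":
            ops.append("D")
            cur = D[i][j]
            i -= 1
            if D[i][j] + p.e == cur:
                state = "D"
            elif M[i][j] + oe == cur:
                state = "M"
            else:
                state = "I"
        else:
            ops.append("I")
            cur = I[i][j]
            j -= 1
            if I[i][j] + p.e == cur:
                state = "I"
            elif M[i][j] + oe == cur:
                state = "M"
            else:
                state = "D"
    ops.reverse()
    return AlignmentPath(_compress(ops), penalty)


def path_to_variants(path: AlignmentPath, ref_seq: str, alt_seq: str,
                     ref_origin: int = 0):
    """Decompose an edit path into normalized variant records.

    Substitution runs emit one SNP per base; each gap run emits a single
    INS or DEL.  Applying the result to ``ref_seq`` reproduces
    ``alt_seq`` exactly.  Returned variants are in ``vcf_io.Variant``
    form with reference offsets shifted by ``ref_origin``.
    """
    from .vcf_io import Variant  # local import to avoid a cycle

    variants = []
    i = j = 0
    for op, n in path.ops:
        if op == "M":
            i += n
            j += n
        elif op == "X":
            for k in range(n):
                variants.append(Variant(
                    start=ref_origin + i + k,
                    ref_allele=ref_seq[i + k],
                    alt_allele=alt_seq[j + k],
                ))
            i += n
            j += n
        elif op == "D":
            variants.append(Variant(
                start=ref_origin + i,
                ref_allele=ref_seq[i:i + n],
                alt_allele="",
            ))
            i += n
        else:  # I
            variants.append(Variant(
                start=ref_origin + i,
                ref_allele="",
                alt_allele=alt_seq[j:j + n],
            ))
            j += n
    return variants


def _forward_reach(ref_w: str, alt_w: str, cluster_ref_len: int,
                   budget: float, p: AffineParams) -> int:
    """Furthest reference offset (within the window) reachable off-diagonal.

    Runs a row-vectorized 3-state cost DP over the window; a cell beyond
    the cluster's reference span that lies on the final main diagonal as
    an exact match is blocked (paths must avoid the diagonal between
    clusters).  Returns the largest ref offset i with any surviving state
    cost <= budget, at least ``cluster_ref_len``.
    """
    n, m = len(ref_w), len(alt_w)
    delta = m - n  # final-diagonal shift: on-diagonal cells have j - i == delta
    oe = p.o + p.e
    ref_arr = np.frombuffer(ref_w.encode(), dtype=np.uint8)
    alt_arr = np.frombuffer(alt_w.encode(), dtype=np.uint8)

    js = np.arange(m + 1)
    M = np.full(m + 1, INF)
    D = np.full(m + 1, INF)
    M[0] = 0.0
    # row 0 insertions
    I = np.where(js > 0, p.o + js * p.e, INF)
    reach = min(cluster_ref_len, n)

    def block(row_i: int, Mrow: np.ndarray) -> np.ndarray:
        # beyond the cluster, exact matches on the final diagonal are
        # dead ends for off-diagonal extension
        if row_i <= cluster_ref_len:
            return Mrow
        jd = row_i + delta
        if 0 <= jd <= m and jd >= 1 and row_i >= 1 \
                and ref_arr[row_i - 1] == alt_arr[jd - 1]:
            Mrow = Mrow.copy()
            Mrow[jd] = INF
        return Mrow

    M = block(0, M)
    for i in range(1, n + 1):
        sub = np.where(alt_arr == ref_arr[i - 1], p.m, p.x)
        best_prev = np.minimum(np.minimum(M, D), I)
        Mn = np.full(m + 1, INF)
        Mn[1:] = best_prev[:-1] + sub
        Dn = np.minimum(np.minimum(M + oe, D + p.e), I + oe)
        Mn = block(i, Mn)
        # I row: prefix-scan of gap opens from M/D cells in this row
        base = np.minimum(Mn, Dn) + p.o
        shifted = base - js * p.e
        acc = np.minimum.accumulate(shifted)
        In = np.full(m + 1, INF)
        In[1:] = acc[:-1] + js[1:] * p.e
        M, D, I = Mn, Dn, In
        alive = np.minimum(np.minimum(M, D), I) <= budget
        if not alive.any():
            break
        reach = max(reach, i)
    return reach


def reach_extend(ref_window: str, alt_window: str, cluster_ref_len: int,
                 budget: float, p: AffineParams, direction: str = "right") -> int:
    """Bounded off-diagonal extension used by the dependency test.

    For direction ``'right'`` the window starts at the cluster's begin and
    extends rightward; ``alt_window`` is the window with the cluster's
    variants applied.  For ``'left'`` the window ends at the cluster's end
    and the extension runs leftward (implemented on reversed sequences).
    Returns the extreme window-relative reference offset reachable by any
    partial alignment path of penalty <= budget that avoids the main
    diagonal beyond the cluster.
    """
    if direction == "right":
        return _forward_reach(ref_window, alt_window, cluster_ref_len, budget, p)
    if direction != "left":
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    r = _forward_reach(ref_window[::-1], alt_window[::-1], cluster_ref_len,
                       budget, p)
    return len(ref_window) - r
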