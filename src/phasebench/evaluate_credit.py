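"""Supercluster evaluation: graph alignment, local phasing, partial credit.

Within each supercluster the two truth haplotype sequences are aligned
against each query haplotype, where the query haplotype is represented as
a reference-merged graph: every query variant can be taken wholly or
skipped wholly (a skipped variant costs nothing, since it may simply be a
false positive), but switching between the reference and the variant
branch inside a variant span is not allowed.  The pairing of truth to
query haplotypes that minimizes total edit distance determines the local
phase category of the supercluster (X: parallel, Y: crossed).

The chosen alignment paths are then cut at sync points -- reference bases
on the main diagonal outside every variant span that the path crosses as
an exact match.  Each segment between sync points is credited
independently: true positive if the query haplotype reproduces the truth
sequence there, false positive/negative if the edit distance to the truth
is no better than the reference's, and partial positive (fractional
credit 1 - ED_query/ED_ref) when the calls reduce but do not eliminate
the edit distance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_core import align_affine
from .gap_params import EDIT_PARAMS
from .supercluster import Supercluster
from .vcf_io import SNP, Variant, apply_variants

log = logging.getLogger(__name__)

_BIG = 10 ** 6

TP = "TP"
FP = "FP"
FN = "FN"
PP = "PP"


@dataclass
class CreditRecord:
    """Evaluation outcome for one variant on one haplotype."""

    variant: Variant
    role: str          # 'truth' or 'query'
    hap: int
    category: str      # TP / FP / FN / PP
    credit: float      # fraction in [0, 1]; TP=1, FP/FN=0, PP strictly between
    supercluster_id: int
    segment_id: int
    seg_min_qual: float  # min QUAL of query variants in the segment

    @property
    def var_class(self) -> str:
        return SNP if self.variant.var_class == SNP else "INDEL"


class QueryGraph:
    """Reference-merged DAG of one query haplotype over a window.

    Nodes are junctions between consumed characters; edges consume one
    reference base (``rail``), one alternate-allele base (``branch``) or
    nothing (``eps``, used to skip an insertion or take a deletion).
    Variant spans may not be entered or left mid-way by construction.
    """

    def __init__(self, window: str, variants: list[Variant]):
        self.window = window
        self.variants = variants
        # incoming[v] = list of (u, kind, char, ref_pos)
        self.incoming: list[list[tuple[int, str, str | None, int]]] = [[]]
        cur = 0
        r = 0
        for v in variants:
            s, e = v.start, v.end
            if s < r:
                raise ValueError("query variants overlap within the window")
            for j in range(r, s):
                cur = self._add_char_chain(cur, [("rail", window[j], j)])
            # build both branch chains first, then the common exit node,
            # so node ids stay topologically ordered
            pending: list[tuple[int, str, str | None, int]] = []
            if e > s:  # skip path: reference branch through the span
                node = cur
                for j in range(s, e - 1):
                    node = self._add_char_chain(node, [("rail", window[j], j)])
                pending.append((node, "rail", window[e - 1], e - 1))
            else:
                pending.append((cur, "eps", None, -1))
            if v.alt_allele:  # take path: the alternate allele
                node = cur
                for ch in v.alt_allele[:-1]:
                    node = self._add_char_chain(node, [("branch", ch, -1)])
                pending.append((node, "branch", v.alt_allele[-1], -1))
            else:
                pending.append((cur, "eps", None, -1))
            after = self._new_node()
            self.incoming[after].extend(pending)
            cur = after
            r = e
        for j in range(r, len(window)):
            cur = self._add_char_chain(cur, [("rail", window[j], j)])
        self.final = cur

    def _new_node(self) -> int:
        self.incoming.append([])
        return len(self.incoming) - 1

    def _add_char_chain(self, u: int, edges) -> int:
        for kind, ch, ref_pos in edges:
            v = self._new_node()
            self.incoming[v].append((u, kind, ch, ref_pos))
            u = v
        return u


def align_truth_to_query_graph(truth_seq: str, graph: QueryGraph):
    """Unit-cost alignment of a truth haplotype against the query graph.

    Returns ``(distance, path)`` where path is the list of backtraced
    steps ``(step_kind, ref_pos, truth_idx)`` with step_kind in
    {'match', 'sub', 'del', 'ins', 'eps'}; ref_pos is the window-relative
    reference offset for rail edges and -1 otherwise.
    """
    T = len(truth_seq)
    truth_arr = np.frombuffer(truth_seq.encode(), dtype=np.uint8)
    ts = np.arange(T + 1, dtype=np.int32)
    n_nodes = len(graph.incoming)
    dist = np.full((n_nodes, T + 1), _BIG, dtype=np.int32)
    dist[0] = ts  # leading truth insertions
    for v in range(1, n_nodes):
        dv = dist[v]
        for u, kind, ch, _pos in graph.incoming[v]:
            du = dist[u]
            if kind == "eps":
                np.minimum(dv, du, out=dv)
            else:
                mism = (truth_arr != ord(ch)).astype(np.int32)
                dv[1:] = np.minimum(dv[1:], du[:-1] + mism)  # diagonal
                np.minimum(dv, du + 1, out=dv)               # delete graph char
        # truth insertions: prefix scan
        dv[:] = np.minimum.accumulate(dv - ts) + ts
    d = int(dist[graph.final, T])

    # Backtrace with deterministic preference: diagonal match, diagonal
    # substitution, eps, graph deletion, truth insertion.
    steps: list[tuple[str, int, int]] = []
    v, t = graph.final, T
    while v != 0 or t != 0:
        cur = int(dist[v, t])
        moved = False
        if t > 0:
            for u, kind, ch, pos in graph.incoming[v]:
                if kind != "eps" and truth_seq[t - 1] == ch \
                        and dist[u, t - 1] == cur:
                    steps.append(("match", pos, t - 1))
                    v, t = u, t - 1
                    moved = True
                    break
            if not moved:
                for u, kind, ch, pos in graph.incoming[v]:
                    if kind != "eps" and truth_seq[t - 1] != ch \
                            and dist[u, t - 1] + 1 == cur:
                        steps.append(("sub", pos, t - 1))
                        v, t = u, t - 1
                        moved = True
                        break
        if not moved:
            for u, kind, ch, pos in graph.incoming[v]:
                if kind == "eps" and dist[u, t] == cur:
                    steps.append(("eps", pos, t))
                    v = u
                    moved = True
                    break
        if not moved:
            for u, kind, ch, pos in graph.incoming[v]:
                if kind != "eps" and dist[u, t] + 1 == cur:
                    steps.append(("del", pos, t))
                    v = u
                    moved = True
                    break
        if not moved:
            if t > 0 and dist[v, t - 1] + 1 == cur:
                steps.append(("ins", -1, t - 1))
                t -= 1
                moved = True
        if not moved:  # pragma: no cover - DP/backtrace mismatch
            raise AssertionError("graph alignment backtrace failed")
    steps.reverse()
    return d, steps


def find_sync_points(path, truth_variants: list[Variant],
                     query_variants: list[Variant]) -> list[int]:
    """Reference offsets the path crosses on the main diagonal.

    A sync point is a reference base that (a) lies outside every truth and
    query variant span, (b) the path matches on the reference rail, and
    (c) is matched in register: the truth character aligned to it is the
    one that maps there once all preceding truth variants are accounted
    for.  Without (c), two equivalent-but-shifted insertions would be cut
    into separate segments by the coincidental matches between their
    junctions.
    """
    spans = [(v.start, v.end) for v in truth_variants + query_variants]
    shifts = sorted((v.end, len(v.alt_allele) - len(v.ref_allele))
                    for v in truth_variants)

    def in_span(pos: int) -> bool:
        return any(s <= pos < e for s, e in spans)

    def truth_shift(pos: int) -> int:
        return sum(d for end, d in shifts if end <= pos)

    return sorted({pos for kind, pos, t in path
                   if kind == "match" and pos >= 0 and not in_span(pos)
                   and t == pos + truth_shift(pos)})


def _levenshtein(a: str, b: str) -> int:
    return int(align_affine(a, b, EDIT_PARAMS).penalty)


def credit_segment(window: str, seg: tuple[int, int],
                   truth_vars: list[Variant], query_vars: list[Variant],
                   sc_id: int, seg_id: int, truth_hap: int,
                   query_hap: int) -> list[CreditRecord]:
    """Assign one shared category and credit to all variants of a segment."""
    if not truth_vars and not query_vars:
        return []
    a, b = seg
    ref_seg = window[a:b]
    truth_seg = apply_variants(ref_seg, truth_vars, origin=a)
    query_seg = apply_variants(ref_seg, query_vars, origin=a)
    ed_ref = _levenshtein(ref_seg, truth_seg)
    ed_query = _levenshtein(truth_seg, query_seg)

    if ed_query == 0:
        category, credit = TP, 1.0
    elif ed_query >= ed_ref:
        if ed_query > ed_ref:
            log.debug("segment %d/%d: query worsens edit distance (%d > %d)",
                      sc_id, seg_id, ed_query, ed_ref)
        category, credit = FP, 0.0
    else:
        category, credit = PP, 1.0 - ed_query / ed_ref
    seg_min_qual = min((v.qual for v in query_vars), default=math.inf)

    records = []
    for v in truth_vars:
        cat = {TP: TP, FP: FN, PP: PP}[category]
        records.append(CreditRecord(v, "truth", truth_hap, cat, credit,
                                    sc_id, seg_id, seg_min_qual))
    for v in query_vars:
        records.append(CreditRecord(v, "query", query_hap, category, credit,
                                    sc_id, seg_id, seg_min_qual))
    return records


def _segment_credits(window: str, path, truth_vars, query_vars,
                     sc_id, truth_hap, query_hap) -> list[CreditRecord]:
    syncs = find_sync_points(path, truth_vars, query_vars)
    bounds = [-1] + syncs + [len(window)]
    records: list[CreditRecord] = []
    seg_id = 0
    for lo, hi in zip(bounds, bounds[1:]):
        a, b = lo + 1, hi
        tv = [v for v in truth_vars if v.start >= a and v.end <= b]
        qv = [v for v in query_vars if v.start >= a and v.end <= b]
        if not tv and not qv:
            continue
        records.extend(credit_segment(window, (a, b), tv, qv, sc_id, seg_id,
                                      truth_hap, query_hap))
        seg_id += 1
    return records


def select_phasing(distances: list[list[int]]) -> str | None:
    """X if parallel pairing is strictly better, Y if crossed, else None."""
    d_x = distances[0][0] + distances[1][1]
    d_y = distances[0][1] + distances[1][0]
    if d_x < d_y:
        return "X"
    if d_y < d_x:
        return "Y"
    return None


def evaluate_supercluster(sc: Supercluster, ref_seq: str,
                          sc_id: int) -> list[CreditRecord]:
    """Four-way alignment, phasing selection and credit for one supercluster.

    Fills in ``sc.distances`` and ``sc.phase`` and returns the credit
    records of both chosen haplotype pairings (in window-relative
    coordinates converted back to absolute offsets).
    """
    window = ref_seq[sc.begin:sc.end]
    shift = -sc.begin
    truth = [[v.shifted(shift) for v in sc.variants("truth", h)] for h in (0, 1)]
    query = [[v.shifted(shift) for v in sc.variants("query", h)] for h in (0, 1)]
    graphs = [QueryGraph(window, qv) for qv in query]
    truth_seqs = [apply_variants(window, tv) for tv in truth]

    distances = [[0, 0], [0, 0]]
    paths = {}
    for t, q in itertools.product((0, 1), (0, 1)):
        d, path = align_truth_to_query_graph(truth_seqs[t], graphs[q])
        distances[t][q] = d
        paths[(t, q)] = path
    sc.distances = distances
    sc.phase = select_phasing(distances)

    pairing = ((0, 1), (1, 0)) if sc.phase == "Y" else ((0, 0), (1, 1))
    records: list[CreditRecord] = []
    for t, q in pairing:
        recs = _segment_credits(window, paths[(t, q)], truth[t], query[q],
                                sc_id, t, q)
        for r in recs:
            r.variant = r.variant.shifted(sc.begin)
        records.extend(recs)
    return records


def qscore(error: float, cap: float = 100.0) -> float:
    """Phred-like transform -10*log10(error), capped for zero error."""
    if error <= 0:
        return cap
    return min(cap, -10.0 * math.log10(error))


def f1_qscore(f1: float) -> float:
    return qscore(1.0 - f1)


def summarize(credits: list[CreditRecord],
              qual_thresholds: list[float] | None = None) -> pd.DataFrame:
    """Precision/recall/F1 per variant class over quality thresholds.

    The sweep retains, at threshold t, only segments whose supporting
    query variants all have QUAL >= t (truth variants are always
    retained; their segments fall back to false negatives when support is
    filtered out).  Counts are real-valued because partial positives
    contribute fractional credit; per-haplotype counts are summed, so a
    homozygous false positive counts twice.  Precision uses truth-side
    true positives: TP_truth / (TP_truth + FP_query).
    """
    if qual_thresholds is None:
        quals = sorted({r.variant.qual for r in credits if r.role == "query"})
        qual_thresholds = quals or [0.0]
    rows = []
    for cls in ("SNP", "INDEL"):
        cls_truth = [r for r in credits if r.role == "truth" and r.var_class == cls]
        cls_query = [r for r in credits if r.role == "query" and r.var_class == cls]
        for t in qual_thresholds:
            tp_truth = sum(r.credit for r in cls_truth if r.seg_min_qual >= t)
            fn_truth = len(cls_truth) - tp_truth
            kept_query = [r for r in cls_query if r.variant.qual >= t
                          and r.seg_min_qual >= t]
            tp_query = sum(r.credit for r in kept_query)
            fp_query = sum(1.0 - r.credit for r in kept_query)
            prec_den = tp_truth + fp_query
            rec_den = tp_truth + fn_truth
            precision = tp_truth / prec_den if prec_den > 0 else float("nan")
            recall = tp_truth / rec_den if rec_den > 0 else float("nan")
            if precision + recall > 0:
                f1 = 2 * precision * recall / (precision + recall)
            else:
                f1 = 0.0 if not math.isnan(precision + recall) else float("nan")
            rows.append({
                "class": cls, "threshold": t,
                "tp_query": tp_query, "tp_truth": tp_truth,
                "fp_query": fp_query, "fn_truth": fn_truth,
                "precision": precision, "recall": recall, "f1": f1,
                "f1_qscore": f1_qscore(f1) if not math.isnan(f1) else float("nan"),
            })
    return pd.DataFrame(rows)


def best_f1(summary: pd.DataFrame) -> pd.DataFrame:
    """Row with the maximum F1 per variant class (reported operating point)."""
    rows = []
    for cls, grp in summary.groupby("class"):
        grp = grp.dropna(subset=["f1"])
        if len(grp) == 0:
            continue
        rows.append(grp.loc[grp["f1"].idxmax()])
    return pd.DataFrame(rows).reset_index(drop=True)


def enumerate_local_phasings(variants: list[Variant]):
    """All per-variant haplotype assignments of heterozygous variants.

    Yields one (hap0 list, hap1 list) pair per assignment; k heterozygous
    variants admit 2**k local phasings, each producing a (possibly
    distinct) pair of haplotype sequences.
    """
    k = len(variants)
    for bits in itertools.product((0, 1), repeat=k):
        hap0 = [v for v, b in zip(variants, bits) if b == 0]
        hap1 = [v for v, b in zip(variants, bits) if b == 1]
        yield hap0, hap1
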