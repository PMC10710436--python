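"""Partitioning haplotype variants into independent clusters.

Two groups of variants on one haplotype are dependent when an optimal
alignment path between their joint representations can stay off the main
reference diagonal in the gap between them without exceeding the penalty
of their original representation.  Dependent variants admit multiple
equivalent VCF representations and must be standardized and evaluated
jointly; independent clusters can be treated in isolation.

Two clustering modes are provided: the alignment-aware iterative
reach-merging algorithm (default) and a cheap positional gap heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_core import align_affine, reach_extend
from .gap_params import AffineParams, get_preset
from .vcf_io import DEL, INS, SNP, Variant, apply_variants

log = logging.getLogger(__name__)

#: maximum off-cluster extension considered when computing stored reaches
REACH_CAP = 200


@dataclass
class Cluster:
    """Ordered dependent variants on one haplotype of one callset."""

    contig: str
    hap: int
    role: str
    variants: list[Variant]
    begin: int = 0
    end: int = 0
    left_reach: int = 0
    right_reach: int = 0
    penalty: float = 0.0
    std_variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variants:
            self.begin = min(v.start for v in self.variants)
            self.end = max(v.end for v in self.variants)
            self.left_reach = self.begin
            self.right_reach = self.end


def variant_penalty(v: Variant, p: AffineParams) -> float:
    """Penalty of one variant in its current (original) representation."""
    if v.var_class == SNP:
        return p.x
    if v.var_class == INS:
        return p.gap_cost(len(v.alt_allele))
    if v.var_class == DEL:
        return p.gap_cost(len(v.ref_allele))
    return align_affine(v.ref_allele, v.alt_allele, p).penalty


def cluster_penalty(variants: list[Variant], p: AffineParams) -> float:
    return sum(variant_penalty(v, p) for v in variants)


def make_cluster(contig: str, hap: int, role: str, variants: list[Variant],
                 p: AffineParams) -> Cluster:
    c = Cluster(contig, hap, role, list(variants))
    c.penalty = cluster_penalty(variants, p)
    return c


def right_reach(c: Cluster, ref: str, p: AffineParams, cap: int) -> int:
    """Rightmost reference offset reachable off-diagonal within budget."""
    cap = min(cap, len(ref))
    window = ref[c.begin:cap]
    alt = apply_variants(window, c.variants, origin=c.begin)
    off = reach_extend(window, alt, c.end - c.begin, c.penalty, p, "right")
    return c.begin + off


def left_reach(c: Cluster, ref: str, p: AffineParams, cap: int) -> int:
    """Leftmost reference offset reachable off-diagonal within budget."""
    cap = max(cap, 0)
    window = ref[cap:c.end]
    alt = apply_variants(window, c.variants, origin=cap)
    off = reach_extend(window, alt, c.end - c.begin, c.penalty, p, "left")
    return cap + off


def clusters_dependent(a: Cluster, b: Cluster, ref: str, p: AffineParams) -> bool:
    """True when budget-limited off-diagonal extensions of a and b can meet.

    ``a`` must lie entirely left of ``b`` on the same haplotype.  The
    forward reach of ``a`` and the backward reach of ``b`` are each
    limited to the other cluster's boundary; the clusters are dependent
    when ``b``'s leftmost reach does not exceed ``a``'s rightmost reach.
    """
    if a.end > b.begin:
        raise ValueError("clusters overlap or are out of order")
    a_right = right_reach(a, ref, p, b.begin)
    b_left = left_reach(b, ref, p, a.end)
    return b_left <= a_right


def joint_realignment_cheaper(a: Cluster, b: Cluster, ref: str,
                              p: AffineParams) -> bool:
    """Exact dependence check: joint realignment strictly beats separate.

    If every optimal alignment path of the combined window returns to the
    main diagonal between the clusters, the optimal joint penalty equals
    the sum of the two windows' separate optima (the path decomposes at a
    diagonal base in the gap).  A strictly cheaper joint optimum therefore
    certifies that some optimal path stays off-diagonal between the
    clusters -- the definition of dependence -- even when the
    budget-limited reach heuristic misses it.  Only worth testing when the
    gap is bridgeable: crossing costs at least e per base.
    """
    gap = b.begin - a.end
    if gap > min(100.0, (a.penalty + b.penalty) / p.e):
        return False
    lo = max(0, a.begin - 1)
    hi = min(len(ref), b.end + 1)
    mid = (a.end + b.begin + 1) // 2
    joint_alt = apply_variants(ref[lo:hi], a.variants + b.variants, origin=lo)
    joint = align_affine(ref[lo:hi], joint_alt, p).penalty
    left_alt = apply_variants(ref[lo:mid], a.variants, origin=lo)
    right_alt = apply_variants(ref[mid:hi], b.variants, origin=mid)
    separate = align_affine(ref[lo:mid], left_alt, p).penalty \
        + align_affine(ref[mid:hi], right_alt, p).penalty
    return joint < separate


def gap_cluster(variants: list[Variant], gap_size: int = 50, *,
                contig: str = "", hap: int = 0, role: str = "query",
                p: AffineParams | None = None) -> list[Cluster]:
    """Positional clustering: merge variants separated by < gap_size bases."""
    p = p or get_preset("C")
    clusters: list[Cluster] = []
    group: list[Variant] = []
    for v in variants:
        if group and v.start - max(g.end for g in group) >= gap_size:
            clusters.append(make_cluster(contig, hap, role, group, p))
            group = []
        group.append(v)
    if group:
        clusters.append(make_cluster(contig, hap, role, group, p))
    return clusters


def iterative_cluster(variants: list[Variant], ref: str,
                      p: AffineParams | None = None, max_iters: int = 100, *,
                      contig: str = "", hap: int = 0,
                      role: str = "query") -> list[Cluster]:
    """Reach-based clustering to a fixpoint of adjacent merges.

    Each variant starts in its own cluster; adjacent dependent clusters
    are merged until no cluster grows (or ``max_iters`` sweeps).
    """
    p = p or get_preset("C")
    clusters = [make_cluster(contig, hap, role, [v], p) for v in variants]
    for _ in range(max_iters):
        if len(clusters) < 2:
            return clusters
        merged: list[Cluster] = [clusters[0]]
        changed = False
        for nxt in clusters[1:]:
            cur = merged[-1]
            if clusters_dependent(cur, nxt, ref, p) \
                    or joint_realignment_cheaper(cur, nxt, ref, p):
                merged[-1] = make_cluster(contig, hap, role,
                                          cur.variants + nxt.variants, p)
                changed = True
            else:
                merged.append(nxt)
        clusters = merged
        if not changed:
            return clusters
    log.warning("clustering did not converge within %d iterations", max_iters)
    return clusters


def compute_reaches(clusters: list[Cluster], ref: str,
                    p: AffineParams | None = None) -> None:
    """Fill in stored left/right reaches, capped at neighbouring clusters."""
    p = p or get_preset("C")
    for i, c in enumerate(clusters):
        lo = clusters[i - 1].end if i > 0 else 0
        hi = clusters[i + 1].begin if i + 1 < len(clusters) else len(ref)
        c.left_reach = left_reach(c, ref, p, max(lo, c.begin - REACH_CAP))
        c.right_reach = right_reach(c, ref, p, min(hi, c.end + REACH_CAP))
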