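"""Grouping truth and query clusters into independent evaluation units.

Clusters from all four haplotypes (two truth, two query) whose reach
intervals come within a fixed distance (default 50 bp) of one another are
grouped transitively into a supercluster.  Superclusters are fully
independent: truth-to-query alignment, local phasing selection and credit
assignment all happen within one supercluster at a time.  A supercluster
may contain clusters from any subset of the four haplotypes; query-only
superclusters yield false-positive candidates and truth-only ones yield
false-negative candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clustering import Cluster

#: default merge distance between cluster reaches, in bases
SUPERCLUSTER_GAP = 50

#: reference context retained on each side of a supercluster window
_WINDOW_MARGIN = 1


@dataclass
class Supercluster:
    """All truth and query clusters of one independent evaluation window."""

    contig: str
    begin: int
    end: int
    #: member clusters keyed (role, hap): truth/query x 0/1
    clusters: dict[tuple[str, int], list[Cluster]] = field(default_factory=dict)
    #: phase category assigned later: 'X', 'Y' or None (uncategorized)
    phase: str | None = None
    #: 2x2 matrix of graph-alignment edit distances [truth hap][query hap]
    distances: list[list[int]] | None = None

    def members(self, role: str, hap: int) -> list[Cluster]:
        return self.clusters.get((role, hap), [])

    def variants(self, role: str, hap: int):
        return [v for c in self.members(role, hap) for v in c.variants]

    def all_clusters(self) -> list[Cluster]:
        return [c for lst in self.clusters.values() for c in lst]


def build_superclusters(truth_clusters: dict[int, list[Cluster]],
                        query_clusters: dict[int, list[Cluster]],
                        contig: str, contig_len: int,
                        distance: int = SUPERCLUSTER_GAP) -> list[Supercluster]:
    """Transitive closure of the "reaches within ``distance``" relation.

    Input cluster lists are per haplotype index and must be sorted; their
    ``left_reach``/``right_reach`` fields encode the extent of possible
    representation drift (positional clustering falls back to the spans).
    Returns sorted, disjoint superclusters covering every input cluster.
    """
    tagged: list[tuple[int, int, str, int, Cluster]] = []
    for role, per_hap in (("truth", truth_clusters), ("query", query_clusters)):
        for hap, clusters in per_hap.items():
            for c in clusters:
                tagged.append((c.left_reach, c.right_reach, role, hap, c))
    tagged.sort(key=lambda t: (t[0], t[1]))

    out: list[Supercluster] = []
    cur: Supercluster | None = None
    cur_right = 0
    for lo, hi, role, hap, c in tagged:
        if cur is None or lo - cur_right > distance:
            cur = Supercluster(contig, begin=lo, end=hi)
            out.append(cur)
            cur_right = hi
        cur.clusters.setdefault((role, hap), []).append(c)
        cur.begin = min(cur.begin, lo)
        cur.end = max(cur.end, hi)
        cur_right = max(cur_right, hi)

    for sc in out:
        sc.begin = max(0, sc.begin - _WINDOW_MARGIN)
        sc.end = min(contig_len, sc.end + _WINDOW_MARGIN)
    return out
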