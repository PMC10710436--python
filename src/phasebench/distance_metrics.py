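"""Representation-independent distances between haplotype sequences.

Two complementary measures are derived from one alignment: the edit
distance ED (number of edited bases) and the distinct edits DE (number of
edit events -- each substituted base and each gap counts once).  The
alignment minimizes 2*DE + ED globally, which is exactly affine-gap
alignment at penalties (m, x, o, e) = (0, 3, 2, 1): a substitution (3)
adds one to both DE (x2) and ED, opening a gap (2) adds one DE, and each
gap base (1) adds one ED.  Note the reported ED is the edit distance of
the 2*DE+ED-optimal path, which can exceed the Levenshtein minimum.

These metrics see only the truth and query sequences, so they are
invariant to how the variants were represented in the VCF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment_core import align_affine
from .evaluate_credit import qscore
from .gap_params import AffineParams, get_preset


def ed_de(a: str, b: str) -> tuple[int, int]:
    """(edit distance, distinct edits) of the 2*DE+ED-optimal alignment."""
    path = align_affine(a, b, get_preset("B"))
    ed = de = 0
    for op, n in path.ops:
        if op == "X":
            ed += n
            de += n
        elif op in "DI":
            ed += n
            de += 1
    return ed, de


def aln_distance(a: str, b: str, p: AffineParams | None = None) -> float:
    """Minimum affine alignment penalty, by default at the standard point C."""
    return align_affine(a, b, p or get_preset("C")).penalty


@dataclass
class DistanceSummary:
    """Distances of query-vs-truth and reference-vs-truth, with Q-scores."""

    ed_query: float
    de_query: float
    aln_query: float
    ed_ref: float
    de_ref: float
    aln_ref: float

    @property
    def ed_qscore(self) -> float:
        return distance_qscore(self.ed_query, self.ed_ref)

    @property
    def de_qscore(self) -> float:
        return distance_qscore(self.de_query, self.de_ref)

    @property
    def aln_qscore(self) -> float:
        return distance_qscore(self.aln_query, self.aln_ref)


def distance_qscore(query_term: float, ref_term: float,
                    cap: float = 100.0) -> float:
    """-10*log10(query/ref); capped when the query term is 0, NaN when the
    reference term is 0 (no baseline to compare against)."""
    if ref_term <= 0:
        return float("nan")
    return qscore(query_term / ref_term, cap=cap)
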