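"""Affine-gap penalty schemes and the variant-representation design space.

A variant representation is determined by the affine-gap penalties used to
align a haplotype back to the reference: match ``m``, substitution ``x``,
and a gap of length ``n`` costing ``g(n) = o + n*e`` with opening penalty
``o`` and extension penalty ``e``.  Different aligners occupy different
points of this design space and therefore emit different (but
sequence-equivalent) VCF representations of the same complex variant.

Penalty tuples can be brought to a normalized form with ``m = 0`` and
``x = 1`` without changing which alignments are optimal, which makes
aligner parameter sets directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AffineParams:
    """Affine-gap penalty tuple ``(m, x, o, e)``.

    All penalties are costs (non-negative; larger is worse).  A gap of
    length ``n`` costs ``o + n*e``, so the first gap base costs ``o + e``.
    """

    m: float
    x: float
    o: float
    e: float

    def __post_init__(self) -> None:
        if self.o < 0 or self.e <= 0 or self.x <= 0 or self.m < 0:
            raise ValueError(
                f"invalid affine parameters (m={self.m}, x={self.x}, "
                f"o={self.o}, e={self.e}): require m,o >= 0 and x,e > 0"
            )

    def gap_cost(self, n: int) -> float:
        """Cost of a gap of length ``n`` bases."""
        if n <= 0:
            return 0.0
        return self.o + n * self.e

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.m, self.x, self.o, self.e)


@dataclass(frozen=True)
class DoubleAffineParams:
    """Two-piece affine gap model: cost of a gap is min(g1(n), g2(n)).

    Conventionally the second piece has a higher opening penalty and a
    lower extension penalty (o2 > o1, e2 < e1), so short gaps are priced
    by the first piece and long gaps by the second.
    """

    first: AffineParams
    second: AffineParams

    def __post_init__(self) -> None:
        if not (self.second.o > self.first.o and self.second.e < self.first.e):
            raise ValueError("double-affine model requires o2 > o1 and e2 < e1")

    def gap_cost(self, n: int) -> float:
        return min(self.first.gap_cost(n), self.second.gap_cost(n))


def normalize_params(p: AffineParams) -> AffineParams:
    """Normalize a penalty tuple to ``m = 0`` and ``x = 1``.

    Two transforms that leave the set of optimal global alignment paths
    unchanged are composed:

    1. shifting the match reward into the other penalties
       (``x + m``, ``o + m/2``, ``e + m/2``) -- every alignment of the
       same sequence pair contains the same total number of aligned plus
       gapped bases, so a constant per-base shift reorders nothing;
    2. dividing all penalties by the (new) substitution penalty, a
       positive rescaling.

    Idempotent: normalizing an already-normalized tuple is the identity.
    """
    x = p.x + p.m
    if x == 0:
        raise ValueError("cannot normalize: x + m == 0")
    o = p.o + p.m / 2.0
    e = p.e + p.m / 2.0
    return AffineParams(0.0, 1.0, o / x, e / x)


def snp_decomposes(p: AffineParams) -> bool:
    """True if a substitution is cheaper expressed as a 1-bp INS + 1-bp DEL.

    In the normalized design space this is the region ``2*(o + e) < x``;
    aligners there never report SNPs.  The boundary itself keeps the
    substitution.
    """
    return 2.0 * (p.o + p.e) < p.x


def double_affine_crossover(d: DoubleAffineParams) -> float:
    """Gap length at which the two affine pieces cost the same.

    ``n = (o2 - o1) / (e1 - e2)``; below this length the first piece is
    cheaper, above it the second.
    """
    e_diff = d.first.e - d.second.e
    if e_diff == 0:
        raise ValueError("crossover undefined when e1 == e2")
    return (d.second.o - d.first.o) / e_diff


# Named design points.  B and C use the exact printed integer penalties:
# B = (0, 3, 2, 1) jointly minimizes 2*DE + ED; C = (0, 5, 6, 2) is the
# proposed reporting standard (centroid of common read aligners).
# A and D are representative placeholders for the copy-number-aligner and
# assembly-aligner corners of the design space: A must satisfy
# snp_decomposes (2*(o+e) < x) and D must penalize gaps more than C does.
PRESETS: dict[str, AffineParams] = {
    "A": AffineParams(0, 8, 1, 1),
    "B": AffineParams(0, 3, 2, 1),
    "C": AffineParams(0, 5, 6, 2),
    "D": AffineParams(0, 2, 4, 1),
}

#: Unit-cost (Levenshtein-equivalent) parameters: gap of length n costs n.
EDIT_PARAMS = AffineParams(0, 1, 0, 1)


def get_preset(name: str) -> AffineParams:
    try:
        return PRESETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def parse_params(spec: str) -> AffineParams:
    """Parse ``'m,x,o,e'`` or a preset name into an AffineParams."""
    if "," in spec:
        parts = [float(v) for v in spec.split(",")]
        if len(parts) != 4:
            raise ValueError(f"expected 4 comma-separated penalties, got {spec!r}")
        return AffineParams(*parts)
    return get_preset(spec)
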