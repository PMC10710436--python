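import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasebench.alignment_core import align_affine, path_to_variants, reach_extend
from phasebench.gap_params import EDIT_PARAMS, AffineParams, get_preset
from phasebench.vcf_io import apply_variants

from .conftest import random_dna
from .oracles import brute_force_reach, dijkstra_affine, exhaustive_min_penalty

dna = st.text(alphabet="ACGT", min_size=0, max_size=10)


class TestAlignAffine:
    def test_identity(self, point_c):
        path = align_affine("ACGT", "ACGT", point_c)
        assert path.ops == [("M", 4)] and path.penalty == 0

    def test_single_substitution_at_c(self, point_c):
        # one substitution (5) beats two 1-bp gaps (2*(6+2)=16)
        path = align_affine("ACGT", "AGGT", point_c)
        assert path.ops == [("M", 1), ("X", 1), ("M", 2)]
        assert path.penalty == 5

    def test_snp_decomposes_at_a(self):
        # at A, 2(o+e)=4 < x=8: the SNP becomes a 1-bp INS + 1-bp DEL
        path = align_affine("ACGT", "AGGT", get_preset("A"))
        assert path.penalty == 4
        ops = {op for op, _ in path.ops}
        assert "X" not in ops and {"I", "D"} <= ops

    def test_gaps_left_shifted(self, point_c):
        path = align_affine("GGGG", "GG", point_c)
        assert path.ops == [("D", 2), ("M", 2)]
        assert path.penalty == point_c.gap_cost(2)

    def test_empty_sequences(self, point_c):
        assert align_affine("", "", point_c).ops == []
        assert align_affine("ACG", "", point_c).penalty == point_c.gap_cost(3)
        assert align_affine("", "ACG", point_c).penalty == point_c.gap_cost(3)

    @pytest.mark.parametrize("preset", ["A", "B", "C", "D"])
    def test_matches_shortest_path_oracle(self, rng, preset):
        p = get_preset(preset)
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(0, 9)))
            b = random_dna(rng, int(rng.integers(0, 9)))
            assert align_affine(a, b, p).penalty == dijkstra_affine(a, b, p)

    def test_matches_exhaustive_enumeration(self, rng, point_c):
        for _ in range(25):
            a = random_dna(rng, int(rng.integers(1, 6)))
            b = random_dna(rng, int(rng.integers(1, 6)))
            assert align_affine(a, b, point_c).penalty == \
                exhaustive_min_penalty(a, b, point_c)

    def test_unit_costs_equal_levenshtein(self, rng):
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(1, 30)))
            b = random_dna(rng, int(rng.integers(1, 30)))
            expected = edlib.align(a, b)["editDistance"]
            assert align_affine(a, b, EDIT_PARAMS).penalty == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=dna, b=dna)
    def test_penalty_recomputes_from_ops(self, a, b):
        p = get_preset("C")
        path = align_affine(a, b, p)
        assert path.recompute_penalty(p) == pytest.approx(path.penalty)
        assert path.ref_len() == len(a) and path.query_len() == len(b)


class TestPathToVariants:
    def test_all_match_is_empty(self, point_c):
        path = align_affine("ACGT", "ACGT", point_c)
        assert path_to_variants(path, "ACGT", "ACGT") == []

    def test_substitution_becomes_snp(self, point_c):
        path = align_affine("ACGT", "AGGT", point_c)
        (v,) = path_to_variants(path, "ACGT", "AGGT")
        assert (v.start, v.ref_allele, v.alt_allele) == (1, "C", "G")
        assert v.var_class == "SNP"

    def test_deletion_left_shifted(self, point_c):
        path = align_affine("GGGG", "GG", point_c)
        (v,) = path_to_variants(path, "GGGG", "GG")
        assert (v.start, v.ref_allele, v.alt_allele) == (0, "GG", "")
        assert apply_variants("GGGG", [v]) == "GG"

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(a=dna, b=dna)
    def test_round_trip_reproduces_alt(self, a, b):
        """Decomposing any optimal path must be representation-preserving."""
        p = get_preset("C")
        variants = path_to_variants(align_affine(a, b, p), a, b)
        assert apply_variants(a, variants) == b
        for u, v in zip(variants, variants[1:]):
            assert u.end <= v.start

    def test_origin_offset(self, point_c):
        path = align_affine("ACGT", "AGGT", point_c)
        (v,) = path_to_variants(path, "ACGT", "AGGT", ref_origin=100)
        assert v.start == 101


class TestReachExtend:
    def test_zero_budget_no_extension(self, point_c):
        # empty cluster: reach stays at its own boundary
        assert reach_extend("ACGTAC", "ACGTAC", 0, 0.0, point_c) == 0

    def test_homopolymer_insertion_covers_run(self, point_c):
        # 1-bp insertion can sit anywhere in the A-run at equal cost, so the
        # reach spans at least the whole run; exact value from enumeration
        ref = "AAAATGC"
        alt = "A" + ref
        budget = point_c.gap_cost(1)
        reach = reach_extend(ref, alt, 0, budget, point_c, "right")
        assert reach >= 4  # at least the full homopolymer run
        assert reach == brute_force_reach(ref, alt, 0, budget, point_c)

    def test_isolated_snp_budget_too_small(self, point_c):
        # budget x=5 < o+e=8: no off-diagonal gap affordable
        ref = "CATGCATG"
        alt = "CGTGCATG"  # SNP at offset 1... cluster [1, 2)
        reach = reach_extend(ref[1:], alt[1:], 1, point_c.x, point_c, "right")
        assert reach == 1

    def test_matches_brute_force_enumeration(self, rng):
        for preset in ("A", "C"):
            p = get_preset(preset)
            for _ in range(30):
                ref = random_dna(rng, 8)
                # plant a 1-bp change to form the cluster alt
                alt = ("" if rng.random() < 0.5 else ref[0]) + ref[1:]
                cluster_len = 1 if len(alt) == len(ref) else 1
                budget = float(p.x if len(alt) == len(ref) else p.gap_cost(1))
                got = reach_extend(ref, alt, cluster_len, budget, p, "right")
                expected = brute_force_reach(ref, alt, cluster_len, budget, p)
                assert got == expected, (ref, alt, preset)

    def test_left_direction_mirrors_right(self, point_c):
        ref = "TGCAAAA"
        alt = ref + "A"  # insertion at the right edge of the A-run
        budget = point_c.gap_cost(1)
        reach = reach_extend(ref, alt, 0, budget, point_c, "left")
        assert reach <= 3  # extends left at least across the A-run
        mirrored = brute_force_reach(ref[::-1], alt[::-1], 0, budget, point_c)
        assert reach == len(ref) - mirrored
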