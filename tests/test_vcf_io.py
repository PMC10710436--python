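import pytest

from phasebench.fixtures import make_fixture
from phasebench.vcf_io import (HaplotypeCallset, Variant, apply_variants,
                               read_bed, read_phased_vcf, trim_alleles,
                               write_fasta, write_vcf)


def _write_vcf_text(path, records, contig="chr1", length=100):
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for pos, ref, alt, qual, gt in records:
        lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT\t{gt}")
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestApplyVariants:
    def test_identity(self):
        assert apply_variants("AAAA", []) == "AAAA"

    def test_snp(self):
        assert apply_variants("ACGT", [Variant(1, "C", "G")]) == "AGGT"

    def test_deletion(self):
        assert apply_variants("GGGG", [Variant(0, "GG", "")]) == "GG"

    def test_insertion_order_preserved_at_same_junction(self):
        vs = [Variant(2, "", "T"), Variant(2, "", "A")]
        assert apply_variants("CCCC", vs) == "CCTACC"

    def test_length_identity(self, rng):
        ref = "ACGTACGTAC"
        vs = [Variant(1, "C", "T"), Variant(4, "AC", ""), Variant(8, "", "GG")]
        out = apply_variants(ref, vs)
        expected = len(ref) - sum(len(v.ref_allele) for v in vs) \
            + sum(len(v.alt_allele) for v in vs)
        assert len(out) == expected

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            apply_variants("ACGT", [Variant(0, "AC", ""), Variant(1, "C", "G")])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            apply_variants("ACGT", [Variant(3, "TT", "")])


class TestTrimming:
    def test_forced_prefix_suffix_trim(self):
        assert trim_alleles(0, "ACGT", "AGGT") == (1, "C", "G")

    def test_trim_to_insertion(self):
        assert trim_alleles(5, "A", "AT") == (6, "", "T")

    def test_idempotent(self):
        start, r, a = trim_alleles(0, "ACGT", "AGGT")
        assert trim_alleles(start, r, a) == (start, r, a)


class TestReadWrite:
    def test_het_split_and_trim(self, tmp_path):
        path = _write_vcf_text(tmp_path / "a.vcf",
                               [(1, "ACGT", "AGGT", 30, "1|0")])
        cs = read_phased_vcf(path)
        hap0, hap1 = cs.haps("chr1")
        assert [(v.start, v.ref_allele, v.alt_allele) for v in hap0] == \
            [(1, "C", "G")]
        assert hap1 == []

    def test_homref_record_contributes_nothing(self, tmp_path):
        path = _write_vcf_text(tmp_path / "a.vcf", [(5, "A", "T", 30, "0|0")])
        cs = read_phased_vcf(path)
        assert cs.n_variants() == 0

    def test_unphased_het_rejected(self, tmp_path):
        path = _write_vcf_text(tmp_path / "a.vcf", [(5, "A", "T", 30, "1/0")])
        with pytest.raises(ValueError, match="phased"):
            read_phased_vcf(path)

    def test_haploid_rejected_unless_skipped(self, tmp_path):
        path = _write_vcf_text(tmp_path / "a.vcf", [(5, "A", "T", 30, "1")])
        with pytest.raises(ValueError, match="diploid"):
            read_phased_vcf(path)
        assert read_phased_vcf(path, skip_bad_genotypes=True).n_variants() == 0

    def test_multiallelic_split(self, tmp_path):
        path = _write_vcf_text(tmp_path / "a.vcf", [(5, "A", "T,G", 30, "1|2")])
        cs = read_phased_vcf(path)
        hap0, hap1 = cs.haps("chr1")
        assert hap0[0].alt_allele == "T" and hap1[0].alt_allele == "G"

    def test_missing_qual_is_zero(self, tmp_path):
        path = _write_vcf_text(tmp_path / "a.vcf", [(5, "A", "T", ".", "1|1")])
        cs = read_phased_vcf(path)
        assert all(v.qual == 0.0 for h in cs.haps("chr1") for v in h)

    def test_region_restriction(self, tmp_path):
        path = _write_vcf_text(tmp_path / "a.vcf",
                               [(5, "A", "T", 30, "1|0"),
                                (50, "A", "T", 30, "1|0")])
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t20\n")
        cs = read_phased_vcf(path, regions=read_bed(str(bed)))
        assert cs.n_variants() == 1

    def test_insertion_anchoring(self, tmp_path):
        # INS ('', 'T') at offset 2 on AACC anchors on the preceding base:
        # POS=2 REF=A ALT=AT
        ref = {"chr1": "AACC"}
        cs = HaplotypeCallset(role="query")
        cs.add("chr1", 0, Variant(2, "", "T", 30.0, "chr1"))
        out = tmp_path / "out.vcf"
        write_vcf(cs, str(out), ref)
        line = [l for l in out.read_text().splitlines()
                if not l.startswith("#")][0]
        fields = line.split("\t")
        assert (fields[1], fields[3], fields[4]) == ("2", "A", "AT")

    def test_empty_callset_header_only(self, tmp_path):
        out = tmp_path / "out.vcf"
        write_vcf(HaplotypeCallset(), str(out), {"chr1": "ACGT"})
        body = [l for l in out.read_text().splitlines()
                if not l.startswith("#")]
        assert body == []

    def test_round_trip(self, tmp_path):
        ref = {"chr1": "ACGTACGTACGTACGTACGT"}
        cs = HaplotypeCallset(role="query")
        cs.add("chr1", 0, Variant(2, "G", "C", 31.5, "chr1"))
        cs.add("chr1", 0, Variant(6, "", "TT", 40.0, "chr1"))
        cs.add("chr1", 1, Variant(6, "", "TT", 40.0, "chr1"))
        cs.add("chr1", 1, Variant(10, "GT", "", 22.0, "chr1"))
        cs.sort_and_check()
        out = tmp_path / "o.vcf"
        write_vcf(cs, str(out), ref)
        back = read_phased_vcf(str(out))
        assert back == cs

    def test_round_trip_random_callsets(self, tmp_path):
        """Generator-produced callsets survive a VCF write/read cycle."""
        for seed in (1, 2, 3):
            ref, _, truth, query, _, _ = make_fixture(seed=seed, length=4000)
            out = tmp_path / f"{seed}.vcf"
            write_vcf(query, str(out), ref)
            back = read_phased_vcf(str(out))
            assert back == query

    def test_overlapping_variants_rejected(self):
        cs = HaplotypeCallset()
        cs.add("chr1", 0, Variant(0, "AC", "", 1.0, "chr1"))
        cs.add("chr1", 0, Variant(1, "C", "G", 1.0, "chr1"))
        with pytest.raises(ValueError, match="overlap"):
            cs.sort_and_check()


def test_write_fasta_read_back(tmp_path):
    from phasebench.vcf_io import read_fasta
    ref = {"chr1": "ACGT" * 40, "chr2": "GGCC" * 10}
    path = tmp_path / "r.fa"
    write_fasta(ref, str(path))
    assert read_fasta(str(path)) == ref
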