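"""Phased VCF and FASTA I/O; per-haplotype variant decomposition.

Internally every variant is held in a minimal, fully trimmed per-haplotype
form: 0-based half-open reference coordinates, uppercase alleles with the
shared prefix/suffix removed (so insertions have an empty ref allele and
deletions an empty alt allele).  The VCF anchoring base is added back only
on write.  Each diploid record contributes one entry to each haplotype
list per non-reference allele; a homozygous ALT record therefore appears
on both haplotype lists, which is what makes a homozygous false positive
count twice downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import pandas as pd
import pysam

SNP = "SNP"
INS = "INS"
DEL = "DEL"
COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class Variant:
    """A single trimmed variant on one haplotype (0-based half-open)."""

    start: int
    ref_allele: str
    alt_allele: str
    qual: float = 0.0
    contig: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"degenerate variant at {self.contig}:{self.start}: "
                "ref and alt alleles are identical"
            )

    @property
    def end(self) -> int:
        return self.start + len(self.ref_allele)

    @property
    def var_class(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return SNP
        if not self.ref_allele:
            return INS
        if not self.alt_allele:
            return DEL
        return COMPLEX

    @property
    def is_indel(self) -> bool:
        return self.var_class != SNP

    def key(self) -> tuple:
        return (self.start, self.ref_allele, self.alt_allele)

    def shifted(self, offset: int) -> "Variant":
        return dataclasses.replace(self, start=self.start + offset)


@dataclass
class HaplotypeCallset:
    """Per-contig, per-haplotype ordered variant lists for one callset."""

    role: str = "query"
    contigs: dict[str, tuple[list[Variant], list[Variant]]] = field(default_factory=dict)

    def haps(self, contig: str) -> tuple[list[Variant], list[Variant]]:
        return self.contigs.setdefault(contig, ([], []))

    def add(self, contig: str, hap: int, variant: Variant) -> None:
        self.haps(contig)[hap].append(variant)

    def n_variants(self) -> int:
        return sum(len(h) for pair in self.contigs.values() for h in pair)

    def all_quals(self) -> list[float]:
        return [v.qual for pair in self.contigs.values() for h in pair for v in h]

    def sort_and_check(self) -> None:
        """Sort each haplotype list and verify spans are disjoint."""
        for contig, pair in self.contigs.items():
            for hap, variants in enumerate(pair):
                variants.sort(key=lambda v: (v.start, v.end))
                for a, b in zip(variants, variants[1:]):
                    if a.end > b.start:
                        raise ValueError(
                            f"overlapping variants on {contig} haplotype "
                            f"{hap + 1}: {a.start}{a.ref_allele}>{a.alt_allele} "
                            f"and {b.start}{b.ref_allele}>{b.alt_allele}"
                        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeCallset):
            return NotImplemented
        return self.role == other.role and self.contigs == other.contigs


def trim_alleles(start: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove the shared suffix then prefix of an allele pair.

    Returns the adjusted start offset and trimmed alleles.  The pair must
    not be identical.
    """
    if ref == alt:
        raise ValueError("cannot trim identical alleles")
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    return start, ref, alt


def apply_variants(reference: str, variants: list[Variant], origin: int = 0) -> str:
    """Splice alt alleles over their reference spans.

    ``origin`` is the reference offset of ``reference[0]``; variant
    coordinates are absolute.  Variants must be sorted and disjoint.
    """
    parts: list[str] = []
    pos = 0
    for v in variants:
        s, e = v.start - origin, v.end - origin
        if s < pos:
            raise ValueError(f"variant at {v.start} overlaps a previous variant")
        if e > len(reference):
            raise ValueError(f"variant at {v.start} extends past the window end")
        parts.append(reference[pos:s])
        parts.append(v.alt_allele)
        pos = e
    parts.append(reference[pos:])
    return "".join(parts)


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into per-contig sorted (start, end) intervals."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["contig", "start", "end"], comment="#")
    regions: dict[str, list[tuple[int, int]]] = {}
    for contig, grp in df.groupby("contig", sort=False):
        regions[str(contig)] = sorted(zip(grp["start"], grp["end"]))
    return regions


def _in_regions(contig: str, pos: int, regions) -> bool:
    ivals = regions.get(contig)
    if not ivals:
        return False
    for s, e in ivals:
        if s <= pos < e:
            return True
    return False


def read_phased_vcf(path: str, regions=None, *, role: str = "query",
                    skip_bad_genotypes: bool = False,
                    pass_only: bool = False) -> HaplotypeCallset:
    """Read a locally phased diploid VCF into per-haplotype variant lists.

    Multi-allelic records are split into biallelic variants and alleles
    trimmed of their shared prefix/suffix.  Heterozygous genotypes must be
    phased; haploid or missing genotypes raise unless
    ``skip_bad_genotypes`` is set (then they are dropped).  Missing QUAL
    is treated as 0 so that such calls survive only the lowest quality
    threshold.  Only the first sample is read.
    """
    callset = HaplotypeCallset(role=role)
    with pysam.VariantFile(path) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            where = f"{rec.chrom}:{rec.pos}"
            if pass_only and "PASS" not in rec.filter and len(rec.filter) > 0:
                continue
            if regions is not None and not _in_regions(rec.chrom, rec.start, regions):
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                if skip_bad_genotypes:
                    continue
                raise ValueError(f"record at {where} lacks a diploid genotype")
            if gt[0] != gt[1] and not sample.phased:
                raise ValueError(
                    f"unphased heterozygous genotype at {where}: locally "
                    "phased truth and query VCFs are required"
                )
            qual = round(float(rec.qual), 3) if rec.qual is not None else 0.0
            for hap, allele_idx in enumerate(gt):
                if allele_idx == 0:
                    continue
                alt = rec.alleles[allele_idx]
                if alt is None or "<" in alt or "[" in alt or "]" in alt:
                    raise ValueError(f"symbolic allele at {where} is unsupported")
                start, ref_a, alt_a = trim_alleles(rec.start, rec.ref.upper(),
                                                   alt.upper())
                callset.add(rec.chrom, hap,
                            Variant(start, ref_a, alt_a, qual, rec.chrom))
    callset.sort_and_check()
    return callset


def write_vcf(callset: HaplotypeCallset, path: str,
              reference: dict[str, str]) -> None:
    """Write a callset as a phased single-sample VCF.

    Identical variants present on both haplotypes are emitted once as
    ``1|1``; all other variants get ``1|0`` / ``0|1``.  Empty-allele
    insertions and deletions are re-anchored on the preceding reference
    base (or the following base at offset 0) per the VCF convention.
    """
    header = pysam.VariantHeader()
    for contig, seq in reference.items():
        header.contigs.add(contig, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SAMPLE")

    with pysam.VariantFile(path, "w", header=header) as out:
        for contig in reference:
            if contig not in callset.contigs:
                continue
            hap0, hap1 = callset.contigs[contig]
            keyed0 = {v.key(): v for v in hap0}
            keyed1 = {v.key(): v for v in hap1}
            records = []
            for v in hap0:
                gt = (1, 1) if v.key() in keyed1 else (1, 0)
                records.append((v, gt))
            for v in hap1:
                if v.key() not in keyed0:
                    records.append((v, (0, 1)))
            records.sort(key=lambda r: (r[0].start, r[0].end))
            seq = reference[contig]
            for v, gt in records:
                start, ref_a, alt_a = v.start, v.ref_allele, v.alt_allele
                if not ref_a or not alt_a:
                    if start > 0:
                        anchor = seq[start - 1]
                        start -= 1
                        ref_a, alt_a = anchor + ref_a, anchor + alt_a
                    else:
                        anchor = seq[v.end]
                        ref_a, alt_a = ref_a + anchor, alt_a + anchor
                rec = out.new_record(contig=contig, start=start,
                                     alleles=(ref_a, alt_a),
                                     qual=v.qual)
                rec.samples["SAMPLE"]["GT"] = gt
                rec.samples["SAMPLE"].phased = True
                out.write(rec)


def read_fasta(path: str) -> dict[str, str]:
    """Load all contigs of a FASTA file as uppercase strings."""
    import pyfaidx

    fasta = pyfaidx.Fasta(path)
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_fasta(reference: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
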