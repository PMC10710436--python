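"""Synthetic benchmark fixtures: reference contigs, diploid truth callsets,
equivalent query representations, and planted call errors.

The generator emulates the situations that make phased small-variant
benchmarking hard: low-complexity tracts (homopolymers and short tandem
repeats) where INDELs are common and can shift, diploid truth callsets
with SNPs, INDELs and complex multi-edit events, query callsets
re-expressed under different affine-gap design points (all
sequence-equivalent), and planted call errors -- false positives, dropped
calls, near-correct INDEL lengths, haplotype flips and downstream
haplotype switches.  Every planted fact is recorded in a ledger so tests
can assert exact recovery.

All outputs are deterministic under the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .standardize import standardize_callset
from .gap_params import get_preset
from .vcf_io import HaplotypeCallset, Variant, apply_variants

BASES = "ACGT"

#: minimum reference distance between planted events; generous enough that
#: each event stays its own supercluster even after representation drift
EVENT_SPACING = 150


@dataclass
class PlantedEvent:
    kind: str                  # SNP / INS / DEL / COMPLEX
    pos: int
    haps: tuple[int, ...]      # haplotypes carrying the event
    variants: list[Variant]


@dataclass
class ErrorLedger:
    """Machine-readable record of every planted call error."""

    false_positives: list[dict] = field(default_factory=list)
    false_negatives: list[dict] = field(default_factory=list)
    length_errors: list[dict] = field(default_factory=list)
    flips: list[dict] = field(default_factory=list)
    switches: list[int] = field(default_factory=list)


@dataclass
class CorruptSpec:
    """Counts of each planted error class (counts, not rates, so recovery
    tests can assert exact totals)."""

    n_fp: int = 0
    n_fn: int = 0
    n_length_errors: int = 0
    n_flips: int = 0
    n_switches: int = 0
    fp_homozygous: bool = False


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_reference(length: int = 10_000, seed: int = 0,
                   repeat_fraction: float = 0.3) -> tuple[str, list[tuple[int, int]]]:
    """Random contig interleaving unique sequence with repeat tracts.

    Tracts are homopolymers (runs of one base) or short tandem repeats
    (2-4 bp units); their coordinates are returned so variants can be
    planted preferentially inside them.  Tract bases approximate
    ``repeat_fraction`` of the contig.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    tracts: list[tuple[int, int]] = []
    pos = 0
    while pos < length:
        if repeat_fraction > 0:
            tract_len = int(rng.integers(8, 21))
            uniq_len = max(1, int(round(tract_len * (1 - repeat_fraction)
                                        / repeat_fraction)))
        else:
            tract_len, uniq_len = 0, length
        chunk = _rand_seq(rng, min(uniq_len, length - pos))
        parts.append(chunk)
        pos += len(chunk)
        if tract_len and pos < length:
            if rng.random() < 0.5:
                unit = BASES[rng.integers(0, 4)]
            else:
                unit = _rand_seq(rng, int(rng.integers(2, 5)))
            tract = (unit * (tract_len // len(unit) + 1))[:tract_len]
            tract = tract[:length - pos]
            tracts.append((pos, pos + len(tract)))
            parts.append(tract)
            pos += len(tract)
    return "".join(parts), tracts


def _pick_positions(rng: np.random.Generator, n: int, length: int,
                    taken: list[int], tracts: list[tuple[int, int]],
                    prefer_tracts: bool, margin: int = 30,
                    spacing: int = EVENT_SPACING,
                    avoid_tracts: bool = False) -> list[int]:
    out: list[int] = []
    attempts = 0
    while len(out) < n and attempts < 200 * max(n, 1):
        attempts += 1
        if prefer_tracts and tracts and rng.random() < 0.6:
            s, e = tracts[rng.integers(0, len(tracts))]
            pos = int(rng.integers(s, e))
        else:
            pos = int(rng.integers(margin, max(margin + 1, length - margin)))
        if pos < margin or pos > length - margin:
            continue
        if avoid_tracts and any(s - 4 <= pos <= e + 12 for s, e in tracts):
            continue
        if all(abs(pos - t) >= spacing for t in taken + out):
            out.append(pos)
    if len(out) < n:
        raise RuntimeError("could not place all variants with required spacing")
    return out


def plant_variants(ref: str, tracts: list[tuple[int, int]], seed: int = 0,
                   snp_rate: float = 1e-3, indel_rate: float = 5e-4,
                   complex_rate: float = 2e-4, hom_fraction: float = 0.3,
                   contig: str = "chr1") -> tuple[HaplotypeCallset, list[PlantedEvent]]:
    """Plant SNPs, INDELs (1-8 bp) and complex events on two haplotypes.

    INDELs are preferentially placed inside repeat tracts, where their
    representation is ambiguous.  Events are spaced far enough apart to
    remain independent.  Returns the truth callset and the planted-event
    ledger; the callset's haplotype sequences are exactly reproducible by
    ``apply_variants``.
    """
    rng = np.random.default_rng(seed)
    length = len(ref)
    n_snp = int(round(snp_rate * length))
    n_indel = int(round(indel_rate * length))
    n_complex = int(round(complex_rate * length))
    taken: list[int] = []
    events: list[PlantedEvent] = []
    callset = HaplotypeCallset(role="truth")

    def qual() -> float:
        return float(round(min(60.0, max(20.0, rng.normal(45, 8))), 1))

    def haps_for_event() -> tuple[int, ...]:
        if rng.random() < hom_fraction:
            return (0, 1)
        return (int(rng.integers(0, 2)),)

    for pos in _pick_positions(rng, n_snp, length, taken, tracts, False):
        taken.append(pos)
        ref_b = ref[pos]
        alt_b = BASES[(BASES.index(ref_b) + int(rng.integers(1, 4))) % 4]
        v = Variant(pos, ref_b, alt_b, qual(), contig)
        haps = haps_for_event()
        for h in haps:
            callset.add(contig, h, v)
        events.append(PlantedEvent("SNP", pos, haps, [v]))

    for pos in _pick_positions(rng, n_indel, length, taken, tracts, True):
        taken.append(pos)
        size = int(min(8, 1 + rng.geometric(0.45)))
        if rng.random() < 0.5:
            # insertion; inside a tract, duplicate local sequence so the
            # placement is genuinely ambiguous
            if any(s <= pos < e for s, e in tracts) and pos + size <= length:
                alt = ref[pos:pos + size]
            else:
                alt = _rand_seq(rng, size)
            v = Variant(pos, "", alt, qual(), contig)
            kind = "INS"
        else:
            if pos + size > length - 30:
                size = 1
            v = Variant(pos, ref[pos:pos + size], "", qual(), contig)
            kind = "DEL"
        haps = haps_for_event()
        for h in haps:
            callset.add(contig, h, v)
        events.append(PlantedEvent(kind, pos, haps, [v]))

    # complex events also prefer repeat tracts; inside an STR the same
    # edits can re-express as copy-number changes, which is exactly the
    # ambiguity the joint-realignment dependence check must resolve
    for pos in _pick_positions(rng, n_complex, length, taken, tracts, True):
        taken.append(pos)
        # a dependent pair: deletion plus nearby SNP on the same haplotype
        del_len = int(rng.integers(2, 5))
        snp_off = pos + del_len + int(rng.integers(1, 4))
        ref_b = ref[snp_off]
        alt_b = BASES[(BASES.index(ref_b) + int(rng.integers(1, 4))) % 4]
        q = qual()
        vs = [Variant(pos, ref[pos:pos + del_len], "", q, contig),
              Variant(snp_off, ref_b, alt_b, q, contig)]
        haps = haps_for_event()
        for h in haps:
            for v in vs:
                callset.add(contig, h, v)
        events.append(PlantedEvent("COMPLEX", pos, haps, vs))

    callset.sort_and_check()
    return callset, events


def render_representation(truth: HaplotypeCallset, ref: dict[str, str],
                          preset: str) -> HaplotypeCallset:
    """Re-express a callset at a design point, or fragment it.

    Presets A-D realign each cluster under the corresponding affine-gap
    penalties; ``fragmented`` decomposes every multi-base gap of the
    standard representation into 1-bp pieces.  All outputs apply to
    identical haplotype sequences.
    """
    if preset in ("A", "B", "C", "D"):
        out = standardize_callset(truth, ref, get_preset(preset))
    elif preset == "fragmented":
        std = standardize_callset(truth, ref, get_preset("C"))
        out = HaplotypeCallset(role=std.role)
        for contig, pair in std.contigs.items():
            for hap, variants in enumerate(pair):
                for v in variants:
                    for piece in _fragment(v):
                        out.add(contig, hap, piece)
        out.sort_and_check()
    else:
        raise ValueError(f"unknown representation preset {preset!r}")
    out.role = "query"
    return out


def _fragment(v: Variant) -> list[Variant]:
    if v.var_class == "INS" and len(v.alt_allele) > 1:
        return [dataclasses.replace(v, alt_allele=b) for b in v.alt_allele]
    if v.var_class == "DEL" and len(v.ref_allele) > 1:
        return [dataclasses.replace(v, start=v.start + i, ref_allele=b)
                for i, b in enumerate(v.ref_allele)]
    return [v]


def _isolated_het_candidates(cs: HaplotypeCallset, contig: str,
                             spacing: int = EVENT_SPACING):
    """Variants alone within ``spacing`` bases present on exactly one hap."""
    hap0, hap1 = cs.haps(contig)
    keys0 = {v.key() for v in hap0}
    keys1 = {v.key() for v in hap1}
    all_pos = sorted([(v.start, 0, v) for v in hap0] +
                     [(v.start, 1, v) for v in hap1],
                     key=lambda t: (t[0], t[1]))
    out = []
    for i, (pos, hap, v) in enumerate(all_pos):
        if v.key() in keys0 and v.key() in keys1:
            continue
        prev_ok = i == 0 or pos - all_pos[i - 1][0] >= spacing
        next_ok = i == len(all_pos) - 1 or all_pos[i + 1][0] - pos >= spacing
        if prev_ok and next_ok:
            out.append((hap, v))
    return out


def corrupt(query: HaplotypeCallset, ref: dict[str, str], spec: CorruptSpec,
            seed: int = 0) -> tuple[HaplotypeCallset, ErrorLedger]:
    """Plant call errors into a query callset; record them in a ledger.

    False positives are isolated novel SNPs; false negatives drop isolated
    heterozygous calls; length errors shorten an isolated 3-bp insertion
    to 2 bp (remaining edit distance 1 of 3, hence fractional credit 2/3);
    flips move an isolated heterozygous call to the other haplotype; a
    switch swaps the haplotype assignment of every call downstream of a
    chosen locus.
    """
    rng = np.random.default_rng(seed)
    ledger = ErrorLedger()
    out = HaplotypeCallset(role="query")
    for contig, (h0, h1) in query.contigs.items():
        out.contigs[contig] = (list(h0), list(h1))

    for contig, seq in ref.items():
        hap_lists = out.haps(contig)
        candidates = _isolated_het_candidates(out, contig)
        rng.shuffle(candidates)

        # drop calls (false negatives)
        for _ in range(spec.n_fn):
            if not candidates:
                raise RuntimeError("not enough isolated candidates for FN errors")
            hap, v = candidates.pop()
            hap_lists[hap].remove(v)
            ledger.false_negatives.append(
                {"contig": contig, "pos": v.start, "hap": hap,
                 "kind": v.var_class})

        # near-correct INDEL lengths (partial positives): an insertion of
        # length L called one base short leaves edit distance 1 of L,
        # hence fractional credit 1 - 1/L
        long_ins = [(h, v) for h, v in candidates
                    if v.var_class == "INS" and len(v.alt_allele) >= 2]
        for _ in range(spec.n_length_errors):
            if not long_ins:
                raise RuntimeError("no isolated multi-base insertion to perturb")
            hap, v = long_ins.pop()
            candidates.remove((hap, v))
            new_q = float(round(rng.uniform(25, 40), 1))
            length = len(v.alt_allele)
            short = dataclasses.replace(v, alt_allele=v.alt_allele[:-1],
                                        qual=new_q)
            hap_lists[hap][hap_lists[hap].index(v)] = short
            ledger.length_errors.append(
                {"contig": contig, "pos": v.start, "hap": hap,
                 "truth_len": length, "called_len": length - 1,
                 "expected_credit": 1.0 - 1.0 / length})

        # haplotype flips
        for _ in range(spec.n_flips):
            if not candidates:
                raise RuntimeError("not enough isolated candidates for flips")
            hap, v = candidates.pop()
            hap_lists[hap].remove(v)
            hap_lists[1 - hap].append(v)
            ledger.flips.append({"contig": contig, "pos": v.start,
                                 "from_hap": hap})

        # novel false positives at empty loci
        taken = [v.start for lst in hap_lists for v in lst]
        fp_pos = _pick_positions(rng, spec.n_fp, len(seq), taken, [], False)
        for pos in fp_pos:
            ref_b = seq[pos]
            alt_b = BASES[(BASES.index(ref_b) + int(rng.integers(1, 4))) % 4]
            q = float(round(rng.uniform(20, 40), 1))
            v = Variant(pos, ref_b, alt_b, q, contig)
            haps = (0, 1) if spec.fp_homozygous else (int(rng.integers(0, 2)),)
            for h in haps:
                hap_lists[h].append(v)
            ledger.false_positives.append(
                {"contig": contig, "pos": pos, "haps": list(haps)})

        # downstream switches
        if spec.n_switches:
            positions = sorted(v.start for lst in hap_lists for v in lst)
            # a switch is only observable if categorizable (heterozygous)
            # calls exist on both sides of the cut
            keys0 = {v.key() for v in hap_lists[0]}
            keys1 = {v.key() for v in hap_lists[1]}
            het_records = sorted(v.start for h in hap_lists for v in h
                                 if not (v.key() in keys0 and v.key() in keys1))
            # collapse records of one event into a single position
            het_pos: list[int] = []
            for p in het_records:
                if not het_pos or p - het_pos[-1] >= EVENT_SPACING:
                    het_pos.append(p)
            # cut only in wide gaps so a switch never splits one event;
            # two het calls on each side make the switch unambiguous
            # (a single trailing disagreement ties with a haplotype flip)
            gap_idx = [i for i in range(2, len(positions) - 1)
                       if positions[i] - positions[i - 1] >= EVENT_SPACING
                       and len(het_pos) >= 4
                       and het_pos[1] < positions[i - 1]
                       and positions[i] < het_pos[-2]]
            if len(gap_idx) < spec.n_switches:
                raise RuntimeError("too few wide gaps to plant switches")
            cut_idx = rng.choice(np.array(gap_idx, dtype=int),
                                 size=spec.n_switches, replace=False)
            cuts = sorted((positions[i - 1] + positions[i]) // 2
                          for i in cut_idx)
            for cut in cuts:
                new0 = [v for v in hap_lists[0] if v.start < cut] + \
                       [v for v in hap_lists[1] if v.start >= cut]
                new1 = [v for v in hap_lists[1] if v.start < cut] + \
                       [v for v in hap_lists[0] if v.start >= cut]
                hap_lists[0][:] = new0
                hap_lists[1][:] = new1
                ledger.switches.append(cut)

    out.sort_and_check()
    return out, ledger


def make_fixture(seed: int = 0, length: int = 10_000,
                 repeat_fraction: float = 0.3, preset: str = "C",
                 errors: CorruptSpec | None = None,
                 contig: str = "chr1", **plant_kwargs):
    """One-call benchmark fixture: reference, truth, query, ledgers."""
    ref_seq, tracts = make_reference(length, seed, repeat_fraction)
    ref = {contig: ref_seq}
    truth, events = plant_variants(ref_seq, tracts, seed + 1,
                                   contig=contig, **plant_kwargs)
    # errors are planted on the standard representation, then the corrupted
    # callset is re-expressed at the requested design point
    query = render_representation(truth, ref, "C")
    ledger = ErrorLedger()
    if errors is not None:
        query, ledger = corrupt(query, ref, errors, seed + 2)
    if preset != "C":
        query = render_representation(query, ref, preset)
    return ref, tracts, truth, query, events, ledger
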