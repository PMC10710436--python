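"""End-to-end evaluation: read -> cluster -> standardize -> supercluster ->
align/phase -> credit -> metrics -> phasing -> reports."""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from . import distance_metrics as dm
from .clustering import compute_reaches, gap_cluster, iterative_cluster
from .evaluate_credit import (FN, FP, CreditRecord, best_f1,
                              evaluate_supercluster, summarize)
from .gap_params import AffineParams, get_preset
from .phase_analysis import PhaseBlock, count_switch_errors, phase_forward_backward
from .standardize import standardize_callset
from .supercluster import Supercluster, build_superclusters
from .vcf_io import HaplotypeCallset, apply_variants, write_vcf

log = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    credits: list[CreditRecord]
    summary: pd.DataFrame
    best: pd.DataFrame
    distance: pd.DataFrame
    superclusters: list[Supercluster]
    phase_blocks: list[PhaseBlock]
    switch_errors: int
    phasing_errors: int
    truth_std: HaplotypeCallset | None = None
    query_std: HaplotypeCallset | None = None
    stage_counts: dict = field(default_factory=dict)


def _cluster_callset(cs: HaplotypeCallset, ref: dict[str, str],
                     p: AffineParams, clustering: str, cluster_gap: int):
    """Per-contig, per-hap cluster lists with reaches filled in."""
    out: dict[str, dict[int, list]] = {}
    for contig, pair in cs.contigs.items():
        seq = ref[contig]
        out[contig] = {}
        for hap, variants in enumerate(pair):
            if clustering == "gap":
                clusters = gap_cluster(variants, cluster_gap, contig=contig,
                                       hap=hap, role=cs.role, p=p)
                for c in clusters:  # fall back to spans as reaches
                    c.left_reach, c.right_reach = c.begin, c.end
            else:
                clusters = iterative_cluster(variants, seq, p, contig=contig,
                                             hap=hap, role=cs.role)
                compute_reaches(clusters, seq, p)
            out[contig][hap] = clusters
    return out


def _distance_sweep(superclusters: list[Supercluster], ref: dict[str, str],
                    thresholds: list[float], p: AffineParams) -> pd.DataFrame:
    """ED/DE/alignment-distance of query vs truth over quality thresholds.

    Distances are summed over supercluster windows (outside them the
    sequences agree).  Per supercluster the value only changes at its own
    variants' quality values, so each local configuration is computed
    once and reused across the global sweep.
    """
    rows = {t: {"ed_query": 0, "de_query": 0, "aln_query": 0.0,
                "ed_ref": 0, "de_ref": 0, "aln_ref": 0.0} for t in thresholds}
    for sc in superclusters:
        window = ref[sc.contig][sc.begin:sc.end]
        shift = -sc.begin
        pairing = ((0, 1), (1, 0)) if sc.phase == "Y" else ((0, 0), (1, 1))
        for t_hap, q_hap in pairing:
            tv = [v.shifted(shift) for v in sc.variants("truth", t_hap)]
            qv = [v.shifted(shift) for v in sc.variants("query", q_hap)]
            truth_seq = apply_variants(window, tv)
            ed_r, de_r = dm.ed_de(window, truth_seq)
            aln_r = dm.aln_distance(window, truth_seq, p)
            cache: dict[tuple, tuple[int, int, float]] = {}
            for t in thresholds:
                kept = tuple(v for v in qv if v.qual >= t)
                key = tuple(v.key() for v in kept)
                if key not in cache:
                    qseq = apply_variants(window, list(kept))
                    ed_q, de_q = dm.ed_de(truth_seq, qseq)
                    aln_q = dm.aln_distance(truth_seq, qseq, p)
                    cache[key] = (ed_q, de_q, aln_q)
                ed_q, de_q, aln_q = cache[key]
                row = rows[t]
                row["ed_query"] += ed_q
                row["de_query"] += de_q
                row["aln_query"] += aln_q
                row["ed_ref"] += ed_r
                row["de_ref"] += de_r
                row["aln_ref"] += aln_r
    records = []
    for t in thresholds:
        r = dict(rows[t])
        r["threshold"] = t
        r["ed_qscore"] = dm.distance_qscore(r["ed_query"], r["ed_ref"])
        r["de_qscore"] = dm.distance_qscore(r["de_query"], r["de_ref"])
        r["aln_qscore"] = dm.distance_qscore(r["aln_query"], r["aln_ref"])
        records.append(r)
    return pd.DataFrame(records)


def evaluate(ref: dict[str, str], truth: HaplotypeCallset,
             query: HaplotypeCallset, *, standardize: bool = True,
             partial_credit: bool = True, clustering: str = "wfa",
             cluster_gap: int = 50, supercluster_gap: int = 50,
             params: AffineParams | None = None,
             distance_sweep: bool = True) -> EvaluationResult:
    """Evaluate a phased query callset against a phased truth callset."""
    p = params or get_preset("C")
    stage_counts = {"truth_in": truth.n_variants(), "query_in": query.n_variants()}

    truth_std = query_std = None
    if standardize:
        truth = truth_std = standardize_callset(truth, ref, p,
                                                clustering=clustering,
                                                cluster_gap=cluster_gap)
        query = query_std = standardize_callset(query, ref, p,
                                                clustering=clustering,
                                                cluster_gap=cluster_gap)
        stage_counts["truth_std"] = truth.n_variants()
        stage_counts["query_std"] = query.n_variants()

    truth_clusters = _cluster_callset(truth, ref, p, clustering, cluster_gap)
    query_clusters = _cluster_callset(query, ref, p, clustering, cluster_gap)

    credits: list[CreditRecord] = []
    superclusters: list[Supercluster] = []
    blocks: list[PhaseBlock] = []
    phasing_errors = 0
    sc_id = 0
    for contig in ref:
        tc = truth_clusters.get(contig, {})
        qc = query_clusters.get(contig, {})
        if not tc and not qc:
            continue
        scs = build_superclusters(tc, qc, contig, len(ref[contig]),
                                  supercluster_gap)
        categories = []
        for sc in scs:
            credits.extend(evaluate_supercluster(sc, ref[contig], sc_id))
            categories.append(sc.phase)
            sc_id += 1
        contig_blocks, _, contig_pe = phase_forward_backward(
            categories, contig=contig)
        blocks.extend(contig_blocks)
        phasing_errors += contig_pe
        superclusters.extend(scs)
    stage_counts["superclusters"] = len(superclusters)

    if not partial_credit:
        for r in credits:
            if 0.0 < r.credit < 1.0:
                r.credit = 0.0
                r.category = FN if r.role == "truth" else FP

    summary = summarize(credits)
    thresholds = sorted(summary["threshold"].unique())
    if distance_sweep:
        distance = _distance_sweep(superclusters, ref, thresholds, p)
    else:
        distance = _distance_sweep(superclusters, ref, thresholds[:1], p)

    return EvaluationResult(
        credits=credits, summary=summary, best=best_f1(summary),
        distance=distance, superclusters=superclusters, phase_blocks=blocks,
        switch_errors=count_switch_errors(blocks),
        phasing_errors=phasing_errors,
        truth_std=truth_std, query_std=query_std, stage_counts=stage_counts)


def credits_frame(credits: list[CreditRecord]) -> pd.DataFrame:
    rows = []
    for r in credits:
        v = r.variant
        rows.append({
            "contig": v.contig, "start": v.start, "ref": v.ref_allele,
            "alt": v.alt_allele, "qual": v.qual, "class": r.var_class,
            "role": r.role, "hap": r.hap, "category": r.category,
            "credit": r.credit, "supercluster": r.supercluster_id,
            "segment": r.segment_id,
        })
    return pd.DataFrame(rows)


def phasing_frame(result: EvaluationResult) -> pd.DataFrame:
    rows = []
    for b in result.phase_blocks:
        rows.append({"contig": b.contig, "state": b.state,
                     "first_supercluster": b.start_index,
                     "last_supercluster": b.end_index - 1,
                     "phase_errors": b.n_phase_errors})
    return pd.DataFrame(rows)


def summary_text(result: EvaluationResult) -> str:
    lines = ["phasebench evaluation summary", "=" * 30, ""]
    for k, v in result.stage_counts.items():
        lines.append(f"{k:>18}: {v}")
    lines.append("")
    lines.append("best operating points (max F1 per class):")
    if len(result.best):
        lines.append(result.best.to_string(index=False,
                                           float_format=lambda x: f"{x:.4f}"))
    lines.append("")
    d = result.distance.iloc[0] if len(result.distance) else None
    if d is not None:
        lines.append(f"distance at lowest threshold: ED {d['ed_query']:.0f} "
                     f"(ref {d['ed_ref']:.0f}), DE {d['de_query']:.0f} "
                     f"(ref {d['de_ref']:.0f}), ALN {d['aln_query']:.1f} "
                     f"(ref {d['aln_ref']:.1f})")
    lines.append(f"switch errors: {result.switch_errors}; "
                 f"supercluster phasing errors: {result.phasing_errors}; "
                 f"phase blocks: {len(result.phase_blocks)}")
    return "\n".join(lines) + "\n"


def write_reports(result: EvaluationResult, ref: dict[str, str],
                  outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write(summary_text(result))
    result.summary.to_csv(os.path.join(outdir, "pr_curve.tsv"),
                          sep="\t", index=False)
    result.distance.to_csv(os.path.join(outdir, "distance.tsv"),
                           sep="\t", index=False)
    credits_frame(result.credits).to_csv(
        os.path.join(outdir, "credits.tsv"), sep="\t", index=False)
    phasing_frame(result).to_csv(os.path.join(outdir, "phasing.tsv"),
                                 sep="\t", index=False)
    if result.truth_std is not None:
        write_vcf(result.truth_std, os.path.join(outdir, "truth.std.vcf"), ref)
    if result.query_std is not None:
        write_vcf(result.query_std, os.path.join(outdir, "query.std.vcf"), ref)
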