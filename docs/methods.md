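# Methods

This note documents the models, algorithms, parameter choices and known
limitations of phasebench. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Variant representation as alignment

Internally every variant is a trimmed, per-haplotype record in 0-based
half-open reference coordinates; insertions have an empty reference allele
and deletions an empty alternate allele. VCF anchoring bases exist only at
the file boundary. Each diploid record contributes one entry per
non-reference allele to the corresponding haplotype list, so a homozygous
record appears on both lists — this is what makes a homozygous false
positive count twice in the summaries.

The representation of a haplotype difference is the minimum-penalty global
alignment under affine-gap penalties `(m, x, o, e)` with gap cost
`g(n) = o + n·e` (the first gap base costs `o + e`). The aligner is a
three-state Gotoh DP with a fully deterministic traceback: at equal
penalty, match/substitution is preferred over deletion over insertion, and
continuing a gap over opening one. Because traceback runs end-to-start,
preferring the diagonal pushes gaps leftmost, so decomposed output is
automatically left-shifted and stable across runs. `path_to_variants`
emits one SNP per substituted base and one INS/DEL per gap run; applying
the result reproduces the input haplotype exactly (property-tested).

### Normalization of penalty tuples

Published aligner parameters are mapped into the `m = 0, x = 1` design
space by `x ← x + m`, `o ← o + m/2`, `e ← e + m/2`, then dividing by the
new `x`. This is the conversion conventionally used to compare score-based
aligner parameter sets, and it reproduces the published normalized tuples
for the standard point C, the Illumina short-read family and minimap2
map-ont. It is *exactly* optimum-preserving only for pure cost models
(`m = 0`, where it is a positive rescaling): for `m > 0` the `o + m/2`
term adds half a match per gap *run*, which can reorder equal-penalty
paths. The property test therefore asserts exact optimum preservation for
`m = 0` tuples only; for `m > 0` the transform is documented as the
field's comparison convention, not an equivalence.

## Clustering dependent variants

Two clusters on one haplotype are dependent when an optimal alignment path
of the joint window can stay off the main reference diagonal between them;
such clusters admit interacting representations and must be realigned
together.

Two tests are combined:

* **Reach test** (`clusters_dependent`): from the left cluster, a
  WFA-style cost-bounded expansion finds the rightmost reference offset
  reachable by any partial alignment path whose penalty does not exceed
  the cluster's original-representation penalty (SNP: `x`; gap:
  `o + n·e`; complex allele pair: its own optimal alignment penalty) and
  that avoids exact matches on the final main diagonal beyond the cluster
  span. The mirrored leftward reach is computed for the right cluster;
  the clusters are dependent when the reaches meet. The DP is
  row-vectorized with numpy; windows are capped at the neighbouring
  cluster (for pair tests) or at 200 bp (`REACH_CAP`, for stored reaches
  used by superclustering).
* **Joint-realignment test** (`joint_realignment_cheaper`): the reach
  test is a budget-limited approximation and can miss dependence when
  each cluster's own budget is too small to bridge the gap even though a
  joint representation is cheaper (observed for a DEL+SNP complex
  re-expressed as two small deletions at another design point). If
  realigning the combined window is strictly cheaper than realigning the
  two windows separately, some optimal path must stay off-diagonal
  between the clusters, so they are merged. The test is attempted only
  when the gap is bridgeable, `gap ≤ min(100, (pen_a + pen_b)/e)`.

`iterative_cluster` starts from single-variant clusters and merges
adjacent dependent clusters to a fixpoint (default cap 100 sweeps, with a
warning on non-convergence). A positional fallback (`gap_cluster`, merge
when separated by < 50 bp) mirrors the cheap mode of the original tool.
Clustering defaults to point C, the same penalties used for
standardization.

## Standardization

Each cluster's variants are applied to the reference over the
reach-extended window (reaches bound every position to which a gap can
migrate, so equivalent input representations see the same context and
realign identically), the window is realigned at point C, and the path is
decomposed into records. Merged records take the minimum member QUAL —
conservative for precision-recall sweeps — and each haplotype of each
callset is standardized independently. Standardization preserves haplotype
sequences exactly and is idempotent (both property-tested).

## Superclustering and evaluation

Clusters from all four haplotypes whose reach intervals come within 50 bp
of one another are grouped transitively into superclusters, which are
evaluated independently. Within a supercluster:

1. Each truth haplotype is aligned (unit costs) against each query
   haplotype represented as a reference-merged graph: every query variant
   is taken wholly or skipped wholly (skipping is free — the call may be a
   false positive), and rail↔branch transitions inside a variant span are
   impossible by construction. The DP runs per graph node over the truth
   prefix vector, with a deterministic backtrace.
2. The haplotype pairing minimizing total edit distance sets the phase
   category: X (parallel), Y (crossed), or uncategorized on ties (for
   crediting, ties fall back to the parallel pairing, which is safe by
   symmetry).
3. **Sync points** cut the chosen path into independently creditable
   segments: a sync point is a reference base outside every truth and
   query variant span that the path crosses as an exact match *in
   register* — the truth character aligned to it must be the one mapping
   there after all preceding truth variants. The register condition is
   essential: two equivalent insertions left-shifted to different
   junctions are otherwise separated by their coincidental in-between
   matches and falsely scored FP+FN.
4. Per segment, with `ED_ref` = edit distance of truth vs reference and
   `ED_query` = truth vs query-applied sequence: `ED_query = 0` → TP;
   `ED_query ≥ ED_ref` → FP/FN (a worsening query is clamped and logged);
   otherwise a partial positive with fraction `1 − ED_query/ED_ref`,
   shared by all variants in the segment.

Precision is `TP_truth / (TP_truth + FP_query)`; recall is
`TP_truth / (TP_truth + FN_truth)`. Counts are per haplotype and summed.
Variant classes are SNP vs INDEL by allele lengths after standardization
(complex inputs are already decomposed); without standardization a
multi-base substitution record counts as INDEL.

### Quality sweep

The PR curve sweeps the sorted distinct query QUAL values. Rather than
re-evaluating per threshold, the single evaluation is reused: a segment is
retained at threshold *t* iff the minimum QUAL of its supporting query
variants is ≥ *t*; a dropped segment contributes its truth variants as
false negatives and its query variants not at all. This matches the usual
PR-curve semantics of benchmarking tools and makes the sweep free.
Q-scores are capped at 100 when the error term is zero; undefined ratios
(zero reference term) are reported as NaN.

## Distance metrics

ED and DE are read off the alignment at point B = (0, 3, 2, 1), whose
penalty equals `2·DE + ED`: each substituted base adds one to both, each
gap adds one DE plus its length in ED. The reported ED is therefore the
edit distance *of the 2DE+ED-optimal path*, which may exceed the plain
Levenshtein distance. Alignment distance uses point C (the standard
reporting penalties; the choice of parameter set here is a package
assumption). Distances are summed over supercluster windows under the
chosen phasing — outside superclusters the sequences agree — with the
query side recomputed only at thresholds where its local variant set
changes.

## Global phasing

Each supercluster's category feeds a per-contig two-state DP minimizing
`switch_cost · switches + phase_error_cost · disagreements` (both weights
default to 1; the relative weighting is a package choice, as only the
joint minimization is specified). Uncategorized superclusters cost nothing
in either state. Ties prefer fewer switches, so an isolated disagreement
is reported as a supercluster phasing error (the signature of a haplotype
flip) rather than two switches. Switch errors are block boundaries within
a contig, never across contigs, and phasing never changes TP/FP/FN totals.

## Synthetic data generator

`fixtures` emulates the conditions the evaluator must survive:

* **Reference** (default 10 kb): random sequence interleaved with
  homopolymer and 2–4 bp STR tracts of 8–20 bp covering ~30 % of bases,
  with tract coordinates recorded. Contigs of this size keep a full
  evaluation well under a second while containing dozens of events.
* **Truth variants**: SNPs at 1e-3/bp, INDELs (1–8 bp, geometric) at
  5e-4/bp placed preferentially inside tracts (insertions there duplicate
  local sequence so placement is genuinely ambiguous), and complex
  DEL+SNP events at 2e-4/bp, also tract-preferring; ~30 % of events are
  homozygous. Events keep ≥ 150 bp spacing so each remains its own
  supercluster — recovery assertions need errors to be attributable.
* **Representations**: the same truth re-rendered at design points A–D by
  per-cluster realignment (at A no SNP records survive), plus a
  `fragmented` mode that splits every multi-base gap of the standard
  representation into 1 bp pieces.
* **Planted errors** (exact counts, each recorded in a ledger): novel
  isolated SNP false positives; dropped isolated heterozygous calls; an
  isolated L bp insertion called one base short (expected credit
  `1 − 1/L`); haplotype flips of isolated heterozygous calls; and
  switches that swap the haplotype assignment of all downstream calls.
  Switch cuts are restricted to inter-event gaps with at least two
  heterozygous events on each side: a switch with only one categorizable
  supercluster beyond it is mathematically indistinguishable from a flip,
  and splitting a single event across haplotypes would not be a pure
  switch error.

What the generator does *not* emulate: sequencing-error profiles, read
depth, genotyping uncertainty, clustered true variation (events are
deliberately spaced), structural variants, or multi-sample VCFs. Passing
tests therefore demonstrate the correctness of the representation,
phasing, credit and phasing-error machinery under controlled ambiguity —
not calling accuracy on real data.

## Numerical and degenerate-input choices

* All penalties are floats; DP traceback compares with the same operation
  order as the forward pass, so equality checks are exact.
* Unit-cost DPs use int32 with a large sentinel; graph-alignment
  backtraces follow a fixed candidate order (diagonal match, diagonal
  substitution, skip-edge, graph deletion, truth insertion).
* Empty sequences, empty callsets, header-only VCFs, variants at contig
  offset 0 (anchored on the following base) and query-only/truth-only
  superclusters are all handled and tested.
* Missing QUAL is read as 0; a merged record's QUAL is the member
  minimum; QUALs are rounded to 3 decimals on read (VCF float32
  round-trip).
* AMRC uses the leftmost (0-based) insertion position and removes the
  submission's own median before ranking; the median of five scores is
  the third order statistic.

## Known limitations

* The reach-based dependence test plus the joint-realignment check still
  examine adjacent cluster *pairs*; a dependence that only materializes
  for a triple whose pairwise tests all fail would be missed. Not
  observed on the seeded fixture sweeps, but not excluded in general.
* Representation invariance is exact on the generator's conditions;
  on real data the original tool reports near-perfect but not perfect
  stability, and the same residual mechanisms (clustering differences
  from false-positive dependencies) apply here.
* The quality sweep's segment-level gating can drop a high-QUAL query
  variant that shares a segment with a low-QUAL one at intermediate
  thresholds.
* Phasing output reports switch errors and supercluster phasing errors;
  flip errors are visible only as the latter and are not separately
  identified.
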