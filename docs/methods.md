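# Methods

This note documents the models, conventions and design choices behind
`tcrsift`, in the order the pipeline runs.

## Read merging

Bulk TCRβ amplicons are sequenced as 2×150 bp pairs whose mates overlap
across the CDR3 junction. `merge_read_pair` reverse-complements mate 2 and
scores every ungapped overlap length L between the 3′ end of mate 1 and the
5′ end of the flipped mate 2 by matches − mismatches; the best-scoring
overlap wins, ties going to the longer one. Pairs whose best overlap is
shorter than `min_overlap` (default 20 nt) or whose overlap mismatch
fraction exceeds `max_mismatch_frac` (default 0.10) are rejected and
counted — these defaults are conventional read-merger settings chosen to
discard inconsistent, non-overlapping pairs while tolerating sequencing
error. At disagreeing positions the base with the higher Phred score is
taken (mate 1 on ties); `N` counts as a mismatch and never wins a
disagreement, so an all-`N` overlap is rejected. Quality-aware resolution is
what makes consensus building error-correcting: a miscalled base usually
carries low quality, so the correct mate wins the disagreement.

## V/J assignment and the junction convention

The assignment is anchor-based and reference-free of external downloads:
each library segment (3′-terminal V with its conserved cysteine codon
annotated, 5′-terminal J with its conserved phenylalanine/tryptophan codon)
is slid ungapped along the consensus; a placement qualifies with identity
≥ `min_identity` (0.9) over ≥ `min_match_len` (20 nt), and the placement
with the most matching bases wins (ties: longer overlap, then
lexicographically smaller segment name — fixed for reproducibility). The
junction is cut from the V-cysteine codon through the J-Phe/Trp codon,
*inclusive of both anchors* (IMGT junction convention). This is stricter
than informal "CDR3" usage; it is stated explicitly because clonotype keys
are built from it. Records without a qualifying V or J placement are flagged
unassigned and counted, so assigned + unassigned + merge-rejected always
equals the number of input pairs.

A bundled toy library (4 TRBV-like, 3 TRBJ-like segments, FASTA plus an
anchor sidecar JSON) makes the package self-contained; real IMGT-derived
libraries in the same layout can be dropped in. Gapped alignment and
allele-level calls are out of scope.

## Clonotypes, productivity, frequencies

Clonotype identity defaults to the triple (junction_nt, v_call, j_call);
key composition is configurable in principle but the triple is used
throughout because nucleotide junctions can coincide across segments. A
junction is productive when its length is a multiple of three, its
translation has no internal stop, and it starts with C and ends with F or W.
Frequencies are percentages of reads in the sample; the selection operates
on post-productivity-filter frequencies (frequencies are recomputed after
discarding non-functional sequences), while pre-filter profiles are kept for
QC. AIRR Rearrangement TSVs round-trip bit-exactly because frequencies are
recomputed from `duplicate_count` on read.

## Frequency matrix, ratios, tiers

The matrix is the union of clonotype keys over compartments with zero
frequency/count for absent cells. The tumor-to-nontumor ratio uses the
adjacent-lung compartment as denominator; when the clonotype is absent from
lung the denominator is floored at the frequency of a single read
(100 / total lung reads). This pseudocount is a declared choice — it keeps
ratios finite, scales with sequencing depth, and is exposed in the module
configuration; no convention for the zero-denominator case is standard.

Selection evaluates the top 100 tumor clonotypes (rank ties broken by
junction sequence), with `top_n=None` available. All thresholds are strict
inequalities: ratio > 5 for candidates, frequency > 0.2 % and ratio > 10
for single-cell grade, frequency > 0.1 % and ratio < 1 for bystanders.
PD-1⁺-fraction support (≥ 0.1 % there, configurable) is annotative only —
it corroborates a call but never gates one, since no principled hard
threshold exists for that fraction.

## Cross-patient matching

Queries are CDR3 amino-acid sequences plus V gene. "Highly related" is
operationalized as Levenshtein distance ≤ 2 on the CDR3 with an identical
V gene (allele suffixes stripped, J not compared); distance is computed
with edlib and cross-checked against a dynamic-programming oracle in the
tests. In FFPE mode a near match is accepted only when frequency > 0.001 %
and coverage > 4 reads (both strict, read counts as the coverage unit);
perfect matches are exempt by default because an exact CDR3+V coincidence is
not a plausible polymerase/fixation artifact — a flag subjects them to the
same filter for sensitivity analyses.

## Cluster bipartition scan

Cells map to clonotypes and expression-cluster labels; because the
tumor-to-nontumor ratio belongs to the clonotype, each clonotype contributes
its ratio at most once per group. By default it counts once in *every* group
where it has ≥ 1 cell (literal once-per-group reading; dual-membership
clonotypes appear on both sides), with a majority-cluster assignment
(ties excluded) available by flag. All (2^k − 2)/2 unordered bipartitions of
the k clusters are enumerated — 15 for five clusters — each tested with a
two-sided Mann–Whitney U; p-values are Bonferroni-multiplied by the number
of bipartitions, capped at 1. Two-sided testing is the default (a one-sided
variant of the scan would be easy to add but the symmetric test is the more
conservative report).

The U statistic comes from midrank sums. The p-value is exact — computed
from the tie-free null distribution of U via the rank-sum counting
recurrence N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1) — whenever the
smaller sample has ≤ 8 observations and the pooled values are tie-free;
otherwise the normal approximation with tie correction and a 0.5 continuity
correction is used. The exact/approximate switch at min(n) ≤ 8 favours
reproducibility at small n and standard behaviour otherwise; if every pooled
value is identical the p-value is defined as 1.

## Variant application and peptide windows

HGVS c. substitutions (`c.183A>T`) and codon replacements
(`c.181-183CAT>CGC`) are parsed with 1-based inclusive coordinates, the
stated reference bases validated against the CDS, and both proteins
translated to the first stop. Protein changes are derived by codon
comparison (position 183 lies in codon ⌈183/3⌉ = 61). For substitutions,
every 9- and 10-mer window containing a changed residue is enumerated,
clipped at the protein ends; windows identical to the wild type at the same
coordinates are excluded since they cannot be neoepitopes. For truncating or
frameshift changes every window overlapping the novel sequence through the
new C-terminus is emitted. Binding scores are injected from a TSV
(`peptide`, `allele`, `ic50_nM`, `percentile_rank`) — the package never
calls a prediction service, keeping builds offline; the filter passes a
candidate when IC50 < 500 nM and/or percentile rank < 6, survivors are
ranked by percentile rank ascending (IC50, then sequence, as tiebreaks;
percentile rank is the allele-comparable score, an IC50-primary ordering is
selectable) and the global top 94 retained, QC peptides appended unranked.
The bundled `synthetic_kras_like_cds` is a synthetic stand-in, not the real
transcript: only residues 55–64 (ILDTAGQEEY, codon 61 = CAA) reproduce the
RAS context that the codon-61 worked examples exercise.

## The synthetic-data generator

The generator defines the conditions under which the pipeline is evaluated;
all generators are pure functions of (config, seed) with per-operation
derived streams.

- **Clone sizes** follow a Zipf law with exponent 1.0 (configurable); the
  selection logic only requires a heavy tail, and the empirical
  rank-abundance slope reproduces the exponent within ±15 % at 5,000 clones.
- **Planted enrichment**: a fully shared 2,000-clonotype background at
  50,000 reads per compartment, with 20 clonotypes drawn from moderately
  abundant ranks (30–500) boosted 20-fold in tumor (and 2× further in the
  PD-1⁺ fraction), multinomially resampled per compartment. The planted
  clones' empirical tumor/lung ratios average ≈ 17 (renormalization eats a
  little of the nominal 20×), squarely above the >5 calling threshold.
- **Reads**: each clonotype's amplicon is full V + insert + full J
  (180–192 nt), so both 150 bp mates cover the junction; substitution errors
  at 0.5 % per base carry Phred 10–25 against 37 for correct calls,
  emulating that sequencers flag most miscalls with reduced quality. This is
  what the quality-aware merger exploits; error-free simulation gives 100 %
  junction recovery, 0.5 % error ≥ 99 %.
- **FFPE panel**: 29 samples, query homologs planted in 6 (perfect matches
  at coverages from 2 to 150; near homologs at supporting coverage in half);
  other samples carry single-substitution derivatives of abundant clones at
  coverage ≤ 2 — the artifact class the frequency/coverage filter is
  designed to reject — and sometimes an artifact-like query near-homolog
  below thresholds.
- **Single-cell dataset**: five clusters, 30 clonotypes homed in the
  designated high-ratio set {0, 2, 3} and 30 in {1, 4}; cells land off-home
  at rate 0.05 (creating dual-group memberships); natural-log ratios are
  N(1.0, 0.35²) vs N(0, 0.35²). The dispersion 0.35 is a design value: the
  generator declares that its planted bipartition attains the minimal
  adjusted p in ≥ 95 of 100 replicates, and with 30 clonotypes per group the
  Mann–Whitney statistic saturates, so the declared 1.0 shift must be a
  clear multiple (≈ 2.9×) of the within-group spread for near-planted
  competitor partitions to lose reliably. Under the null (shift 0) the
  Bonferroni-corrected scan reaches any adjusted p < 0.05 in ≲ 5 % of
  replicates.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: VDJ recombination biology (insertion/deletion
profiles, segment-usage priors), UMI structure, position-dependent quality
models, clonotype sharing between patients beyond the planted homologs, and
expression-derived cluster labels (cluster assignments are generated, not
clustered from counts).

## Problem sizes

Default test and reproduction runs use 1,000 read pairs for junction
recovery, 2,020 clonotypes at 50,000 reads per compartment for selection,
100 replicates for the bipartition-scan power and null checks, and the
29-sample panel — sizes at which every quantity of interest is stable from
seed to seed while a full run stays in the tens of seconds.

## Known limitations

- Anchor-based ungapped V/J assignment assumes the toy-library geometry
  (junction inside the mate overlap, no indels); real repertoires need a
  gapped aligner and full germline references.
- The pseudocount ratio floor makes absent-in-lung ratios depth-dependent by
  construction; comparing ratios across samples of very different depth
  should use counts, not ratios alone.
- The exact Mann–Whitney branch requires tie-free data; tied small samples
  fall back to the (less accurate at small n) normal approximation.
- Frameshift peptide windowing treats the entire novel tail as mutated and
  does not model stop-loss read-through.
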