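# Methods

This note records the statistical model behind each stage, every default
and its rationale, what the synthetic generator does and does not emulate,
the numerical choices, and the known limitations.

## 1. Event model and coordinates

All junction coordinates are 1-based inclusive **intron** positions, the
dialect of STAR's `SJ.out.tab` (9 columns; only column 7, unique-mapping
read count, is used). A cassette-exon skipping event is an ordered junction
triplet (UJ, DJ, SJ) on one chromosome with

- `SJ.start == UJ.start` and `SJ.end == DJ.end`,
- `UJ.end < DJ.start`, with at least one exonic base between them.

The cassette exon is `[UJ.end + 1, DJ.start − 1]`. The event id
`chrom:ujstart-ujend:djstart-djend` is strand-free; a triplet mixing `+`
and `−` junctions is rejected, while undefined-strand junctions inherit the
strand of their partners. Enumeration is a hash join on shared junction
starts/ends; the test suite checks it against an exhaustive scan of all
ordered triples.

## 2. Junction-level filters

- **Support:** a junction is kept when its count reaches `min_reads = 5` in
  at least one sample of the dataset (per cancer type). Rationale: single
  spurious alignments routinely produce 1–4 read junctions.
- **Balance:** in **every** sample of the dataset, the flanking counts must
  satisfy `|UJC − DJC| < 10` **or** `|UJC − DJC| < 2 · min(UJC, DJC)` (both
  inequalities strict). Strongly unbalanced flanks indicate an alternative
  first/last exon or a mapping artifact rather than a cassette exon.
  Because the rule quantifies over samples, it becomes stricter as cohorts
  grow; see §8 for the measured consequence under Poisson noise.

Discovery runs per cancer-type dataset; per-type event sets are unified by
event id for the cross-cancer stages.

## 3. PSI and coverage

For counts (UJC, DJC, SJC):

- `PSI = ½(UJC + DJC) / (½(UJC + DJC) + SJC)`; undefined (NaN) when the
  denominator is 0.
- `coverage = ½(UJC + DJC) + SJC`.

An event enters testing in a cancer type only if `coverage ≥ min_cov = 10`
in **both** members of at least `min_pairs = 15` matched pairs. Ten
informative reads bound the PSI standard error near 0.15 at worst; fifteen
pairs is the smallest n at which the Wilcoxon test can reach the corrected
significance thresholds with a reasonable margin.

## 4. Differential calling

Per event and cancer type, a paired two-sided Wilcoxon signed-rank test on
tumor-minus-normal PSI over coverage-qualified pairs (zero differences
dropped, scipy's exact null for n ≤ 25 without ties, otherwise the normal
approximation with tie and continuity correction). p-values are
Benjamini–Hochberg adjusted **within each cancer type** over its tested
events. A call is significant iff `q ≤ fdr = 0.05` **and**
`|mean ΔPSI| ≥ min_delta = 0.10`: the rank test alone can reach
significance on consistent but biologically negligible shifts, so an
effect-size floor is imposed jointly.

## 5. Recurrence and markers

- Events significant in ≥ 2 cancer types are **coherent** when every mean
  ΔPSI has the same sign, otherwise **non-coherent**; single-type events are
  labelled `single`.
- A **marker** for a cancer type is an event with same-direction
  `|ΔPSI| ≥ marker_delta = 0.10` in at least `marker_frac = 90%` of its
  coverage-qualified pairs (fraction = max(n_up, n_down)/n_pairs). The 90%
  bar targets per-patient diagnostic usefulness, not cohort-mean shifts.

## 6. Motif enrichment and conservation

Scanned regions per event, in transcription orientation: the cassette exon,
and up to `flank = 250` nt of each flanking intron adjacent to the exon
(truncated to the intron when shorter; 250 nt covers the region where
splicing-factor binding concentrates while limiting multiple testing). On
`−` strand events the genomic left/right windows swap upstream/downstream
roles and sequences are reverse-complemented; undefined-strand events are
excluded from sequence analyses.

For every k-mer (k ∈ {4, 5, 6}) the unit is **presence per region** (an
exon either contains the k-mer or not), which makes the hypergeometric
model exact: with the foreground and background regions as the finite
population, the upper-tail hypergeometric p-value tests over-representation
of k-mer-bearing regions in the foreground. Foreground = regions of
significantly changed events (intron flanks stratified by change direction,
exons pooled across directions since exonic elements act in both);
background = tested-but-unchanged events. BH correction runs within each
(region, direction, cancer type) stratum at `motif_fdr = 0.01` — stricter
than the event-level FDR because the k-mer family is large and
cross-correlated. Enriched k-mers are mapped to factors by substring match
against a small built-in table (RBFOX: TGCATG/GCATG; QKI:
ACTAAC/CTAA(C)); the table is user-replaceable.

Conservation profiles average a per-base score track in a ±50-nt window
around each occurrence midpoint (`start + (len − 1)//2`, genomic strand);
missing track positions are excluded per offset rather than imputed.

## 7. Synthetic cohort generator

`CohortDesign()` defaults **are** the study conditions used by the
acceptance analyses: 3 cancer types × 20 matched pairs, 1000 events of
which 100 are altered with |ΔPSI| = 0.25, mean junction depth 50.

Model, per event and sample:

- Truth: normal-tissue PSI π ~ U(0.10, 0.90); altered events draw their
  baseline so that both directions of the ±0.25 effect stay inside [0, 1]
  without clamping. 65% of altered events are coherent across types; a
  non-coherent event flips its sign in the last cancer type (emulating a
  tissue whose splicing program diverges from the others).
- Per-sample depth d ~ Gamma(mean 50, CV 0.3) — overdispersion across
  libraries; per-sample PSI jitter: a Beta(2, 2)-shaped deviation within
  ±0.05 (biological variability between patients).
- Counts: UJC, DJC ~ Poisson(d·π) independently, SJC ~ Poisson(d·(1 − π)).
  Independent flank draws are what the balance filter sees as noise.
- Gene models: non-overlapping loci on one chromosome, exon length
  U(60, 240), intron length U(300, 500), 50% − strand, i.i.d. uniform
  background sequence.
- Motifs: TGCATG is written into the transcription-oriented downstream
  intron window of 60% of tumor-included altered events versus 10% of all
  other events (reverse-complemented on − strand loci so the oriented
  window reads the k-mer forwards).
- Conservation: baseline 0.4 over all scan windows, 0.9 on planted motif
  bases, both with ±0.05 uniform noise.

What it deliberately does **not** emulate: alignment and mapping artifacts,
multi-mapping reads, annotation errors, overlapping or nested splicing
events, more than one isoform dimension per locus (only the cassette exon
varies), realistic sequence composition (uniform background), linked
expression changes, batch effects, and unpaired designs. Conclusions about
those failure modes cannot be drawn from this generator.

`mirror_cohort` reverse-complements the genome and maps every coordinate
p → L − p + 1 with strands flipped; biology is unchanged, so any
discrepancy in discovery, PSI, differential calls, or enrichment between a
cohort and its mirror is a strand-handling bug. The acceptance suite runs
this probe end to end.

## 8. Measured behavior of the balance filter

At the default conditions, the every-sample balance rule removes roughly
14% of true (event, cancer type) instances through Poisson noise alone
(e.g. UJC = 3, DJC = 13 in one sample of 40: the difference 10 fails both
strict inequalities). This is the specified filter operating as designed —
it trades per-dataset sensitivity for protection against systematically
unbalanced flanks. Consequently sensitivity is quoted at the **event
level** (detected in ≥ 1 cancer type), which at default conditions is
0.98–1.00 with empirical FDR 0 across seeds; per-instance sensitivity is
about 0.86.

## 9. Numerical and engineering choices

- Exact Wilcoxon null for n ≤ 25 without ties (scipy), else normal
  approximation with tie and continuity corrections; n < 2 is untestable
  (NaN p), and all-zero differences return p = 1.
- BH via the standard step-up with NaN passthrough (untested entries never
  consume a rank).
- Hypergeometric tails via `scipy.stats.hypergeom.sf(k − 1, …)` —
  survival-function form avoids summing many tiny terms.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; cohorts and pipeline outputs are
  byte-reproducible. The TSV header hash covers analysis parameters only
  (not file paths), so the same analysis in another directory produces
  identical artifacts.
- No caching: stages re-derive deterministically from inputs + config.

## 10. Limitations

- Only cassette (skipped-exon) events are modelled; mutually exclusive
  exons, alternative 5'/3' splice sites, and intron retention are out of
  scope.
- PSI from junction counts is a ratio estimator; it is biased at low
  coverage (the coverage filter bounds, but does not remove, this bias).
- The balance filter's every-sample quantifier makes discovery sensitivity
  decrease with cohort size at fixed depth (§8).
- Presence/absence k-mer testing ignores occurrence multiplicity and
  positional clustering; the conservation profile is descriptive, not a
  test.
- Factor assignment by substring lookup is indicative only; motif tables
  for most splicing factors overlap heavily.
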