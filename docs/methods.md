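# Methods

This note records the models, conventions and design choices behind
`nmdscope`, in the order the pipeline runs them.

## Coordinate model

All internal coordinates are 0-based half-open; GTF I/O converts from and
to the format's 1-based inclusive convention at the boundary, so interval
lengths and gaps are plain differences and no ±1 arithmetic leaks into the
rules. Exons are stored genomic-ascending regardless of strand; the 5′→3′
transcript orientation is applied in exactly one place, the projection of a
genomic position onto the spliced mRNA. Attribute parsing accepts both
`gene_biotype` (Ensembl) and `gene_type` (GENCODE) keys, preferring the
former; transcripts whose features span multiple chromosomes or strands are
rejected outright rather than silently split — corrupt annotation should
fail loudly.

## NMD-susceptibility rule

A coding transcript is NMD-prone when at least one of three features
holds. All quantities are spliced (exonic) base counts, with the reference
point *s* = spliced offset of the stop codon's 3′-most base:

- **LONG_UTR3** — 3′UTR length = spliced length − (s + 1) ≥ 1250 bp. The
  threshold is inclusive.
- **UTR3_INTRON** — at least one intron lies within the 3′UTR, where "within"
  means both flanking exons consist entirely of 3′UTR sequence.
- **DOWNSTREAM_JUNCTION** — some junction's distance d = (offset of the last
  exonic base 5′ of the junction) − s exceeds 50 nt, strictly.

Conventions worth spelling out:

- A junction counts as downstream of the stop only when at least one 3′UTR
  base precedes it (d ≥ 1). A junction falling exactly at the stop/UTR
  boundary (d = 0) triggers nothing: the EJC deposited there sits at the
  terminating ribosome's position and is displaced during termination.
- The two junction-based criteria are deliberately disjoint in attribution.
  An intron whose upstream exon still contains coding sequence is the
  territory of the distance criterion (it fires iff d > 50); the
  3′UTR-intron criterion covers introns strictly inside the UTR. A
  junction 1–50 nt downstream of the stop whose upstream exon carries the
  CDS therefore triggers neither — consistent with the biology of the
  50-nt rule, where a junction that close to the stop does not elicit
  decay. This makes each reported rule an independent structural cause,
  which is what the synthetic generator's one-feature-per-transcript
  planting verifies.
- Stop-codon resolution: explicit `stop_codon` features win when present
  (their 3′-most spliced base is *s*); otherwise *s* comes from the CDS.
  GTF dialects disagree on whether the CDS includes the stop codon, so
  both are supported via `cds_includes_stop` (default true: *s* is the
  CDS's 3′-most spliced base; when false, *s* is 3 spliced bases further,
  clamped at the transcript end).
- Transcripts with neither CDS nor stop codon (non-coding biotypes) are
  *not evaluable*: reported with zeroed features, never prone, and kept in
  the output so denominators remain auditable.
- Gene-level aggregation is any-transcript OR by default (a gene is prone
  when ≥ 1 transcript is); an all-transcripts policy is available. OR is
  the weakest defensible assumption when RNA features are classified per
  transcript but counted per gene, and the choice is explicit
  configuration rather than buried.

## Differential-expression filter

Fold change is the literal FPKM ratio case/control; with the default
pseudocount of 0, a gene expressed only in the case condition has fold
change +∞ (retained as up-regulated) and a 0/0 gene is undefined and
excluded. A positive pseudocount is available for users who prefer
stabilized ratios. A gene is DE when q ≤ 0.05 (inclusive — "0.05 or less")
and fold change > 1.5 or < 0.67 (both strict — "greater than"/"less
than"). Benjamini–Hochberg adjustment (`bh_fdr`, via statsmodels) is
provided for tables that carry only p-values; q-values present in the
input are otherwise consumed as-is, since estimating them is the upstream
quantifier's job. The biotype breakdown collapses pseudogene sub-biotypes
into a single `pseudogene` bucket through an editable mapping, and counts
DE genes missing from the annotation under `unknown` with a warning. Both
the fraction of annotated and of detected genes are reported, since "x % of
transcripts are differentially expressed" depends on that denominator;
*detected* means nonzero FPKM in at least one condition.

## Gene-set over-representation

The enrichment p-value is the hypergeometric upper tail P(X ≥ k),
evaluated with scipy's log-space survival function rather than naive
factorials. Sets and query are intersected with the universe before
counting, so out-of-background identifiers can only shrink K, n and k,
never inflate significance. The default universe is the expressed genes
(nonzero FPKM in either condition); all annotated genes is the documented
alternative. Identifier matching is case-insensitive with an optional
offline synonym map — cross-species symbol drift is user-controlled, no
network lookups. Per-set p-values are reported without correction across
sets by default (significance flag at p < 0.05), matching the practice the
pipeline emulates; BH across sets is available where more rigor is wanted.
A set with no members in the universe yields K = 0, p = 1 and a
`degenerate` flag.

## Splicing-event summary

Events are consumed from a MISO-style summary table; ψ inference itself is
out of scope. An event is significant when Bayes factor > 10 and
|Δψ| > 0.2 (both strict) and its informative-read count meets a floor
(default 20, inclusive). The single read floor is a deliberate surrogate
for MISO's per-isoform read-class thresholds — the only desk-reproducible
form of that filter — and is labeled as such. Δψ is absolute by default
(a signed mode exists) and BF = +∞, MISO's marker for overwhelming
evidence, passes the filter. The summary reports counts and percentages
per event type over the five-category vocabulary (SE, A3SS, A5SS, ALE,
AFE) plus the distinct-gene count; percentages are over represented types
and total 100.

## Synthetic data

The generators exist to make every downstream claim testable against
planted truth; their defaults are the study conditions the pipeline is
built for.

- **Annotation** (default 50 genes, 1 transcript each): 15 % of genes are
  non-coding (lincRNA / antisense / processed pseudogene, no CDS); 40 % of
  coding transcripts are planted prone, each with exactly one triggering
  feature chosen uniformly — a 3′UTR drawn in [1250, 5000] bp, one 3′UTR
  intron with every junction ≤ 50 nt downstream of the stop, or a junction
  51–500 nt downstream. Non-prone coding transcripts keep 3′UTRs in
  [60, 1200) bp and (30 % of the time) a benign junction ≤ 50 nt
  downstream, so near-threshold geometry is represented on both sides.
  5′UTRs are 20–300 bp, CDS 300–1500 bp, introns 80–2000 bp, strands
  random.
- **Expression** (default 10 % DE, balanced up/down): control FPKM is
  log-uniform on [1, 100]; DE genes get fixed fold changes 3.0 (up) and
  1/3 (down) with q uniform in (0, 0.05]; null genes get fold change
  uniform in [0.9, 1.1] and q in (0.05, 1]. Requesting planted fold
  changes inside the filter's dead zone (fc_up ≤ 1.5 or fc_down ≥ 0.67) is
  a generation error, since the truth would be unrecoverable by design.
- **Gene sets**: one set with an exact planted overlap against a
  designated query (remaining members drawn outside the query), the rest
  uniform draws from the universe — their overlap follows the
  hypergeometric null, which the calibration test checks across seeds.
- **Events** (default 500 events, 20 % significant): significant events
  draw BF log-uniform in (10, 10⁶], |Δψ| in (0.21, 0.8] and reads at or
  above the floor; each null event violates exactly one criterion. Event
  types follow a composition vector mapped to integer counts by largest
  remainder; the default composition is the published breakdown SE 61.4 %,
  ALE 18.5 %, A3SS 11.15 %, A5SS 9.24 % (normalized — the printed values
  total 100.3 % from rounding), with AFE in the vocabulary at weight 0
  because no printed share exists for it.

Determinism contract: one integer seed per generator invocation; entity
geometry uses child streams keyed by (seed, entity index); identical seed
and parameters reproduce identical output bytes.

What the generators do *not* emulate: read-level sampling noise, FPKM
variance structure, isoform-sharing between overlapping genes, annotation
errors, or correlated q-values. Passing the planted-truth tests therefore
demonstrates that the rules and thresholds are implemented exactly, not
that the pipeline is robust to the estimation noise of real quantifiers —
on real data the upstream tools own that uncertainty.

## Numerical and degenerate-input choices

- Hypergeometric tails are exact to < 1e-12 relative error against
  rational-arithmetic enumeration on all universes N ≤ 20; k = 0 returns
  exactly 1.0.
- Thresholds are validated (positive where required, up_min > down_max);
  violations raise configuration errors rather than producing empty
  output.
- Empty inputs fail loudly: an empty DE set has no biotype breakdown and
  no NMD intersection, and the pipeline halts at the enrichment stage with
  an empty-query error; an empty significant-event set has no summary.
- Reports contain no timestamps, so reruns are byte-comparable; every
  fraction in the report carries its numerator and denominator.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
250 random transcripts for classifier/oracle equivalence, 1000-gene
expression tables, universes of 300–1000 genes, 200–500 events, and
200-seed calibration loops. These sizes were chosen so every distributional
check has comfortable resolution while the whole suite stays interactive.

## Known limitations

- NMD-susceptibility here is structural annotation geometry only: no
  sequence, no uORFs, no PTC calls from variants, no decay-rate
  prediction. Prone/not-prone is a hypothesis label, not a measurement.
- The 3′UTR-intron/junction attribution convention (above) is one
  defensible reading of an OR-of-three rule whose criteria overlap; the
  combined prone verdict is insensitive to it except for the
  junction-within-50-nt corner, which the convention deliberately treats
  as NMD-evading.
- The gene-level biotype is taken from the transcript records' gene
  attributes; when a gene's transcripts disagree, the first record wins.
- Disease gene-set content is user-supplied; the package ships no curated
  lists, so published per-disease p-values are not reproduction targets.
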