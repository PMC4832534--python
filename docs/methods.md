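# Methods

## Coordinates and interval arithmetic

All intervals are 1-based and fully closed (`chrN:start-end`, exactly as
array-CNV reports print them); two intervals overlap iff they share at
least one base, and a database report "fully overlaps" a candidate iff
it contains it. Conversion to 0-based half-open coordinates happens only
in the BED writer. Chromosome labels are normalized on ingest (strip a
`chr`/`Chr` prefix, uppercase X/Y) because real tables mix conventions.

CNV size in Mb is `(end − start) / 10^6`, rounded to two decimals — the
span, not the base count. This is the convention under which 17 of the
18 reference-cohort sizes are reproduced exactly from their own
coordinate strings; the `+1` alternative reproduces none of the
x.x5-boundary cases. The 18th entry (the chrX:4,642,016-11,935,042
deletion) prints 7.2 Mb while its own coordinates give 7.29 Mb under
either convention; the package always computes from coordinates and the
`reproduce-table1` command flags the discrepancy rather than
special-casing it. The source's stated size range ("0.07 to 9.23 Mb")
contains a maximum matching no printed CNV; neither value is used as an
oracle anywhere.

## The filter cascade

Criteria are applied in the fixed order I → II → III → IV → V → VI →
VII; evaluation stops at the first failure (later verdicts are recorded
as `not_evaluated`) and the audit trace keeps, per call, all verdicts
plus the control frequency, the database report count and the overlapped
CNS gene symbols. Boundary semantics read the exclusion phrasings
literally: log Bayes factor *below* 30 is excluded (exactly 30 survives),
*fewer than* 3 markers is excluded, control frequency *above* 1 % is
excluded, and *five or more* fully-containing database reports exclude.

Two rules the source workflow leaves unstated are explicit, defaulted
parameters here:

- **Control-cohort identity (criterion III).** Whether a control carries
  "the same" CNV needs an identity notion across samples. Default: same
  type and reciprocal overlap ≥ 0.5 (`FilterConfig.control_match_*`).
  Frequency is the fraction of control *individuals* with ≥ 1 matching
  call over the full cohort size (individuals without calls count in the
  denominator), reported to 4 decimals — a single carrier among 1307
  controls gives 0.0008.
- **Database containment (criterion VI).** "Fully overlapping report" is
  read in the stringent direction — the report contains the candidate —
  and is type-matched by default (`MIXED` records match both types);
  both choices are config-exposed since the looser readings are also
  defensible. Reports are counted individually; duplicates count.

The two manual gates are modelled as an optional machine-readable
decision table so the cascade is fully automatable yet can replay human
review: an `exclude` decision fails a call at IV; a `rebreak` decision
(VII) replaces the breakpoints, and the corrected interval governs the
annotation criteria V and VI, while the caller-level statistics (I, II)
and the control match (III) keep referring to the reported interval —
the corrected breakpoints describe what the variant really spans, the
reported ones what the caller measured. Criteria I, II, III, V and VI
depend only on the call and static resources, so permuting them never
changes the retained set (tested exhaustively); the review gates are
order-sensitive by design and fixed in cascade position.

Sample QC (≥ 95 % marker call rate) is a pre-screen, not a cascade
criterion: calls from failed samples never enter the cascade, and the
usable samples define the diagnostic-yield denominator.

## Trio segregation

qPCR-style relative copy ratios are normalized so 1.0 means the
reference copy number. Per-locus calls use fixed thresholds — loss below
0.75, gain above 1.25 — and a person's state is the majority per-locus
call, required to be a strict majority with at least 2 agreeing loci.
The thresholds and the majority rule are this package's surrogates for
unpublished assay criteria; both are config-exposed
(`SegregationConfig`). They sit halfway between the expected ratios
(0.5 / 1.0 / 1.5 for one-copy changes against two copies), giving > 3 sd
of margin at a realistic qPCR noise of sd ≈ 0.08.

Male X-chromosome loci are referenced to a single copy: input ratios on
the two-copy calibrator scale are doubled before thresholding, so a
hemizygous duplication (2 copies, raw ratio 1.0) and a female carrier
(3 copies, raw 1.5) are both gains, and a normal male X (raw 0.5) is
normal — required for maternally transmitted X duplications in male
fetuses to segregate correctly. MLPA confirmations flow through the same
ratio interface; the probe-mix identity is metadata.

Confirmation precedes segregation: the fetal state must reproduce the
array call's type, otherwise the CNV is reported unconfirmed and never
classified. Given a confirmed fetal aberration, the verdict is a total
function on the 4×4 grid of parental states (loss / normal / gain /
missing): a parent carries the CNV iff their state equals the fetal
aberration; both carriers → biparental, one → maternal/paternal, none
with both parents measured → de novo, one parent missing with the other
normal → paternal/maternal-excluded, both missing → not tested. A parent
showing the *opposite* aberration does not carry the fetal CNV and is
treated as a non-carrier; with both parents non-carriers and measured,
the verdict is de novo.

## Classification

Disease causing requires de novo occurrence and/or ≥ 1 bp overlap with a
type-compatible *established* curated region; probably disease causing
requires a *candidate*-region overlap without either trigger; everything
else is a VUS. Inheritance from a healthy parent, or untested status, is
recorded as evidence but never changes the class — so the class is
monotone in evidence. The curated lists are data, not code: the packaged
default holds five established regions (6q27 terminal deletion, 6p25
*FOXC1* deletion, 17p11.2 Potocki-Lupski duplication, Xp22.2 *MID1*
deletion, Xp22.32-p22.33 duplication) and one candidate region (3p26.3
*CNTN6*); users substitute their own evidence base by passing a
different region table. Region coordinates are hg19 gene/band spans.

The diagnostic yield is `100 × (fetuses with ≥ 1 disease-causing CNV) /
(analyzed fetuses)`, rounded to the nearest integer per cent — 4 of 33
gives 12 %.

## The packaged reference cohort

`cnvtriage/data` ships the 18 validated CNVs of a 33-fetus study as
TSVs with a sha256 manifest: coordinates, types, cytogenetic bands,
printed sizes, marker and flanking-SNP identifiers (`Telomer` marks a
call running into a telomere) and per-CNV inheritance outcomes (4 de
novo, 1 maternal, 1 paternal-excluded, 12 untested). Because per-call
quality scores are not published, fixture calls carry placeholder
log-Bayes-factor/marker values far above threshold (named constants), so
cascade verdicts on the fixture are driven by the real coordinates,
cohort and annotation inputs. The accompanying gene table holds one
representative CNS-flagged gene per CNV with an approximate hg19 coding
span — enough for criterion V to genuinely evaluate, not a complete
annotation — and the control table encodes the published observation
that exactly two of the 18 CNVs (both in one fetus) were each seen once
among 1307 controls. The fixture follows the published per-CNV tallies
throughout, including the two entries where the source's own prose is in
tension with them (one deletion discussed as phenotype-explaining is
tallied VUS; one band is spelled differently in the abstract than in the
results table — the results-table values are used).

## Synthetic cohorts

The generator emulates the study conditions: 35 recruited fetuses with 2
array-QC failures (call rates drawn below 0.95) and a 1307-individual
control cohort, on a miniature genome of three 10-Mb autosomes plus X.
Planted CNVs occupy disjoint 400-kb slots separated by 200-kb gaps, so
no two planted features interact by accident; requesting more CNVs than
slots is an error. Each planted call belongs to a class violating
exactly one criterion — true (6 by default), low confidence (5, LBF
uniform 2–29.9), under-supported (5, 1–2 markers), and common (4,
alternating between control-common, carried by 2 % of controls, and
database-common, covered by 6 fully-containing reports) — and every
class overlaps a planted CNS-flagged gene so only the intended criterion
can act. True CNVs get trio ratio panels (3–4 loci; Gaussian noise
sd = 0.05 by default, a realistic qPCR spread) with planted inheritance
(de novo fraction 0.5); planting is autosomal, with male-X ratio
handling exercised by dedicated unit tests. All randomness flows from
one seed through a single generator stream; equal seeds give
byte-identical bundles.

What the synthetic data does *not* emulate: LRR/BAF probe-level signal,
correlated breakpoint uncertainty between cases and controls, population
structure in control frequencies, segmental-duplication hotspots, or
cohort-scale call counts (thousands of raw calls per real cohort).
Passing the planted-truth tests therefore demonstrates that the
*decision logic* is correct under the stated identity rules, not that
the thresholds are optimal for any particular array platform.

## Problem sizes and numerics

The shipped tests and the acceptance script run the fixture pipeline
(18 calls × 1307 controls), 20-seed cascade-invariant sweeps (~22 calls
each), 500-trio inheritance-recovery simulations and 500-interval
brute-force oracle comparisons — all complete in seconds on one core.
Ratios are clipped at 0; frequencies are exact rationals reported to 4
decimals; per-class tallies are integer counts; no optimization or
iterative numerics are involved, so results are exactly reproducible
across platforms for a fixed seed.

## Known limitations

- Criterion III's identity rule and criterion VI's containment direction
  are declared defaults, not published definitions; changing them can
  change retained sets near the thresholds.
- The qPCR thresholds assume one-copy changes; mosaic or multi-copy
  amplifications (ratios near the thresholds) may be called unconfirmed.
- Curated-region overlap uses ≥ 1 bp with type compatibility; no dosage
  or gene-level weighting is attempted (no ACMG/ClinGen scoring).
- No genome-build liftover: all coordinates, packaged and user-supplied,
  must share one build (the packaged data are hg19).
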