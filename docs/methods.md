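# Methods

## Reference models and coordinates

Each panel gene is represented by exactly one reference isoform, named
explicitly in the panel configuration (gene symbol, transcript id, and any
excluded exons). All events are defined relative to this isoform;
junctions matching *other* annotated isoforms are still treated as
alternative events with measurable PSI, which mirrors how constitutively
expressed minor isoforms show up in control profiles.

Exon intervals are stored 1-based inclusive (the GTF/STAR convention);
cumulative transcript arithmetic runs on derived 0-based half-open arrays.
Transcript positions use r.-style notation: exonic bases map to the
cumulative coordinate, intronic bases to nearest-boundary offsets
(`n+k` after a donor, `n-k` before an acceptor; midpoint ties anchor to
the donor). This is a simplified deterministic scheme, not full HGVS:
no uncertainty syntax, no multi-transcript names.

Excluded exons (e.g. a region confounded by a near-identical pseudogene)
stay in the model so transcript coordinates are unchanged, but any event
whose skipped exons or genomic span touches them is dropped from
quantification, and they are not counted in coverage QC.

## Event classification

A junction is an excised interval; its two attachment points are compared
with the reference exon boundaries. Both ends at canonical boundaries of
adjacent exons is the canonical junction; of non-adjacent exons, a full
skip (ESF) of everything between. One canonical end with the other end
strictly inside an exon is a partial skip (ESP); strictly inside the
adjoining intron, an intronic extension (IP). An end coinciding exactly
with a canonical boundary is always read as canonical, which prevents
zero-length partial-skip artifacts.

The IP signature is inherently ambiguous: a junction from a canonical
boundary into the adjoining intron is equally consistent with an exon
extension and with one flank of a cryptic exon — junction counts cannot
distinguish a retained stretch from a re-spliced one. The classifier
therefore labels such junctions IP provisionally, and a pairing pass
upgrades a donor-anchored and an acceptor-anchored candidate in the same
intron to a single cryptic-exon event (IC) whenever the implied intronic
interval between them is non-empty; each candidate consumed by a pair
loses its IP reading, unpaired candidates remain IP. Every compatible
pair yields its own IC, so two alternative cryptic exons in one intron
are both reported.

Junctions with both ends inside exons (exitron-like) have no category in
this taxonomy and are left unassigned with a logged reason. Frame status
is purely `(inserted − deleted) mod 3`.

## PSI quantification

PSI = 100·alt/region. The region denominator is the alternative count
plus the rounded mean of uniquely-mapping reads over the canonical
junctions the event replaces: one junction for ESP/IP, the k+1 junctions
spanned by a k-exon skip, and the host intron's canonical junction for
IC (whose alternative count is likewise the rounded mean of its two
flanks). Averaging rather than summing avoids counting one canonical
molecule at several junctions, and reduces to alt/(alt+canonical) for
single-junction events. This construction is isolated behind
`quantify.region_reads` so an alternative denominator (for example, all
reads overlapping the genomic region, junction-spanning or not) can be
swapped in without touching the callers. Only uniquely-mapping reads are
counted; multi-mapped counts are carried through I/O but never used.
Events with no supporting unique read are not emitted — absence and
PSI 0 are equivalent.

## Control profile and QC

A sample passes coverage QC when at least 85% (inclusive) of the panel's
non-excluded exons have mean depth ≥ 50×; both thresholds are
configuration values. Sequencing-level metrics (fraction of Q30 bases
> 0.75, mean base quality > 30, perfect-index fraction > 0.85) are
accepted as a precomputed table and gate the sample when supplied; the
package does not compute them from reads.

Per event the profile keeps two summaries: median and IQR over the
controls in which the event was detected (the reference-table view), and
mean/SD over *all* QC-passing controls with PSI 0 assigned where the
event was absent (the vector the t-test runs against). An event seen in
no control is absent from the profile; a patient presenting it is tested
against an all-zero vector and flagged novel.

The common-event filter keeps events with at least `floor(freq_min · n)`
controls at PSI ≥ `psi_min` (defaults 0.05 and 5). The floor form is
deliberate — with 345 controls it gives a count threshold of 17 even
though 17/345 is 4.93% — because that is how such thresholds are applied
in practice when a published count and a rounded percentage disagree; a
strict ceiling reading is available via `strict=True`.

## Aberrant calling

One-sample two-sided t-test of the patient PSI against the zero-assigned
control vector, df = n−1. With zero control variance the statistic is
undefined; the implementation reports p = 1 on equality and p = 0
otherwise with an explicit `degenerate` flag (rather than NaN), because a
control-absent event at high patient PSI is the clinically decisive
finding and must sort first, not drop out.

Multiple testing is corrected per patient sample with the Holm–Šidák
step-down: ascending p, adjusted `1 − (1 − p_(i))^(m−i+1)`, running
maximum, capped at 1. The adjusted values are computed through
`expm1`/`log1p` so that p-values far below double epsilon still satisfy
adjusted ≥ raw. The tested family is the set of that patient's events
passing the direction filter (patient PSI strictly above the control
mean) and both gates (PSI ≥ 5, region reads ≥ 50); the per-sample family
matches the clinical reporting unit. Events outside the family are
reported with raw statistics but no adjusted p and can never be
significant. Significance requires all four criteria: PSI ≥ 5, PSI above
the control mean, adjusted p < 0.05, region reads ≥ 50.

A known property, not a defect of the implementation: the one-sample
design compares a single noisy patient measurement against the standard
error of the control *mean*, so as an outlier test it is anticonservative
— a patient drawn from the same population as the controls will often
reach small p once past the gates. The PSI and direction gates, not the
t-test alone, carry much of the specificity. The type-I guarantee that
is tested (and holds) is calibration of the test itself: when the patient
PSI equals the cohort-shared true PSI, the significant-call rate among
gate-passing tests stays at the nominal level.

## Synthetic data

The generator emulates the study design the package targets: a panel of
18 genes (8–45 exons of 60–250 nt, introns 300–3000 nt), 345 controls,
and deep targeted capture. Junction depth is negative binomial with mean
500× and size 10 (≈32% coefficient of variation — the realistic stressor
for the 50-read gate); given the per-event depth D, alternative reads are
Binomial(D, PSI/100) and the replaced canonical junctions receive D − alt,
making the PSI estimator exactly binomial around the truth. Background
events occur at roughly one per five exons (so per-gene event counts
track exon counts), with population frequencies in 0.15–0.95 and
per-carrier PSI ~ Beta(2, 30)·100 (mean ≈6%); the panel's first event is
made ubiquitous and in-frame at Beta(15, 24)·100 (mean ≈38%), emulating
the strongest constitutive alternative event seen in blood. Spike-ins
are placed on introns unused by the background catalog and drawn
uniformly from PSI 20–60, one per patient. Random streams are split per
sample and per event from the master seed, so enlarging a cohort never
changes existing samples.

What the generator does *not* emulate: read-level artifacts (alignment
ambiguity, splice-motif biases, overhang filters), multi-mapping around
pseudogenes, batch structure in PSI, correlated depth along a transcript,
and partially shared denominators between overlapping events (the catalog
keeps event regions disjoint). Passing tests therefore demonstrate the
statistical machinery and the classification geometry, not robustness to
alignment-level noise in real data.

## Numerical and scale choices

Rounded means use half-up rounding for determinism. PSI is kept
unrounded internally and rounded to two decimals only for display.
Acceptance-style checks run at reduced problem sizes chosen to keep the
whole suite fast while leaving the statistics well-resolved: parameter
recovery uses 200 controls × 20 events (≈4000 cells), null calibration
50 cohorts × 20 events × 40 controls (≈1000 tests, of which the direction
filter admits about half), and power 200 patient replicates against 100
controls. Holm–Šidák and the t-test are verified against independent
references (statsmodels' implementation and scipy's `ttest_1samp`)
as oracles, never used as the implementation.

## Known limitations

* One reference isoform per gene; no isoform deconvolution or
  expression normalization.
* The denominator uses junction-spanning reads only; a laboratory whose
  convention counts all overlapping reads will see systematically lower
  PSI for the same data.
* Cryptic exons spanning more than one intron, and exitron-like
  junctions, are not classified.
* The multiple-testing family is per patient sample; a per-cohort family
  would be more conservative and is not implemented.
* No batch-effect modeling or correction.
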