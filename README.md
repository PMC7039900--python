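# spliceprofile

Detection of aberrant RNA splicing in targeted capture RNA-seq of a
hereditary-cancer gene panel, using a healthy-control reference splicing
profile built from whole-blood samples.

Clinical DNA panel testing misses or cannot interpret variants whose effect
is mis-splicing — deep-intronic changes creating cryptic exons, weakened
donor/acceptor sites causing exon skipping or intron retention. Capture
RNA-seq of the panel genes in blood makes these effects directly
observable as non-canonical splice junctions. The catch is that healthy
transcriptomes are full of low-level alternative splicing: calling a
patient's event aberrant requires knowing how often, and how strongly,
that event occurs in healthy controls. This package implements that
comparison for laboratories working from junction-count tables
(STAR `SJ.out.tab` dialect) and per-exon coverage summaries.

## Method

Every observed junction is an excised genomic interval, classified against
one designated reference isoform per gene into the event taxonomy
**ESF** (full exon skipping), **ESP** (partial exon skipping via an
alternative donor/acceptor), **ES** (reporting aggregate of the two),
**IP** (exon extension into the adjoining intron) and **IC** (cryptic exon,
evidenced by split reads on both flanks). Each event *e* in sample *s* is
quantified by its percent spliced in,

```
PSI(e, s) = 100 · alt_reads / region_reads,
region_reads = alt_reads + round(mean of unique reads over the canonical
                                 junctions the event replaces)
```

Across QC-passing controls (a sample passes when ≥85% of panel exons have
mean coverage ≥50×), each event gets a detected-only median/IQR for
reporting and a zero-assigned mean/SD vector for testing. A patient event
is compared to that vector with a one-sample two-sided t-test,

```
t = (mean(controls) − PSI_patient) / (SD(controls) / √n),   df = n − 1,
```

p-values are Holm–Šidák-adjusted within the patient's family of tested
events, and the event is called **significant** when all four criteria
hold: PSI ≥ 5, PSI above the control mean, adjusted p < 0.05, and
region coverage ≥ 50 reads. Events never seen in controls are tested
against an all-zero vector (degenerate branch, p reported as 0 and
flagged). Frame status is `in-frame` iff the net length change is a
multiple of 3. Event names are deterministic r.-style labels such as
`r.5075_5152del` or `r.80_81ins81-8_81-1`.

A seed-reproducible synthetic-data generator (`spliceprofile.synthetic_data`)
emulates the whole study design — panel gene models, common low-PSI
background events, heterozygous spike-ins at PSI 20–60%, negative-binomial
capture depth with binomial junction sampling — so every stage is testable
without access to patient data.

## Worked example

Simulate a cohort (60 controls, 2 patients each carrying one spiked
splicing event) and run the full pipeline:

```
$ spliceprofile simulate demo/cohort --seed 7 --controls 60 --patients 2 --genes 6
$ spliceprofile run --config demo/config.json     # paths to the cohort files
```

`demo/out/aberrant_calls.tsv` then contains, among the significant rows:

```
sample_id  gene    event           patient_psi  region_reads  control_mean_psi  p_adjusted  novel_in_patient
PAT0001    GENE01  r.1602_1827del  39.75        395           0.0000            0.0         True
PAT0002    GENE01  r.2062_2122del  25.90        444           0.0000            0.0         True
```

Both rows are the simulated spike-ins (truth PSI 39.4 and 27.9): events
absent from all 60 controls, observed in one patient each at high PSI with
ample coverage — the signature of a heterozygous splice-disrupting
variant. Background events shared with controls appear in the same table
with their control means and adjusted p-values.

The diagnostic-yield arithmetic for a screening cohort:

```
$ spliceprofile yield --before 77 --after 84
positive before RNA: 77
positive after RNA:  84
RNA-attributable:    7
relative increase:   9.1%
```

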