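# tnspore

Transposon-insertion sequencing (Tn-seq) analysis of bacterial sporulation:
a reusable pipeline for finding genes whose disruption blocks, delays, or
*accelerates* spore formation in *Bacillus subtilis*-style screens, together
with a fully seeded synthetic-library simulator so every stage can be
verified without external sequencing data.

## The problem and the method

A Mariner (Himar1) transposon inserts exclusively at TA dinucleotides. In a
pooled library saturating ~63% of a genome's TA sites, each clone's
abundance can be read out by sequencing transposon–chromosome junctions
(MmeI digestion leaves ~16 nt of flanking genomic sequence per read) and
tallying reads at each TA site. Comparing the library at the onset of
starvation (T0) against the survivors of an 80 °C heat-kill at 5 or 24 hours
(T5/T24) turns sporulation into a selectable phenotype:

- **Depletion screen** (sporulation-defective genes). For each gene, the
  per-TA-site read counts of the two libraries (zeros at unoccupied sites
  included — the TA site is the sampling unit) are compared with a
  two-sided Mann–Whitney *U* test; counts are first scaled to reads per
  10⁷ mapped reads. A gene is a hit when *p* < 0.05 and the fold reduction
  *f* = (T0 + c)/(T_sel + c) exceeds 2 (24-hour screen) or 5 (stricter
  5-hour screen), with a pseudocount of c = 1 normalized read. For ≤ 8
  sites the *p*-value is exact, by tie-aware enumeration of all C(2n, n)
  rank splits (a subset-sum dynamic program over doubled midranks);
  otherwise the normal approximation with tie and continuity corrections
  is used. Genes whose reference coverage is too sparse (`low_coverage`)
  or whose modest reduction leaves insertions across the whole ORF
  (`dispersed`) are flagged explicitly rather than curated by eye.
- **Sliding-window scan** (premature-sporulation loci). Insertions that
  make cells sporulate *early* are enriched among T5 spores, often in
  intergenic promoter regions. A 13-TA-site window slides (step 1) over
  every site with ≥ 1 read in both libraries; windows with exact MWU
  *p* ≤ 0.02 and ≥ 3-fold T5 enrichment are merged into regions and
  classified as intragenic (likely inactivation) or upstream of a nearby
  downstream gene (likely over-expression).
- **Phenotype statistics.** Sporulation efficiency (heat-resistant CFU as
  % of wild type) and the co-culture competitive index
  CI = (mut/WT spores at T5) / (mut/WT CFU at T0), with mean ± SEM over
  replicates.

The simulator emulates the screen end to end — Bernoulli TA-site occupancy,
lognormal clone abundances, a multinomial heat-kill bottleneck acting
through per-gene fitness factors, transient T5-only accelerator loci, and
FASTQ junction-read emission — and always writes the ground truth, so
recall, false-hit rates, fold recovery, and scan localization are measured,
not assumed.

## Worked example

```bash
tnspore -v demo --seed 1 --out demo_run
```

simulates a 250 kb, 200-gene genome (15 sporulation-defective genes at
fitness 0.01, 10 delayed-only genes, 3 accelerator loci, 10 essential
genes), emits ~470,000 junction reads per library, re-maps them, runs both
screens and the window scan, and scores everything against the truth:

```
INFO tnspore: T0: emitted 469196 reads, mapped 469196 (0 ambiguous, 0 unmapped)
INFO tnspore: n_ta_sites = 15538
INFO tnspore: defective_recall_t24 = 1.0
INFO tnspore: delayed_recall_t5 = 1.0
INFO tnspore: delayed_called_t24 = 0
INFO tnspore: neutral_false_hit_fraction_t24 = 0.0
INFO tnspore: n_truth_accelerator_loci = 3
INFO tnspore: n_enriched_regions = 3
INFO tnspore: accelerator_loci_recovered = 3
```

All 15 defective genes are recovered at T24 (the 10 delayed genes are — by
design — invisible at T24 and all recovered at T5), no neutral gene is
called, and the three accelerator loci each produce exactly one enriched
region. The top of `demo_run/screen_T24.tsv`:

```
gene      n_ta_sites  t_ref_reads  t_sel_reads  fold_change  p_value
gene0069  65          2326         33           70.4         5.1e-13
gene0066  71          2221         25           88.7         6.0e-11
gene0126  67          2492         38           65.5         2.7e-10
```

i.e. genes designed at 100-fold depletion are estimated at ~65–90-fold
after the bottleneck and renormalization, at vanishing *p*-values.
`demo_run/report.md` holds the full confusion matrices and region table.

The same stages are available separately (`tnspore simulate / map / screen /
scan / phenotype`) on FASTA + GFF3 + FASTQ or pre-tallied profile TSVs; see
`--help` for the thresholds, all of which default to the screen conventions
above.

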