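# Methods

## Coordinates and containers

All genomic coordinates are 1-based and inclusive (GFF3 convention). A TA
site is identified by the coordinate of its T and occupies two bases; TA is
its own reverse complement, so the site list is strand-symmetric and
insertions in either orientation collapse onto one site count (orientation
is not tracked). A TA site belongs to a gene only if both bases lie within
the gene's `[start, end]`; no terminal trimming is applied. Circular
genomes are treated linearly: an origin-spanning TA would be the only site
affected genome-wide, and it is not indexed. Insertion profiles are stored
as `position<TAB>count` TSV (or 0-based half-open bedgraph, each site
spanning its dinucleotide), and a library's `total_mapped_reads` is always
recomputed as the sum of its counts, so depth conservation cannot silently
break.

## The rank test

Per-gene and per-window comparisons use the two-sided Mann–Whitney *U*
test on per-TA-site counts, with zeros at unoccupied sites retained: the
site, not the read, is the sampling unit, and discarding shared zeros
would discard the evidence of depletion. Count vectors are tied-heavy, so
the exact null distribution is computed tie-aware: midranks are doubled to
integers and a subset-sum dynamic program counts, for every achievable
rank sum, the number of size-n₁ subsets of the pooled sample attaining it
— literally the enumeration over all C(n₁+n₂, n₁) group assignments, in
polynomial time. The two-sided p-value is P(|S − E[S]| ≥ |s_obs − E[S]|);
for the equal group sizes used here the null is symmetric and this equals
the doubled one-tail. The exact path is used for genes with ≤ 8 TA sites
and for *all* 13-site scan windows (26 pooled observations are well within
enumeration cost); larger genes use the normal approximation with tie and
continuity corrections. A fully tied pool (e.g. two all-zero essential-gene
vectors) carries no evidence and returns p = 1. Both routes are validated
against independent oracles in the tests: brute-force `itertools`
enumeration, scipy's tie-free exact method, and a hypergeometric closed
form for exactly tied window constructions.

## Normalization, fold change, and thresholds

Libraries are scaled to reads per 10⁷ mapped reads before comparison; the
screen is then invariant to sequencing depth (a property test multiplies
one library's counts by an integer and asserts identical U, p, fold, and
calls). Fold change is (ref + c)/(sel + c) on normalized gene totals with
pseudocount c = 1 normalized read, keeping complete depletion finite; the
raw ratio (infinite when the selected total is zero) is reported alongside
with a `zero_selected` flag. Hit calling is the conjunction p < α and
f > fold_min with α = 0.05 and fold_min = 2 (24-hour screen) or 5 (5-hour
screen). No multiple-testing correction is applied by default — the screen
thresholds raw p-values; a Benjamini–Hochberg column is available opt-in.
Manual profile curation is replaced by two explicit, configurable flags:
`low_coverage` (fewer than 5 TA sites with ≥ 1 reference read; such genes
are excluded from hits, mirroring genes with too few insertions at T0 to
assess) and `dispersed` (f < 3 while ≥ 80% of reference-occupied sites
remain occupied after selection; reported, never filtered).

## Window scan

Eligible sites are exactly those with ≥ 1 raw read in both libraries. A
13-site window steps one eligible site at a time; each window is tested
with the exact MWU on normalized counts, and significance is p ≤ 0.02
together with ≥ 3-fold enrichment of normalized selected sums. Overlapping
or book-ended significant windows merge into a region spanning the T of
its first member site to the A of its last; regions inherit min p and peak
fold. A region is intragenic if its midpoint falls in a gene; otherwise it
is assigned upstream of the nearest downstream gene on either strand
within 500 bp (the gene's 5′ end may fall inside the region, since
enriched windows bleed a few sites into the gene). The step size, merge
rule, and 500 bp assignment distance are declared dialect parameters of
this implementation; published screens of this design did not state them.

Because a window containing ~10 of 13 enriched sites still clears both
thresholds, merged regions systematically extend about 3 eligible sites
(occasionally up to ~7 under jackpot noise) beyond a truth locus on each
side. This is a property of whole-window merging, not an error; boundary
accuracy finer than that would require trimming windows to their enriched
cores, which this dialect deliberately does not do.

## The simulator

The generator's defaults are the study conditions being emulated: 63%
TA-site saturation (~26 disrupted sites per average gene), 50 reads per
occupied site, and a 750,000-clone selection pool. A synthetic genome is
i.i.d.-uniform (expected TA density 1/16 per dinucleotide position) with
non-overlapping genes of mean length 900 bp tiled left to right; 10% of
intergenic gaps are promoter-sized (600–800 bp) so over-expression loci
have somewhere to live. Occupied sites get lognormal(0, 0.5²) clone
abundances — the dispersion mimics jackpot effects in pooled transformant
libraries; σ = 0.5 is a modeling choice, as real libraries' abundance
dispersion is not published. T0 reads are multinomial at depth
50 × (occupied sites). Selection reweights each clone by the fitness
factor of the gene or accelerator region containing its site
(sporulation-defective: w at T5 and T24; delayed: w at T5 only;
accelerator loci: w = 10 at T5 only, reproducing transient T5-specific
enrichment; essential genes carry no insertions at all), draws
`bottleneck_size` survivors multinomially, then draws reads from the
survivors. Accelerator loci are kept ≥ 2 kb apart by the design draw so
they form distinct enriched regions. Junction reads are ITR + 16 nt
genomic tag (uniform orientation) + constant adapter at Q40, error-free by
default (a substitution rate is configurable). Every stage consumes an
independent, labelled random stream derived from the master seed, so
outputs are byte-reproducible and adding a stage never perturbs earlier
draws.

What the simulator does *not* model: PCR duplicates and amplification
bias, sequencing-error-driven mismapping, local insertion-site preference
beyond the TA requirement, operon polarity, multi-chromosome genomes, and
germination-efficiency genetics. Passing recovery tests therefore show the
statistics behave correctly under the screen's own sampling model, not
that real libraries are free of these artefacts.

## Read mapping

Tags are looked up by exact match: for each TA site, the 16 bases
immediately 3′ of the TA on each strand are registered; k-mers occurring
at more than one site are quarantined as ambiguous and never assigned. At
16 nt on megabase genomes exact matching loses almost nothing (the
round-trip test on a 100 kb genome re-maps ≥ 99% of reads, the remainder
exactly accounted as ambiguous) and keeps the mapper bit-reproducible. The
ITR is located by exact substring search starting within the first 30 nt
of the read, first occurrence winning; reads with no ITR, an N-containing
or short tag, an ambiguous tag, or an unknown tag are tallied in separate
buckets that always sum to the input read count. Real pipelines using a
conventional aligner with unstated mismatch policy may differ marginally
in absolute counts.

## Null behaviour of the screen

Under the null (all fitness factors 1), the T0 and selected libraries are
resamplings of the *same* clone pool, so their per-site counts are
positively correlated through the shared lognormal abundances. The MWU
null hypothesis of two independent samples therefore does not hold, and
the test is strongly conservative: across 20 neutral screens of 200 genes,
the fraction of genes with p < 0.05 is ~0, not 0.05, and no gene passes
the joint (p < 0.05, fold > 2) rule. This is faithful to real Tn-seq —
timepoint libraries genuinely share clone structure — and it errs in the
safe direction for screening (no inflation of false hits), but nominal
p-values should not be read as calibrated tail probabilities. Power is
unaffected in practice: genes at fitness 0.01 with ≥ 10 occupied sites are
recalled at ~100% with median fold estimates of ~90–110 against the
designed 100 (the small downward bias comes from renormalization after
~7% of the library's clone mass is removed by selection).

## Problem sizes

Measurements run at desk scale: 200-gene (~250 kb) genomes for screen
benchmarks and 60-gene (~90 kb) genomes for the 2 × 20 full window scans,
chosen so the complete acceptance computation finishes in about two
minutes on one CPU while keeping ≥ 4,000 null genes and 60 truth loci per
measurement. The selection bottleneck stays at the full 7.5 × 10⁵ in all
benchmark measurements — it is cheap to sample at site resolution and the
fold-recovery band depends on it (at a 10⁴ bottleneck a 100×-depleted
gene expects < 1 surviving clone and its fold estimate degenerates to the
pseudocount ceiling); a 10⁴ bottleneck appears only in quick unit tests
whose asserted property (hit calling, not fold magnitude) tolerates it.
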