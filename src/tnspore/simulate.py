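"""Synthetic Mariner Tn-seq libraries with known ground truth.

The generator emulates the structure of a pooled-transformant sporulation
screen: a transposon library saturating a configurable fraction of TA sites
(default 63%), per-clone abundances with jackpot dispersion, a heat-kill
selection bottleneck acting through per-gene fitness factors between T0 and
the selected timepoints (T5/T24), transient "accelerator" loci enriched
only at T5, and multinomial read sampling at a configured depth.  Every
dataset is emitted alongside a :class:`SimulationTruth` so recovery can be
scored exactly.

Randomness: every stage consumes an independent, labelled stream derived
from the master seed (`substream`), so adding a stage never perturbs the
draws of earlier stages and a seed fully determines every output.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import (Genome, GeneAnnotation, InsertionLibrary, TASiteIndex,
                     find_ta_sites, reverse_complement, sites_in_gene)

# Gene fitness classes.  Fitness factors multiply a clone's sampling weight
# at the heat-kill selection; accelerators act through regions, not genes.
NEUTRAL = "neutral"
ESSENTIAL = "essential"
SPO_DEFECTIVE = "spo_defective"    # w < 1 at T5 and T24
SPO_DELAYED = "spo_delayed"        # w < 1 at T5 only (spores eventually form)
ACCELERATOR_OE = "accelerator_OE"  # upstream over-expression locus, w > 1 at T5
ACCELERATOR_KO = "accelerator_KO"  # intragenic inactivation locus, w > 1 at T5

GENE_CLASSES = (NEUTRAL, ESSENTIAL, SPO_DEFECTIVE, SPO_DELAYED,
                ACCELERATOR_OE, ACCELERATOR_KO)

# Magellan-style Mariner inverted terminal repeat used as the read prefix,
# and a TruSeq-style adapter as the constant 3' filler.
DEFAULT_ITR = "ACAGGTTGGATGATAAGTCCCCGG"
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTC"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults are the library-scale facts of the screen being emulated:
    63% TA-site saturation, ~750,000-clone selection pools, and read depth
    sized to tens of reads per occupied site.
    """

    seed: int = 1
    genome_length: int = 250_000
    n_genes: int = 200
    mean_gene_length: int = 900
    saturation: float = 0.63
    mean_reads_per_site: float = 50.0
    bottleneck_size: int | None = 750_000
    abundance_sigma: float = 0.5        # lognormal sigma of clone abundances
    gene_class_table: dict[str, tuple[str, float]] = field(default_factory=dict)
    tag_length: int = 16
    itr_motif: str = DEFAULT_ITR
    adapter: str = DEFAULT_ADAPTER
    substitution_rate: float = 0.0      # per-base read error rate
    gap_range: tuple[int, int] = (100, 300)
    wide_gap_range: tuple[int, int] = (600, 800)
    wide_gap_fraction: float = 0.1      # fraction of intergenic gaps made promoter-sized
    oe_region_span: int = 500           # upstream span of over-expression loci

    def __post_init__(self):
        if not 0 <= self.saturation <= 1:
            raise ValueError("saturation must be in [0, 1]")
        if self.mean_reads_per_site <= 0:
            raise ValueError("mean_reads_per_site must be positive")
        if self.tag_length < 1:
            raise ValueError("tag_length must be positive")


@dataclass
class Region:
    """A genomic interval carrying a T5-specific enrichment factor."""

    start: int
    end: int
    factor: float
    kind: str            # accelerator_OE | accelerator_KO
    gene: str            # the gene the locus acts on


@dataclass
class SimulationTruth:
    """Designed per-gene classes/factors plus realized T0 clone abundances."""

    gene_classes: dict[str, tuple[str, float]]
    regions: list[Region] = field(default_factory=list)
    t0_abundance: dict[int, float] = field(default_factory=dict)

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, (c, _) in self.gene_classes.items() if c == cls]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(g, c, w) for g, (c, w) in sorted(self.gene_classes.items())],
            columns=["gene", "class", "fitness_factor"],
        )


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, labelled random stream derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# Genome and design
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Genome, list[GeneAnnotation]]:
    """I.i.d.-uniform genome with non-overlapping tiled genes.

    Uniform bases give an expected TA density of 1/16 per position.  Genes
    are tiled left to right with intergenic gaps drawn from ``gap_range``
    (a ``wide_gap_fraction`` of gaps are promoter-sized, giving room for
    upstream over-expression loci).  Raises if the genes cannot fit.
    """
    rng = rng if rng is not None else substream(config.seed, "genome")
    seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
    genes: list[GeneAnnotation] = []
    pos = 1
    for i in range(config.n_genes):
        if rng.random() < config.wide_gap_fraction:
            gap = int(rng.integers(*config.wide_gap_range, endpoint=True))
        else:
            gap = int(rng.integers(*config.gap_range, endpoint=True))
        length = max(120, int(round(rng.normal(config.mean_gene_length,
                                               0.15 * config.mean_gene_length))))
        start = pos + gap
        end = start + length - 1
        if end > config.genome_length:
            raise ValueError(
                f"cannot fit {config.n_genes} genes of mean length "
                f"{config.mean_gene_length} into {config.genome_length} bp "
                f"(failed at gene {i + 1})"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"gene{i + 1:04d}", f"SYN_{i + 1:04d}",
                                    start, end, strand))
        pos = end
    return Genome("synthetic", seq), genes


def assign_classes(genes: list[GeneAnnotation], config: SimulationConfig,
                   n_essential: int = 0, n_defective: int = 0,
                   n_delayed: int = 0, n_accelerator_ko: int = 0,
                   n_accelerator_oe: int = 0,
                   w_defective: float = 0.01, w_delayed: float = 0.05,
                   accelerator_factor: float = 10.0,
                   min_locus_separation: int = 2000,
                   rng: np.random.Generator | None = None) -> SimulationTruth:
    """Draw a gene-class design and its accelerator regions.

    Over-expression loci are placed in the ``oe_region_span`` bp immediately
    upstream of genes whose upstream gap is wide enough to hold the locus
    without touching the neighbouring gene; inactivation loci are the gene
    bodies of long genes.  Accelerator loci are kept at least
    ``min_locus_separation`` bp apart so they form distinct enriched
    regions.  All remaining genes are neutral unless the config already
    pins a class for them.
    """
    rng = rng if rng is not None else substream(config.seed, "design")
    table: dict[str, tuple[str, float]] = dict(config.gene_class_table)
    regions: list[Region] = []
    unassigned = [g for g in genes if g.gene_name not in table]
    rng.shuffle(unassigned)

    def take(n: int, ok=lambda g: True) -> list[GeneAnnotation]:
        chosen = []
        for g in list(unassigned):
            if len(chosen) == n:
                break
            if ok(g):
                chosen.append(g)
                unassigned.remove(g)
        if len(chosen) < n:
            raise ValueError("not enough eligible genes for the requested design")
        return chosen

    for g in take(n_essential):
        table[g.gene_name] = (ESSENTIAL, 0.0)
    for g in take(n_defective):
        table[g.gene_name] = (SPO_DEFECTIVE, w_defective)
    for g in take(n_delayed):
        table[g.gene_name] = (SPO_DELAYED, w_delayed)

    span = config.oe_region_span
    order = sorted(genes, key=lambda g: g.start)
    prev_end = {order[i].gene_name: (order[i - 1].end if i else 0)
                for i in range(len(order))}

    def separated(start: int, end: int) -> bool:
        return all(start - r.end > min_locus_separation
                   or r.start - end > min_locus_separation for r in regions)

    for g in take(n_accelerator_oe,
                  ok=lambda g: (g.start - prev_end[g.gene_name] > span + 20
                                and separated(g.start - span, g.start - 1))):
        table[g.gene_name] = (ACCELERATOR_OE, accelerator_factor)
        regions.append(Region(g.start - span, g.start - 1,
                              accelerator_factor, ACCELERATOR_OE, g.gene_name))
    for g in take(n_accelerator_ko,
                  ok=lambda g: g.length >= 16 * 20 and separated(g.start, g.end)):
        table[g.gene_name] = (ACCELERATOR_KO, accelerator_factor)
        regions.append(Region(g.start, g.end, accelerator_factor,
                              ACCELERATOR_KO, g.gene_name))
    for g in unassigned:
        table[g.gene_name] = (NEUTRAL, 1.0)
    return SimulationTruth(gene_classes=table, regions=regions)


# ---------------------------------------------------------------------------
# Libraries
# ---------------------------------------------------------------------------

def _site_gene_map(index: TASiteIndex, genes: list[GeneAnnotation]) -> dict[int, str]:
    out: dict[int, str] = {}
    for g in genes:
        for p in sites_in_gene(index, g):
            out[int(p)] = g.gene_name
    return out


def simulate_t0_library(index: TASiteIndex, genes: list[GeneAnnotation],
                        truth: SimulationTruth, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> InsertionLibrary:
    """T0 library: Bernoulli(saturation) occupancy, lognormal clone abundances,
    multinomial reads at depth ``mean_reads_per_site`` x occupied sites.

    Sites inside essential genes are never occupied (those transformants do
    not survive outgrowth).  The realized abundances are recorded in
    ``truth.t0_abundance``; selection resamples that same clone pool.
    """
    rng = rng if rng is not None else substream(config.seed, "t0")
    pos = index.positions
    n = pos.size
    essential = set(truth.genes_of_class(ESSENTIAL))
    site_gene = _site_gene_map(index, genes)
    allowed = np.array([site_gene.get(int(p)) not in essential for p in pos])
    occupied = allowed & (rng.random(n) < config.saturation)
    abundance = np.zeros(n)
    abundance[occupied] = rng.lognormal(0.0, config.abundance_sigma, occupied.sum())
    truth.t0_abundance = {int(p): float(a)
                          for p, a in zip(pos[occupied], abundance[occupied])}
    n_occ = int(occupied.sum())
    if n_occ == 0:
        return InsertionLibrary("T0", {}, index.genome_id)
    total = int(round(config.mean_reads_per_site * n_occ))
    reads = rng.multinomial(total, abundance[occupied] / abundance[occupied].sum())
    counts = {int(p): int(c) for p, c in zip(pos[occupied], reads) if c > 0}
    return InsertionLibrary("T0", counts, index.genome_id)


def selection_weights(index: TASiteIndex, genes: list[GeneAnnotation],
                      truth: SimulationTruth, label: str) -> np.ndarray:
    """Per-site fitness factors at timepoint ``label`` ("T5" or "T24").

    Defective genes are depleted at both selected timepoints, delayed genes
    only at T5, and accelerator loci are enriched only at T5 (their T24
    profile returns to neutral).  Intergenic sites outside any accelerator
    region are neutral.
    """
    w = np.ones(index.positions.size)
    site_gene = _site_gene_map(index, genes)
    for i, p in enumerate(index.positions):
        g = site_gene.get(int(p))
        if g is None:
            continue
        cls, factor = truth.gene_classes.get(g, (NEUTRAL, 1.0))
        if cls == SPO_DEFECTIVE:
            w[i] = factor
        elif cls == SPO_DELAYED and label == "T5":
            w[i] = factor
    if label == "T5":
        for reg in truth.regions:
            inside = (index.positions >= reg.start) & (index.positions + 1 <= reg.end)
            w[inside] = reg.factor
    return w


def apply_selection(index: TASiteIndex, genes: list[GeneAnnotation],
                    truth: SimulationTruth, config: SimulationConfig,
                    label: str,
                    rng: np.random.Generator | None = None) -> InsertionLibrary:
    """Heat-kill selection and re-sequencing of the T0 clone pool.

    Each clone's sampling weight is its T0 abundance times the fitness
    factor of the gene or region containing its site; ``bottleneck_size``
    survivors are drawn multinomially (``None`` means an unbounded pool, no
    resampling), then reads are drawn multinomially at the configured depth.
    """
    if not truth.t0_abundance:
        raise ValueError("no T0 clone abundances: run simulate_t0_library first")
    rng = rng if rng is not None else substream(config.seed, f"select-{label}")
    pos = index.positions
    abundance = np.array([truth.t0_abundance.get(int(p), 0.0) for p in pos])
    weights = abundance * selection_weights(index, genes, truth, label)
    if not np.any(weights > 0):
        raise ValueError("all selection weights are zero")
    probs = weights / weights.sum()
    if config.bottleneck_size is not None:
        survivors = rng.multinomial(config.bottleneck_size, probs).astype(float)
        if survivors.sum() == 0:
            raise ValueError("selection bottleneck left no survivors")
        probs = survivors / survivors.sum()
    n_occ = int((abundance > 0).sum())
    total = int(round(config.mean_reads_per_site * n_occ))
    reads = rng.multinomial(total, probs)
    counts = {int(p): int(c) for p, c in zip(pos, reads) if c > 0}
    return InsertionLibrary(label, counts, index.genome_id)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def emit_reads(library: InsertionLibrary, genome: Genome,
               config: SimulationConfig, path,
               rng: np.random.Generator | None = None) -> int:
    """Write one junction read per sampled count to FASTQ.

    Read layout mirrors an MmeI junction library: ITR motif, then
    ``tag_length`` genomic bases immediately 3' of the TA on a uniformly
    chosen strand, then constant adapter filler; constant Q40 qualities.
    Sites whose tag would run off the genome end are skipped with a warning.
    Returns the number of reads written.
    """
    rng = rng if rng is not None else substream(config.seed, f"reads-{library.condition}")
    seq = genome.sequence
    L = config.tag_length
    qual = "I" * (len(config.itr_motif) + L + len(config.adapter))
    n_written = 0
    with open(path, "w") as fh:
        for p in sorted(library.counts):
            count = library.counts[p]
            # forward tag: bases after the A; reverse tag: revcomp of bases before the T
            fwd = seq[p + 1: p + 1 + L]
            rev = reverse_complement(seq[max(0, p - 1 - L): p - 1])
            if len(fwd) < L or len(rev) < L:
                warnings.warn(f"TA site {p}: tag extends beyond genome end; skipped")
                continue
            for _ in range(count):
                tag = fwd if rng.random() < 0.5 else rev
                read = config.itr_motif + tag + config.adapter
                if config.substitution_rate > 0:
                    read = _mutate(read, config.substitution_rate, rng)
                n_written += 1
                fh.write(f"@read{n_written:08d}\n{read}\n+\n{qual[:len(read)]}\n")
    return n_written


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    bases = np.array(list(read))
    hits = np.nonzero(rng.random(bases.size) < rate)[0]
    for i in hits:
        bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
    return "".join(bases)


# ---------------------------------------------------------------------------
# Convenience: one full synthetic screen
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScreen:
    """All artefacts of one simulated screen."""

    config: SimulationConfig
    genome: Genome
    genes: list[GeneAnnotation]
    index: TASiteIndex
    truth: SimulationTruth
    t0: InsertionLibrary
    t5: InsertionLibrary
    t24: InsertionLibrary


def simulate_screen(config: SimulationConfig, *, n_essential: int = 0,
                    n_defective: int = 0, n_delayed: int = 0,
                    n_accelerator_ko: int = 0, n_accelerator_oe: int = 0,
                    w_defective: float = 0.01, w_delayed: float = 0.05,
                    accelerator_factor: float = 10.0) -> SyntheticScreen:
    """Generate genome, design, and T0/T5/T24 libraries for one seed."""
    genome, genes = simulate_genome(config)
    index = find_ta_sites(genome)
    truth = assign_classes(genes, config, n_essential=n_essential,
                           n_defective=n_defective, n_delayed=n_delayed,
                           n_accelerator_ko=n_accelerator_ko,
                           n_accelerator_oe=n_accelerator_oe,
                           w_defective=w_defective, w_delayed=w_delayed,
                           accelerator_factor=accelerator_factor)
    t0 = simulate_t0_library(index, genes, truth, config)
    t5 = apply_selection(index, genes, truth, config, "T5")
    t24 = apply_selection(index, genes, truth, config, "T24")
    return SyntheticScreen(config, genome, genes, index, truth, t0, t5, t24)
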