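"""Reference handling for Mariner Tn-seq.

The Mariner (Himar1/magellan) transposon inserts exclusively at TA
dinucleotides, so the natural unit of insertion counting is the TA site.
This module provides the genome/annotation containers, TA-site indexing,
gene/site containment, and the on-disk insertion-profile formats (TSV and
bedgraph) that the screening statistics operate on.

Coordinate conventions
----------------------
All coordinates are 1-based and inclusive (GFF3 convention).  A TA site is
identified by the coordinate of its T; the site occupies positions
``(p, p+1)``.  TA is its own reverse complement, so the site list is
strand-symmetric and insertions in either orientation collapse onto one
site.  Circular genomes are treated linearly: a TA straddling the origin
is not indexed (at most one site genome-wide).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A reference sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in genome {self.id!r}: {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TASiteIndex:
    """Ordered 1-based coordinates of the T of every TA dinucleotide."""

    genome_id: str
    positions: np.ndarray  # int64, strictly increasing
    genome_length: int

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size and not np.all(np.diff(pos) > 0):
            raise ValueError("TA positions must be strictly increasing")

    def __len__(self) -> int:
        return int(self.positions.size)

    def position_set(self) -> set[int]:
        return set(int(p) for p in self.positions)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model on the reference (1-based inclusive coordinates)."""

    gene_name: str
    locus_tag: str
    start: int
    end: int
    strand: str = "+"
    is_essential: bool | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_name}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_name}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class InsertionLibrary:
    """Per-TA-site read counts for one sequencing library (T0/T5/T24/custom).

    ``total_mapped_reads`` is always the sum of counts; it is recomputed at
    construction so the conservation invariant cannot silently break.
    """

    condition: str
    counts: dict[int, int]
    genome_id: str = ""
    total_mapped_reads: int = field(init=False)

    def __post_init__(self):
        clean: dict[int, int] = {}
        for pos, c in self.counts.items():
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count at position {pos}")
            if c > 0:
                clean[int(pos)] = c
        self.counts = clean
        self.total_mapped_reads = sum(clean.values())

    def __len__(self) -> int:
        return len(self.counts)

    def validate_against(self, index: TASiteIndex) -> None:
        """Raise if any counted position is not a TA site of ``index``."""
        bad = set(self.counts) - index.position_set()
        if bad:
            raise ValueError(
                f"{len(bad)} counted positions are not TA sites "
                f"(e.g. {sorted(bad)[:5]})"
            )

    def vector(self, positions: np.ndarray) -> np.ndarray:
        """Raw counts at ``positions`` as a float array (0 where absent)."""
        return np.array([self.counts.get(int(p), 0) for p in positions], dtype=float)

    def scaled(self, per: float = 1e7) -> dict[int, float]:
        """Counts normalized to reads-per-``per`` mapped reads."""
        if self.total_mapped_reads == 0:
            raise ValueError(f"library {self.condition!r} has zero mapped reads")
        s = per / self.total_mapped_reads
        return {p: c * s for p, c in self.counts.items()}


def find_ta_sites(genome: Genome) -> TASiteIndex:
    """Index every TA dinucleotide (overlaps allowed; N never forms a site)."""
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype="S1")
    if arr.size < 2:
        return TASiteIndex(genome.id, np.empty(0, dtype=np.int64), len(genome))
    mask = (arr[:-1] == b"T") & (arr[1:] == b"A")
    positions = np.nonzero(mask)[0].astype(np.int64) + 1  # 1-based T coordinate
    return TASiteIndex(genome.id, positions, len(genome))


def sites_in_gene(index: TASiteIndex, gene: GeneAnnotation) -> np.ndarray:
    """TA positions fully contained in [gene.start, gene.end].

    Both bases of the dinucleotide must lie inside the gene, so a TA
    straddling either boundary is excluded.  Strand-independent; no
    terminal trimming is applied.
    """
    if gene.start < 1 or gene.end > index.genome_length:
        raise ValueError(
            f"gene {gene.gene_name} [{gene.start},{gene.end}] outside genome "
            f"of length {index.genome_length}"
        )
    lo = np.searchsorted(index.positions, gene.start, side="left")
    hi = np.searchsorted(index.positions, gene.end - 1, side="right")
    return index.positions[lo:hi]


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, seq_id: str | None = None,
               topology: str = "linear") -> Genome:
    """Read a genome from (multi-record) FASTA.

    The first record is used unless ``seq_id`` selects another.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        if seq_id is None or rec.id == seq_id:
            return Genome(rec.id, str(rec.seq).upper(), topology)
    raise ValueError(f"no record {seq_id!r} in {path}" if seq_id else f"empty FASTA {path}")


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i:i + width] + "\n")


def read_gff3(path: str | os.PathLike,
              feature_types: tuple[str, ...] = ("gene", "CDS")) -> list[GeneAnnotation]:
    """Read gene models from GFF3 (feature types gene, then CDS as fallback).

    Gene names come from the ``gene`` (or ``Name``) attribute, locus tags from
    ``locus_tag`` (or ``ID``).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    for ftype in feature_types:
        feats = list(db.features_of_type(ftype))
        if feats:
            break
    else:
        return []
    genes = []
    for f in feats:
        name = (f.attributes.get("gene") or f.attributes.get("Name")
                or f.attributes.get("locus_tag") or [f.id])[0]
        tag = (f.attributes.get("locus_tag") or [f.id])[0]
        ess = f.attributes.get("essential")
        genes.append(GeneAnnotation(
            gene_name=name, locus_tag=tag, start=f.start, end=f.end,
            strand=f.strand if f.strand in ("+", "-") else "+",
            is_essential=None if ess is None else ess[0].lower() in ("1", "true", "yes"),
        ))
    genes.sort(key=lambda g: g.start)
    return genes


def write_gff3(genes: list[GeneAnnotation], genome: Genome,
               path: str | os.PathLike) -> None:
    """Minimal GFF3 writer for simulated annotations."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for g in sorted(genes, key=lambda g: g.start):
            attrs = f"ID={g.locus_tag};gene={g.gene_name};locus_tag={g.locus_tag}"
            if g.is_essential is not None:
                attrs += f";essential={'true' if g.is_essential else 'false'}"
            fh.write(f"{genome.id}\ttnspore\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


PROFILE_HEADER = "position\tcount"


def write_profile(lib: InsertionLibrary, path: str | os.PathLike,
                  fmt: str = "tsv") -> None:
    """Write a profile as TSV (``position\\tcount``) or bedgraph.

    The bedgraph is 0-based half-open; each TA site spans its dinucleotide
    ``[p-1, p+1)``.
    """
    positions = sorted(lib.counts)
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write(PROFILE_HEADER + "\n")
            for p in positions:
                fh.write(f"{p}\t{lib.counts[p]}\n")
        elif fmt == "bedgraph":
            chrom = lib.genome_id or "genome"
            for p in positions:
                fh.write(f"{chrom}\t{p - 1}\t{p + 1}\t{lib.counts[p]}\n")
        else:
            raise ValueError(f"unknown profile format {fmt!r}")


def read_profile(path: str | os.PathLike, condition: str = "custom",
                 genome_id: str = "", index: TASiteIndex | None = None) -> InsertionLibrary:
    """Read a TSV or bedgraph profile (format sniffed from the first line).

    If ``index`` is given, positions are validated against it.
    """
    counts: dict[int, int] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith(("#", "track"))]
    if lines and lines[0] == PROFILE_HEADER:
        for ln in lines[1:]:
            p_s, c_s = ln.split("\t")
            pos, c = int(p_s), int(c_s)
            if c < 0:
                raise ValueError(f"negative count at position {pos} in {path}")
            counts[pos] = counts.get(pos, 0) + c
    else:
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) != 4:
                raise ValueError(f"malformed profile line in {path}: {ln!r}")
            chrom, start, _end, val = fields
            genome_id = genome_id or chrom
            pos, c = int(start) + 1, int(val)
            if c < 0:
                raise ValueError(f"negative count at position {pos} in {path}")
            counts[pos] = counts.get(pos, 0) + c
    lib = InsertionLibrary(condition=condition, counts=counts, genome_id=genome_id)
    if index is not None:
        lib.validate_against(index)
    return lib
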