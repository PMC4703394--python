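"""Assign transposon-junction reads to TA sites by exact genomic-tag lookup.

An MmeI junction read carries the transposon ITR followed by ~16 nt of
genomic sequence flanking the insertion site.  At 16 nt on a megabase-scale
genome, exact k-mer lookup resolves nearly every read, keeps the mapper
dependency-free, and is bit-reproducible; tags occurring at more than one
site are quarantined as ambiguous and never assigned.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

from .genome import Genome, InsertionLibrary, TASiteIndex, reverse_complement


@dataclass
class TagIndex:
    """Exact map from tag k-mer to TA position (1-based T coordinate).

    Both flanks of every site are registered (the tag 3' of the TA on each
    strand).  A k-mer seen at more than one site lives only in
    ``ambiguous``; within-site duplicates (palindromic flanks) are fine.
    """

    tag_length: int
    tags: dict[str, int] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.tags)


@dataclass
class MappingStats:
    """Per-category read tallies; categories partition the input."""

    n_reads: int = 0
    n_no_itr: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0
    n_mapped: int = 0

    def check(self) -> None:
        assert self.n_reads == (self.n_no_itr + self.n_ambiguous
                                + self.n_unmapped + self.n_mapped)

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in
                ("n_reads", "n_no_itr", "n_ambiguous", "n_unmapped", "n_mapped")}


def build_tag_index(genome: Genome, index: TASiteIndex,
                    tag_length: int = 16) -> TagIndex:
    """Register, for each TA site, the ``tag_length`` bases immediately 3' of
    the TA on each strand; collisions across sites go to the ambiguous set.

    Tags containing N or running off the genome end are not registered.
    """
    if tag_length < 10:
        raise ValueError("tag_length must be >= 10 for meaningful uniqueness")
    if tag_length > len(genome):
        raise ValueError("tag_length longer than the genome")
    seq = genome.sequence
    ti = TagIndex(tag_length=tag_length)
    for p in index.positions:
        p = int(p)
        fwd = seq[p + 1: p + 1 + tag_length]
        rev = reverse_complement(seq[max(0, p - 1 - tag_length): p - 1])
        for tag in (fwd, rev):
            if len(tag) < tag_length or "N" in tag:
                continue
            if tag in ti.ambiguous:
                continue
            prev = ti.tags.get(tag)
            if prev is None:
                ti.tags[tag] = p
            elif prev != p:
                del ti.tags[tag]
                ti.ambiguous.add(tag)
    return ti


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path):
    """Yield (index, sequence) from FASTQ, raising on truncated records."""
    with _open_maybe_gzip(path) as fh:
        i = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual or not seq or not plus:
                raise ValueError(f"truncated FASTQ record at index {i} in {path}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at index {i} in {path}")
            yield i, seq.strip()
            i += 1


def map_reads(fastq_path, tag_index: TagIndex, itr_motif: str,
              condition: str = "custom", genome_id: str = "",
              itr_search_span: int = 30) -> tuple[InsertionLibrary, MappingStats]:
    """Tally junction reads at TA sites.

    Per read: the ITR motif is located by exact substring search starting
    within the first ``itr_search_span`` nt (first occurrence wins); the
    following ``tag_length`` bases are looked up in the tag index.  Reads
    with no ITR, an ambiguous tag, or an unknown/N-containing/short tag are
    counted in their own buckets and never assigned.
    """
    L = tag_index.tag_length
    counts: dict[int, int] = {}
    stats = MappingStats()
    for _i, seq in _iter_fastq(fastq_path):
        stats.n_reads += 1
        at = seq.find(itr_motif)
        if at < 0 or at >= itr_search_span:
            stats.n_no_itr += 1
            continue
        tag = seq[at + len(itr_motif): at + len(itr_motif) + L]
        if len(tag) < L or "N" in tag:
            stats.n_unmapped += 1
            continue
        if tag in tag_index.ambiguous:
            stats.n_ambiguous += 1
            continue
        pos = tag_index.tags.get(tag)
        if pos is None:
            stats.n_unmapped += 1
            continue
        stats.n_mapped += 1
        counts[pos] = counts.get(pos, 0) + 1
    stats.check()
    return InsertionLibrary(condition, counts, genome_id), stats
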