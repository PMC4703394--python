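"""Sliding-window scan for loci over-represented after early selection.

Insertions that make cells enter sporulation prematurely are *enriched*
among heat-resistant spores at the 5-hour timepoint, often in intergenic
(promoter) regions that no per-gene screen can see.  The scan therefore
slides a 13-TA-site window, one eligible site at a time, across every TA
site that registered at least one read in both compared libraries, tests
each window with a two-sided Mann-Whitney U (exact, tie-aware enumeration:
13 sites per group is well within enumeration cost), and keeps windows with
p <= 0.02 that are at least 3-fold enriched in selected reads.  Overlapping
significant windows are merged into regions, which are classified as
intragenic or upstream of a nearby downstream gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, InsertionLibrary, TASiteIndex
from .screen import normalize
from .stats import mann_whitney_exact


@dataclass
class EligibleSiteTrack:
    """TA sites with >= 1 raw read in both libraries, in genomic order,
    with parallel normalized count vectors."""

    positions: np.ndarray     # 1-based TA coordinates, strictly increasing
    ref_norm: np.ndarray
    sel_norm: np.ndarray

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class WindowResult:
    first_pos: int            # TA coordinate of the first site in the window
    last_pos: int             # TA coordinate of the last site
    start_index: int          # index of the first site in the eligible track
    window_size: int
    p_value: float
    fold_enrichment: float    # normalized selected sum / reference sum
    significant: bool


@dataclass
class EnrichedRegion:
    """Merged run of significant windows (genomic TA coordinates)."""

    start: int                # min TA position of member windows
    end: int                  # max TA position (+1 covers the A of the site)
    peak_fold: float
    min_p: float
    member_window_count: int
    first_site_index: int     # eligible-track index of the leftmost site
    last_site_index: int
    classification: str = "unassigned"
    gene: str | None = None


def eligible_sites(lib_ref: InsertionLibrary, lib_sel: InsertionLibrary,
                   index: TASiteIndex) -> EligibleSiteTrack:
    """Exactly the TA sites with raw count >= 1 in both libraries."""
    ref_raw = lib_ref.vector(index.positions)
    sel_raw = lib_sel.vector(index.positions)
    ref_norm, sel_norm = normalize(lib_ref, lib_sel, index)
    keep = (ref_raw >= 1) & (sel_raw >= 1)
    return EligibleSiteTrack(index.positions[keep], ref_norm[keep], sel_norm[keep])


def scan(track: EligibleSiteTrack, window_size: int = 13,
         p_max: float = 0.02, fold_min_enrich: float = 3.0) -> list[WindowResult]:
    """Test every run of ``window_size`` consecutive eligible sites (step 1).

    Significance is the conjunction of the exact two-sided Mann-Whitney
    p-value and the fold-enrichment threshold.
    """
    n = len(track)
    if n < window_size:
        warnings.warn(f"eligible track has {n} sites < window size {window_size}")
        return []
    results = []
    for i in range(n - window_size + 1):
        rn = track.ref_norm[i: i + window_size]
        sn = track.sel_norm[i: i + window_size]
        _u, p = mann_whitney_exact(sn, rn)
        fold = float(sn.sum() / rn.sum())
        results.append(WindowResult(
            first_pos=int(track.positions[i]),
            last_pos=int(track.positions[i + window_size - 1]),
            start_index=i, window_size=window_size, p_value=float(p),
            fold_enrichment=fold,
            significant=bool(p <= p_max and fold >= fold_min_enrich)))
    return results


def merge_windows(windows: list[WindowResult]) -> list[EnrichedRegion]:
    """Merge significant windows that share at least one eligible site.

    Windows of size w starting at eligible-track indices i and j share a
    site iff |i - j| < w; book-ended windows (adjacent, sharing none) are
    merged too.  Region coordinates are genomic: from the T of the first
    member site to the A of the last.
    """
    sig = sorted((w for w in windows if w.significant), key=lambda w: w.start_index)
    regions: list[EnrichedRegion] = []
    for w in sig:
        if regions and w.start_index <= regions[-1].last_site_index + 1:
            r = regions[-1]
            r.end = max(r.end, w.last_pos + 1)
            r.peak_fold = max(r.peak_fold, w.fold_enrichment)
            r.min_p = min(r.min_p, w.p_value)
            r.member_window_count += 1
            r.last_site_index = max(r.last_site_index,
                                    w.start_index + w.window_size - 1)
        else:
            regions.append(EnrichedRegion(
                start=w.first_pos, end=w.last_pos + 1,
                peak_fold=w.fold_enrichment, min_p=w.p_value,
                member_window_count=1, first_site_index=w.start_index,
                last_site_index=w.start_index + w.window_size - 1))
    return regions


def classify_region(region: EnrichedRegion, genes: list[GeneAnnotation],
                    upstream_bp: int = 500) -> EnrichedRegion:
    """Label a region intragenic (midpoint inside a gene) or upstream of the
    nearest downstream gene on either strand within ``upstream_bp``."""
    mid = (region.start + region.end) // 2
    for g in genes:
        if g.start <= mid <= g.end:
            region.classification, region.gene = "intragenic", g.gene_name
            return region
    best: tuple[int, GeneAnnotation] | None = None
    for g in genes:
        # downstream gene on either strand; a region may overlap the gene's
        # 5' end when enriched windows bleed into it, so clamp the gap at 0
        if g.strand == "+" and g.start >= region.start:
            d = max(0, g.start - region.end)
        elif g.strand == "-" and g.end <= region.end:
            d = max(0, region.start - g.end)
        else:
            continue
        if d <= upstream_bp and (best is None or d < best[0]):
            best = (d, g)
    if best is not None:
        region.classification, region.gene = "upstream", best[1].gene_name
    else:
        region.classification, region.gene = "unassigned", None
    return region


def scan_libraries(lib_ref: InsertionLibrary, lib_sel: InsertionLibrary,
                   index: TASiteIndex, genes: list[GeneAnnotation] | None = None,
                   window_size: int = 13, p_max: float = 0.02,
                   fold_min_enrich: float = 3.0,
                   upstream_bp: int = 500) -> tuple[list[WindowResult],
                                                    list[EnrichedRegion]]:
    """Full scan: eligible track, windows, merged + classified regions."""
    track = eligible_sites(lib_ref, lib_sel, index)
    windows = scan(track, window_size=window_size, p_max=p_max,
                   fold_min_enrich=fold_min_enrich)
    regions = merge_windows(windows)
    if genes is not None:
        for r in regions:
            classify_region(r, genes, upstream_bp=upstream_bp)
    return windows, regions


def regions_table(regions: list[EnrichedRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "start": r.start, "end": r.end, "peak_fold": r.peak_fold,
        "min_p": r.min_p, "n_windows": r.member_window_count,
        "classification": r.classification, "gene": r.gene or "",
    } for r in regions], columns=["start", "end", "peak_fold", "min_p",
                                  "n_windows", "classification", "gene"])


def write_regions_bed(regions: list[EnrichedRegion], genome_id: str,
                      path) -> None:
    """0-based half-open BED of merged regions."""
    with open(path, "w") as fh:
        for i, r in enumerate(sorted(regions, key=lambda r: r.start), 1):
            name = f"region{i}|{r.classification}" + (f"|{r.gene}" if r.gene else "")
            fh.write(f"{genome_id}\t{r.start - 1}\t{r.end}\t{name}\t0\t.\n")
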