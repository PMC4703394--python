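"""Per-gene depletion screen: Mann-Whitney U on insertion profiles.

For every annotated gene the per-TA-site read counts of a reference library
(T0) and a selected library (T5 or T24 after heat kill) are compared with a
two-sided Mann-Whitney U test; zeros at unoccupied sites are genuine
observations and are included, since the TA site is the sampling unit.
Libraries of unequal depth are made comparable by scaling each to reads per
ten million mapped reads.  Genes are called hits when the p-value and the
fold reduction both clear their thresholds (p < 0.05 with >2-fold reduction
for the 24-hour screen; a >5-fold reduction is the convention for the
stricter 5-hour screen) and the gene is not flagged low-coverage.

Curation that the original screen did by eye is encoded as two explicit,
configurable flags that are reported but never silently filter:

* ``low_coverage`` — too few TA sites carried reads in the reference
  library for depletion to be assessable;
* ``dispersed`` — a modest fold reduction with insertions retained across
  most of the reference-occupied sites (reduction without clearing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, InsertionLibrary, TASiteIndex, sites_in_gene
from .stats import benjamini_hochberg, mann_whitney

NORM_SCALE = 1e7  # reads per ten million
NEG_LOG10_CAP = 320.0


@dataclass
class ScreenConfig:
    """Thresholds and curation parameters of the depletion screen."""

    alpha: float = 0.05
    fold_min: float = 2.0
    low_coverage_min_sites: int = 5
    dispersed_fold_max: float = 3.0
    dispersed_retention_min: float = 0.8
    pseudocount: float = 1.0      # in normalized read units
    exact_max_n: int = 8          # exact MWU enumeration up to this many sites
    with_bh: bool = False         # optional BH q-value column

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_min < 1:
            raise ValueError("fold_min must be >= 1")


@dataclass
class GeneDepletionResult:
    gene: str
    locus_tag: str
    n_ta_sites: int
    t_ref_reads: int
    t_sel_reads: int
    t_ref_norm: float
    t_sel_norm: float
    fold_change: float            # (ref + c) / (sel + c), normalized units
    raw_ratio: float              # ref/sel without pseudocount (inf when sel = 0)
    u_stat: float
    p_value: float
    flags: list[str] = field(default_factory=list)
    is_hit: bool = False

    @property
    def neg_log10_p(self) -> float:
        if not np.isfinite(self.p_value):
            return float("nan")
        if self.p_value <= 0:
            return NEG_LOG10_CAP
        return min(-math.log10(self.p_value), NEG_LOG10_CAP)


def normalize(lib_ref: InsertionLibrary, lib_sel: InsertionLibrary,
              index: TASiteIndex) -> tuple[np.ndarray, np.ndarray]:
    """Per-site count vectors over the full TA index, each library scaled to
    reads per ten million of its own mapped total."""
    if lib_ref.total_mapped_reads == 0 or lib_sel.total_mapped_reads == 0:
        raise ValueError("cannot normalize a library with zero mapped reads")
    ref = lib_ref.vector(index.positions) * (NORM_SCALE / lib_ref.total_mapped_reads)
    sel = lib_sel.vector(index.positions) * (NORM_SCALE / lib_sel.total_mapped_reads)
    return ref, sel


def fold_change(t_ref_norm_total: float, t_sel_norm_total: float,
                pseudocount: float = 1.0) -> tuple[float, float, bool]:
    """Fold reduction (reference over selected) on normalized gene totals.

    Returns ``(fold, raw_ratio, zero_denominator)``; the pseudocount keeps
    complete depletion finite, the raw ratio is reported alongside (inf when
    the selected total is zero).
    """
    f = (t_ref_norm_total + pseudocount) / (t_sel_norm_total + pseudocount)
    raw = t_ref_norm_total / t_sel_norm_total if t_sel_norm_total > 0 else float("inf")
    return f, raw, t_sel_norm_total == 0


def gene_mwu(ref_counts, sel_counts, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U over a gene's per-site counts (zeros kept)."""
    return tuple(mann_whitney(ref_counts, sel_counts, exact_max_n=exact_max_n))


def run_screen(lib_ref: InsertionLibrary, lib_sel: InsertionLibrary,
               genes: list[GeneAnnotation], index: TASiteIndex,
               config: ScreenConfig | None = None) -> list[GeneDepletionResult]:
    """Screen every gene for depletion of insertions after selection.

    Output is sorted by p-value ascending; genes without TA sites are
    reported with a ``no_ta_sites`` flag and an undefined test.
    """
    config = config or ScreenConfig()
    for lib in (lib_ref, lib_sel):
        if lib.genome_id and index.genome_id and lib.genome_id != index.genome_id:
            raise ValueError(
                f"library {lib.condition!r} maps to genome {lib.genome_id!r}, "
                f"not {index.genome_id!r}"
            )
    ref_norm, sel_norm = normalize(lib_ref, lib_sel, index)
    ref_raw = lib_ref.vector(index.positions)
    sel_raw = lib_sel.vector(index.positions)
    pos_to_i = {int(p): i for i, p in enumerate(index.positions)}

    results: list[GeneDepletionResult] = []
    for g in genes:
        sites = sites_in_gene(index, g)
        idx = np.array([pos_to_i[int(p)] for p in sites], dtype=int)
        if idx.size == 0:
            results.append(GeneDepletionResult(
                gene=g.gene_name, locus_tag=g.locus_tag, n_ta_sites=0,
                t_ref_reads=0, t_sel_reads=0, t_ref_norm=0.0, t_sel_norm=0.0,
                fold_change=float("nan"), raw_ratio=float("nan"),
                u_stat=float("nan"), p_value=float("nan"),
                flags=["no_ta_sites"], is_hit=False))
            continue
        rn, sn = ref_norm[idx], sel_norm[idx]
        rr, sr = ref_raw[idx], sel_raw[idx]
        u, p = gene_mwu(rn, sn, exact_max_n=config.exact_max_n)
        f, raw, zero_den = fold_change(rn.sum(), sn.sum(), config.pseudocount)

        flags = []
        ref_occupied = rr >= 1
        n_occ = int(ref_occupied.sum())
        if n_occ < config.low_coverage_min_sites:
            flags.append("low_coverage")
        if n_occ > 0:
            retention = float((sr[ref_occupied] >= 1).mean())
            if f < config.dispersed_fold_max and retention >= config.dispersed_retention_min:
                flags.append("dispersed")
        if zero_den:
            flags.append("zero_selected")
        is_hit = (p < config.alpha and f > config.fold_min
                  and "low_coverage" not in flags)
        results.append(GeneDepletionResult(
            gene=g.gene_name, locus_tag=g.locus_tag, n_ta_sites=int(idx.size),
            t_ref_reads=int(rr.sum()), t_sel_reads=int(sr.sum()),
            t_ref_norm=float(rn.sum()), t_sel_norm=float(sn.sum()),
            fold_change=float(f), raw_ratio=float(raw),
            u_stat=float(u), p_value=float(p), flags=flags, is_hit=is_hit))
    results.sort(key=lambda r: (math.inf if math.isnan(r.p_value) else r.p_value,
                                r.gene))
    return results


_COLUMNS = ["gene", "locus_tag", "n_ta_sites", "t_ref_reads", "t_sel_reads",
            "fold_change", "u_stat", "p_value", "neg_log10_p", "flags", "is_hit"]


def results_table(results: list[GeneDepletionResult],
                  with_bh: bool = False) -> pd.DataFrame:
    """Fixed-column results table (plus raw ratio / occupied-site columns)."""
    rows = [{
        "gene": r.gene, "locus_tag": r.locus_tag, "n_ta_sites": r.n_ta_sites,
        "t_ref_reads": r.t_ref_reads, "t_sel_reads": r.t_sel_reads,
        "fold_change": r.fold_change, "u_stat": r.u_stat, "p_value": r.p_value,
        "neg_log10_p": r.neg_log10_p, "flags": ",".join(r.flags),
        "is_hit": r.is_hit, "raw_ratio": r.raw_ratio,
    } for r in results]
    df = pd.DataFrame(rows, columns=_COLUMNS + ["raw_ratio"])
    if with_bh:
        df["bh_q"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def volcano_table(results: list[GeneDepletionResult]) -> pd.DataFrame:
    """Plot-ready (gene, fold, -log10 p) table; -log10(p) capped at 320."""
    def capped(p: float) -> bool:
        return bool(np.isfinite(p) and (p <= 0 or -math.log10(p) > NEG_LOG10_CAP))

    rows = [{
        "gene": r.gene, "fold_change": r.fold_change,
        "neg_log10_p": r.neg_log10_p,
        "p_capped": capped(r.p_value),
        "is_hit": r.is_hit, "flags": ",".join(r.flags),
    } for r in results]
    return pd.DataFrame(rows, columns=["gene", "fold_change", "neg_log10_p",
                                       "p_capped", "is_hit", "flags"])
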