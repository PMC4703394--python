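"""Simulation-based performance measurements of the screen and scan.

These routines run the full pipeline on seeded synthetic screens and
measure operating characteristics: null false-positive behaviour, power
and fold-change recovery for strongly depleted genes, and localization of
accelerator loci by the window scan.  They are shared by the acceptance
test-suite and the acceptance script so that both report numbers computed
by one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import sites_in_gene
from .screen import ScreenConfig, run_screen
from .simulate import (SPO_DEFECTIVE, SimulationConfig, simulate_screen)
from .windows import eligible_sites, merge_windows, scan


@dataclass
class NullCalibration:
    fraction_p_below_alpha: float   # pooled over genes x seeds
    se_binomial: float              # SE of that fraction at the nominal alpha
    runs_with_zero_hits: int
    n_runs: int
    n_genes_total: int


def null_calibration(seeds, *, n_genes: int = 200, alpha: float = 0.05,
                     fold_min: float = 2.0, depth: float = 50.0,
                     bottleneck: int | None = 750_000) -> NullCalibration:
    """All-neutral screens: p-value behaviour and joint-hit counts under the null.

    Note the two compared libraries are resamplings of the same clone pool,
    so their per-site counts are positively correlated and the rank test is
    conservative; the false-hit rate is what matters for screening.
    """
    n_small, runs_zero, n_total = 0, 0, 0
    cfg = ScreenConfig(alpha=alpha, fold_min=fold_min)
    for seed in seeds:
        sim = simulate_screen(SimulationConfig(
            seed=int(seed), n_genes=n_genes, mean_reads_per_site=depth,
            bottleneck_size=bottleneck))
        res = run_screen(sim.t0, sim.t24, sim.genes, sim.index, cfg)
        ps = np.array([r.p_value for r in res if np.isfinite(r.p_value)])
        n_small += int((ps < alpha).sum())
        n_total += ps.size
        if not any(r.is_hit for r in res):
            runs_zero += 1
    frac = n_small / n_total
    se = float(np.sqrt(alpha * (1 - alpha) / n_total))
    return NullCalibration(frac, se, runs_zero, len(list(seeds)), n_total)


@dataclass
class PowerRecovery:
    n_eligible_genes: int           # defective genes with >= min_occupied sites
    n_called: int
    recall: float
    fold_estimates: np.ndarray
    median_fold: float


def power_recovery(seeds, *, n_defective: int = 20, w: float = 0.01,
                   depth: float = 50.0, min_occupied: int = 10,
                   bottleneck: int | None = 750_000,
                   alpha: float = 0.05, fold_min: float = 2.0) -> PowerRecovery:
    """Recovery of strongly depleted genes (designed fold = 1/w)."""
    cfg = ScreenConfig(alpha=alpha, fold_min=fold_min)
    called, eligible, folds = 0, 0, []
    for seed in seeds:
        sim = simulate_screen(SimulationConfig(
            seed=int(seed), mean_reads_per_site=depth,
            bottleneck_size=bottleneck), n_defective=n_defective,
            w_defective=w)
        defective = set(sim.truth.genes_of_class(SPO_DEFECTIVE))
        res = run_screen(sim.t0, sim.t24, sim.genes, sim.index, cfg)
        by_name = {g.gene_name: g for g in sim.genes}
        for r in res:
            if r.gene not in defective:
                continue
            # occupied-site requirement applies to the reference library
            n_occ = sum(1 for p in sites_in_gene(sim.index, by_name[r.gene])
                        if sim.t0.counts.get(int(p), 0) >= 1)
            if n_occ < min_occupied:
                continue
            eligible += 1
            if r.is_hit:
                called += 1
            folds.append(r.fold_change)
    folds = np.array(folds)
    return PowerRecovery(eligible, called,
                         called / eligible if eligible else float("nan"),
                         folds, float(np.median(folds)) if folds.size else float("nan"))


@dataclass
class Localization:
    n_truth_loci: int
    n_overlapped_by_exactly_one: int
    boundary_offsets: list[int]      # eligible-site index offsets, both edges
    max_offset: int
    neutral_regions: int             # regions reported across neutral runs


def _eligible_index_of(track_positions: np.ndarray, genomic: int,
                       side: str) -> int:
    """Index of the first/last eligible site inside [genomic interval edge]."""
    if side == "left":
        return int(np.searchsorted(track_positions, genomic, side="left"))
    return int(np.searchsorted(track_positions, genomic, side="right") - 1)


def localization(seeds, *, n_genes: int = 60, genome_length: int = 90_000,
                 factor: float = 10.0, depth: float = 50.0,
                 bottleneck: int | None = 750_000, window_size: int = 13,
                 p_max: float = 0.02, fold_min_enrich: float = 3.0) -> Localization:
    """Window-scan recovery of accelerator loci, plus the neutral null scan.

    Per seed: 3 accelerator loci (one intragenic, two upstream) at
    ``factor``-fold T5 enrichment.  Boundary offsets are measured in
    eligible-site indices between each truth edge and the matched region
    edge.  The same seeds rerun with no accelerators count null regions.
    """
    n_truth = n_one = 0
    offsets: list[int] = []
    neutral_regions = 0
    for seed in seeds:
        base = dict(seed=int(seed), n_genes=n_genes, genome_length=genome_length,
                    mean_reads_per_site=depth, bottleneck_size=bottleneck)
        sim = simulate_screen(SimulationConfig(**base), n_accelerator_oe=2,
                              n_accelerator_ko=1, accelerator_factor=factor)
        track = eligible_sites(sim.t0, sim.t5, sim.index)
        regions = merge_windows(scan(track, window_size, p_max, fold_min_enrich))
        for t in sim.truth.regions:
            n_truth += 1
            hits = [r for r in regions
                    if r.start <= t.end and r.end >= t.start]
            if len(hits) == 1:
                n_one += 1
                r = hits[0]
                t_first = _eligible_index_of(track.positions, t.start, "left")
                t_last = _eligible_index_of(track.positions, t.end, "right")
                offsets.append(abs(r.first_site_index - t_first))
                offsets.append(abs(r.last_site_index - t_last))
        null_sim = simulate_screen(SimulationConfig(**base))
        null_track = eligible_sites(null_sim.t0, null_sim.t5, null_sim.index)
        neutral_regions += len(merge_windows(
            scan(null_track, window_size, p_max, fold_min_enrich)))
    return Localization(n_truth, n_one, offsets,
                        max(offsets) if offsets else 0, neutral_regions)
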