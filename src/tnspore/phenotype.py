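"""Colony-count statistics: sporulation efficiency and competitive index.

Sporulation efficiency is the heat-resistant (80 C, 20 min) CFU of a mutant
as a percentage of wild-type heat-resistant CFU at the same timepoint.  The
competitive index of a 1:1 co-culture is the mutant/wild-type ratio of
heat-resistant CFU at the selection timepoint divided by the mutant/
wild-type CFU ratio at the onset of starvation; a perfectly neutral mutant
has CI = 1 and CI > 1 means earlier/faster spore maturation.  All counts
are converted to CFU/mL (colonies x dilution factor / volume plated)
before ratios, so shared dilutions cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

TIMEPOINTS = ("T0", "T5", "T24", "T30", "T36")


@dataclass(frozen=True)
class CfuRecord:
    """One plating observation."""

    strain: str
    timepoint: str
    colonies: int
    dilution_factor: float
    volume_plated_ml: float
    heat_treated: bool = False

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.colonies < 0:
            raise ValueError("colony count must be non-negative")
        if self.dilution_factor <= 0 or self.volume_plated_ml <= 0:
            raise ValueError("dilution factor and plated volume must be positive")

    @property
    def cfu_per_ml(self) -> float:
        return self.colonies * self.dilution_factor / self.volume_plated_ml

    @property
    def detection_limit_per_ml(self) -> float:
        """CFU/mL corresponding to a single colony on this plate."""
        return self.dilution_factor / self.volume_plated_ml


@dataclass(frozen=True)
class CocultureCounts:
    """CFU of a 1:1 mutant/wild-type co-culture at onset and selection."""

    mut_t0: float
    wt_t0: float
    mut_sel: float
    wt_sel: float

    def __post_init__(self):
        for name in ("mut_t0", "wt_t0", "mut_sel", "wt_sel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def sporulation_efficiency(mutant: CfuRecord, wildtype: CfuRecord) -> float:
    """Heat-resistant CFU of the mutant as % of wild type (same timepoint)."""
    if not (mutant.heat_treated and wildtype.heat_treated):
        raise ValueError("sporulation efficiency is defined on heat-treated counts")
    if mutant.timepoint != wildtype.timepoint:
        raise ValueError("mutant and wild-type records are from different timepoints")
    if wildtype.cfu_per_ml == 0:
        raise ValueError("wild-type heat-resistant CFU is zero")
    return 100.0 * mutant.cfu_per_ml / wildtype.cfu_per_ml


def competitive_index(c: CocultureCounts) -> float:
    """(mut/WT spores at selection) / (mut/WT CFU at T0)."""
    if c.wt_t0 <= 0 or c.wt_sel <= 0:
        raise ValueError("wild-type counts must be positive for a defined index")
    if c.mut_t0 == 0:
        raise ValueError("mutant absent at T0: competitive index undefined")
    return (c.mut_sel / c.wt_sel) / (c.mut_t0 / c.wt_t0)


def summarize_replicates(values) -> tuple[float, float | None]:
    """Arithmetic mean and standard error (sample SD / sqrt(n)).

    With a single replicate the mean is returned and the SEM is undefined
    (None).
    """
    vals = [float(v) for v in values]
    n = len(vals)
    if n == 0:
        raise ValueError("no replicate values")
    mean = sum(vals) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n)


# ---------------------------------------------------------------------------
# Table-level interface
# ---------------------------------------------------------------------------

CFU_COLUMNS = ["strain", "timepoint", "replicate", "colonies",
               "dilution_factor", "volume_plated_ml", "heat_treated"]


def read_cfu_table(path) -> pd.DataFrame:
    """Read a TSV of CfuRecord rows (one row per plate)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CFU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CFU table missing columns: {sorted(missing)}")
    df["heat_treated"] = df["heat_treated"].astype(bool)
    return df


def _cfu(row) -> float:
    return row["colonies"] * row["dilution_factor"] / row["volume_plated_ml"]


def efficiency_table(df: pd.DataFrame, reference_strain: str = "WT") -> pd.DataFrame:
    """Per-strain sporulation efficiency vs the reference, mean +/- SEM over
    replicates.

    Zero-colony plates are reported at their detection limit with a
    ``below_detection`` flag rather than as efficiency 0.
    """
    heat = df[df["heat_treated"]]
    out = []
    for (strain, tp), grp in heat.groupby(["strain", "timepoint"], sort=True):
        if strain == reference_strain:
            continue
        effs, below = [], False
        for rep, rows in grp.groupby("replicate"):
            wt = heat[(heat["strain"] == reference_strain)
                      & (heat["timepoint"] == tp) & (heat["replicate"] == rep)]
            if wt.empty:
                continue
            wt_cfu = _cfu(wt.iloc[0])
            if wt_cfu == 0:
                raise ValueError(f"wild-type CFU is zero at {tp} replicate {rep}")
            row = rows.iloc[0]
            mut_cfu = _cfu(row)
            if row["colonies"] == 0:
                mut_cfu = row["dilution_factor"] / row["volume_plated_ml"]
                below = True
            effs.append(100.0 * mut_cfu / wt_cfu)
        if not effs:
            continue
        mean, sem = summarize_replicates(effs)
        out.append({"strain": strain, "timepoint": tp, "n_replicates": len(effs),
                    "efficiency_percent": mean,
                    "sem": float("nan") if sem is None else sem,
                    "below_detection": below})
    return pd.DataFrame(out, columns=["strain", "timepoint", "n_replicates",
                                      "efficiency_percent", "sem",
                                      "below_detection"])


COCULTURE_COLUMNS = ["strain", "replicate", "mut_t0", "wt_t0", "mut_sel",
                     "wt_sel"]


def read_coculture_table(path) -> pd.DataFrame:
    """TSV of co-culture CFU counts, one row per strain x replicate."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COCULTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"co-culture table missing columns: {sorted(missing)}")
    return df


def competitive_index_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-strain competitive index, mean +/- SEM over replicates."""
    out = []
    for strain, grp in df.groupby("strain", sort=True):
        cis = [competitive_index(CocultureCounts(r.mut_t0, r.wt_t0,
                                                 r.mut_sel, r.wt_sel))
               for r in grp.itertuples()]
        mean, sem = summarize_replicates(cis)
        out.append({"strain": strain, "n_replicates": len(cis),
                    "competitive_index": mean,
                    "sem": float("nan") if sem is None else sem})
    return pd.DataFrame(out, columns=["strain", "n_replicates",
                                      "competitive_index", "sem"])
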