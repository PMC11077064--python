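"""Live-imaging chromosome-partitioning quantitation.

Operates on per-timepoint ROI statistics (mean intensity and area of the
chromosome and cytosol regions of one cell) exported from upstream image
segmentation. Three metrics are derived:

* the chromosome partition coefficient — the fraction of total cellular
  signal on chromosomes, ``(I_chr * A_chr) / (I_chr * A_chr + I_cyt * A_cyt)``;
* the chromosome/cytosol enrichment ratio ``I_chr / I_cyt``;
* per-cell fold change of either metric normalized to that cell's mean at
  a reference mitotic stage (metaphase by default).

Stage-level summaries report the cross-cell mean and standard deviation
of the partition coefficient and a two-sample two-tailed t-test between
stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ROI_COLUMNS = ["cell_id", "timepoint", "stage", "i_chr", "a_chr", "i_cyt", "a_cyt"]
STAGES = ("metaphase", "anaphase", "telophase", "other")


@dataclass(frozen=True)
class ROIStats:
    """One cell at one timepoint: chromosome and cytosol ROI statistics."""

    cell_id: str
    timepoint: float
    stage: str
    i_chr: float
    a_chr: float
    i_cyt: float
    a_cyt: float

    def __post_init__(self) -> None:
        if self.a_chr <= 0 or self.a_cyt <= 0:
            raise ValueError(f"cell {self.cell_id!r}: ROI areas must be positive")
        for name in ("i_chr", "i_cyt"):
            v = getattr(self, name)
            if v < 0:
                logger.warning(
                    "cell %r t=%s: negative background-subtracted %s=%g clamped to 0",
                    self.cell_id, self.timepoint, name, v,
                )
                object.__setattr__(self, name, 0.0)


def partition_coefficient(r: ROIStats) -> float:
    """Fraction of total signal on chromosomes, in [0, 1].

    ``(I_chr * A_chr) / (I_chr * A_chr + I_cyt * A_cyt)``. Undefined when
    both integrated signals are zero.
    """
    chrom = r.i_chr * r.a_chr
    cyt = r.i_cyt * r.a_cyt
    if chrom + cyt == 0:
        raise ValueError(
            f"cell {r.cell_id!r} t={r.timepoint}: zero signal in both compartments"
        )
    return chrom / (chrom + cyt)


def enrichment_ratio(r: ROIStats) -> float:
    """Chromosome-over-cytosol mean intensity ratio, ``I_chr / I_cyt``."""
    if r.i_cyt == 0:
        raise ValueError(
            f"cell {r.cell_id!r} t={r.timepoint}: cytosolic intensity is zero"
        )
    return r.i_chr / r.i_cyt


def read_roi_csv(path: str | Path) -> list[ROIStats]:
    """Read an ROI-statistics table (CSV with the documented columns)."""
    df = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        ROIStats(str(row.cell_id), float(row.timepoint), str(row.stage),
                 float(row.i_chr), float(row.a_chr), float(row.i_cyt), float(row.a_cyt))
        for row in df.itertuples()
    ]


def series_table(rows: list[ROIStats]) -> pd.DataFrame:
    """Per-row partition coefficient and enrichment ratio as a DataFrame."""
    records = []
    for r in rows:
        records.append(
            {
                "cell_id": r.cell_id,
                "timepoint": r.timepoint,
                "stage": r.stage,
                "partition": partition_coefficient(r),
                "enrichment": enrichment_ratio(r) if r.i_cyt > 0 else np.nan,
            }
        )
    return pd.DataFrame(records)


def fold_change_series(
    rows: list[ROIStats],
    reference_stage: str = "metaphase",
    metric: str = "partition",
) -> pd.DataFrame:
    """Fold change of one cell's metric over its reference-stage mean.

    All rows must belong to a single cell; the reference is the mean of
    the chosen metric over that cell's rows labeled ``reference_stage``,
    so reference timepoints average to 1.
    """
    if not rows:
        raise ValueError("fold_change_series requires at least one row")
    cells = {r.cell_id for r in rows}
    if len(cells) != 1:
        raise ValueError(f"fold_change_series expects one cell, got {sorted(cells)}")
    table = series_table(rows)
    if metric not in ("partition", "enrichment"):
        raise ValueError(f"unknown metric {metric!r}")
    ref = table.loc[table.stage == reference_stage, metric]
    if ref.empty:
        raise ValueError(
            f"cell {rows[0].cell_id!r}: no rows at reference stage {reference_stage!r}"
        )
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise ValueError(f"cell {rows[0].cell_id!r}: zero reference-stage mean")
    table["fold_change"] = table[metric] / ref_mean
    return table


def summarize_by_stage(
    rows: list[ROIStats],
    stages: tuple[str, str] = ("metaphase", "telophase"),
) -> pd.DataFrame:
    """Cross-cell mean +- sd of the partition coefficient per stage.

    Each cell contributes its within-cell mean partition per stage; the
    two requested stages are compared with a two-tailed two-sample
    (pooled-variance) t-test. Requires at least two cells per stage.
    """
    table = series_table(rows)
    per_cell = (
        table[table.stage.isin(stages)]
        .groupby(["stage", "cell_id"], sort=False)["partition"]
        .mean()
    )
    groups = {}
    for stage in stages:
        vals = per_cell.loc[stage] if stage in per_cell.index.get_level_values(0) else pd.Series(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"stage {stage!r}: need >= 2 cells, got {len(vals)}")
        groups[stage] = np.asarray(vals, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identical groups give a 0/0 t
        t, p = stats.ttest_ind(groups[stages[0]], groups[stages[1]], equal_var=True)
    if np.isnan(p):
        p = 1.0
    out = pd.DataFrame(
        {
            "stage": list(stages),
            "n_cells": [len(groups[s]) for s in stages],
            "mean": [groups[s].mean() for s in stages],
            "sd": [groups[s].std(ddof=1) for s in stages],
        }
    )
    out.attrs["t_statistic"] = float(t) if not np.isnan(t) else 0.0
    out.attrs["p_value"] = float(p)
    return out
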