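"""Peak-clustering statistic H for protein spectra peak tables.

For each direct-dimension column (cross-section) j of a spectrum, the
clustering statistic is

    H_j = 2 * sqrt(sum_i sigma^2(delta_i^j)) / sqrt(sum_i SW_i^2)

where delta_i^j are the indirect-dimension chemical shifts of the peaks on
that cross-section, sigma is the population standard deviation, M is the
number of indirect dimensions (1 for 2D spectra, 2 for 3D), and SW_i is the
spectral width of indirect dimension i, taken as the span between the
extreme peak positions of the whole entry.  H_j = 0 means the peaks of the
cross-section coincide (or there is a single peak); for M = 1 the two-peaks-
at-the-extremes case gives H_j = 1, the population-SD upper bound.

Columns are formed by binning the direct-dimension shift into fixed windows
of 0.02 ppm, the typical direct-dimension extent of a peak.

Input peak tables are DataFrames (or CSV files) with columns
``entry_id, direct_ppm, indirect1_ppm[, indirect2_ppm]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakColumn",
    "ClusteringReport",
    "group_columns",
    "clustering_H",
    "dataset_histogram",
    "read_peak_table",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_PPM = 0.02

_INDIRECT_COLUMNS = ("indirect1_ppm", "indirect2_ppm")


@dataclass
class PeakColumn:
    """Peaks sharing one direct-dimension bin: (n_peaks, M) indirect shifts."""

    bin_id: int
    shifts: np.ndarray

    @property
    def n_peaks(self) -> int:
        return self.shifts.shape[0]

    @property
    def m_indirect(self) -> int:
        return self.shifts.shape[1]


@dataclass
class ClusteringReport:
    """Per-column H values pooled over entries, plus their histogram."""

    values: pd.DataFrame  # columns: entry_id, bin_id, n_peaks, H
    bin_edges: np.ndarray
    counts: np.ndarray
    skipped_entries: tuple[str, ...] = ()


def _indirect_cols(table: pd.DataFrame) -> list[str]:
    cols = [c for c in _INDIRECT_COLUMNS if c in table.columns]
    if not cols:
        raise ValueError(
            "peak table needs 'indirect1_ppm' (and optionally 'indirect2_ppm') columns"
        )
    return cols


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak-table CSV (entry_id, direct_ppm, indirect1_ppm[, indirect2_ppm])."""
    table = pd.read_csv(path)
    missing = {"entry_id", "direct_ppm"} - set(table.columns)
    if missing:
        raise ValueError(f"peak table is missing columns {sorted(missing)}")
    _indirect_cols(table)
    return table


def group_columns(
    table: pd.DataFrame, bin_width_ppm: float = DEFAULT_BIN_PPM
) -> list[PeakColumn]:
    """Group a (single-entry) peak table into direct-dimension columns.

    Peaks are assigned to bins of ``bin_width_ppm`` via
    floor(direct_ppm / bin_width); rows with NaN shifts are skipped (count
    logged).
    """
    if bin_width_ppm <= 0:
        raise ValueError("bin width must be positive")
    cols = _indirect_cols(table)
    if len(table) == 0:
        return []
    needed = table[["direct_ppm", *cols]]
    ok = np.isfinite(needed.to_numpy(dtype=float)).all(axis=1)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipped %d peak rows with non-finite shifts", n_skipped)
    clean = table.loc[ok]
    if len(clean) == 0:
        return []
    bins = np.floor(clean["direct_ppm"].to_numpy(dtype=float) / bin_width_ppm).astype(int)
    out = []
    for bin_id in np.unique(bins):
        shifts = clean.loc[bins == bin_id, cols].to_numpy(dtype=float)
        out.append(PeakColumn(bin_id=int(bin_id), shifts=shifts))
    return out


def clustering_H(column: PeakColumn, sw: tuple[float, ...] | np.ndarray) -> float:
    """Clustering statistic of one column given indirect spectral widths.

    Uses the population (n-divisor) standard deviation, so a single-peak
    column yields exactly 0 and two peaks at the extremes of SW yield
    exactly 1 (for M = 1).
    """
    sw = np.asarray(sw, dtype=float)
    if sw.shape != (column.m_indirect,):
        raise ValueError(
            f"need one spectral width per indirect dimension ({column.m_indirect})"
        )
    if np.any(sw <= 0):
        raise ValueError("spectral widths must be positive")
    if column.n_peaks < 2:
        return 0.0
    variances = column.shifts.var(axis=0, ddof=0)
    return float(2.0 * math.sqrt(variances.sum()) / math.sqrt((sw**2).sum()))


def dataset_histogram(
    tables,
    bins=50,
    bin_width_ppm: float = DEFAULT_BIN_PPM,
    sw: tuple[float, ...] | None = None,
) -> ClusteringReport:
    """Pool per-column H values over a collection of peak tables.

    ``tables`` is an iterable of peak-table DataFrames; a single DataFrame
    is split by ``entry_id``.  Spectral widths default to the per-entry span
    (max - min) of the observed indirect shifts ("per protein"); pass ``sw``
    to use fixed widths instead (the per-spectrum variant).  Entries with
    zero span in some dimension are skipped (logged and reported).
    """
    if isinstance(tables, pd.DataFrame):
        tables = [grp for _, grp in tables.groupby("entry_id", sort=True)]
    else:
        tables = list(tables)
    if not tables:
        raise ValueError("need at least one peak table")

    rows = []
    skipped: list[str] = []
    for table in tables:
        cols = _indirect_cols(table)
        for entry_id, entry in table.groupby("entry_id", sort=True):
            if sw is None:
                shifts = entry[cols].to_numpy(dtype=float)
                shifts = shifts[np.isfinite(shifts).all(axis=1)]
                if shifts.size == 0:
                    skipped.append(str(entry_id))
                    continue
                span = shifts.max(axis=0) - shifts.min(axis=0)
                if np.any(span <= 0):
                    logger.warning("entry %s has zero indirect span; skipped", entry_id)
                    skipped.append(str(entry_id))
                    continue
                entry_sw = tuple(span)
            else:
                entry_sw = tuple(sw)
            for col in group_columns(entry, bin_width_ppm):
                rows.append(
                    {
                        "entry_id": entry_id,
                        "bin_id": col.bin_id,
                        "n_peaks": col.n_peaks,
                        "H": clustering_H(col, entry_sw),
                    }
                )
    values = pd.DataFrame(rows, columns=["entry_id", "bin_id", "n_peaks", "H"])
    h = values["H"].to_numpy(dtype=float)
    # upper edge >= 1 so every scored column lands in a bin (counts conserved)
    upper = max(1.0, float(h.max()) if h.size else 1.0)
    counts, edges = np.histogram(h, bins=bins, range=(0.0, upper))
    return ClusteringReport(
        values=values,
        bin_edges=edges,
        counts=counts,
        skipped_entries=tuple(skipped),
    )
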