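"""Library-size normalization, cell-level QC, and the tau specificity index.

Counts are held genes x cells. Normalization is counts-per-million (CPM)
against each cell's total mapped reads followed by log2(CPM + 1). Cell QC
rejects cells whose genes-detected or mapped-read count falls more than
``k`` median absolute deviations below the cohort median. Tau summarizes how
restricted a gene's mean expression profile is across cell subclasses:
0 for a uniform profile, 1 for expression confined to a single subclass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellCounts",
    "QCReport",
    "compute_cpm",
    "log_transform",
    "qc_filter_cells",
    "subclass_mean_expression",
    "compute_tau",
    "trimmed_mean_gate",
]


@dataclass
class CellCounts:
    """Raw gene counts (genes x cells) with per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, rows indexed by gene, columns by cell.
    labels
        Subclass label per cell (index matches ``counts.columns``). Cells
        without an assignment should carry the label ``"unassigned"``.
    totals
        Total mapped reads per cell. When omitted, column sums of ``counts``
        are used. An externally supplied vector (e.g. total reads from the
        aligner, which includes reads outside the count matrix) overrides.
    """

    counts: pd.DataFrame
    labels: pd.Series
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.columns.difference(self.labels.index)
        if len(missing):
            raise ValueError(f"cells without labels: {list(missing)[:5]}")
        self.labels = self.labels.reindex(self.counts.columns)
        if self.totals is not None:
            self.totals = self.totals.reindex(self.counts.columns)
            if self.totals.isna().any():
                raise ValueError("totals missing for some cells")

    @property
    def cell_totals(self) -> pd.Series:
        if self.totals is not None:
            return self.totals
        return self.counts.sum(axis=0)

    @property
    def genes_detected(self) -> pd.Series:
        """Number of genes with at least one read, per cell."""
        return (self.counts > 0).sum(axis=0)


def compute_cpm(matrix: CellCounts) -> pd.DataFrame:
    """Counts per million mapped reads, per cell.

    Cells with a zero total are excluded from the result with a warning;
    they cannot be normalized.
    """
    totals = matrix.cell_totals
    zero = totals[totals <= 0].index
    if len(zero):
        warnings.warn(
            f"excluding {len(zero)} cell(s) with zero total reads: "
            f"{list(zero)[:5]}",
            stacklevel=2,
        )
    keep = totals[totals > 0].index
    counts = matrix.counts[keep]
    return counts.div(totals[keep], axis=1) * 1e6


def log_transform(cpm: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """log2(CPM + 1); zero stays zero and CPM 1 maps to exactly 1."""
    values = np.asarray(cpm, dtype=float)
    if (values < 0).any():
        raise ValueError("CPM values must be non-negative")
    out = np.log2(values + 1.0)
    if isinstance(cpm, pd.DataFrame):
        return pd.DataFrame(out, index=cpm.index, columns=cpm.columns)
    return out


@dataclass
class QCReport:
    """Thresholds and per-metric medians/MADs from :func:`qc_filter_cells`."""

    median_genes: float
    mad_genes: float
    threshold_genes: float
    median_reads: float
    mad_reads: float
    threshold_reads: float
    n_kept: int
    n_rejected: int
    rejected: list = field(default_factory=list)


def _median_mad(values: np.ndarray) -> tuple[float, float]:
    # unscaled MAD: median of absolute deviations, no 1.4826 factor
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def qc_filter_cells(
    matrix: CellCounts, k: float = 3.0
) -> tuple[CellCounts, list, QCReport]:
    """Reject cells lying more than ``k`` MADs below the median.

    Two per-cell metrics are screened: number of genes detected and total
    mapped reads. A cell is rejected if *either* metric is strictly below
    ``median - k * MAD``. With a degenerate MAD of 0 the threshold equals
    the median, so only cells strictly below the median are rejected.
    """
    if matrix.counts.shape[1] < 1:
        raise ValueError("need at least one cell")
    genes = matrix.genes_detected.to_numpy(dtype=float)
    reads = matrix.cell_totals.to_numpy(dtype=float)
    med_g, mad_g = _median_mad(genes)
    med_r, mad_r = _median_mad(reads)
    thr_g = med_g - k * mad_g
    thr_r = med_r - k * mad_r
    bad = (genes < thr_g) | (reads < thr_r)
    cells = matrix.counts.columns
    rejected = list(cells[bad])
    kept_cells = cells[~bad]
    kept = CellCounts(
        counts=matrix.counts[kept_cells],
        labels=matrix.labels[kept_cells],
        totals=None if matrix.totals is None else matrix.totals[kept_cells],
    )
    report = QCReport(
        median_genes=med_g,
        mad_genes=mad_g,
        threshold_genes=thr_g,
        median_reads=med_r,
        mad_reads=mad_r,
        threshold_reads=thr_r,
        n_kept=len(kept_cells),
        n_rejected=len(rejected),
        rejected=rejected,
    )
    return kept, rejected, report


def subclass_mean_expression(
    norm: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Mean log2(CPM+1) per gene per subclass (genes x subclasses).

    Subclasses with no cells in ``norm`` are dropped with a warning.
    """
    labels = labels.reindex(norm.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some cells")
    if isinstance(labels.dtype, pd.CategoricalDtype):
        empty = set(labels.cat.categories) - set(labels)
        if empty:
            warnings.warn(
                f"subclasses with no cells excluded: {sorted(empty)}",
                stacklevel=2,
            )
    return norm.T.groupby(labels, observed=True).mean().T


def compute_tau(profile: pd.DataFrame) -> pd.DataFrame:
    """Tau specificity index per gene from a subclass mean-expression profile.

    tau = sum_i (1 - y_i) / (n - 1) with y_i = x_i / max_i(x_i), where x_i is
    the mean log2(CPM+1) in subclass i and n the number of subclasses. For an
    all-zero profile the maximum is 0 and tau is undefined (NaN, flagged)
    rather than coerced to a number.
    """
    x = profile.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("tau requires at least two subclasses")
    if (x < 0).any():
        raise ValueError("expression profile must be non-negative")
    n = x.shape[1]
    peak = x.max(axis=1)
    undefined = peak == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        y = x / peak[:, None]
    tau = (1.0 - y).sum(axis=1) / (n - 1)
    tau[undefined] = np.nan
    return pd.DataFrame(
        {"tau": tau, "undefined": undefined}, index=profile.index
    )


def trimmed_mean_gate(
    values: np.ndarray | pd.Series,
    min_cells: int = 100,
    threshold: float = 1.0,
) -> bool:
    """Expression gate on a subclass: >min_cells cells and a 25-75% trimmed
    mean of per-cell log2(CPM+1) above ``threshold``.

    The trimmed mean averages values lying in the closed interquartile
    interval [Q1, Q3]; values tied with a quartile are included.
    """
    values = np.asarray(values, dtype=float)
    if values.size <= min_cells:
        return False
    q1, q3 = np.percentile(values, [25, 75])
    inner = values[(values >= q1) & (values <= q3)]
    return bool(inner.mean() > threshold)
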