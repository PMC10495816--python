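"""Experiment-level QC: empty-channel FDR, completeness, cell filters.

The count-based FDR exploits deliberately empty target channels: any
identification there is a false transfer from the reference, so the ratio
max(identifications in empty channels) / min(identifications in filled
channels) bounds the false-discovery rate of channel-level identification
at a given Channel.Q.Value cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default Channel.Q.Value sweep, covering the commonly discussed cutoffs
DEFAULT_FDR_THRESHOLDS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.30, 0.45, 1.0)


@dataclass
class ChannelFdrCurve:
    thresholds: tuple[float, ...]
    fdr_at_threshold: dict[float, float]  # NaN where min(filled) == 0
    level: str = "precursor"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": list(self.thresholds),
                "fdr": [self.fdr_at_threshold[t] for t in self.thresholds],
                "level": self.level,
            }
        )


def count_based_fdr_point(empty_counts, filled_counts) -> float:
    """max(empty) / min(filled) for one threshold; NaN if min(filled) == 0."""
    empty_counts = list(empty_counts)
    filled_counts = list(filled_counts)
    if not empty_counts or not filled_counts:
        raise ValueError("need at least one empty and one filled channel count")
    lo = min(filled_counts)
    if lo == 0:
        return math.nan
    return max(empty_counts) / lo


def count_based_fdr(rows: pd.DataFrame, design, level: str = "precursor",
                    thresholds=DEFAULT_FDR_THRESHOLDS) -> ChannelFdrCurve:
    """Count-based FDR curve over a Channel.Q.Value threshold sweep.

    ``rows`` is a report DataFrame with resolved channels; ``design``
    declares which (run, channel) pairs are empty vs target. Counts are
    distinct precursors (or protein groups) per (run, channel) passing each
    threshold.
    """
    if level not in ("precursor", "protein"):
        raise ValueError("level must be 'precursor' or 'protein'")
    key = "protein_group" if level == "protein" else "precursor_id"

    empty_pairs = [(run, ch) for run in design.runs
                   for ch in design.channels_with_role(run, "empty")]
    filled_pairs = [(run, ch) for run in design.runs
                    for ch in design.channels_with_role(run, "target")]
    if not empty_pairs or not filled_pairs:
        raise ValueError("design must declare at least one empty and one target channel")

    fdr: dict[float, float] = {}
    for t in thresholds:
        passing = rows[rows["channel_q_value"] < t]
        counts = passing.groupby(["run_id", "channel"])[key].nunique()

        def n(pair):
            return int(counts.get(pair, 0))

        fdr[t] = count_based_fdr_point([n(p) for p in empty_pairs],
                                       [n(p) for p in filled_pairs])
    return ChannelFdrCurve(tuple(thresholds), fdr, level)


def expected_completeness(mean_abundance) -> float:
    """Poisson shot-noise completeness model: 1 - exp(-x)."""
    x = np.asarray(mean_abundance, dtype=float)
    if (x < 0).any():
        raise ValueError("mean abundance must be non-negative")
    out = 1.0 - np.exp(-x)
    return float(out) if out.ndim == 0 else out


def completeness_by_quartile(matrix: pd.DataFrame) -> pd.Series:
    """Fraction of observed entries per abundance-rank quartile.

    Rows are ranked by decreasing mean intensity and split into four
    quartiles (any remainder goes to the earlier quartiles); completeness is
    the fraction of non-missing entries in each quartile.
    """
    if matrix.empty:
        raise ValueError("matrix is empty")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(-np.nanmean(values, axis=1), kind="stable")
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    fractions = {}
    start = 0
    for q, size in enumerate(sizes, start=1):
        block = values[order[start:start + size]]
        fractions[f"Q{q}"] = (
            float(np.isfinite(block).mean()) if block.size else math.nan
        )
        start += size
    return pd.Series(fractions, name="completeness")


@dataclass
class CellFilterResult:
    retained: list[str]
    audit: pd.DataFrame  # cell, protein_count, stage, reason
    median: float
    sd: float


def filter_cells(protein_counts: pd.Series, total_proteins: int,
                 sd_window: float = 1.5, empty_fraction: float = 0.01) -> CellFilterResult:
    """Two-stage single-cell filter on identified-protein counts.

    Stage 1 drops "empty" cells whose protein count is at or below
    ``empty_fraction`` of the experiment-wide number of distinct proteins.
    Stage 2 keeps cells whose count lies within ``sd_window`` standard
    deviations around the median, with median and SD computed on the
    stage-1 survivors and inclusive bounds.
    """
    if len(protein_counts) < 3:
        raise ValueError("need at least three cells")
    counts = protein_counts.astype(float)
    threshold = empty_fraction * total_proteins

    stage1 = counts[counts > threshold]
    audit_rows = []
    for cell, c in counts.items():
        if c <= threshold:
            audit_rows.append((cell, c, 1, f"count {c:g} <= {threshold:g} (empty)"))

    if len(stage1) == 0:
        warnings.warn("all cells removed as empty", stacklevel=2)
        audit = pd.DataFrame(audit_rows, columns=["cell", "protein_count", "stage", "reason"])
        return CellFilterResult([], audit, math.nan, math.nan)

    med = float(stage1.median())
    sd = float(stage1.std(ddof=1)) if len(stage1) > 1 else 0.0
    if math.isnan(sd):
        sd = 0.0
    lo, hi = med - sd_window * sd, med + sd_window * sd

    retained = []
    for cell, c in stage1.items():
        if lo <= c <= hi:
            retained.append(cell)
        else:
            audit_rows.append((cell, c, 2, f"count {c:g} outside [{lo:g}, {hi:g}]"))
    if not retained:
        warnings.warn("no cells retained after the SD window", stacklevel=2)
    audit = pd.DataFrame(audit_rows, columns=["cell", "protein_count", "stage", "reason"])
    return CellFilterResult(retained, audit, med, sd)


def summed_signal(matrix: pd.DataFrame) -> pd.Series:
    """Total MS signal per cell (column): sum of non-missing intensities."""
    values = matrix.to_numpy(dtype=float)
    totals = np.where(np.isfinite(values), values, 0.0).sum(axis=0)
    out = pd.Series(totals, index=matrix.columns, name="summed_signal")
    empty = out.index[~np.isfinite(values).any(axis=0)] if values.size else out.index
    if len(empty):
        warnings.warn(f"cells with no signal at all: {list(empty)}", stacklevel=2)
    return out


def pairwise_pearson(matrix: pd.DataFrame, min_shared: int = 3) -> tuple[pd.DataFrame, float]:
    """Pearson correlation of log2 intensities on pairwise-complete rows.

    Returns the correlation matrix (diagonal 1, NaN where fewer than
    ``min_shared`` shared rows) and the median off-diagonal correlation.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_mat = np.log2(matrix.to_numpy(dtype=float))
    log_mat[~np.isfinite(log_mat)] = np.nan
    n = matrix.shape[1]
    corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(log_mat[:, i]) & np.isfinite(log_mat[:, j])
            if both.sum() >= min_shared:
                corr[i, j] = corr[j, i] = float(
                    np.corrcoef(log_mat[both, i], log_mat[both, j])[0, 1]
                )
    frame = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    off = corr[np.triu_indices(n, k=1)]
    off = off[np.isfinite(off)]
    median_off = float(np.median(off)) if off.size else math.nan
    return frame, median_off
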