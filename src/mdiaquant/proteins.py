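"""Protein-level quantification: MaxLFQ roll-up, normalization, CV summaries.

MaxLFQ combines the precursor intensities of a protein into per-sample
protein abundances: for every sample pair the protein log-ratio is the
median of the per-precursor log-ratios over precursors seen in both
samples, and the per-sample log-abundances are the least-squares solution
of that pairwise ratio system over the largest connected component of the
sample graph. The free additive constant is anchored so that the summed
linear protein intensity equals the summed observed precursor intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components


@dataclass(frozen=True)
class ProteinQuantConfig:
    min_precursors_per_protein: int = 1
    normalization: str = "none"  # none | median_per_channel
    log_base: int = 2

    def __post_init__(self):
        if self.min_precursors_per_protein < 1:
            raise ValueError("min_precursors_per_protein must be >= 1")
        if self.normalization not in ("none", "median_per_channel"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _maxlfq_profile(log_mat: np.ndarray) -> np.ndarray:
    """Per-sample log2 abundances from one protein's precursor x sample block.

    Solves min over x of sum_{i<j} (x_j - x_i - r_ij)^2 with r_ij the median
    precursor log-ratio; samples outside the largest connected component
    come back NaN. The solution is mean-centered (anchoring happens later).
    """
    n_prec, n_samp = log_mat.shape
    obs = np.isfinite(log_mat)
    present = obs.any(axis=0)

    adj = np.zeros((n_samp, n_samp), dtype=bool)
    ratio = np.full((n_samp, n_samp), np.nan)
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            both = obs[:, i] & obs[:, j]
            if both.any():
                adj[i, j] = adj[j, i] = True
                ratio[i, j] = np.median(log_mat[both, j] - log_mat[both, i])

    n_comp, labels = connected_components(adj, directed=False)
    # restrict to the largest component among samples with any observation
    sizes = np.bincount(labels[present], minlength=n_comp) if present.any() else np.array([])
    if sizes.size == 0 or sizes.max() == 0:
        return np.full(n_samp, np.nan)
    comp = int(np.argmax(sizes))
    members = np.where((labels == comp) & present)[0]

    if len(members) == 1:
        x = np.full(n_samp, np.nan)
        col = log_mat[:, members[0]]
        x[members[0]] = float(np.nanmedian(col[np.isfinite(col)]))
        return x

    idx = {s: k for k, s in enumerate(members)}
    rows_a, rhs = [], []
    for i in members:
        for j in members:
            if i < j and adj[i, j]:
                row = np.zeros(len(members))
                row[idx[j]] = 1.0
                row[idx[i]] = -1.0
                rows_a.append(row)
                rhs.append(ratio[i, j])
    # pin the mean to zero to make the system full rank
    rows_a.append(np.full(len(members), 1.0 / len(members)))
    rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.asarray(rows_a), np.asarray(rhs), rcond=None)

    x = np.full(n_samp, np.nan)
    x[members] = sol
    return x


@dataclass
class RollupResult:
    matrix: pd.DataFrame
    n_dropped_proteins: int
    dropped_proteins: list[str]


def maxlfq_rollup(precursor_matrix: pd.DataFrame, protein_map: pd.Series,
                  cfg: ProteinQuantConfig | None = None) -> RollupResult:
    """Roll a precursor x sample intensity matrix up to protein groups.

    ``protein_map`` maps every precursor (row key) to its protein group.
    Proteins with fewer than ``min_precursors_per_protein`` precursors are
    dropped and counted. Intensities are linear in and linear out.
    """
    cfg = cfg or ProteinQuantConfig()
    if precursor_matrix.empty:
        raise ValueError("precursor matrix is empty")
    missing = set(precursor_matrix.index) - set(protein_map.index)
    if missing:
        raise ValueError(f"protein map does not cover precursors: {sorted(missing)[:5]}")

    samples = list(precursor_matrix.columns)
    groups = protein_map.loc[precursor_matrix.index]
    profiles: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for protein, precursors in groups.groupby(groups).groups.items():
        block = precursor_matrix.loc[list(precursors)]
        if len(block) < cfg.min_precursors_per_protein:
            dropped.append(str(protein))
            continue
        values = block.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_mat = np.where(values > 0, np.log2(values), np.nan)
        x = _maxlfq_profile(log_mat)
        if not np.isfinite(x).any():
            dropped.append(str(protein))
            continue
        # anchor: summed linear protein intensity over quantified samples
        # equals the summed observed precursor intensity in those samples
        quantified = np.isfinite(x)
        observed_total = np.nansum(np.where(np.isfinite(log_mat[:, quantified]),
                                            values[:, quantified], 0.0))
        linear = np.where(quantified, np.exp2(np.where(quantified, x, 0.0)), np.nan)
        shift = observed_total / np.nansum(linear)
        profiles[str(protein)] = linear * shift

    matrix = pd.DataFrame.from_dict(profiles, orient="index", columns=samples)
    matrix.index.name = "protein_group"
    if cfg.normalization == "median_per_channel" and not matrix.empty:
        matrix = median_normalize(matrix)
    return RollupResult(matrix=matrix, n_dropped_proteins=len(dropped),
                        dropped_proteins=sorted(dropped))


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-sample medians in log space, preserving within-sample ratios.

    Each sample's log2 median is shifted to the median of the original
    per-sample medians, so the transform is idempotent. Raises on an
    all-missing sample, naming it.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_mat = np.log2(matrix.to_numpy(dtype=float))
    log_mat[~np.isfinite(log_mat)] = np.nan
    medians = np.nanmedian(log_mat, axis=0) if matrix.shape[0] else np.array([])
    for name, med in zip(matrix.columns, medians):
        if not np.isfinite(med):
            raise ValueError(f"sample {name!r} has no finite values to normalize")
    grand = float(np.median(medians))
    shifted = log_mat - medians[np.newaxis, :] + grand
    return pd.DataFrame(np.exp2(shifted), index=matrix.index, columns=matrix.columns)


def cv_per_row(matrix: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Per-row coefficient of variation (%) over a sample group.

    CV = sample standard deviation (n-1) / mean of the linear intensities,
    over non-missing entries; rows with fewer than two values are excluded.
    """
    sub = matrix[samples] if samples is not None else matrix
    if sub.shape[1] < 2:
        raise ValueError("CV needs a group of at least two samples")
    values = sub.to_numpy(dtype=float)
    n = np.isfinite(values).sum(axis=1)
    mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)
    sd = np.nanstd(np.where(np.isfinite(values), values, np.nan), axis=1, ddof=1)
    out = pd.DataFrame({"n": n, "mean": mean, "cv_percent": 100.0 * sd / mean},
                       index=sub.index)
    return out[out["n"] >= 2]


def median_cv(matrix: pd.DataFrame, samples: list[str] | None = None) -> float:
    """Median CV (%) across rows with at least two values."""
    table = cv_per_row(matrix, samples)
    if len(table) == 0:
        raise ValueError("no rows with >= 2 values in the group")
    return float(table["cv_percent"].median())
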