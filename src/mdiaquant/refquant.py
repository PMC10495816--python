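"""RefQuant: reference-channel ratio estimation for multiplexed DIA.

The reference channel carries the same high-input proteome in every run, so
each low-input target channel can be quantified *relative* to it. For every
precursor in a run, each shared ion (fragment by fragment index, plus the
MS1 area) yields one target/reference ratio. The ratio distribution is
asymmetric — interference inflates a fraction of the ratios — so a robust
location estimate is taken: ratios are sorted ascending and only the lowest
40% retained (at least one), and the precursor ratio R is their arithmetic
mean. Multiplying R by a precursor-specific scaling factor — the median
reference intensity across all runs — converts the ratio into an absolute
intensity estimate for the target channel.

The scaling factor falls back through the reference quantities in order
Ms1.Area -> Precursor.Translated -> Precursor.Normalised -> summed ion
intensities, moving on whenever fewer than two non-missing values exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .report_io import ExperimentDesign

DEFAULT_QUANTILE_FRACTION = 0.40


@dataclass(frozen=True)
class RefQuantConfig:
    #: fraction of the ascending-sorted ratio list retained before averaging
    quantile_fraction: float = DEFAULT_QUANTILE_FRACTION
    #: average retained ratios in log space (geometric mean) instead of linear
    log_space_mean: bool = False

    def __post_init__(self):
        if not 0 < self.quantile_fraction <= 1:
            raise ValueError("quantile_fraction must be in (0, 1]")


@dataclass
class RatioEstimate:
    precursor: str
    run_id: str
    target_channel: int
    ratios: np.ndarray
    n_total: int
    n_retained: int
    ratio: float
    quantile_fraction: float = DEFAULT_QUANTILE_FRACTION


@dataclass
class ScalingFactor:
    precursor: str
    value: float
    source: str  # ms1_area | precursor_translated | precursor_normalised | summed_ions


@dataclass
class RefQuantResult:
    """Precursor-level intensity matrix plus per-estimate provenance."""

    matrix: pd.DataFrame          # rows: precursor, columns: sample names
    long: pd.DataFrame            # one row per (precursor, run, target channel)
    protein_map: pd.Series        # precursor -> protein group
    n_dropped_no_reference: int = 0
    dropped_precursors: list[str] = field(default_factory=list)


def extract_ion_ratios(target_fragments, reference_fragments,
                       target_ms1=math.nan, reference_ms1=math.nan) -> np.ndarray:
    """Target/reference ratio per shared ion, fragment index order then MS1.

    Only ions where both channel quantities are present and positive form a
    ratio. Returns an empty array when no ion is shared.
    """
    t = np.asarray(target_fragments, dtype=float)
    r = np.asarray(reference_fragments, dtype=float)
    if t.shape != r.shape:
        raise ValueError(
            f"fragment vectors are not aligned: {t.shape[0]} target vs {r.shape[0]} reference ions"
        )
    ok = np.isfinite(t) & np.isfinite(r) & (t > 0) & (r > 0)
    ratios = list(t[ok] / r[ok])
    if np.isfinite(target_ms1) and np.isfinite(reference_ms1) and target_ms1 > 0 and reference_ms1 > 0:
        ratios.append(target_ms1 / reference_ms1)
    return np.asarray(ratios, dtype=float)


def retained_count(n_total: int, quantile_fraction: float = DEFAULT_QUANTILE_FRACTION) -> int:
    """Number of ratios kept from an ascending sort: max(1, floor(q * n))."""
    if n_total < 1:
        raise ValueError("need at least one ratio")
    return max(1, math.floor(quantile_fraction * n_total))


def estimate_ratio(ratios, quantile_fraction: float = DEFAULT_QUANTILE_FRACTION,
                   log_space_mean: bool = False, *, precursor: str = "",
                   run_id: str = "", target_channel: int = -1) -> RatioEstimate:
    """Robust precursor ratio: mean of the lowest-quantile ascending ratios."""
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate a ratio from an empty ratio list")
    if not (np.isfinite(arr).all() and (arr > 0).all()):
        raise ValueError("ratios must be positive finite reals")
    n = arr.size
    k = retained_count(n, quantile_fraction)
    retained = np.sort(arr, kind="stable")[:k]
    if log_space_mean:
        ratio = float(np.exp(np.mean(np.log(retained))))
    else:
        # exactly rounded sum: the retained set is tiny and the estimate is
        # compared against reference computations
        ratio = math.fsum(retained) / k
    return RatioEstimate(
        precursor=precursor, run_id=run_id, target_channel=target_channel,
        ratios=arr, n_total=n, n_retained=k, ratio=ratio,
        quantile_fraction=quantile_fraction,
    )


def _median_if_enough(values: list[float], minimum: int = 2) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v) and v > 0]
    if len(vals) >= minimum:
        return float(np.median(vals))
    return None


def reference_scaling_factor(precursor: str, reference_quantities: pd.DataFrame) -> ScalingFactor:
    """Cross-run scaling factor of a precursor from its reference-channel rows.

    ``reference_quantities`` holds one row per run with columns ``ms1_area``,
    ``precursor_translated``, ``precursor_normalised`` and
    ``fragment_quant_raw`` (list of floats). The fallback hierarchy requires
    at least two non-missing values per level before it is used; the final
    summed-ion level accepts any number of runs.
    """
    if len(reference_quantities) == 0:
        raise ValueError(f"precursor {precursor!r} has no reference observation in any run")
    for source in ("ms1_area", "precursor_translated", "precursor_normalised"):
        med = _median_if_enough(list(reference_quantities[source]))
        if med is not None:
            return ScalingFactor(precursor, med, source)
    sums = []
    for _, row in reference_quantities.iterrows():
        total = float(np.nansum(np.asarray(row["fragment_quant_raw"], dtype=float)))
        ms1 = row["ms1_area"]
        if np.isfinite(ms1) and ms1 > 0:
            total += float(ms1)
        if total > 0:
            sums.append(total)
    if not sums:
        raise ValueError(f"precursor {precursor!r} has no usable reference quantity")
    return ScalingFactor(precursor, float(np.median(sums)), "summed_ions")


def refquant_intensity(estimate: RatioEstimate, scale: ScalingFactor) -> float:
    """Target-channel intensity: ratio R times the reference scaling factor."""
    return estimate.ratio * scale.value


def _precursor_key(rows: pd.DataFrame) -> pd.Series:
    return rows["stripped_sequence"].astype(str) + "_" + rows["charge"].astype(str)


def run_refquant(rows: pd.DataFrame, design: ExperimentDesign,
                 config: RefQuantConfig | None = None) -> RefQuantResult:
    """Quantify every target channel of every run against its reference.

    ``rows`` is a (filtered) report DataFrame with resolved integer channels.
    Precursors without any reference-channel observation are dropped and
    counted. Entries with no shared ion stay missing (never zero).
    """
    config = config or RefQuantConfig()
    for run in design.runs:
        design.reference_channel(run)  # raises if a run lacks a reference

    rows = rows.copy()
    rows["precursor"] = _precursor_key(rows)

    # per-run reference channel lookup
    ref_channel = {run: design.reference_channel(run) for run in design.runs}
    known_runs = set(design.runs)
    unknown = set(rows["run_id"]) - known_runs
    if unknown:
        raise ValueError(f"report contains runs absent from the design: {sorted(unknown)}")

    is_ref = rows.apply(lambda r: r["channel"] == ref_channel[r["run_id"]], axis=1)
    ref_rows = rows[is_ref]

    # scaling factor per precursor: cross-run median of reference quantities
    scales: dict[str, ScalingFactor] = {}
    for precursor, grp in ref_rows.groupby("precursor", sort=False):
        scales[precursor] = reference_scaling_factor(precursor, grp)

    protein_map = (
        rows.drop_duplicates("precursor").set_index("precursor")["protein_group"]
    )

    dropped = sorted(set(rows["precursor"]) - set(scales))

    target_role = {
        (run, ch): design.sample_name(run, ch)
        for run in design.runs
        for ch in design.channels_with_role(run, "target") + design.channels_with_role(run, "empty")
    }

    records = []
    ref_lookup = {
        (r["precursor"], r["run_id"]): r for _, r in ref_rows.iterrows()
    }
    for (precursor, run_id), grp in rows[~is_ref].groupby(["precursor", "run_id"], sort=False):
        if precursor not in scales:
            continue
        ref = ref_lookup.get((precursor, run_id))
        if ref is None:
            continue  # reference not observed in this run: nothing to ratio against
        scale = scales[precursor]
        for _, target in grp.iterrows():
            channel = int(target["channel"])
            sample = target_role.get((run_id, channel))
            if sample is None:
                continue  # channel not declared for this run
            ratios = extract_ion_ratios(
                target["fragment_quant_raw"], ref["fragment_quant_raw"],
                target["ms1_area"], ref["ms1_area"],
            )
            if ratios.size == 0:
                continue
            est = estimate_ratio(
                ratios, config.quantile_fraction, config.log_space_mean,
                precursor=precursor, run_id=run_id, target_channel=channel,
            )
            records.append(
                {
                    "precursor": precursor,
                    "protein_group": target["protein_group"],
                    "run_id": run_id,
                    "channel": channel,
                    "sample": sample,
                    "n_total": est.n_total,
                    "n_retained": est.n_retained,
                    "ratio": est.ratio,
                    "scale": scale.value,
                    "scale_source": scale.source,
                    "intensity": refquant_intensity(est, scale),
                }
            )

    long = pd.DataFrame(
        records,
        columns=[
            "precursor", "protein_group", "run_id", "channel", "sample",
            "n_total", "n_retained", "ratio", "scale", "scale_source", "intensity",
        ],
    )
    if len(long):
        matrix = long.pivot_table(index="precursor", columns="sample",
                                  values="intensity", aggfunc="first")
        matrix.columns.name = None
    else:
        matrix = pd.DataFrame()
    return RefQuantResult(
        matrix=matrix,
        long=long,
        protein_map=protein_map,
        n_dropped_no_reference=len(dropped),
        dropped_precursors=dropped,
    )


def summed_ion_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-channel summed ion intensity (fragments + MS1) per precursor/run.

    The plain quantification path for bulk designs without a dominant
    reference: one row per report row with the total detected ion signal.
    """
    rows = rows.copy()
    rows["precursor"] = _precursor_key(rows)

    def total(row):
        s = float(np.nansum(np.asarray(row["fragment_quant_raw"], dtype=float)))
        if np.isfinite(row["ms1_area"]) and row["ms1_area"] > 0:
            s += float(row["ms1_area"])
        return s if s > 0 else math.nan

    rows["summed_intensity"] = rows.apply(total, axis=1)
    return rows[
        ["precursor", "protein_group", "run_id", "channel", "summed_intensity"]
    ].reset_index(drop=True)


def ms1_ratio_table(rows: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Plain MS1-area target/reference ratios, the non-RefQuant comparator.

    One row per (precursor, run, target channel) where both MS1 areas are
    present; used to contrast RefQuant's robustness against single-quantity
    MS1 quantification.
    """
    rows = rows.copy()
    rows["precursor"] = _precursor_key(rows)
    ref_channel = {run: design.reference_channel(run) for run in design.runs}
    is_ref = rows.apply(lambda r: r["channel"] == ref_channel[r["run_id"]], axis=1)
    ref_ms1 = {
        (r["precursor"], r["run_id"]): r["ms1_area"]
        for _, r in rows[is_ref].iterrows()
    }
    records = []
    for _, target in rows[~is_ref].iterrows():
        key = (target["precursor"], target["run_id"])
        ref = ref_ms1.get(key, math.nan)
        t = target["ms1_area"]
        if np.isfinite(ref) and ref > 0 and np.isfinite(t) and t > 0:
            records.append(
                {
                    "precursor": target["precursor"],
                    "run_id": target["run_id"],
                    "channel": int(target["channel"]),
                    "ms1_ratio": float(t / ref),
                }
            )
    return pd.DataFrame(records, columns=["precursor", "run_id", "channel", "ms1_ratio"])
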