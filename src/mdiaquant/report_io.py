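"""Reading, filtering and channel resolution for DIA-NN-style long reports.

The consumed dialect is the DIA-NN 1.8.1 long report: one tab-separated row
per precursor x run x channel, with per-fragment raw quantities in a
semicolon-delimited ``Fragment.Quant.Raw`` column, an ``Ms1.Area`` and two
precursor-level quantities, plus the q-value columns used for filtering.
Column names are configurable through a schema map so that other dialects
can be adapted.

Zero or empty quantity tokens are parsed as missing values, not measured
zeros: the search engine emits 0 for fragments it could not integrate, and
a zero would later produce degenerate target/reference ratios.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chemistry import LabelScheme

#: internal column name -> DIA-NN 1.8.1 report column name
DEFAULT_SCHEMA: dict[str, str] = {
    "run_id": "Run",
    "protein_group": "Protein.Group",
    "genes": "Genes",
    "precursor_id": "Precursor.Id",
    "modified_sequence": "Modified.Sequence",
    "stripped_sequence": "Stripped.Sequence",
    "charge": "Precursor.Charge",
    "channel": "Channel",
    "q_value": "Q.Value",
    "global_pg_q_value": "Global.PG.Q.Value",
    "pg_q_value": "PG.Q.Value",
    "lib_pg_q_value": "Lib.PG.Q.Value",
    "channel_q_value": "Channel.Q.Value",
    "translated_q_value": "Translated.Q.Value",
    "ms1_area": "Ms1.Area",
    "precursor_translated": "Precursor.Translated",
    "precursor_normalised": "Precursor.Normalised",
    "fragment_quant_raw": "Fragment.Quant.Raw",
}

#: columns that may be absent from a report without raising
OPTIONAL_COLUMNS = frozenset({"genes", "channel", "translated_q_value", "modified_sequence"})

_QUANT_COLUMNS = ("ms1_area", "precursor_translated", "precursor_normalised")
_QVALUE_COLUMNS = (
    "q_value",
    "global_pg_q_value",
    "pg_q_value",
    "lib_pg_q_value",
    "channel_q_value",
    "translated_q_value",
)


class SchemaError(ValueError):
    """A required report column is missing."""


class ReportParseError(ValueError):
    """A report cell could not be parsed."""


class ChannelResolutionError(ValueError):
    """The channel of a precursor id could not be determined."""


def _parse_quant_token(token: str, row_number: int, column: str) -> float:
    token = token.strip()
    if token in ("", "NA", "NaN", "nan"):
        return math.nan
    try:
        value = float(token)
    except ValueError:
        raise ReportParseError(
            f"non-numeric quantity token {token!r} in column {column}, data row {row_number}"
        ) from None
    # zero means "not integrated" in the consumed dialect
    return value if value > 0 else math.nan


def _split_fragments(cell, row_number: int, column: str) -> list[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    return [_parse_quant_token(tok, row_number, column) for tok in str(cell).split(";")]


def read_report(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a long report table into a DataFrame with internal column names.

    Fragment quantities are split on ';' into lists of floats with NaN for
    missing/zero entries. Raises :class:`SchemaError` naming the first
    missing required column, :class:`ReportParseError` with the data row
    number on malformed numeric cells.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    present = set(raw.columns)
    for internal, external in schema.items():
        if external not in present and internal not in OPTIONAL_COLUMNS:
            raise SchemaError(f"report is missing required column {external!r}")

    out = pd.DataFrame(index=raw.index)
    for internal, external in schema.items():
        if external not in present:
            continue
        col = raw[external]
        if internal == "fragment_quant_raw":
            out[internal] = [
                _split_fragments(cell, i + 1, external) for i, cell in enumerate(col)
            ]
        elif internal in _QUANT_COLUMNS:
            out[internal] = [
                _parse_quant_token(cell, i + 1, external) for i, cell in enumerate(col)
            ]
        elif internal in _QVALUE_COLUMNS:
            vals = pd.to_numeric(col.replace("", np.nan), errors="coerce")
            bad = vals.isna() & (col != "")
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise ReportParseError(
                    f"non-numeric q-value in column {external}, data row {row}"
                )
            if ((vals < 0) | (vals > 1)).any():
                row = int(((vals < 0) | (vals > 1)).idxmax()) + 1
                raise ReportParseError(
                    f"q-value outside [0, 1] in column {external}, data row {row}"
                )
            out[internal] = vals.astype(float)
        elif internal == "charge":
            out[internal] = pd.to_numeric(col, errors="raise").astype(int)
        elif internal == "channel":
            out[internal] = pd.to_numeric(col.replace("", np.nan), errors="coerce")
        else:
            out[internal] = col.astype(str)
    return out


def write_report(rows: pd.DataFrame, path, schema: dict[str, str] | None = None) -> None:
    """Write rows (internal column names) back to the report dialect.

    Missing fragment entries are serialized as ``0`` and missing scalar
    quantities as empty strings, matching what :func:`read_report` maps back
    to NaN — a read/write/read round trip is lossless.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    out = pd.DataFrame(index=rows.index)
    for internal, external in schema.items():
        if internal not in rows.columns:
            continue
        col = rows[internal]
        if internal == "fragment_quant_raw":
            out[external] = [
                ";".join("0" if math.isnan(v) else repr(float(v)) for v in frags)
                for frags in col
            ]
        elif internal in _QUANT_COLUMNS:
            out[external] = ["" if math.isnan(v) else repr(float(v)) for v in col]
        elif internal == "channel":
            out[external] = ["" if pd.isna(v) else str(int(v)) for v in col]
        elif internal in _QVALUE_COLUMNS:
            out[external] = [repr(float(v)) for v in col]
        else:
            out[external] = col
    out.to_csv(path, sep="\t", index=False)


# --- channel resolution -----------------------------------------------------

_LABEL_TOKEN = re.compile(r"Dimethyl-(?:n|K)-(\d+)")


def parse_channel(precursor_id: str, scheme: LabelScheme | None = None,
                  explicit_channel=None) -> int:
    """Resolve the channel number of a precursor id.

    An explicit channel column value takes precedence; otherwise the
    channel-decorated modified sequence is scanned for label tokens of the
    form ``Dimethyl-n-<k>`` / ``Dimethyl-K-<k>``, which must all agree on k.
    """
    if explicit_channel is not None and not pd.isna(explicit_channel):
        channel = int(explicit_channel)
    else:
        ks = {int(m) for m in _LABEL_TOKEN.findall(precursor_id)}
        if not ks:
            raise ChannelResolutionError(
                f"cannot resolve channel of {precursor_id!r}: "
                "no Channel column value and no label tokens"
            )
        if len(ks) > 1:
            raise ChannelResolutionError(
                f"conflicting label tokens in {precursor_id!r}: channels {sorted(ks)}"
            )
        channel = ks.pop()
    if scheme is not None and channel not in scheme.channels:
        raise ChannelResolutionError(
            f"channel {channel} of {precursor_id!r} is not part of scheme {scheme.name}"
        )
    return channel


def resolve_channels(rows: pd.DataFrame, scheme: LabelScheme | None = None) -> pd.DataFrame:
    """Fill/overwrite the ``channel`` column from ids where it is missing."""
    rows = rows.copy()
    explicit = rows["channel"] if "channel" in rows.columns else pd.Series(np.nan, rows.index)
    rows["channel"] = [
        parse_channel(pid, scheme, explicit_channel=ch)
        for pid, ch in zip(rows["precursor_id"], explicit)
    ]
    rows["channel"] = rows["channel"].astype(int)
    return rows


# --- q-value filtering ------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Strict-inequality q-value thresholds. 1.0 disables a criterion."""

    max_global_pg_q: float = 1.0
    max_pg_q: float = 1.0
    max_lib_pg_q: float = 1.0
    max_q: float = 1.0
    max_channel_q: float = 1.0
    preset_name: str = "custom"

    def __post_init__(self):
        for name in ("max_global_pg_q", "max_pg_q", "max_lib_pg_q", "max_q", "max_channel_q"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def replace(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


#: bulk preset: protein-group confidence plus per-channel confidence
BULK_FILTERS = FilterConfig(
    max_global_pg_q=0.01, max_pg_q=0.05, max_channel_q=0.01, preset_name="bulk"
)
#: single-cell preset: library PG confidence, precursor q, relaxed channel q
SINGLE_CELL_FILTERS = FilterConfig(
    max_lib_pg_q=0.01, max_q=0.01, max_channel_q=0.15, preset_name="single-cell"
)

FILTER_PRESETS = {"bulk": BULK_FILTERS, "single-cell": SINGLE_CELL_FILTERS}


@dataclass
class FilterResult:
    rows: pd.DataFrame
    removed_counts: dict[str, int]
    n_input: int

    @property
    def n_retained(self) -> int:
        return len(self.rows)


_FILTER_MAP = {
    "global_pg_q_value": "max_global_pg_q",
    "pg_q_value": "max_pg_q",
    "lib_pg_q_value": "max_lib_pg_q",
    "q_value": "max_q",
    "channel_q_value": "max_channel_q",
}


def apply_qc_filters(rows: pd.DataFrame, cfg: FilterConfig) -> FilterResult:
    """Keep rows passing ALL thresholds with strict '<' comparisons.

    Per-criterion removal counts report how many rows each criterion would
    remove on its own (a row can be counted by several criteria).
    """
    keep = pd.Series(True, index=rows.index)
    removed: dict[str, int] = {}
    for column, attr in _FILTER_MAP.items():
        threshold = getattr(cfg, attr)
        if threshold >= 1.0 or column not in rows.columns:
            continue
        passing = rows[column] < threshold
        removed[column] = int((~passing).sum())
        keep &= passing
    return FilterResult(rows=rows[keep].copy(), removed_counts=removed, n_input=len(rows))


# --- experiment design ------------------------------------------------------

ROLES = ("reference", "target", "empty")


@dataclass(frozen=True)
class ExperimentDesign:
    """Mapping of (run, channel) to role and sample name.

    Every run must declare at most one reference channel; each (run,
    channel) pair maps to exactly one role.
    """

    table: pd.DataFrame  # columns: run, channel, role, sample_name

    def __post_init__(self):
        t = self.table
        required = {"run", "channel", "role", "sample_name"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"design table is missing columns {sorted(missing)}")
        bad_roles = set(t["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        if t.duplicated(["run", "channel"]).any():
            dup = t[t.duplicated(["run", "channel"])].iloc[0]
            raise ValueError(f"duplicate design entry for run {dup['run']!r} channel {dup['channel']}")
        n_ref = t[t["role"] == "reference"].groupby("run").size()
        over = n_ref[n_ref > 1]
        if len(over):
            raise ValueError(f"more than one reference channel in run(s) {list(over.index)}")

    @property
    def runs(self) -> list[str]:
        return list(dict.fromkeys(self.table["run"]))

    def reference_channel(self, run: str) -> int:
        sel = self.table[(self.table["run"] == run) & (self.table["role"] == "reference")]
        if len(sel) == 0:
            raise ValueError(f"run {run!r} declares no reference channel")
        return int(sel["channel"].iloc[0])

    def channels_with_role(self, run: str, role: str) -> list[int]:
        sel = self.table[(self.table["run"] == run) & (self.table["role"] == role)]
        return [int(c) for c in sel["channel"]]

    def sample_name(self, run: str, channel: int) -> str:
        sel = self.table[(self.table["run"] == run) & (self.table["channel"] == channel)]
        if len(sel) == 0:
            raise ValueError(f"no design entry for run {run!r} channel {channel}")
        return str(sel["sample_name"].iloc[0])


def read_design(path) -> ExperimentDesign:
    table = pd.read_csv(path, sep="\t", dtype={"run": str, "sample_name": str})
    table["channel"] = table["channel"].astype(int)
    return ExperimentDesign(table)


def write_design(design: ExperimentDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)
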