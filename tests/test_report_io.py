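"""Report parsing, channel resolution, q-value filtering and designs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mdiaquant as mq
from mdiaquant.report_io import (
    ChannelResolutionError,
    ReportParseError,
    SchemaError,
)

from conftest import make_report


HEADER = (
    "Run\tProtein.Group\tGenes\tPrecursor.Id\tModified.Sequence\tStripped.Sequence\t"
    "Precursor.Charge\tChannel\tQ.Value\tGlobal.PG.Q.Value\tPG.Q.Value\t"
    "Lib.PG.Q.Value\tChannel.Q.Value\tTranslated.Q.Value\tMs1.Area\t"
    "Precursor.Translated\tPrecursor.Normalised\tFragment.Quant.Raw"
)


def write_tsv(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


def one_row(fragments="100;200;0;50", channel="4"):
    return (
        f"run1\tP1\tG1\t(Dimethyl-n-4)PEPTIDER2\t(Dimethyl-n-4)PEPTIDER\tPEPTIDER\t2\t"
        f"{channel}\t0.001\t0.001\t0.01\t0.001\t0.001\t0.001\t1000\t500\t500\t{fragments}"
    )


class TestReadReport:
    def test_zero_fragment_tokens_become_missing(self, tmp_path):
        path = write_tsv(tmp_path / "r.tsv", [HEADER, one_row()])
        rows = mq.read_report(path)
        frags = rows["fragment_quant_raw"].iloc[0]
        assert frags[:2] == [100.0, 200.0]
        assert math.isnan(frags[2])
        assert frags[3] == 50.0

    def test_header_only_gives_empty_collection(self, tmp_path):
        path = write_tsv(tmp_path / "r.tsv", [HEADER])
        assert len(mq.read_report(path)) == 0

    def test_missing_required_column_names_it(self, tmp_path):
        header = HEADER.replace("\tChannel.Q.Value", "")
        row = "\t".join(one_row().split("\t")[:12] + one_row().split("\t")[13:])
        path = write_tsv(tmp_path / "r.tsv", [header, row])
        with pytest.raises(SchemaError, match="Channel.Q.Value"):
            mq.read_report(path)

    def test_non_numeric_token_reports_row_number(self, tmp_path):
        path = write_tsv(tmp_path / "r.tsv", [HEADER, one_row(), one_row("1;oops;3")])
        with pytest.raises(ReportParseError, match="row 2"):
            mq.read_report(path)

    def test_read_write_read_round_trip(self, tmp_path):
        sim = mq.simulate_report(
            mq.preset("scBenchmark", seed=11).replace(n_proteins=10)
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        mq.write_report(sim.report, p1)
        first = mq.read_report(p1)
        mq.write_report(first, p2)
        second = mq.read_report(p2)
        pd.testing.assert_frame_equal(first, second)
        # quantity columns survive the trip at full precision
        assert list(first["ms1_area"].dropna()) == list(
            sim.report["ms1_area"].dropna()
        )


class TestParseChannel:
    def test_token_grammar(self):
        pid = "AAK(Dimethyl-K-4)LLVK(Dimethyl-K-4)(Dimethyl-n-4)2"
        assert mq.parse_channel(pid) == 4

    def test_explicit_channel_overrides_tokens(self):
        pid = "(Dimethyl-n-4)PEPTIDER2"
        assert mq.parse_channel(pid, explicit_channel=8) == 8

    def test_conflicting_tokens_rejected(self):
        pid = "(Dimethyl-n-0)PEPK(Dimethyl-K-8)R2"
        with pytest.raises(ChannelResolutionError, match="conflicting"):
            mq.parse_channel(pid)

    def test_unresolvable_without_tokens_or_column(self):
        with pytest.raises(ChannelResolutionError, match="cannot resolve"):
            mq.parse_channel("PEPTIDER2")

    def test_total_on_synthetic_reports(self):
        sim = mq.simulate_report(
            mq.preset("fiveplex_1_2_4_2_1", seed=5).replace(n_proteins=8)
        )
        stripped = sim.report.drop(columns=["channel"])
        resolved = mq.resolve_channels(stripped, sim.config.scheme)
        assert (resolved["channel"] == sim.report["channel"]).all()


class TestFilters:
    def test_single_cell_threshold_is_strict(self):
        rows = make_report([{"channel_q_value": 0.15}])
        assert mq.apply_qc_filters(rows, mq.SINGLE_CELL_FILTERS).n_retained == 0

    def test_perfect_rows_retained(self):
        rows = make_report([{ }])
        for cfg in (mq.BULK_FILTERS, mq.SINGLE_CELL_FILTERS):
            assert mq.apply_qc_filters(rows, cfg).n_retained == 1

    def test_counts_removed_per_criterion(self):
        rows = make_report(
            [{"channel_q_value": q} for q in (0.01, 0.10, 0.20)]
        )
        result = mq.apply_qc_filters(rows, mq.SINGLE_CELL_FILTERS)
        assert result.n_retained == 2
        assert result.removed_counts["channel_q_value"] == 1

    def test_bulk_preset_matches_documented_thresholds(self):
        assert mq.BULK_FILTERS.max_global_pg_q == 0.01
        assert mq.BULK_FILTERS.max_pg_q == 0.05
        assert mq.BULK_FILTERS.max_channel_q == 0.01
        assert mq.SINGLE_CELL_FILTERS.max_lib_pg_q == 0.01
        assert mq.SINGLE_CELL_FILTERS.max_q == 0.01
        assert mq.SINGLE_CELL_FILTERS.max_channel_q == 0.15

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        lo=st.floats(0.001, 1.0),
        hi=st.floats(0.001, 1.0),
        qs=st.lists(st.floats(0, 1), min_size=1, max_size=20),
    )
    def test_filtering_monotone_in_threshold(self, lo, hi, qs):
        lo, hi = sorted((lo, hi))
        rows = make_report([{"channel_q_value": q} for q in qs])
        kept_lo = mq.apply_qc_filters(
            rows, mq.FilterConfig(max_channel_q=lo)
        ).rows.index
        kept_hi = mq.apply_qc_filters(
            rows, mq.FilterConfig(max_channel_q=hi)
        ).rows.index
        assert set(kept_lo) <= set(kept_hi)


class TestExperimentDesign:
    def test_round_trip(self, tmp_path, two_channel_design):
        path = tmp_path / "design.tsv"
        mq.write_design(two_channel_design, path)
        back = mq.read_design(path)
        pd.testing.assert_frame_equal(back.table, two_channel_design.table)

    def test_two_references_in_one_run_rejected(self):
        with pytest.raises(ValueError, match="more than one reference"):
            mq.ExperimentDesign(
                pd.DataFrame(
                    {
                        "run": ["r", "r"],
                        "channel": [0, 4],
                        "role": ["reference", "reference"],
                        "sample_name": ["a", "b"],
                    }
                )
            )

    def test_duplicate_run_channel_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            mq.ExperimentDesign(
                pd.DataFrame(
                    {
                        "run": ["r", "r"],
                        "channel": [4, 4],
                        "role": ["target", "empty"],
                        "sample_name": ["a", "b"],
                    }
                )
            )

    def test_role_lookups(self, two_channel_design):
        assert two_channel_design.reference_channel("run1") == 0
        assert two_channel_design.channels_with_role("run1", "target") == [4]
        assert two_channel_design.sample_name("run1", 4) == "run1_d4"
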