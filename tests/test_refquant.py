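"""RefQuant ratio extraction, robust estimation and scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mdiaquant as mq
from conftest import make_report


def brute_force_ratio(ratios, quantile_fraction=0.40):
    """Independent oracle: explicit sort and index arithmetic."""
    ordered = sorted(ratios)
    k = max(1, math.floor(quantile_fraction * len(ordered)))
    kept = ordered[:k]
    return math.fsum(kept) / len(kept)


class TestExtractIonRatios:
    def test_shared_ions_only_fragment_order_then_ms1(self, nan):
        ratios = mq.extract_ion_ratios(
            [10, 20, nan, 5], [1000, 1000, 500, nan], 30, 2000
        )
        assert list(ratios) == pytest.approx([0.01, 0.02, 0.015])

    def test_identical_channels_give_unit_ratios(self):
        ratios = mq.extract_ion_ratios([3, 7], [3, 7], 11, 11)
        assert list(ratios) == [1.0, 1.0, 1.0]

    def test_all_target_missing_gives_empty(self, nan):
        assert mq.extract_ion_ratios([nan, nan], [1, 2], nan, 5).size == 0

    def test_misaligned_fragment_vectors_rejected(self):
        with pytest.raises(ValueError, match="not aligned"):
            mq.extract_ion_ratios([1, 2], [1, 2, 3])


class TestEstimateRatio:
    def test_lowest_quantile_mean_hand_example(self):
        est = mq.estimate_ratio([0.01, 0.02, 0.03, 0.04, 0.05, 1.0, 1.1])
        assert est.n_retained == 2  # floor(0.4 * 7)
        assert est.ratio == pytest.approx(0.015)

    def test_fourteen_ratios_retain_five(self):
        ratios = [k * 0.001 for k in range(1, 15)]
        est = mq.estimate_ratio(ratios)
        assert est.n_retained == 5
        assert est.ratio == pytest.approx(0.003)

    def test_constant_ratios_for_any_fraction(self):
        for q in (0.1, 0.4, 1.0):
            assert mq.estimate_ratio([0.7] * 9, q).ratio == pytest.approx(0.7)

    def test_estimate_lies_within_retained_range(self):
        est = mq.estimate_ratio([5.0, 1.0, 3.0, 2.0, 4.0])
        kept = sorted(est.ratios)[: est.n_retained]
        assert min(kept) <= est.ratio <= max(kept)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mq.estimate_ratio([])

    def test_geometric_mean_option(self):
        est = mq.estimate_ratio([1.0, 4.0], quantile_fraction=1.0, log_space_mean=True)
        assert est.ratio == pytest.approx(2.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        ratios=st.lists(
            st.floats(1e-4, 1e4, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=20,
        ),
        q=st.sampled_from([0.1, 0.25, 0.4, 0.6, 1.0]),
    )
    def test_matches_brute_force_oracle(self, ratios, q):
        assert mq.estimate_ratio(ratios, q).ratio == brute_force_ratio(ratios, q)


class TestScalingFactor:
    @staticmethod
    def frame(ms1, trans, norm, frags):
        return pd.DataFrame(
            {
                "ms1_area": ms1,
                "precursor_translated": trans,
                "precursor_normalised": norm,
                "fragment_quant_raw": frags,
            }
        )

    def test_ms1_median_is_default(self, nan):
        q = self.frame([100, 200, 300], [1, 1, 1], [1, 1, 1], [[1]] * 3)
        sf = mq.reference_scaling_factor("p", q)
        assert (sf.value, sf.source) == (200.0, "ms1_area")

    def test_fallback_to_precursor_translated(self, nan):
        q = self.frame([150, nan, nan], [80, 120, 100], [1, 1, 1], [[1]] * 3)
        sf = mq.reference_scaling_factor("p", q)
        assert (sf.value, sf.source) == (100.0, "precursor_translated")

    def test_final_fallback_sums_available_ions(self, nan):
        q = self.frame([nan], [nan], [nan], [[10.0, 20.0, 30.0]])
        sf = mq.reference_scaling_factor("p", q)
        assert (sf.value, sf.source) == (60.0, "summed_ions")

    def test_no_reference_observation_is_an_error(self):
        with pytest.raises(ValueError, match="no reference observation"):
            mq.reference_scaling_factor("p", self.frame([], [], [], []))

    def test_intensity_is_ratio_times_scale(self):
        est = mq.estimate_ratio([0.015], quantile_fraction=1.0)
        sf = mq.ScalingFactor("p", 200.0, "ms1_area")
        assert mq.refquant_intensity(est, sf) == pytest.approx(3.0)


def _paired_rows(target_frags, ref_frags, target_ms1, ref_ms1, run="run1"):
    return make_report(
        [
            {
                "run_id": run,
                "channel": 0,
                "fragment_quant_raw": ref_frags,
                "ms1_area": ref_ms1,
                "precursor_id": "(Dimethyl-n-0)PEPTIDER2",
            },
            {
                "run_id": run,
                "channel": 4,
                "fragment_quant_raw": target_frags,
                "ms1_area": target_ms1,
                "precursor_id": "(Dimethyl-n-4)PEPTIDER2",
            },
        ]
    )


class TestRunRefQuant:
    def test_single_entry_composition(self, two_channel_design, nan):
        rows = _paired_rows([10, 20, nan, 5], [1000, 1000, 500, nan], 30, 2000)
        # scale falls back to summed ions (one run): 2500 + 2000 = 4500
        result = mq.run_refquant(rows, two_channel_design)
        assert result.matrix.shape == (1, 1)
        est = result.long.iloc[0]
        assert est["n_total"] == 3
        assert est["ratio"] == pytest.approx(0.01)  # retain floor(0.4*3)=1
        assert est["intensity"] == pytest.approx(0.01 * 4500)

    def test_all_target_quantities_missing_entry_absent_not_zero(
        self, two_channel_design, nan
    ):
        rows = _paired_rows([nan, nan], [100, 100], nan, 500)
        result = mq.run_refquant(rows, two_channel_design)
        assert len(result.long) == 0
        assert result.matrix.empty

    def test_cross_run_median_scale_shared_between_runs(self, nan):
        design = mq.ExperimentDesign(
            pd.DataFrame(
                {
                    "run": ["run1", "run1", "run2", "run2"],
                    "channel": [0, 4, 0, 4],
                    "role": ["reference", "target"] * 2,
                    "sample_name": ["run1_ref", "run1_d4", "run2_ref", "run2_d4"],
                }
            )
        )
        r1 = _paired_rows([10.0], [100.0], 50.0, 1000.0, run="run1")
        r2 = _paired_rows([20.0], [100.0], 50.0, 3000.0, run="run2")
        rows = pd.concat([r1, r2], ignore_index=True)
        result = mq.run_refquant(rows, design)
        scales = result.long["scale"].unique()
        assert list(scales) == [2000.0]  # median of MS1 areas 1000 and 3000

    def test_precursor_without_reference_dropped_and_counted(self, two_channel_design):
        rows = make_report(
            [{"channel": 4, "stripped_sequence": "ORPHANPEPK",
              "precursor_id": "(Dimethyl-n-4)ORPHANPEPK2"}]
        )
        result = mq.run_refquant(rows, two_channel_design)
        assert result.n_dropped_no_reference == 1
        assert result.dropped_precursors == ["ORPHANPEPK_2"]

    def test_run_without_reference_is_a_configuration_error(self):
        design = mq.ExperimentDesign(
            pd.DataFrame(
                {
                    "run": ["run1"],
                    "channel": [4],
                    "role": ["target"],
                    "sample_name": ["run1_d4"],
                }
            )
        )
        with pytest.raises(ValueError, match="no reference"):
            mq.run_refquant(make_report([{}]), design)

    def test_scale_equivariance_in_target(self, two_channel_design, nan):
        base = _paired_rows([10, 20, 30], [100, 100, 100], 40, 400)
        out1 = mq.run_refquant(base, two_channel_design).long.iloc[0]
        scaled = _paired_rows([30, 60, 90], [100, 100, 100], 120, 400)
        out3 = mq.run_refquant(scaled, two_channel_design).long.iloc[0]
        assert out3["ratio"] == pytest.approx(3 * out1["ratio"])
        assert out3["intensity"] == pytest.approx(3 * out1["intensity"])

    def test_reference_rescaling_leaves_intensities_unchanged(self, nan):
        """Scaling every reference quantity by c cancels between R and scale."""
        design = mq.ExperimentDesign(
            pd.DataFrame(
                {
                    "run": ["run1", "run1", "run2", "run2"],
                    "channel": [0, 4, 0, 4],
                    "role": ["reference", "target"] * 2,
                    "sample_name": ["run1_ref", "run1_d4", "run2_ref", "run2_d4"],
                }
            )
        )

        def data(c):
            r1 = _paired_rows([10, 20], [100 * c, 200 * c], 40, 400 * c, run="run1")
            r2 = _paired_rows([12, 24], [110 * c, 210 * c], 44, 440 * c, run="run2")
            return pd.concat([r1, r2], ignore_index=True)

        base = mq.run_refquant(data(1.0), design).long
        scaled = mq.run_refquant(data(7.0), design).long
        assert np.allclose(scaled["intensity"], base["intensity"])
        assert np.allclose(scaled["ratio"], base["ratio"] / 7.0)
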