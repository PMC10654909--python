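import numpy as np
import pandas as pd
import pytest

from cstval.agreement import ConfusionMatrix4, summary_metrics
from cstval.measures import SleepMeasures
from cstval.report import (
    Demographics,
    SessionResult,
    SubgroupSpec,
    device_table,
    rank_heatmap_matrix,
    round_half_up,
    site_average_macro_f1,
    stage_margin,
    subgroup_column_means,
    subgroup_side_differences,
    subgroup_table,
    top_k_stage_average,
)

MEASURES = SleepMeasures(8.0, 6.5, 0.3, 1.2, 81.25, 70.0)


def result(session, participant, device, counts, site="S1", klass="wearable",
           sex="male", ahi=10.0, bmi=22.0, se=80.0):
    ref = SleepMeasures(8.0, 6.4, 0.4, 1.2, se, 80.0)
    return SessionResult(
        session_id=session,
        participant_id=participant,
        device_id=device,
        device_class=klass,
        site=site,
        confusion=ConfusionMatrix4(np.asarray(counts)),
        measures_device=MEASURES,
        measures_reference=ref,
        demographics=Demographics(sex=sex, age=40.0, bmi=bmi, ahi=ahi),
    )


DIAG = np.diag([100, 200, 50, 80])
OFFDIAG = np.array(
    [[60, 30, 5, 5], [20, 150, 20, 10], [5, 15, 30, 0], [5, 10, 5, 60]]
)


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "x, decimals, expected",
        [(0.47895, 4, 0.479), (0.00005, 4, 0.0001), (0.6726, 3, 0.673),
         (0.5, 0, 1.0), (-0.00005, 4, -0.0001)],
    )
    def test_ties_round_away_from_zero(self, x, decimals, expected):
        assert round_half_up(x, decimals) == expected


class TestDeviceTable:
    def test_single_session_equals_its_summary(self):
        res = [result("s1", "p1", "devA", OFFDIAG)]
        table = device_table(res)
        s = summary_metrics(ConfusionMatrix4(OFFDIAG))
        assert table.loc["devA", "macro_f1"] == pytest.approx(s.macro_f1)
        assert table.loc["devA", "kappa"] == pytest.approx(s.kappa)
        assert table.loc["devA", "n"] == 1

    def test_pooled_differs_from_per_participant_average(self):
        """Two sessions with disjoint stage support: pooling the counts is
        not the same as averaging per-session metrics."""
        c1 = np.zeros((4, 4), dtype=int)
        c1[0, 0], c1[1, 1], c1[0, 1] = 50, 30, 20
        c2 = np.zeros((4, 4), dtype=int)
        c2[2, 2], c2[3, 3], c2[3, 2] = 40, 30, 30
        res = [
            result("s1", "p1", "devA", c1),
            result("s2", "p2", "devA", c2),
        ]
        pooled = device_table(res, mode="pooled")
        averaged = device_table(res, mode="per_participant")
        summed = summary_metrics(ConfusionMatrix4(c1 + c2))
        assert pooled.loc["devA", "macro_f1"] == pytest.approx(summed.macro_f1)
        assert pooled.loc["devA", "macro_f1"] != pytest.approx(
            averaged.loc["devA", "macro_f1"]
        )

    def test_participant_count_distinct(self):
        res = [
            result("s1", "p1", "devA", DIAG),
            result("s2", "p1", "devA", DIAG),
            result("s3", "p2", "devA", DIAG),
        ]
        assert device_table(res).loc["devA", "n"] == 2

    def test_inconsistent_device_class_rejected(self):
        res = [
            result("s1", "p1", "devA", DIAG, klass="wearable"),
            result("s2", "p2", "devA", DIAG, klass="airable"),
        ]
        with pytest.raises(ValueError, match="inconsistent classes"):
            device_table(res)

    def test_site_restriction(self):
        res = [
            result("s1", "p1", "devA", DIAG, site="S1"),
            result("s2", "p2", "devA", OFFDIAG, site="S2"),
        ]
        t1 = device_table(res, site="S1")
        assert t1.loc["devA", "accuracy"] == pytest.approx(1.0)


class TestSiteAverage:
    def test_mean_invariant_to_ordering(self):
        values = [0.5, 0.62, 0.31, 0.44]
        assert site_average_macro_f1(values) == site_average_macro_f1(values[::-1])

    def test_single_device_site(self):
        assert site_average_macro_f1([0.5669]) == 0.5669


class TestSubgroups:
    def make_results(self):
        return [
            result("s1", "p1", "devA", DIAG, ahi=5, bmi=22, sex="male", se=80),
            result("s2", "p2", "devA", OFFDIAG, ahi=30, bmi=28, sex="female", se=90),
            result("s3", "p3", "devB", OFFDIAG, ahi=5, bmi=22, sex="male", se=80),
            result("s4", "p4", "devB", DIAG, ahi=30, bmi=28, sex="female", se=90),
        ]

    def test_matrix_shape_and_thresholds(self):
        table = subgroup_table(self.make_results())
        assert list(table.index) == ["devA", "devB"]
        assert "ahi<=15" in table.columns and "bmi>25" in table.columns
        # p1 (AHI 5) is devA's only low-AHI participant and scored perfectly
        assert table.loc["devA", "ahi<=15"] == pytest.approx(1.0)

    def test_empty_cell_flagged_missing_and_excluded_from_mean(self):
        res = [
            result("s1", "p1", "devA", DIAG, ahi=5),
            result("s2", "p2", "devB", OFFDIAG, ahi=5),
        ]
        table = subgroup_table(res, specs=(SubgroupSpec("ahi", 15.0),))
        assert table["ahi>15"].isna().all()
        means = subgroup_column_means(table)
        assert np.isnan(means["ahi>15"])
        assert means["ahi<=15"] == pytest.approx(
            round_half_up(table["ahi<=15"].mean(), 4)
        )

    def test_column_means_bracket_overall_in_per_participant_mode(self):
        res = self.make_results()
        table = subgroup_table(res, specs=(SubgroupSpec("ahi", 15.0),),
                               mode="per_participant")
        overall = device_table(res, mode="per_participant")["macro_f1"]
        for device in table.index:
            lo = min(table.loc[device])
            hi = max(table.loc[device])
            assert lo - 1e-12 <= overall[device] <= hi + 1e-12

    def test_side_differences(self):
        table = pd.DataFrame(
            {"ahi<=15": [0.3636, 0.5], "ahi>15": [0.4565, 0.45]},
            index=["SleepScore", "Other"],
        )
        diffs = subgroup_side_differences(table, (SubgroupSpec("ahi", 15.0),))
        assert diffs.loc["SleepScore", "ahi"] == pytest.approx(0.0929)
        assert diffs["ahi"].idxmax() == "SleepScore"


class TestStageMargin:
    def test_margin_and_ordering(self):
        res = stage_margin({"a": 0.7065, "b": 0.5967, "c": 0.3})
        assert res.top_device == "a" and res.runner_up == "b"
        assert res.margin == pytest.approx(0.1098)
        assert not res.tie

    def test_tie_reports_both(self):
        res = stage_margin({"a": 0.5, "b": 0.5, "c": 0.3})
        assert res.margin == 0.0 and res.tie
        assert set(res.tied_devices) == {"a", "b"}

    def test_needs_two_devices(self):
        with pytest.raises(ValueError):
            stage_margin({"a": 0.5})


class TestTopKAverage:
    def test_subset_mean(self):
        f1 = {"a": 0.6, "b": 0.4, "c": 0.9}
        assert top_k_stage_average(f1, ["a", "b"]) == 0.5

    def test_singleton_subset(self):
        assert top_k_stage_average({"a": 0.612}, ["a"]) == 0.612

    def test_unknown_device_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            top_k_stage_average({"a": 0.6}, ["a", "nope"])


class TestRankHeatmap:
    def test_linear_map(self):
        table = pd.DataFrame([[0.2, 0.6, 1.0]], index=["d"], columns=list("xyz"))
        out = rank_heatmap_matrix(table)
        np.testing.assert_allclose(out.loc["d"], [0.0, 0.5, 1.0], atol=1e-12)

    def test_constant_row_flagged_nan(self):
        table = pd.DataFrame([[0.5, 0.5, 0.5], [0.1, 0.2, 0.4]],
                             index=["flat", "ok"], columns=list("xyz"))
        out = rank_heatmap_matrix(table)
        assert out.loc["flat"].isna().all()
        assert not out.loc["ok"].isna().any()

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.random((2, 3)), index=["a", "b"],
                             columns=list("xyz"))
        out = rank_heatmap_matrix(table)
        for device in table.index:
            row = table.loc[device]
            expected = (row - row.min()) / (row.max() - row.min())
            np.testing.assert_allclose(out.loc[device], expected)
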