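"""Index-R computation, slope-threshold calling, and screen-level summaries."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoreg.genome_io import GeneSet
from mitoreg import screen as sc
from ._oracles import hypergeom_upper_tail


class TestIndexR:
    def test_identity_when_scores_match_control(self):
        assert sc.compute_index_r([3, 4, 5], [3, 4, 5]) == 1.0

    def test_hand_arithmetic(self):
        assert sc.compute_index_r([3, 3, 4], [5, 5, 5]) == pytest.approx(10 / 3 / 5)

    def test_all_zero_scores_floor(self):
        assert sc.compute_index_r([0, 0, 0], [5, 5]) == 0.0

    def test_zero_control_mean_raises(self):
        with pytest.raises(sc.DegenerateControlError):
            sc.compute_index_r([1, 2], [0, 0])


class TestCallModifier:
    @pytest.mark.parametrize(
        "ir_rnai,ir_combo,expected",
        [
            (1.0, 0.74, "enhancer"),  # just below the 0.75 line
            (1.0, 0.76, "none"),
            (1.0, 0.75, "none"),  # on the line: strict inequality
            (1.0, 1.0, "none"),  # diagonal
            (0.8, 1.3, "suppressor"),  # 1.3 > 1.5 * 0.8 = 1.2
            (0.8, 1.2, "none"),
        ],
    )
    def test_slope_threshold_rules(self, ir_rnai, ir_combo, expected):
        call = sc.call_modifier(sc.IndexRPair("g", ir_rnai, ir_combo))
        assert call.call == expected

    def test_zero_rnai_index_flagged_not_called(self):
        call = sc.call_modifier(sc.IndexRPair("g", 0.0, 0.5))
        assert call.call == "none"
        assert "undefined_ratio" in call.flags
        assert math.isnan(call.ratio)

    @given(
        ir_rnai=st.floats(0.05, 3.0),
        ir_combo=st.floats(0.0, 3.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, ir_rnai, ir_combo, scale):
        """Multiplying both Index-R values by c > 0 never changes the call."""
        base = sc.call_modifier(sc.IndexRPair("g", ir_rnai, ir_combo))
        scaled = sc.call_modifier(sc.IndexRPair("g", ir_rnai * scale, ir_combo * scale))
        assert base.call == scaled.call

    @given(
        ir_rnai=st.floats(0.05, 3.0),
        combo_hi=st.floats(0.0, 3.0),
        delta=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_combo_arm(self, ir_rnai, combo_hi, delta):
        """Decreasing ir_combo never moves a call away from enhancer."""
        rank = {"suppressor": 0, "none": 1, "enhancer": 2}
        hi = sc.call_modifier(sc.IndexRPair("g", ir_rnai, combo_hi))
        lo = sc.call_modifier(sc.IndexRPair("g", ir_rnai, max(combo_hi - delta, 0.0)))
        assert rank[lo.call] >= rank[hi.call]


class TestCalibration:
    def test_reference_ratio_is_the_slope(self):
        assert sc.calibrate_enhancer_slope(sc.IndexRPair("ewg", 1.0, 0.75)) == 0.75
        assert sc.calibrate_enhancer_slope(sc.IndexRPair("ewg", 0.9, 0.6)) == pytest.approx(0.6 / 0.9)

    def test_non_synergistic_reference_warns(self):
        with pytest.warns(UserWarning, match="not synergistic"):
            slope = sc.calibrate_enhancer_slope(sc.IndexRPair("ewg", 1.0, 1.2))
        assert slope == pytest.approx(1.2)

    @given(ir_rnai=st.floats(0.1, 2.0), ir_combo=st.floats(0.01, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_reference_sits_exactly_on_its_own_boundary(self, ir_rnai, ir_combo):
        """Using the calibrated slope, the reference point itself is 'none'
        (strict inequality) but any lower combo value is an enhancer."""
        pair = sc.IndexRPair("ref", ir_rnai, ir_combo)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slope = sc.calibrate_enhancer_slope(pair)
        at_boundary = sc.call_modifier(pair, enhancer_slope=slope)
        assert at_boundary.call != "enhancer"
        below = sc.IndexRPair("ref", ir_rnai, ir_combo * 0.9)
        if slope < 1.35:  # keep clear of the suppressor threshold
            assert sc.call_modifier(below, enhancer_slope=slope).call == "enhancer"


def _call(gene, call, ratio):
    return sc.ModifierCall(gene, call, ratio)


class TestConsolidation:
    @pytest.mark.parametrize(
        "calls,expected_call,expect_conflict",
        [
            ([("enhancer", 0.5), ("none", 0.9)], "enhancer", False),
            ([("none", 0.9), ("none", 1.1)], "none", False),
            ([("enhancer", 0.5), ("suppressor", 1.8)], "none", True),
            ([("suppressor", 1.6), ("suppressor", 1.9)], "suppressor", False),
        ],
    )
    def test_rule_table(self, calls, expected_call, expect_conflict):
        result = sc.consolidate_gene_calls([_call("g", c, r) for c, r in calls])
        assert result.call == expected_call
        assert ("conflict" in result.flags) == expect_conflict

    def test_extreme_line_wins(self):
        result = sc.consolidate_gene_calls([_call("g", "enhancer", 0.6), _call("g", "enhancer", 0.4)])
        assert result.ratio == 0.4
        result = sc.consolidate_gene_calls([_call("g", "suppressor", 1.6), _call("g", "suppressor", 2.0)])
        assert result.ratio == 2.0

    def test_mixed_gene_ids_rejected(self):
        with pytest.raises(ValueError):
            sc.consolidate_gene_calls([_call("g1", "none", 1.0), _call("g2", "none", 1.0)])


class TestGroupSummary:
    def _calls(self, spec):
        """spec: {gene: call}"""
        return {g: _call(g, c, 0.5 if c == "enhancer" else 1.0) for g, c in spec.items()}

    def test_fraction_printed_as_in_the_pilot(self):
        genes = {f"m{i}": ("enhancer" if i < 33 else "none") for i in range(40)}
        group = GeneSet("Mito-EBR", frozenset(genes))
        df = sc.group_summary(self._calls(genes), [group])
        row = df.iloc[0]
        assert (row["n"], row["n_enhancer"]) == (40, 33)
        assert row["fraction"] == pytest.approx(0.825)

    def test_zero_enhancer_group(self):
        genes = {f"x{i}": "none" for i in range(10)}
        df = sc.group_summary(self._calls(genes), [GeneSet("g", frozenset(genes))])
        assert df.iloc[0]["fraction"] == 0.0

    def test_enrichment_p_matches_exact_hypergeometric(self):
        spec = {f"a{i}": ("enhancer" if i < 4 else "none") for i in range(6)}
        spec |= {f"b{i}": ("enhancer" if i < 1 else "none") for i in range(6)}
        groups = [GeneSet("A", frozenset(k for k in spec if k.startswith("a"))),
                  GeneSet("B", frozenset(k for k in spec if k.startswith("b")))]
        df = sc.group_summary(self._calls(spec), groups, reference_group="A")
        p = df.loc[df["group"] == "B", "p_vs_reference"].item()
        assert p == pytest.approx(hypergeom_upper_tail(12, 6, 5, 4), rel=1e-12)

    def test_strong_enrichment_is_significant(self):
        spec = {f"a{i}": ("enhancer" if i < 33 else "none") for i in range(40)}
        spec |= {f"b{i}": ("enhancer" if i < 5 else "none") for i in range(58)}
        groups = [GeneSet("A", frozenset(k for k in spec if k.startswith("a"))),
                  GeneSet("B", frozenset(k for k in spec if k.startswith("b")))]
        df = sc.group_summary(self._calls(spec), groups, reference_group="A")
        assert df.loc[df["group"] == "B", "p_vs_reference"].item() < 1e-6

    def test_overlapping_groups_rejected(self):
        calls = self._calls({"g1": "none", "g2": "none"})
        groups = [GeneSet("A", frozenset({"g1", "g2"})), GeneSet("B", frozenset({"g2"}))]
        with pytest.raises(ValueError, match="disjoint"):
            sc.group_summary(calls, groups)


class TestScoreScreen:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["line_id", "gene_id", "arm", "score"])

    def test_end_to_end_calls(self):
        rows = []
        for s in [5, 5, 5]:
            rows += [("ctrl-1", "ctrl", "rnai_only", s), ("ctrl-1", "ctrl", "rnai_mitoxhoi", s)]
        # enhancer: rnai 4/5, combo 1/5 -> ratio 0.3125
        for arm, s in [("rnai_only", 4), ("rnai_mitoxhoi", 1)]:
            rows += [("gE-L1", "gE", arm, s)] * 3
        # null gene on the diagonal
        for arm, s in [("rnai_only", 4), ("rnai_mitoxhoi", 4)]:
            rows += [("gN-L1", "gN", arm, s)] * 3
        result = sc.score_screen(self._frame(rows), control_rnai_line="ctrl-1")
        assert result.gene_calls["gE"].call == "enhancer"
        assert result.gene_calls["gN"].call == "none"

    def test_calibration_changes_the_slope(self):
        rows = []
        for s in [5]:
            rows += [("ctrl-1", "ctrl", "rnai_only", s), ("ctrl-1", "ctrl", "rnai_mitoxhoi", s)]
        rows += [("ref-L1", "ref", "rnai_only", 5), ("ref-L1", "ref", "rnai_mitoxhoi", 3)]  # ratio 0.6
        rows += [("g1-L1", "g1", "rnai_only", 5), ("g1-L1", "g1", "rnai_mitoxhoi", 2)]  # ratio 0.4
        rows += [("g2-L1", "g2", "rnai_only", 5), ("g2-L1", "g2", "rnai_mitoxhoi", 3)]  # ratio 0.6
        result = sc.score_screen(self._frame(rows), control_rnai_line="ctrl-1", calibrate_on="ref")
        # slope becomes 0.6: g1 (0.4) is below it, g2 sits on the boundary
        assert result.gene_calls["g1"].call == "enhancer"
        assert result.gene_calls["g2"].call == "none"

    def test_lethal_flag_propagates(self):
        frame = pd.DataFrame(
            [
                ("ctrl-1", "ctrl", "rnai_only", 5, False),
                ("ctrl-1", "ctrl", "rnai_mitoxhoi", 5, False),
                ("gL-L1", "gL", "rnai_only", 0, True),
                ("gL-L1", "gL", "rnai_mitoxhoi", 0, True),
            ],
            columns=["line_id", "gene_id", "arm", "score", "lethal"],
        )
        result = sc.score_screen(frame, control_rnai_line="ctrl-1")
        assert "lethal" in result.gene_calls["gL"].flags
        assert "undefined_ratio" in result.gene_calls["gL"].flags
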