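import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceratio.detect import (
    combine_significance,
    compute_srd,
    event_srd,
    intersect_comparisons,
    map_isoforms,
    rank_candidates,
    select_candidates,
)
from spliceratio.events import build_events, group_junctions_by_site
from spliceratio.io import ExonAnnotation


def srd_reference(sr_t, sr_c):
    """Independent two-line restatement of the score used as an oracle."""
    return (1 + sum(sr_t - x for x in sr_c)) / (
        1 + statistics.stdev(sr_c) / len(sr_c)
    )


class TestComputeSrd:
    def test_identity_when_controls_agree(self):
        assert compute_srd(0.5, [0.5, 0.5, 0.5]) == 1.0

    def test_worked_example(self):
        # numerator 1 + (0.4 + 0.4 + 0.3) = 2.1; sd([.5,.5,.6]) = 0.0577
        assert compute_srd(0.9, [0.5, 0.5, 0.6]) == pytest.approx(2.0603, abs=5e-4)

    def test_zero_numerator(self):
        assert compute_srd(0.2, [0.5, 0.5, 0.6]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            n_c = int(rng.integers(2, 8))
            sr_t = float(rng.random())
            sr_c = rng.random(n_c).tolist()
            assert abs(compute_srd(sr_t, sr_c) - srd_reference(sr_t, sr_c)) < 1e-12

    def test_average_variant_divides_by_control_count(self):
        sr_c = [0.5, 0.5, 0.6]
        summed = compute_srd(0.9, sr_c)
        averaged = compute_srd(0.9, sr_c, average=True)
        denom = 1 + statistics.stdev(sr_c) / 3
        assert averaged == pytest.approx(1 / denom + (summed - 1 / denom) / 3)

    def test_needs_two_controls(self):
        with pytest.raises(ValueError):
            compute_srd(0.5, [0.5])

    @given(
        sr_lo=st.floats(0, 1), sr_hi=st.floats(0, 1),
        sr_c=st.lists(st.floats(0, 1), min_size=2, max_size=6),
    )
    @settings(deadline=None)
    def test_strictly_increasing_in_treatment_ratio(self, sr_lo, sr_hi, sr_c):
        lo, hi = sorted((sr_lo, sr_hi))
        if hi - lo > 1e-12:
            assert compute_srd(hi, sr_c) > compute_srd(lo, sr_c)


class TestEventSrd:
    def _event(self):
        j_in, j_skip = ("chr1", 100, 200, "+"), ("chr1", 100, 400, "+")
        groups = [g for g in group_junctions_by_site([j_in, j_skip]) if len(g.members) == 2]
        ann = [ExonAnnotation("g", "t", "chr1", 201, 300, "+")]
        return build_events(groups, ann)[0]

    def test_max_rule(self):
        ev = self._event()
        srd, junction = event_srd(ev, 1.8, 0.3)
        assert srd == 1.8 and junction == ev.inclusion_junction

    def test_tie_goes_to_inclusion_junction(self):
        ev = self._event()
        _, junction = event_srd(ev, 1.2, 1.2)
        assert junction == ev.inclusion_junction

    def test_complementary_ratios_make_exactly_one_junction_rise(self):
        # two-junction group: SRs sum to 1 in every sample, so the two
        # junction scores mirror each other around 1 for a common sd
        sr_t, sr_c = 0.8, [0.5, 0.55, 0.45]
        up = compute_srd(sr_t, sr_c)
        down = compute_srd(1 - sr_t, [1 - x for x in sr_c])
        assert up > 1 > down
        denom = 1 + statistics.stdev(sr_c) / len(sr_c)  # equal for both junctions
        assert up + down == pytest.approx(2 / denom, abs=1e-12)


class TestCombineSignificance:
    def test_odd_count_is_plain_median(self):
        table = pd.DataFrame({"a": [0.01], "b": [0.02], "c": [0.5]})
        assert combine_significance(table).iloc[0] == pytest.approx(0.02)

    def test_even_count_interpolates_geometrically(self):
        table = pd.DataFrame({"a": [0.01], "b": [0.04]})
        assert combine_significance(table).iloc[0] == pytest.approx(0.02)


class TestSelection:
    def _frames(self, med_t, n_controls=3):
        idx = [f"e{i}" for i in range(len(med_t))]
        tp = pd.DataFrame({"t1": med_t, "t2": med_t}, index=idx)
        bp = pd.DataFrame(
            {f"c{k}": np.linspace(0.01, 1.0, len(med_t)) for k in range(n_controls)},
            index=idx,
        )
        return tp, bp

    def test_always_unremarkable_event_never_selected(self):
        tp, bp = self._frames([1.0] * 50)
        out = select_candidates(tp, bp, selection="percentile")
        assert not out["selected"].any()

    def test_percentile_threshold_value(self):
        tp, bp = self._frames(np.linspace(0.01, 1.0, 100).tolist())
        out = select_candidates(tp, bp, q=5.0, selection="percentile")
        assert out["threshold"].iloc[0] == pytest.approx(
            np.percentile(np.linspace(0.01, 1.0, 100), 5)
        )

    def test_fdr_rule_selects_enriched_small_p(self):
        med_t = [1e-6] * 10 + np.linspace(0.2, 1.0, 90).tolist()
        tp, bp = self._frames(med_t)
        out = select_candidates(tp, bp, selection="fdr", fdr_target=0.1)
        assert out["selected"][:10].all()

    def test_background_needs_three_controls(self):
        tp, bp = self._frames([0.5] * 20, n_controls=2)
        with pytest.raises(ValueError, match="controls"):
            select_candidates(tp, bp)


class TestRanking:
    expression = {
        "t1": {"i1": 10.0, "s1": 1.0, "i2": 2.0, "s2": 2.0},
        "c1": {"i1": 5.0, "s1": 4.0, "i2": 2.0, "s2": 2.0},
    }
    isoform_map = {"evA": (("i1",), ("s1",)), "evB": (("i2",), ("s2",))}

    def test_score_is_sum_of_class_differences(self):
        ranked = rank_candidates(
            ["evA"], self.expression, self.isoform_map, ["t1"], ["c1"]
        )
        assert ranked == [("evA", pytest.approx(8.0))]  # |10-5| + |1-4|

    def test_unmapped_event_scores_zero_and_sorts_last(self):
        ranked = rank_candidates(
            ["evX", "evA"], self.expression, self.isoform_map, ["t1"], ["c1"]
        )
        assert [e for e, _ in ranked] == ["evA", "evX"]
        assert ranked[1][1] == 0.0

    def test_input_order_does_not_matter(self):
        a = rank_candidates(
            ["evA", "evB", "evX"], self.expression, self.isoform_map, ["t1"], ["c1"]
        )
        b = rank_candidates(
            ["evX", "evB", "evA"], self.expression, self.isoform_map, ["t1"], ["c1"]
        )
        assert a == b


class TestIsoformMapping:
    def test_classes_from_middle_exon_membership(self):
        ann = [
            ExonAnnotation("g", "tin", "chr1", 1, 10, "+"),
            ExonAnnotation("g", "tin", "chr1", 201, 300, "+"),
            ExonAnnotation("g", "tin", "chr1", 401, 500, "+"),
            ExonAnnotation("g", "tskip", "chr1", 1, 10, "+"),
            ExonAnnotation("g", "tskip", "chr1", 401, 500, "+"),
        ]
        j_in, j_skip = ("chr1", 100, 200, "+"), ("chr1", 100, 400, "+")
        groups = [g for g in group_junctions_by_site([j_in, j_skip]) if len(g.members) == 2]
        (ev,) = build_events(groups, ann)
        mapping = map_isoforms([ev], ann)
        assert mapping[ev.event_id] == (("tin",), ("tskip",))


class TestIntersect:
    def test_concordant_intersection(self):
        consensus, disc = intersect_comparisons(
            {
                "cmp1": {"A": "EX", "B": "IN", "C": "EX"},
                "cmp2": {"B": "IN", "C": "EX", "D": "IN"},
            }
        )
        assert consensus == {"B": "IN", "C": "EX"} and disc == []

    def test_discordant_direction_reported_not_kept(self):
        consensus, disc = intersect_comparisons(
            {"cmp1": {"A": "EX"}, "cmp2": {"A": "IN"}}
        )
        assert consensus == {} and disc == ["A"]

    def test_single_comparison_identity(self):
        sel = {"A": "EX", "B": None}
        consensus, disc = intersect_comparisons({"only": sel})
        assert consensus == sel and disc == []
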