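import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from spliceratio.cohort import (
    ase_frequency_filter,
    cohort_association_table,
    cox_hr_binary,
    fisher_association,
    intersect_sets,
    survival_association,
)
from spliceratio.simulate import SimulationConfig, simulate_cohort


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration over fixed-margin tables."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    obs = comb(r1, a) * comb(n - r1, c1 - a)
    total = sum(
        pr
        for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        if (pr := comb(r1, x) * comb(n - r1, c1 - x)) <= obs
    )
    return total / comb(n, c1)


def _cohort_frame(occurrence_columns, n):
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                       "group": 0, "time": 1.0, "event": 1})
    for name, col in occurrence_columns.items():
        df[name] = col
    return df


class TestFrequencyFilter:
    def test_strictly_above_threshold_retained(self):
        df = _cohort_frame({"a": [1] * 3 + [0] * 37}, 40)  # 7.5%
        assert ase_frequency_filter(df) == ["a"]

    def test_boundary_frequency_excluded(self):
        df = _cohort_frame({"a": [1] * 2 + [0] * 38}, 40)  # exactly 5%
        assert ase_frequency_filter(df) == []

    def test_all_zero_column_excluded_and_empty_cohort_errors(self):
        df = _cohort_frame({"a": [0] * 10}, 10)
        assert ase_frequency_filter(df) == []
        with pytest.raises(ValueError):
            ase_frequency_filter(df.iloc[:0])


class TestFisher:
    def test_perfect_separation_table(self):
        occ = [1] * 5 + [0] * 5
        grp = [1] * 5 + [0] * 5
        res = fisher_association(occ, grp)
        assert res.fisher_p == pytest.approx(2 / 252, abs=1e-12)
        assert res.table == ((5, 0), (0, 5))

    def test_zero_margin_gives_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = fisher_association([0] * 8, [1] * 4 + [0] * 4)
        assert res.fisher_p == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 9, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            occ = [1] * a + [0] * b + [1] * c + [0] * d
            grp = [1] * (a + b) + [0] * (c + d)
            res = fisher_association(occ, grp)
            assert res.fisher_p == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )


class TestSurvival:
    def test_logrank_matches_hand_worked_risk_table(self):
        # groups A: deaths at 1, 2; B: deaths at 3, 4 (no censoring).
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36,
        # chi-square = (2 - 5/6)^2 / (17/36) = 49/17.
        res = survival_association([1, 1, 0, 0], [1, 2, 3, 4], [1, 1, 1, 1])
        assert res.logrank_statistic == pytest.approx(49 / 17, rel=1e-9)

    def test_identical_groups_are_null(self):
        time = [1.0, 2.0, 3.0, 5.0] * 2
        event = [1, 0, 1, 1] * 2
        occ = [1] * 4 + [0] * 4
        res = survival_association(occ, time, event)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-9)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)

    def test_recovers_twofold_hazard(self):
        rng = np.random.default_rng(7)
        occ = np.r_[np.ones(500, int), np.zeros(500, int)]
        time = rng.exponential(1 / np.where(occ == 1, 0.2, 0.1))
        res = survival_association(occ, time, np.ones(1000, int))
        assert 1.7 <= res.hazard_ratio <= 2.4
        assert res.ci_low < res.hazard_ratio < res.ci_high
        assert res.direction == "unfavorable"

    def test_newton_breslow_agrees_with_lifelines_on_untied_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        x = rng.integers(0, 2, 200)
        time = rng.exponential(1 / (0.1 * 1.8 ** x))
        event = (rng.random(200) < 0.8).astype(int)
        hr, _, _ = cox_hr_binary(time, event, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e"
        )
        assert math.log(hr) == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        occ = rng.integers(0, 2, 60)
        time = rng.exponential(1.0, 60) + 0.01
        event = rng.integers(0, 2, 60) | 1
        a = survival_association(occ, time, event)
        b = survival_association(occ, 2.0 * time, event)
        assert a.hazard_ratio == pytest.approx(b.hazard_ratio, rel=1e-9)
        assert a.logrank_p == pytest.approx(b.logrank_p, rel=1e-9)

    def test_eventless_group_reports_unbounded_hr(self):
        res = survival_association(
            [1, 1, 1, 0, 0, 0], [1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0]
        )
        assert res.hazard_ratio == math.inf
        assert 0 < res.logrank_p <= 1


class TestVenn:
    def test_three_set_core(self):
        regions = intersect_sets({"X": {"A", "B"}, "Y": {"B", "C"}, "Z": {"B"}})
        assert regions["core"]["members"] == ["B"]
        assert regions["X&Y&Z"]["members"] == ["B"]

    def test_disjoint_sets_have_empty_core(self):
        regions = intersect_sets({"X": {"A"}, "Y": {"B"}})
        assert regions["core"]["count"] == 0

    def test_exclusive_regions_partition_the_union(self):
        sets = {"X": {"A", "B", "D"}, "Y": {"B", "C"}, "Z": {"B", "D", "E"}}
        regions = intersect_sets(sets)
        exclusive = [
            r for label, r in regions.items() if label != "core"
        ]
        union = set().union(*sets.values())
        assert sum(r["count"] for r in exclusive) == len(union)


class TestCohortStage:
    def test_planted_association_and_hazard_are_flagged(self):
        config = SimulationConfig(cohort_size=400, seed=3)
        cohort, truth = simulate_cohort(config)
        table = cohort_association_table(cohort).set_index("ase_id")
        assert table.loc[truth.cohort_assoc, "group_associated"].all()
        assert table.loc[truth.cohort_hr, "survival_associated"].all()
        # hazard-planted ASEs are reported as unfavorable
        assert (table.loc[truth.cohort_hr, "hazard_ratio"] > 1).all()

    def test_bh_column_bounded_below_by_raw_p(self):
        cohort, _ = simulate_cohort(SimulationConfig(cohort_size=300, seed=8))
        table = cohort_association_table(cohort)
        ok = table["fisher_p"].notna()
        assert (table.loc[ok, "fisher_p_bh"] >= table.loc[ok, "fisher_p"] - 1e-15).all()
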