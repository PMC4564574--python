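"""Task scoring, behavioral filters and performance indices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pupilcc.behavior import (
    filter_rt_floor,
    filter_rt_sd,
    score_2back,
    score_switch,
    sqrt_transform,
    stroop_effect,
    subject_outliers,
    switch_cost,
)


def _trials(task, stimuli=None, conditions=None, correct=None, rt=None, block=None):
    n = (
        len(stimuli)
        if stimuli is not None
        else len(conditions or correct or rt or block)
    )
    return pd.DataFrame(
        {
            "subject_id": ["s1"] * n,
            "task": [task] * n,
            "block": block or [1] * n,
            "trial_index": range(n),
            "stimulus": stimuli or [""] * n,
            "condition": conditions or [""] * n,
            "correct": correct if correct is not None else [True] * n,
            "rt_ms": rt if rt is not None else [600.0] * n,
        }
    )


class TestScore2Back:
    def test_third_trial_matching_two_back_is_match(self):
        out = score_2back(_trials("2back", stimuli=list("ABA")))
        assert out["condition"].tolist() == ["", "", "match"]
        assert out["scorable"].tolist() == [False, False, True]

    def test_all_correct_makes_every_defined_encoding_ok(self):
        out = score_2back(_trials("2back", stimuli=list("ABCDE")))
        assert out["encoding_ok"].iloc[:3].all()
        assert out["encoding_ok"].iloc[3:].isna().all()

    def test_encoding_ok_reflects_correctness_two_later(self):
        out = score_2back(
            _trials("2back", stimuli=list("ABCDE"), correct=[True, True, False, True, True])
        )
        # trial 0 is encoded for trial 2, which was answered incorrectly
        assert out["encoding_ok"].tolist()[:3] == [False, True, True]

    def test_blocks_scored_independently(self):
        out = score_2back(_trials("2back", stimuli=list("ABABAB"), block=[1] * 3 + [2] * 3))
        # block 2 restarts: its first two trials are non-scorable
        assert out["scorable"].tolist() == [False, False, True] * 2

    def test_match_labels_equal_brute_force_scan(self, rng):
        letters = rng.choice(list("BCDFG"), size=60)
        blocks = [1] * 30 + [2] * 30
        out = score_2back(_trials("2back", stimuli=list(letters), block=blocks))
        for i, row in out.iterrows():
            j = i - 30 if row["block"] == 2 else i
            if j < 2:
                assert row["condition"] == ""
            else:
                expect = letters[i] == letters[i - 2]
                assert (row["condition"] == "match") == expect


class TestRtFilters:
    def test_floor_excludes_fast_switch_trial(self):
        out = filter_rt_floor(_trials("switch", rt=[299.0, 600.0]))
        assert out["rt_floor_excluded"].tolist() == [True, False]

    def test_exactly_300_is_kept(self):
        out = filter_rt_floor(_trials("2back", rt=[300.0]))
        assert not out["rt_floor_excluded"].iloc[0]

    def test_stroop_exempt_from_floor(self):
        out = filter_rt_floor(_trials("stroop", rt=[250.0]))
        assert not out["rt_floor_excluded"].iloc[0]

    def test_extreme_rt_flagged_in_cell(self):
        rt = [600.0] * 10 + [5000.0]
        out = filter_rt_sd(_trials("stroop", conditions=["congruent"] * 11, rt=rt))
        assert out["rt_sd_excluded"].tolist() == [False] * 10 + [True]

    def test_identical_rts_never_flagged(self):
        out = filter_rt_sd(_trials("switch", conditions=["switch"] * 6, rt=[700.0] * 6))
        assert not out["rt_sd_excluded"].any()

    def test_flags_equal_zscore_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            rt = rng.lognormal(6.5, 0.4, size=n)
            out = filter_rt_sd(_trials("stroop", conditions=["incongruent"] * n, rt=list(rt)))
            mean, sd = rt.mean(), rt.std(ddof=1)
            expect = np.abs(rt - mean) > 3 * sd if sd > 0 else np.zeros(n, bool)
            assert out["rt_sd_excluded"].tolist() == expect.tolist()

    def test_sd_trim_is_single_pass(self):
        # after removing the extreme value the next-largest would be >3 SD of
        # the remainder; a single-pass trim must not flag it
        rt = [600.0] * 20 + [980.0, 5000.0]
        out = filter_rt_sd(_trials("stroop", conditions=["congruent"] * 22, rt=rt))
        assert out["rt_sd_excluded"].sum() == 1

    def test_incorrect_trials_not_used_for_reference(self):
        rt = [600.0] * 10 + [5000.0]
        correct = [True] * 10 + [False]
        out = filter_rt_sd(
            _trials("stroop", conditions=["congruent"] * 11, rt=rt, correct=correct)
        )
        assert not out["rt_sd_excluded"].any()


class TestSubjectOutliers:
    def test_all_equal_none_flagged(self):
        flags = subject_outliers(pd.Series([3.0] * 10))
        assert not flags.any()

    def test_one_extreme_among_35_flagged(self, rng):
        values = pd.Series(np.concatenate([rng.normal(10, 1, 34), [40.0]]))
        flags = subject_outliers(values)
        assert flags.tolist() == [False] * 34 + [True]

    def test_flags_equal_zscore_enumeration(self, rng):
        values = pd.Series(rng.normal(size=50))
        flags = subject_outliers(values, k=2.0)
        z = (values - values.mean()) / values.std(ddof=1)
        assert flags.tolist() == (z.abs() > 2.0).tolist()

    def test_missing_values_ignored(self):
        values = pd.Series([1.0, np.nan, 1.1, 0.9, 1.0])
        flags = subject_outliers(values)
        assert not flags.any()


class TestSqrtTransform:
    def test_exact_values(self):
        assert sqrt_transform([0, 4]).tolist() == [0.0, 2.0]
        assert sqrt_transform([2])[0] == pytest.approx(1.41421356, abs=1e-8)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform([-1])

    def test_reduces_right_skew(self, rng):
        counts = rng.poisson(rng.lognormal(1.5, 0.8, size=500))
        before = stats.skew(counts)
        after = stats.skew(sqrt_transform(counts))
        assert before > 0
        assert after < before


class TestEffects:
    def test_stroop_effect_arithmetic(self):
        trials = _trials(
            "stroop",
            conditions=["congruent", "congruent", "incongruent", "incongruent"],
            rt=[600.0, 620.0, 700.0, 720.0],
        )
        rt_eff, err_eff = stroop_effect(trials)
        assert rt_eff == pytest.approx(100.0)
        assert err_eff == pytest.approx(0.0)

    def test_identical_distributions_zero_effect(self):
        trials = _trials(
            "stroop",
            conditions=["congruent", "incongruent"] * 4,
            rt=[650.0] * 8,
        )
        assert stroop_effect(trials) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_published_group_means_give_82ms_effect(self):
        # group-level means as printed: incongruent 705 ms, congruent 623 ms
        trials = _trials(
            "stroop", conditions=["congruent", "incongruent"], rt=[623.0, 705.0]
        )
        assert stroop_effect(trials)[0] == pytest.approx(82.0)

    def test_error_effect_uses_percentages(self):
        trials = _trials(
            "stroop",
            conditions=["congruent"] * 4 + ["incongruent"] * 4,
            correct=[True] * 4 + [False, True, True, True],
            rt=[600.0] * 8,
        )
        _, err_eff = stroop_effect(trials)
        assert err_eff == pytest.approx(25.0)

    def test_switch_labeling_from_cue_colors(self):
        colors = ["yellow", "yellow", "blue", "blue", "yellow"]
        trials = _trials(
            "switch",
            stimuli=[f"{i + 1}|{c}" for i, c in enumerate(colors)],
            block=[3] * 5,
        )
        out = score_switch(trials)
        assert out["condition"].tolist() == ["", "nonswitch", "switch", "nonswitch", "switch"]

    def test_published_group_means_give_169ms_cost(self):
        trials = score_switch(
            _trials(
                "switch",
                stimuli=["1|yellow", "2|yellow", "3|blue", "4|blue", "6|yellow"],
                rt=[900.0, 1110.0, 1279.0, 1110.0, 1279.0],
                block=[3] * 5,
            )
        )
        rt_cost, correct_cost = switch_cost(trials)
        assert rt_cost == pytest.approx(169.0)
        assert correct_cost == pytest.approx(0.0)

    def test_switch_cost_correct_rate_difference(self):
        trials = score_switch(
            _trials(
                "switch",
                stimuli=["1|yellow", "2|yellow", "3|blue", "4|blue", "6|yellow", "7|yellow"],
                correct=[True, True, False, True, True, True],
                rt=[1000.0] * 6,
                block=[3] * 6,
            )
        )
        # switch trials: idx 2 (error), idx 4 (correct) -> rate 0.5
        # non-switch trials: idx 1, 3, 5 all correct -> rate 1.0
        _, correct_cost = switch_cost(trials)
        assert correct_cost == pytest.approx(-0.5)

    def test_pure_blocks_do_not_enter_switch_cost(self):
        trials = score_switch(
            _trials(
                "switch",
                stimuli=["1|yellow"] * 4 + ["1|yellow", "2|blue", "3|blue"],
                rt=[100.0] * 4 + [1000.0, 1200.0, 1000.0],
                block=[1] * 4 + [3] * 3,
            )
        )
        rt_cost, _ = switch_cost(trials)
        assert rt_cost == pytest.approx(200.0)
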