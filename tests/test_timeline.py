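"""Relative time, Holm adjustment, Wilcoxon tests, milestone alignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from discstager import (
    EventTimes,
    ProgressionProfile,
    holm_adjust,
    milestone_alignment,
    progression_profile,
    relative_time,
    sens_vs_ac_tests,
    total_variation,
)
from discstager.simclassify import AssignmentTable
from discstager.timeline import _wilcoxon_rank_sum

from conftest import make_obs

WT = EventTimes(condition="SAM_25C", wandering_h=46.0, pupariation_h=49.0)


class TestRelativeTime:
    def test_endpoints(self):
        assert relative_time(49.0, WT, event="pupariation") == 1.0
        assert relative_time(49.0, WT) == 1.0
        assert relative_time(0.0, WT) == 0.0

    def test_wandering_uses_condition_mean(self):
        # wild type at 25C wanders at 46 of 49 h
        assert relative_time(44.0, WT, event="wandering") == pytest.approx(
            46 / 49
        )
        assert relative_time(46 / 49 * 49, WT) == pytest.approx(0.9388, abs=1e-4)

    def test_clamps_slight_overshoot_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="discstager.timeline"):
            assert relative_time(50.0, WT) == 1.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_linearity_and_order_preservation(self):
        ts = np.linspace(0, 49, 20)
        rel = [relative_time(t, WT) for t in ts]
        assert np.allclose(rel, ts / 49)
        assert all(a <= b for a, b in zip(rel, rel[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            EventTimes(condition="x", wandering_h=50.0, pupariation_h=49.0)
        with pytest.raises(ValueError):
            relative_time(-1.0, WT)


class TestHolm:
    def test_hand_computed_stepdown(self):
        assert holm_adjust([0.001, 0.02, 0.04]) == pytest.approx(
            [0.003, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == [0.3]

    def test_order_is_preserved(self):
        p = [0.04, 0.001, 0.02]
        assert holm_adjust(p) == pytest.approx([0.04, 0.003, 0.04])

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=12)
    )
    def test_never_decreases_monotone_and_capped(self, pvals):
        adj = holm_adjust(pvals)
        assert all(a >= p for a, p in zip(adj, pvals))
        assert all(0 <= a <= 1 for a in adj)
        order = np.argsort(np.asarray(pvals), kind="stable")
        sorted_adj = [adj[i] for i in order]
        assert all(a <= b for a, b in zip(sorted_adj, sorted_adj[1:]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1, allow_nan=False),
                 min_size=1, max_size=10)
    )
    def test_agrees_with_statsmodels(self, pvals):
        ours = holm_adjust(pvals)
        theirs = multipletests(pvals, method="holm")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


def permutation_oracle(x, y):
    """Exhaustive two-sided permutation p for the rank-sum statistic
    (twice the smaller one-sided tail, capped at 1)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)

    def u(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    obs = u(range(n1))
    ge = le = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        val = u(idx)
        ge += val >= obs - 1e-12
        le += val <= obs + 1e-12
    return min(1.0, 2 * min(ge, le) / total)


class TestWilcoxon:
    @pytest.mark.parametrize("trial", range(6))
    def test_small_groups_match_enumeration_oracle(self, trial):
        rng = np.random.default_rng(trial)
        x = rng.integers(2, 7, size=rng.integers(3, 8))
        y = rng.integers(2, 7, size=rng.integers(3, 8))
        _, p = _wilcoxon_rank_sum(x, y)
        # two-sided conventions differ slightly under heavy ties
        assert p == pytest.approx(permutation_oracle(x, y), abs=0.03)

    def test_all_tied_is_null(self):
        _, p = _wilcoxon_rank_sum(np.array([3, 3, 3]), np.array([3, 3]))
        assert p == 1.0

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        x = rng.integers(2, 7, size=15)
        y = rng.integers(2, 7, size=15) + 2
        stat, p = _wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert stat == ref.statistic and p == ref.pvalue


def _co_scored(condition, pairs, time_h=20.0):
    return [
        (f"{condition}_{i}", condition, time_h, "none",
         {"Ac": ac, "Sens": se})
        for i, (ac, se) in enumerate(pairs)
    ]


class TestSensVsAc:
    def test_identical_sets_show_no_significance(self):
        pairs = [(4, 4)] * 6 + [(4, 5)] * 4 + [(5, 5)] * 8 + [(5, 6)] * 2
        a = make_obs(_co_scored("a", pairs))
        b = make_obs(_co_scored("b", pairs))
        df = sens_vs_ac_tests(a, b)
        assert not df.empty
        assert not df["significant"].any()

    def test_detects_one_stage_shift_at_ac_4_and_5(self):
        # Sens one stage behind in condition b at Ac stages 4-5, n=15 per group
        rng = np.random.default_rng(3)
        base = {4: 4, 5: 5, 6: 6}
        pa, pb = [], []
        for ac in (4, 5, 6):
            for _ in range(15):
                pa.append((ac, base[ac] + int(rng.integers(0, 2))))
                shift = -1 if ac in (4, 5) else 0
                pb.append((ac, base[ac] + shift + int(rng.integers(0, 2))))
        df = sens_vs_ac_tests(
            make_obs(_co_scored("a", pa)), make_obs(_co_scored("b", pb))
        )
        flagged = set(df.loc[df["significant"], "ac_stage"])
        assert flagged == {4, 5}

    def test_small_groups_skipped_with_notice(self, caplog):
        import logging

        pairs_a = [(4, 4)] * 5 + [(5, 5)]          # Ac stage 5: n=1 in a
        pairs_b = [(4, 4)] * 5 + [(5, 5)] * 5
        with caplog.at_level(logging.INFO, logger="discstager.timeline"):
            df = sens_vs_ac_tests(
                make_obs(_co_scored("a", pairs_a)),
                make_obs(_co_scored("b", pairs_b)),
            )
        assert 5 not in set(df["ac_stage"])
        assert any("skipped" in r.message for r in caplog.records)

    def test_requires_co_scored_discs(self):
        a = make_obs([("a0", "a", 0.0, "none", {"Ac": 1})])
        b = make_obs([("b0", "b", 0.0, "none", {"Sens": 1})])
        with pytest.raises(ValueError, match="co-scored"):
            sens_vs_ac_tests(a, b)


def profile_from(rows, condition="c", stages=("A", "B", "K")):
    frame = pd.DataFrame(
        [
            {"relative_time": rt, "time_h": rt * 49, "event": ev,
             "milestone": ms, **dict(zip(stages, props))}
            for rt, ev, ms, props in rows
        ]
    )
    return ProgressionProfile(
        condition=condition, frame=frame, stage_columns=list(stages)
    )


class TestMilestoneAlignment:
    def test_identical_profiles_align_with_zero_distance(self):
        p = profile_from(
            [(0.0, "moult", "moult", (1.0, 0, 0)),
             (1.0, "pupariation", "pupariation", (0, 0, 1.0))]
        )
        v = milestone_alignment(p, p, "pupariation")
        assert v.aligned and v.tv_distance == 0.0

    def test_symmetry(self):
        pa = profile_from([(1.0, "pupariation", "pupariation", (0.1, 0.2, 0.7))])
        pb = profile_from([(1.0, "pupariation", "pupariation", (0.0, 0.4, 0.6))])
        va = milestone_alignment(pa, pb, "pupariation")
        vb = milestone_alignment(pb, pa, "pupariation")
        assert va.aligned == vb.aligned
        assert va.tv_distance == pytest.approx(vb.tv_distance)

    def test_modal_mismatch_is_never_aligned(self):
        # distributions nearly identical but different modal stage
        pa = profile_from([(1.0, "pupariation", "pupariation", (0.0, 0.49, 0.51))])
        pb = profile_from([(1.0, "pupariation", "pupariation", (0.0, 0.51, 0.49))])
        v = milestone_alignment(pa, pb, "pupariation")
        assert v.tv_distance < 0.25 and not v.aligned
        assert (v.modal_stage_a, v.modal_stage_b) == ("K", "B")

    def test_missing_milestone_raises(self):
        p = profile_from([(0.5, "none", "", (0.5, 0.5, 0.0))])
        with pytest.raises(KeyError):
            milestone_alignment(p, p, "moult")

    def test_unknown_milestone_rejected(self):
        p = profile_from([(0.0, "moult", "moult", (1.0, 0, 0))])
        with pytest.raises(ValueError):
            milestone_alignment(p, p, "eclosion")

    def test_relative_time_matching_uses_nearest_row(self):
        pa = profile_from(
            [(0.4, "none", "", (1.0, 0, 0)), (0.6, "none", "", (0, 1.0, 0))]
        )
        pb = profile_from([(0.62, "none", "", (0, 1.0, 0))])
        v = milestone_alignment(pa, pb, 0.58)
        assert v.aligned and v.modal_stage_a == v.modal_stage_b == "B"


def test_total_variation_bounds():
    p = pd.Series({"A": 1.0})
    q = pd.Series({"K": 1.0})
    assert total_variation(p, q) == 1.0
    assert total_variation(p, p) == 0.0


class TestProgressionProfile:
    def _table(self, rows, condition="c"):
        frame = pd.DataFrame.from_dict(
            {k: v for k, v in rows}, orient="index",
            columns=["A", "B", "K"],
        )
        frame.index = pd.MultiIndex.from_tuples(
            frame.index, names=["time_h", "event"]
        )
        return AssignmentTable(condition=condition, frame=frame)

    def test_rows_sorted_and_milestones_flagged(self):
        table = self._table(
            [((46.0, "wandering"), [0, 1.0, 0]),
             ((0.0, "moult"), [1.0, 0, 0]),
             ((20.0, "none"), [0.5, 0.5, 0]),
             ((49.0, "pupariation"), [0, 0, 1.0])]
        )
        prof = progression_profile(table, WT)
        assert list(prof.frame["relative_time"]) == sorted(
            prof.frame["relative_time"]
        )
        assert prof.frame["relative_time"].iloc[-1] == 1.0
        assert list(prof.frame["milestone"]) == [
            "moult", "", "wandering", "pupariation",
        ]

    def test_wandering_flagged_even_at_shared_clock_time(self):
        # a numbered 46 h sample and wandering discs share the clock time
        table = self._table(
            [((46.0, "none"), [0, 1.0, 0]),
             ((46.0, "wandering"), [0, 0.9, 0.1])]
        )
        prof = progression_profile(table, WT)
        assert set(prof.frame["milestone"]) == {"", "wandering"}
        w = prof.milestone_row("wandering")
        assert w["K"] == 0.1
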