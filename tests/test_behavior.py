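"""Consistency filter, Cohen's kappa, and behavioral summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arithmeeg.behavior import (
    cohen_kappa,
    consistency_filter,
    summarize_accuracy,
    summarize_rt,
)
from arithmeeg.synthdata import REFERENCE_STRATEGY_CROSSTAB

from helpers import LARGE, SMALL, make_trial as _trial, trials_from_crosstab as _trials_from_crosstab


class TestConsistencyFilter:
    def test_reference_crosstab_counts(self):
        trials = _trials_from_crosstab(REFERENCE_STRATEGY_CROSSTAB)
        retained, table, excluded = consistency_filter(trials)
        assert len(trials) == 2480
        assert len(retained) == 2156
        assert len(excluded) == 324
        assert table.n_unknown == 32
        assert np.array_equal(table.counts, REFERENCE_STRATEGY_CROSSTAB)

    def test_fully_consistent_reports_nothing_excluded(self):
        trials = [_trial(SMALL, "retrieve"), _trial(LARGE, "procedure")]
        retained, _, excluded = consistency_filter(trials)
        assert len(retained) == 2 and not excluded

    def test_unknown_report_excluded_with_reason(self):
        retained, _, excluded = consistency_filter([_trial(SMALL, "unknown")])
        assert not retained
        assert excluded[0][1] == "unknown"

    def test_conservation_and_idempotence(self):
        trials = _trials_from_crosstab(REFERENCE_STRATEGY_CROSSTAB)
        retained, _, excluded = consistency_filter(trials)
        assert len(retained) + len(excluded) == len(trials)
        retained2, _, excluded2 = consistency_filter(retained)
        assert retained2 == retained and not excluded2


class TestCohenKappa:
    def test_reference_agreement_table(self):
        p_o, kappa = cohen_kappa([[1080, 144], [148, 1076]])
        assert p_o == pytest.approx(2156 / 2448)
        assert round(p_o, 2) == 0.88
        assert round(kappa, 2) == 0.76

    def test_perfect_agreement(self):
        _, kappa = cohen_kappa([[50, 0], [0, 70]])
        assert kappa == pytest.approx(1.0)

    def test_chance_agreement(self):
        _, kappa = cohen_kappa([[50, 50], [50, 50]])
        assert kappa == pytest.approx(0.0)

    def test_degenerate_marginals_undefined(self):
        _, kappa = cohen_kappa([[8, 0], [0, 0]])
        assert np.isnan(kappa)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([[0, 0], [0, 0]])

    @given(
        st.lists(st.integers(min_value=0, max_value=200), min_size=4, max_size=4)
    )
    @settings(max_examples=50, deadline=None)
    def test_label_swap_invariance_and_sklearn_agreement(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        table = np.array([[a, b], [c, d]])
        p_o, kappa = cohen_kappa(table)
        p_o2, kappa2 = cohen_kappa(table[::-1, ::-1])  # swap both labelings
        assert p_o2 == pytest.approx(p_o)
        if np.isnan(kappa):
            assert np.isnan(kappa2)
            return
        assert kappa2 == pytest.approx(kappa)
        # independent oracle: sklearn on the expanded label vectors
        from sklearn.metrics import cohen_kappa_score

        y1 = [0] * (a + b) + [1] * (c + d)
        y2 = [0] * a + [1] * b + [0] * c + [1] * d
        if len(set(y1)) > 1 or len(set(y2)) > 1:
            assert kappa == pytest.approx(cohen_kappa_score(y1, y2), abs=1e-12)

    def test_kappa_one_iff_offdiagonal_zero(self):
        assert cohen_kappa([[3, 0], [0, 5]])[1] == pytest.approx(1.0)
        assert cohen_kappa([[3, 1], [0, 5]])[1] < 1.0


class TestAccuracySummary:
    def test_all_correct(self):
        trials = [
            _trial(SMALL, "retrieve", participant=p, correct=True)
            for p in ("p01", "p02")
        ]
        out = summarize_accuracy(trials)
        assert out["mean"].iloc[0] == pytest.approx(1.0)
        assert out["sd"].iloc[0] == pytest.approx(0.0)

    def test_proportion_contribution(self):
        trials = [
            _trial(SMALL, "retrieve", correct=i >= 2) for i in range(20)
        ]  # 18/20 correct
        out = summarize_accuracy(trials)
        assert out["mean"].iloc[0] == pytest.approx(0.90)

    def test_missing_participant_condition_warns(self):
        trials = [
            _trial(SMALL, "retrieve", participant="p01"),
            _trial(SMALL, "retrieve", participant="p02"),
            _trial(LARGE, "procedure", participant="p01"),
        ]
        with pytest.warns(UserWarning, match="participants contribute"):
            summarize_accuracy(trials)


class TestRtSummary:
    def test_single_trial_all_statistics_equal(self):
        out = summarize_rt([_trial(SMALL, "retrieve", rt=2.0)])
        row = out.iloc[0]
        for col in ("min", "q1", "median", "mean", "q3", "max"):
            assert row[col] == pytest.approx(2.0)

    def test_median_robust_mean_not(self):
        trials = [_trial(SMALL, "retrieve", rt=r) for r in (1, 2, 3, 4, 100)]
        row = summarize_rt(trials).iloc[0]
        assert row["median"] == pytest.approx(3.0)
        assert row["mean"] == pytest.approx(22.0)

    def test_quartile_convention_linear_interpolation(self):
        trials = [_trial(SMALL, "retrieve", rt=r) for r in (1, 2, 3, 4)]
        row = summarize_rt(trials).iloc[0]
        # linear interpolation: q1 = 1 + 0.75*(2-1), q3 = 3 + 0.25*(4-3)
        assert row["q1"] == pytest.approx(1.75)
        assert row["q3"] == pytest.approx(3.25)

    def test_quantile_ordering_invariant(self, rng):
        trials = [
            _trial(SMALL, "retrieve", rt=float(r))
            for r in rng.lognormal(0.5, 0.8, size=200)
        ]
        row = summarize_rt(trials).iloc[0]
        assert (
            row["min"] <= row["q1"] <= row["median"] <= row["q3"] <= row["max"]
        )
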