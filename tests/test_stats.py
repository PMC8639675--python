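"""Mixed-effects models: effect recovery, degenerate inputs, post-hocs."""

import numpy as np
import pandas as pd
import pytest

from arithmeeg.stats import (
    fit_accuracy_model,
    fit_erders_model,
    fit_rt_model,
    pairwise_posthoc,
)
from arithmeeg.synthdata import (
    STRATEGIES,
    SimulationConfig,
    generate_behavior,
    simulate_null_erders,
)

OPERATIONS = ("subtraction", "multiplication")
CONDITIONS = [(s, o) for s in STRATEGIES for o in OPERATIONS]


def _behavior_frame(cfg, n_participants, n_per_cell, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        for cond in CONDITIONS:
            for _ in range(n_per_cell):
                rt, correct, _ = generate_behavior(cond, cfg, rng)
                rows.append(
                    {
                        "participant": f"p{i:02d}",
                        "strategy": cond[0],
                        "operation": cond[1],
                        "rt": rt,
                        "correct": correct,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def behavior_31():
    return _behavior_frame(SimulationConfig(), 31, 20, seed=77)


class TestRtModel:
    def test_configured_effects_detected(self, behavior_31):
        effects, fitted = fit_rt_model(behavior_31[behavior_31.correct])
        p = effects.set_index("term")["p"]
        assert p["strategy"] < 0.001
        assert p["strategy x operation"] < 0.001
        assert fitted.kind == "ig_glmm"
        assert (effects["stat_kind"] == "chi2").all()

    def test_effect_direction_matches_generator(self, behavior_31):
        _, fitted = fit_rt_model(behavior_31[behavior_31.correct])
        _, emm = pairwise_posthoc(fitted, ["strategy"])
        emm = emm.set_index("strategy")["emmean"]
        assert emm["procedure"] > emm["retrieve"]

    def test_single_condition_rejected(self, behavior_31):
        sub = behavior_31[
            (behavior_31.strategy == "retrieve")
            & (behavior_31.operation == "subtraction")
        ]
        with pytest.raises(ValueError):
            fit_rt_model(sub)

    def test_nonpositive_rt_rejected(self, behavior_31):
        df = behavior_31.copy()
        df.loc[df.index[0], "rt"] = -1.0
        with pytest.raises(ValueError):
            fit_rt_model(df)


class TestAccuracyModel:
    def test_strategy_gap_detected(self, behavior_31):
        effects, _ = fit_accuracy_model(behavior_31)
        p = effects.set_index("term")["p"]
        assert p["strategy"] < 0.01

    def test_complete_separation_flagged(self):
        df = _behavior_frame(
            SimulationConfig(acc_probs={c: 1.0 for c in CONDITIONS}), 5, 10, seed=3
        )
        with pytest.warns(UserWarning, match="separation"):
            _, fitted = fit_accuracy_model(df)
        assert any("separation" in w for w in fitted.extra["warnings"])


class TestErdersModel:
    def test_full_factorial_structure(self, rng):
        records = simulate_null_erders(31, rng)
        effects, fitted = fit_erders_model(records)
        assert len(effects) == 15  # all terms up to the four-way interaction
        assert len(fitted.data) == 31 * 32  # full factorial per band
        assert (effects["df2"] == 930).all()
        assert (effects["stat_kind"] == "F").all()

    def test_injected_strategy_effect_detected(self, rng):
        records = simulate_null_erders(31, rng)
        records.loc[records.strategy == "retrieve", "value"] += 20.0
        effects, fitted = fit_erders_model(records)
        p = effects.set_index("term")["p"]
        assert p["strategy"] < 0.001
        _, emm = pairwise_posthoc(fitted, ["strategy"])
        emm = emm.set_index("strategy")["emmean"]
        assert emm["retrieve"] - emm["procedure"] == pytest.approx(20.0, abs=3.0)

    def test_single_band_required(self, rng):
        records = pd.concat(
            [
                simulate_null_erders(4, rng, band="theta"),
                simulate_null_erders(4, rng, band="lower_alpha"),
            ]
        )
        with pytest.raises(ValueError, match="single band"):
            fit_erders_model(records)


class TestPosthoc:
    @pytest.fixture(scope="class")
    def lmm_fit(self):
        records = simulate_null_erders(12, np.random.default_rng(5))
        _, fitted = fit_erders_model(records)
        return fitted

    def test_contrast_count_is_c_k_2(self, lmm_fit):
        con4, emm4 = pairwise_posthoc(lmm_fit, ["strategy", "operation"])
        assert len(emm4) == 4 and len(con4) == 6
        con16, emm16 = pairwise_posthoc(lmm_fit, ["strategy", "roi", "hemisphere"])
        assert len(emm16) == 16 and len(con16) == 120

    def test_tukey_never_below_unadjusted(self, lmm_fit):
        con, _ = pairwise_posthoc(lmm_fit, ["strategy", "roi", "hemisphere"])
        assert (con["p_tukey"] >= con["p_unadjusted"] - 1e-12).all()

    def test_confidence_intervals_bracket_estimates(self, lmm_fit):
        _, emm = pairwise_posthoc(lmm_fit, ["roi"])
        assert ((emm["ci_low"] < emm["emmean"]) & (emm["emmean"] < emm["ci_high"])).all()

    def test_unknown_factor_rejected(self, lmm_fit):
        with pytest.raises(ValueError, match="not in model"):
            pairwise_posthoc(lmm_fit, ["band"])
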