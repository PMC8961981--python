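"""Adherence labelling, propensity weighting, scenario grid, RCT harness."""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest

from dmtrank import (
    EvaluationError,
    RCTArmSpec,
    compare_with_rct,
    label_adherence,
    propensity_weights,
    run_scenarios,
    scenario_table,
    weighted_outcome_model,
)
from dmtrank.evaluation import PS_COVARIATES, _smd, rank_sets


class TestSMD:
    def test_unweighted_hand_oracle(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        treated = np.array([True, True, False, False])
        # means 0.5 vs 2.5; pooled SD sqrt((0.25 + 0.25)/2) = 0.5
        assert _smd(df, treated, None)["x"] == pytest.approx(-4.0)

    def test_weights_shift_the_means(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        treated = np.array([True, True, False, False])
        w = np.array([1.0, 3.0, 3.0, 1.0])
        # weighted means 0.75 vs 0.25; pooled SD 0.5
        assert _smd(df, treated, w)["x"] == pytest.approx(1.0)

    def test_constant_column_yields_zero(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        treated = np.array([True, False, True, False])
        assert _smd(df, treated, None)["x"] == 0.0


@pytest.fixture(scope="module")
def confounded_label(sampled_table):
    """Deterministic covariate-driven group label with noise."""
    rng = np.random.default_rng(8)
    score = np.array(
        [0.5 * r.predictors.edss + 0.6 * r.predictors.relapses_last_12m
         for r in sampled_table]
    )
    return (score + rng.normal(0, 1.0, len(score))) > np.median(score)


class TestPropensityWeights:
    def test_balances_covariates(self, sampled_table, confounded_label):
        wr = propensity_weights(sampled_table, confounded_label)
        assert wr.max_smd_after < wr.max_smd_before
        assert np.all(wr.weights > 0)
        assert np.all((wr.propensity > 0) & (wr.propensity < 1))
        assert set(wr.smd_before) == set(wr.smd_after)

    def test_hajek_means_near_one_per_group(self, sampled_table, confounded_label):
        wr = propensity_weights(sampled_table, confounded_label)
        f = np.asarray(confounded_label, bool)
        # normalization happens pre-trimming; percentile clipping can move
        # the post-trim mean a few percent
        assert wr.weights[f].mean() == pytest.approx(1.0, abs=0.1)
        assert wr.weights[~f].mean() == pytest.approx(1.0, abs=0.1)

    def test_single_group_rejected(self, sampled_table):
        with pytest.raises(EvaluationError):
            propensity_weights(sampled_table, np.ones(len(sampled_table), bool))
        with pytest.raises(EvaluationError):
            propensity_weights(sampled_table, np.zeros(len(sampled_table), bool))

    def test_only_ate_estimand(self, sampled_table, confounded_label):
        with pytest.raises(EvaluationError, match="ATE"):
            propensity_weights(sampled_table, confounded_label, estimand="ATT")


class TestWeightedOutcomeModel:
    def _with_counts(self, rows, followed, low, high):
        out = []
        for r, f in zip(rows, followed):
            out.append(dataclasses.replace(r, relapse_count=low if f else high))
        return out

    def test_relapse_slope_sign(self, sampled_table):
        followed = np.arange(len(sampled_table)) % 2 == 0
        rows = self._with_counts(sampled_table, followed, 0, 2)
        res = weighted_outcome_model(
            rows, np.ones(len(rows)), followed, "relapse", scenario="top1"
        )
        assert res.slope_coefficient < 0  # followed group has fewer relapses
        assert res.p_value < 1e-6
        assert res.group_outcome_rate["followed_arr"] < res.group_outcome_rate["other_arr"]
        assert not res.degenerate

    def test_cdp_slope_sign(self, sampled_table):
        rng = np.random.default_rng(3)
        followed = np.arange(len(sampled_table)) % 2 == 0
        rows = [
            dataclasses.replace(r, cdp_event=bool(rng.random() < (0.05 if f else 0.4)))
            for r, f in zip(sampled_table, followed)
        ]
        res = weighted_outcome_model(
            rows, np.ones(len(rows)), followed, "cdp", scenario="top1"
        )
        assert res.slope_coefficient < 0
        assert res.p_value < 1e-4

    def test_degenerate_outcome_reported_not_crashed(self, sampled_table):
        followed = np.arange(len(sampled_table)) % 2 == 0
        rows = self._with_counts(sampled_table, followed, 0, 0)
        res = weighted_outcome_model(rows, np.ones(len(rows)), followed, "relapse")
        assert res.degenerate
        assert res.slope_coefficient is None and res.p_value is None

    def test_invalid_weights_rejected(self, sampled_table):
        followed = np.arange(len(sampled_table)) % 2 == 0
        w = np.ones(len(sampled_table))
        w[0] = 0.0
        with pytest.raises(EvaluationError, match="weights"):
            weighted_outcome_model(sampled_table, w, followed, "relapse")


class TestAdherenceLabels:
    def test_rank_set_sizes_and_nesting(self, relapse_fit, sampled_table):
        sub = sampled_table[:60]
        top1 = rank_sets(relapse_fit, sub, "top1", max_draws=100)
        top2 = rank_sets(relapse_fit, sub, "top2", max_draws=100)
        bottom2 = rank_sets(relapse_fit, sub, "bottom2", max_draws=100)
        for s1, s2, b2 in zip(top1, top2, bottom2):
            assert len(s1) == 1 and len(s2) == 2 and len(b2) == 2
            assert s1 <= s2
            assert not (s2 & b2)  # catalogue has 6 DMTs

    def test_labels_match_rank_sets(self, relapse_fit, sampled_table):
        sub = sampled_table[:60]
        labels = label_adherence(sub, relapse_fit, "top2", max_draws=100)
        sets = rank_sets(relapse_fit, sub, "top2", max_draws=100)
        expect = [r.assigned_dmt in s for r, s in zip(sub, sets)]
        assert labels.tolist() == expect

    def test_labels_deterministic(self, relapse_fit, sampled_table):
        a = label_adherence(sampled_table[:60], relapse_fit, "top1", max_draws=100)
        b = label_adherence(sampled_table[:60], relapse_fit, "top1", max_draws=100)
        assert a.tolist() == b.tolist()


@pytest.fixture(scope="module")
def results(sampled_table, relapse_fit, cdp_fit):
    return run_scenarios(sampled_table, relapse_fit, cdp_fit, max_draws=100)


class TestScenarioGrid:
    def test_full_grid(self, results):
        cells = {(r.scenario, r.outcome) for r in results}
        assert cells == {
            (s, o) for s in ("top1", "top2", "bottom2") for o in ("relapse", "cdp")
        }

    def test_balance_achieved_per_cell(self, results):
        for r in results:
            assert r.max_smd_after <= r.max_smd_before + 1e-9
            assert r.n_followed + r.n_other == results[0].n_followed + results[0].n_other

    def test_table_rendering(self, results):
        df = scenario_table(results)
        assert len(df) == 6
        assert {"scenario", "model", "slope_coefficient", "p_value"} <= set(df.columns)


class TestRCTHarness:
    def _arm(self, **kw):
        base = dict(
            trial="TRIAL-1",
            dmt_id="fingolimod",
            outcome="relapse",
            duration_months=24.0,
            published_event_free=0.70,
            filters={"edss": (0.0, 5.5), "relapses_last_12m": (1.0, 99.0)},
        )
        base.update(kw)
        return RCTArmSpec(**base)

    def test_comparison_basics(self, relapse_fit, sampled_table):
        cmp = compare_with_rct(sampled_table, relapse_fit, self._arm())
        assert 0 < cmp.n_cohort < len(sampled_table)  # filters bind
        assert 0.0 < cmp.predicted_mean < 1.0
        lo, hi = cmp.predicted_ci90
        assert lo <= cmp.predicted_mean <= hi
        assert cmp.difference == pytest.approx(cmp.predicted_mean - 0.70)
        assert cmp.flagged == (abs(cmp.difference) >= 0.10)
        assert "age" in cmp.baseline and "sd" in cmp.baseline["age"]

    def test_outcome_mismatch_rejected(self, cdp_fit, sampled_table):
        with pytest.raises(EvaluationError, match="outcome"):
            compare_with_rct(sampled_table, cdp_fit, self._arm())

    def test_empty_cohort_names_binding_filter(self, relapse_fit, sampled_table):
        arm = self._arm(filters={"age": (90.0, 99.0), "edss": (0.0, 9.0)})
        with pytest.raises(EvaluationError, match="age"):
            compare_with_rct(sampled_table, relapse_fit, arm)

    def test_list_from_json_roundtrip(self, tmp_path):
        payload = [
            {
                "trial": "TRIAL-1",
                "dmt_id": "natalizumab",
                "outcome": "cdp",
                "duration_months": 24,
                "published_event_free": 0.83,
                "published_ci90": [0.80, 0.86],
                "filters": {"edss": [0, 5.5]},
            }
        ]
        path = tmp_path / "arms.json"
        path.write_text(json.dumps(payload))
        arms = RCTArmSpec.list_from_json(path)
        assert len(arms) == 1
        assert arms[0].dmt_id == "natalizumab"
        assert arms[0].published_ci90 == (0.80, 0.86)
        assert arms[0].filters == {"edss": (0.0, 5.5)}
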