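"""Bayes-inverted occult-risk predictions and prevalence summaries."""

import itertools

import numpy as np
import pytest

import lyspread as ly
from lyspread.risk import RiskError

from conftest import naive_transition_matrix, random_params

CT = ly.MODALITIES["CT"]


def _scenario(lnl_names, involved=()):
    return {v: (1 if v in involved else 0) for v in lnl_names}


class TestPosteriorStateDistribution:
    def test_perfect_modality_collapses_to_diagnosis(self, toy_graph, toy_params):
        post = ly.posterior_state_distribution(
            toy_graph, toy_params, {"A": 1, "B": 0}, "early", ly.PERFECT_MODALITY
        )
        expect = np.zeros(4)
        expect[ly.StateSpace(("A", "B")).index_of((1, 0))] = 1.0
        np.testing.assert_allclose(post, expect, atol=1e-14)

    def test_sums_to_one(self, winning, ref_params):
        rng = np.random.default_rng(2)
        ss = ly.StateSpace(winning.lnl_names)
        for _ in range(20):
            p = random_params(winning, rng)
            diag = {v: int(rng.integers(2)) for v in winning.lnl_names}
            post = ly.posterior_state_distribution(winning, p, diag, "late", CT, ss)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_bayes_rule_enumeration(self, toy_graph, toy_params):
        """Exhaustive Bayes-rule evaluation on the two-level toy."""
        mod = ly.Modality("toy", sensitivity=0.8, specificity=0.9)
        ss = ly.StateSpace(("A", "B"))
        prior = ly.state_distribution(toy_graph, toy_params, "late", ss)
        diag = {"A": 1, "B": 0}
        num = np.zeros(4)
        for k, state in enumerate(itertools.product([0, 1], repeat=2)):
            lik = 1.0
            for v, name in enumerate(("A", "B")):
                z, x = diag[name], state[v]
                if x == 1:
                    lik *= mod.sensitivity if z == 1 else 1 - mod.sensitivity
                else:
                    lik *= 1 - mod.specificity if z == 1 else mod.specificity
            num[k] = lik * prior[k]
        expect = num / num.sum()
        got = ly.posterior_state_distribution(toy_graph, toy_params, diag, "late", mod, ss)
        np.testing.assert_allclose(got, expect, atol=1e-13)

    def test_impossible_diagnosis_raises(self, toy_graph):
        p = ly.ModelParams(b={"A": 0.0, "B": 0.3}, t={("A", "B"): 0.2}, p_late=0.4)
        with pytest.raises(RiskError):
            ly.posterior_state_distribution(
                toy_graph, p, {"A": 1, "B": 0}, "early", ly.PERFECT_MODALITY
            )


class TestMarginalRisk:
    def test_all_ignore_pattern_gives_one(self, toy_graph, toy_params):
        ss = ly.StateSpace(("A", "B"))
        post = ly.posterior_state_distribution(
            toy_graph, toy_params, {"A": 1, "B": 0}, "early", CT, ss
        )
        assert ly.marginal_risk(post, {}, ss) == pytest.approx(1.0)

    def test_published_level_ii_cn0_risk(self, winning, ref_params):
        """Early-T cN0 microscopic level II risk ~31.13%."""
        risk = ly.occult_risk(
            winning, ref_params, "II", _scenario(winning.lnl_names), "early", CT
        )
        assert 100 * risk == pytest.approx(31.13, abs=0.1)

    def test_published_level_iv_risks_given_ii_iii(self, winning, ref_params):
        diag = _scenario(winning.lnl_names, ("II", "III"))
        early = ly.occult_risk(winning, ref_params, "IV", diag, "early", CT)
        late = ly.occult_risk(winning, ref_params, "IV", diag, "late", CT)
        assert 100 * early == pytest.approx(3.0, abs=1.0)
        assert 100 * late == pytest.approx(5.0, abs=1.0)

    def test_risk_monotone_in_evidence_severity(self, winning, ref_params):
        """Occult III risk is higher given clinical II involvement than cN0."""
        for tcat in ("early", "late"):
            cn0 = ly.occult_risk(
                winning, ref_params, "III", _scenario(winning.lnl_names), tcat, CT
            )
            ii = ly.occult_risk(
                winning, ref_params, "III",
                _scenario(winning.lnl_names, ("II",)), tcat, CT,
            )
            assert ii > cn0

    def test_late_risk_at_least_early(self, winning, ref_params):
        scenarios = [(), ("II",), ("II", "III"), ("II", "III", "IV")]
        for involved in scenarios:
            diag = _scenario(winning.lnl_names, involved)
            for level in winning.lnl_names:
                if level in involved:
                    continue
                early = ly.occult_risk(winning, ref_params, level, diag, "early", CT)
                late = ly.occult_risk(winning, ref_params, level, diag, "late", CT)
                assert late >= early - 1e-12

    def test_abstract_bounds(self, winning, ref_params):
        """IV risk <= 5% with III clinically negative; V <= 5% outside the
        extensive advanced-T scenario."""
        names = winning.lnl_names
        for tcat in ("early", "late"):
            for involved in [(), ("II",)]:
                risk = ly.occult_risk(
                    winning, ref_params, "IV", _scenario(names, involved), tcat, CT
                )
                assert risk <= 0.05
        v_scenarios = [
            (tcat, inv)
            for tcat in ("early", "late")
            for inv in [(), ("II",), ("II", "III")]
        ] + [("early", ("II", "III", "IV"))]
        for tcat, involved in v_scenarios:
            risk = ly.occult_risk(
                winning, ref_params, "V", _scenario(names, involved), tcat, CT
            )
            assert risk <= 0.05


class TestPredictedPrevalence:
    def test_no_spread_zero_prevalence(self, winning):
        p = ly.ModelParams(
            b={v: 0.0 for v in winning.lnl_names},
            t={a: 0.0 for a in winning.lnl_arcs},
            p_late=0.5,
        )
        assert ly.predicted_prevalence(winning, p, {"II": 1}, "late") == 0.0

    def test_matches_empirical_frequency(self, toy_graph, toy_params):
        n = 200_000
        cohort = ly.simulate_cohort(toy_graph, toy_params, n, fraction_late=1.0, seed=13)
        for pattern in ({"A": 1, "B": 1}, {"A": 1, "B": None}, {"A": 0, "B": 1}):
            pred = ly.predicted_prevalence(toy_graph, toy_params, pattern, "late")
            count, total = cohort.counts("consensus", pattern)
            se = np.sqrt(pred * (1 - pred) / total)
            assert count / total == pytest.approx(pred, abs=3 * se)


class TestRiskOverSamples:
    def test_constant_samples_zero_std(self, winning, ref_params):
        theta = np.tile(ref_params.to_vector(winning), (50, 1))
        res = ly.risk_over_samples(
            winning, theta, _scenario(winning.lnl_names), "early", CT,
            pattern={"II": 1}, subsample_fraction=0.5,
        )
        assert res.std == pytest.approx(0.0, abs=1e-15)
        assert res.mean == pytest.approx(0.3113, abs=0.001)

    def test_subsampling_consistency(self, winning, ref_params):
        rng = np.random.default_rng(8)
        theta = np.clip(
            ref_params.to_vector(winning) + 0.02 * rng.standard_normal((400, 11)),
            0.001, 0.999,
        )
        diag = _scenario(winning.lnl_names)
        full = ly.risk_over_samples(
            winning, theta, diag, "early", CT, pattern={"II": 1},
            subsample_fraction=1.0,
        )
        half = ly.risk_over_samples(
            winning, theta, diag, "early", CT, pattern={"II": 1},
            subsample_fraction=0.5, seed=4,
        )
        assert half.mean == pytest.approx(full.mean, abs=3 * full.std / np.sqrt(200))


class TestBetaPrevalence:
    def test_published_fig_counts(self):
        post = ly.beta_posterior_prevalence(100, 423)
        assert post.alpha == 101 and post.beta == 324
        assert post.mode == pytest.approx(100 / 423, abs=1e-12)

    def test_empty_data_gives_uniform(self):
        post = ly.beta_posterior_prevalence(0, 0)
        assert (post.alpha, post.beta) == (1.0, 1.0)

    def test_symmetric_mode(self):
        assert ly.beta_posterior_prevalence(5, 10).mode == pytest.approx(0.5)
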