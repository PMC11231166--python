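"""Diagnose-time priors, observation model and cohort likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lyspread as ly
from lyspread.likelihood import DataError, observation_weights

from conftest import naive_diagnosis_prob, random_params


class TestBinomialTimePrior:
    def test_mean(self):
        prior = ly.binomial_time_prior(0.3, 10)
        assert prior.mean == pytest.approx(3.0, abs=1e-12)

    def test_degenerate(self):
        prior = ly.binomial_time_prior(0.0, 10)
        np.testing.assert_array_equal(prior.pmf, np.eye(11)[0])

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_normalized(self, p):
        assert ly.binomial_time_prior(p, 10).pmf.sum() == pytest.approx(1.0, abs=1e-12)


class TestObservationMatrix:
    def test_perfect_is_identity(self):
        ss = ly.enumerate_states(3)
        B = ly.build_observation_matrix(ly.MODALITIES["pathology"], ss).B
        np.testing.assert_array_equal(B, np.eye(8))

    def test_single_level_ct(self):
        ss = ly.enumerate_states(1)
        ct = ly.MODALITIES["CT"]
        B = ly.build_observation_matrix(ct, ss).B
        np.testing.assert_allclose(B, [[0.76, 0.24], [0.19, 0.81]], atol=1e-12)

    def test_rows_sum_to_one(self):
        ss = ly.StateSpace(("I", "II", "III", "IV", "V", "VII"))
        for mod in ly.MODALITIES.values():
            B = ly.build_observation_matrix(mod, ss).B
            np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


class TestStateDistribution:
    def test_no_spread_stays_healthy(self, winning):
        p = ly.ModelParams(
            b={v: 0.0 for v in winning.lnl_names},
            t={a: 0.0 for a in winning.lnl_arcs},
            p_late=0.5,
        )
        dist = ly.state_distribution(winning, p, "late")
        assert dist[0] == 1.0 and dist[1:].sum() == 0.0

    def test_single_level_closed_form(self):
        g = ly.SpreadGraph(("A",), ())
        p = ly.ModelParams(b={"A": 0.25}, t={}, p_late=0.37, t_max=10)
        prior = ly.binomial_time_prior(p.p_late, p.t_max)
        dist = ly.state_distribution(g, p, "late")
        expect = sum(
            prior.pmf[t] * (1 - (1 - 0.25) ** t) for t in range(p.t_max + 1)
        )
        assert dist[1] == pytest.approx(expect, abs=1e-12)

    def test_level_ii_marginal_near_published_prevalence(self, winning, ref_params):
        """Advanced-T marginal involvement of level II is about 79%."""
        ss = ly.StateSpace(winning.lnl_names)
        dist = ly.state_distribution(winning, ref_params, "late", ss)
        marginal = dist[ss.involvement_mask("II")].sum()
        assert marginal == pytest.approx(0.79, abs=0.01)

    def test_stochastic_dominance_late_over_early(self, winning):
        """p_late > p_early implies higher involvement of every level."""
        rng = np.random.default_rng(11)
        ss = ly.StateSpace(winning.lnl_names)
        for _ in range(20):
            p = random_params(winning, rng)
            if p.p_late <= p.p_early:
                continue
            de = ly.state_distribution(winning, p, "early", ss)
            dl = ly.state_distribution(winning, p, "late", ss)
            for v in winning.lnl_names:
                mask = ss.involvement_mask(v)
                assert dl[mask].sum() >= de[mask].sum() - 1e-12


class TestDiagnosisLikelihoods:
    def test_perfect_modality_equals_state_distribution(self, toy_graph, toy_params):
        dist = ly.state_distribution(toy_graph, toy_params, "early")
        ell = ly.diagnosis_likelihoods(
            toy_graph, toy_params, ly.PERFECT_MODALITY, "early"
        )
        np.testing.assert_allclose(ell, dist, atol=1e-14)

    def test_normalization_random_draws(self, winning):
        rng = np.random.default_rng(5)
        ss = ly.StateSpace(winning.lnl_names)
        ct = ly.MODALITIES["CT"]
        for _ in range(200):
            p = random_params(winning, rng)
            ell = ly.diagnosis_likelihoods(winning, p, ct, "late", ss)
            assert ell.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_level_closed_form(self):
        g = ly.SpreadGraph(("A",), ())
        p = ly.ModelParams(b={"A": 0.3}, t={}, p_late=0.6, t_max=5)
        mod = ly.Modality("toy", sensitivity=0.8, specificity=0.9)
        prior = ly.binomial_time_prior(0.6, 5)
        expect = sum(
            prior.pmf[t]
            * ((1 - (1 - 0.3) ** t) * 0.8 + (1 - 0.3) ** t * (1 - 0.9))
            for t in range(6)
        )
        ell = ly.diagnosis_likelihoods(g, p, mod, "late")
        assert ell[1] == pytest.approx(expect, abs=1e-12)


def _cohort_of(patterns, lnl_names, modality="consensus"):
    records = [
        ly.PatientRecord(str(i), tcat, {modality: dict(pat)})
        for i, (tcat, pat) in enumerate(patterns)
    ]
    return ly.Cohort(records, tuple(lnl_names))


class TestCohortLogLikelihood:
    def test_all_unknown_contributes_zero(self, toy_graph, toy_params):
        cohort = _cohort_of([("early", {"A": None, "B": None})], ("A", "B"))
        ll = ly.cohort_log_likelihood(toy_graph, toy_params, cohort)
        assert ll == pytest.approx(0.0, abs=1e-14)

    def test_empty_cohort_is_zero(self, toy_graph, toy_params):
        cohort = ly.Cohort([], ("A", "B"))
        assert ly.cohort_log_likelihood(toy_graph, toy_params, cohort) == 0.0

    def test_additivity(self, toy_graph, toy_params):
        p1 = ("early", {"A": 1, "B": 0})
        p2 = ("late", {"A": 0, "B": None})
        both = ly.cohort_log_likelihood(
            toy_graph, toy_params, _cohort_of([p1, p2], ("A", "B"))
        )
        sep = sum(
            ly.cohort_log_likelihood(toy_graph, toy_params, _cohort_of([p], ("A", "B")))
            for p in (p1, p2)
        )
        assert both == pytest.approx(sep, abs=1e-12)

    @pytest.mark.parametrize(
        "pattern",
        [{"A": 1, "B": 0}, {"A": 0, "B": 0}, {"A": None, "B": 1}, {"A": 1, "B": None}],
    )
    @pytest.mark.parametrize("tcat", ["early", "late"])
    def test_matches_exhaustive_enumeration(self, toy_graph, toy_params, pattern, tcat):
        """Path/completion/time enumeration oracle on the two-level chain."""
        mod = ly.Modality("toy", sensitivity=0.8, specificity=0.9)
        cohort = _cohort_of([(tcat, pattern)], ("A", "B"), modality="toy")
        got = ly.cohort_log_likelihood(toy_graph, toy_params, cohort, mod)
        expect = np.log(
            naive_diagnosis_prob(toy_graph, toy_params, pattern, tcat, mod)
        )
        assert got == pytest.approx(expect, abs=1e-10)

    def test_marginalization_equals_sum_over_completions(self, winning, ref_params):
        ss = ly.StateSpace(winning.lnl_names)
        ell = ly.diagnosis_likelihoods(winning, ref_params, ly.MODALITIES["CT"], "late", ss)
        # marginal probability of (II=1, VII unknown, rest 0)
        pattern = {"I": 0, "II": 1, "III": 0, "IV": 0, "V": 0}
        w = observation_weights(ss, pattern, ly.MODALITIES["CT"])
        dist = ly.state_distribution(winning, ref_params, "late", ss)
        marginal = w @ dist
        total = 0.0
        for vii in (0, 1):
            idx = ss.index_of((0, 1, 0, 0, 0, vii))
            total += ell[idx]
        assert marginal == pytest.approx(total, abs=1e-12)

    def test_all_healthy_likelihood_decreasing_in_b(self, winning):
        rng = np.random.default_rng(17)
        cohort = _cohort_of(
            [("early", {v: 0 for v in winning.lnl_names})], winning.lnl_names
        )
        for _ in range(5):
            p = random_params(winning, rng)
            base = ly.cohort_log_likelihood(winning, p, cohort)
            for v in winning.lnl_names:
                bumped = ly.ModelParams(
                    b={**p.b, v: min(1.0, p.b[v] + 0.05)},
                    t=dict(p.t),
                    p_late=p.p_late,
                    t_max=p.t_max,
                )
                assert ly.cohort_log_likelihood(winning, bumped, cohort) < base

    def test_zero_probability_returns_neg_inf(self, toy_graph):
        # b_A = 0 makes an isolated-A diagnosis impossible under perfect obs.
        p = ly.ModelParams(b={"A": 0.0, "B": 0.5}, t={("A", "B"): 0.2}, p_late=0.4)
        cohort = _cohort_of([("early", {"A": 1, "B": 0})], ("A", "B"))
        assert ly.cohort_log_likelihood(toy_graph, p, cohort) == -np.inf

    def test_level_mismatch_raises(self, toy_graph, toy_params):
        cohort = _cohort_of([("early", {"X": 1, "Y": 0})], ("X", "Y"))
        with pytest.raises(DataError):
            ly.cohort_log_likelihood(toy_graph, toy_params, cohort)
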