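"""Odds-likelihood propagation: primitives, invariants, oracle equivalence.

The oracle used here is an independent hand-rolled recursion over the
*formula list* (not the staged graph): per consequent it applies the odds
update / interpolation formulas directly, with min/max collapse written
out in plain arithmetic.  Engine and oracle must agree exactly.
"""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbfin import (EvidenceState, QuantifyConfig, assign_poi_params, assign_symptom_params,
                   build_net, combine_conjunction, combine_disjunction, explain,
                   parse_formula, posterior_odds, posterior_prob_certain,
                   posterior_prob_uncertain, prior_odds, propagate, quantify_record)
from hbfin.errors import DomainError, InferenceError
from hbfin.inference_engine import replay_entry
from helpers import POI_PRIOR, oracle_posteriors, run_engine


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

class TestPrimitives:
    def test_even_odds(self):
        assert prior_odds(0.5) == pytest.approx(1.0)

    def test_indifference_prior_odds(self):
        assert prior_odds(0.02) == pytest.approx(0.02 / 0.98)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_certain_prior_rejected(self, p):
        with pytest.raises(DomainError):
            prior_odds(p)

    def test_likelihood_product(self):
        assert posterior_odds(1.0, [2.0, 3.0]) == pytest.approx(6.0)
        assert posterior_odds(0.7, []) == 0.7
        assert posterior_odds(prior_odds(0.02), [200.0]) == pytest.approx(4.0816, abs=1e-4)

    def test_negative_likelihood_rejected(self):
        with pytest.raises(DomainError):
            posterior_odds(1.0, [-0.5])

    def test_posterior_probability(self):
        assert posterior_prob_certain(1.0) == pytest.approx(0.5)
        assert posterior_prob_certain(0.0) == 0.0
        assert posterior_prob_certain(4.081632653) == pytest.approx(0.803213, abs=1e-6)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(1e-9, 1 - 1e-9))
    def test_odds_probability_round_trip(self, p):
        assert posterior_prob_certain(prior_odds(p)) == pytest.approx(p, abs=1e-12)

    def test_min_max_combination(self):
        assert combine_conjunction([0.3, 0.7]) == 0.3
        assert combine_disjunction([0.3, 0.7]) == 0.7
        assert combine_conjunction([0.42]) == 0.42
        with pytest.raises(DomainError):
            combine_conjunction([])
        with pytest.raises(DomainError):
            combine_disjunction([])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_conjunction_never_exceeds_disjunction(self, probs):
        assert combine_conjunction(probs) <= combine_disjunction(probs)


class TestInterpolation:
    def test_prior_at_baseline(self):
        assert posterior_prob_uncertain(0.02, 0.8, 0.0002, 0.2, 0.2) == pytest.approx(0.02)

    def test_upper_endpoint_is_certain_posterior(self):
        assert posterior_prob_uncertain(0.02, 0.8, 0.0002, 0.2, 1.0) == pytest.approx(0.8)

    def test_lower_endpoint_is_disconfirmed_posterior(self):
        assert posterior_prob_uncertain(0.02, 0.8, 0.0002, 0.2, 0.0) == pytest.approx(0.0002)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(DomainError):
            posterior_prob_uncertain(0.02, 0.8, 0.0002, 0.0, 0.5)
        with pytest.raises(DomainError):
            posterior_prob_uncertain(0.02, 0.8, 0.0002, 1.0, 0.5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(0.05, 0.95))
    def test_branches_agree_at_baseline(self, px):
        at = posterior_prob_uncertain(0.02, 0.8, 0.0002, px, px)
        just_below = posterior_prob_uncertain(0.02, 0.8, 0.0002, px, px - 1e-9)
        just_above = posterior_prob_uncertain(0.02, 0.8, 0.0002, px, px + 1e-9)
        assert at == pytest.approx(0.02)
        assert just_below == pytest.approx(at, abs=1e-6)
        assert just_above == pytest.approx(at, abs=1e-6)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_evidence_belief(self, e1, e2):
        lo, hi = sorted((e1, e2))
        p_lo = posterior_prob_uncertain(0.02, 0.8, 0.0002, 0.2, lo)
        p_hi = posterior_prob_uncertain(0.02, 0.8, 0.0002, 0.2, hi)
        assert p_lo <= p_hi + 1e-12

    def test_monotone_in_sufficiency(self):
        posts = [
            posterior_prob_certain(posterior_odds(prior_odds(0.02), [ls]))
            for ls in (1, 10, 100, 1000)
        ]
        assert posts == sorted(posts)


# ---------------------------------------------------------------------------
# staged propagation
# ---------------------------------------------------------------------------

TWO_STAGE = [
    parse_formula("forall p. S1a(p) & S2a(p) -> M1(p)"),
    parse_formula("forall p. S3a(p) -> M2(p)"),
    parse_formula("forall p. S4a(p) & M1(p) & M2(p) -> TOP(p)"),
]

DISJUNCTIVE = [
    parse_formula("forall p. S1a(p) | S2a(p) -> D(p)"),
    parse_formula("forall p. S3a(p) -> ALT(p)"),
    parse_formula("forall p. S4a(p) -> ALT(p)"),
]


class TestPropagation:
    def test_all_unknown_retains_priors(self, net, table):
        from hbfin import PatientRecord

        evidence = quantify_record(net, PatientRecord(), table=table)
        result = propagate(net, evidence)
        assert all(p == POI_PRIOR for p in result.posteriors.values())
        assert all(e.branch == "prior_retained" for e in result.trace.values())

    def test_worked_record_confirms_hypertension(self, net, table, worked_record):
        result = propagate(net, quantify_record(net, worked_record, table=table))
        expected = posterior_prob_certain(posterior_odds(prior_odds(0.02), [200.0]))
        assert result.posteriors["HT"] == pytest.approx(expected)
        assert result.posteriors["HT"] == pytest.approx(0.803213, abs=1e-6)
        assert result.posteriors["HT"] > POI_PRIOR
        assert result.ranking[0] == "HT"

    def test_certain_false_conjunction_applies_node_necessity(self):
        # one antecedent known false, sibling unknown: the collapsed
        # evidence is certainly false and the node's LN applies
        grades = {"S1a": 0.0, "S2a": None}
        result = run_engine([parse_formula("forall p. S1a(p) & S2a(p) -> H(p)")], grades)
        expected = posterior_prob_certain(posterior_odds(prior_odds(0.02), [0.01]))
        assert result.posteriors["H"] == pytest.approx(expected)
        assert expected == pytest.approx(0.000204, abs=1e-6)

    def test_lone_symptom_uses_rule_likelihoods(self):
        result = run_engine([parse_formula("forall p. S1a(p) -> H(p)")], {"S1a": 1.0})
        # Rule 1 at full grade: LS = 100
        expected = posterior_prob_certain(posterior_odds(prior_odds(0.02), [100.0]))
        assert result.posteriors["H"] == pytest.approx(expected)

    def test_inert_with_unit_likelihoods(self):
        net = build_net(TWO_STAGE)
        for h in net.hypothesis_nodes:
            net.set_params(h, POI_PRIOR, 1.0, 1.0)
        for grades in itertools.product([0.0, 0.4, 1.0], repeat=2):
            evidence = {}
            for node, g in zip(sorted(net.symptom_nodes), (*grades, 0.5, 0.5)):
                evidence[node] = EvidenceState(
                    node=node, grade=g, probability=g, status="uncertain" if 0 < g < 1
                    else ("certain_true" if g == 1 else "certain_false"), prior=0.2)
            result = propagate(net, evidence)
            assert all(p == pytest.approx(POI_PRIOR) for p in result.posteriors.values())

    def test_unquantified_net_rejected(self):
        net = build_net([parse_formula("forall p. S1a(p) -> H(p)")])
        with pytest.raises(InferenceError, match="not quantified"):
            propagate(net, {"S1a": assign_symptom_params(1.0, node="S1a")})

    @pytest.mark.parametrize("formulas", [TWO_STAGE, DISJUNCTIVE])
    def test_oracle_equivalence_certain_evidence(self, formulas):
        symptoms = sorted({l.name for f in formulas for l in f.antecedents if l.kind == "symptom"})
        for bits in itertools.product([0.0, 1.0], repeat=len(symptoms)):
            grades = dict(zip(symptoms, bits))
            result = run_engine(formulas, grades)
            expected = oracle_posteriors(formulas, grades)
            for h, p in expected.items():
                assert result.posteriors[h] == pytest.approx(p, abs=1e-12), (h, grades)

    @pytest.mark.parametrize("formulas", [TWO_STAGE, DISJUNCTIVE])
    def test_oracle_equivalence_uncertain_evidence(self, formulas):
        symptoms = sorted({l.name for f in formulas for l in f.antecedents if l.kind == "symptom"})
        levels = [None, 0.0, 0.1, 0.35, 0.8, 1.0]
        for combo in itertools.product(levels, repeat=len(symptoms)):
            grades = dict(zip(symptoms, combo))
            result = run_engine(formulas, grades)
            expected = oracle_posteriors(formulas, grades)
            for h, p in expected.items():
                assert result.posteriors[h] == pytest.approx(p, abs=1e-12), (h, grades)

    def test_posterior_monotone_in_collapsed_evidence(self):
        formulas = [parse_formula("forall p. S1a(p) & S2a(p) -> H(p)")]
        posts = [run_engine(formulas, {"S1a": g, "S2a": 1.0}).posteriors["H"]
                 for g in (0.0, 0.1, 0.2, 0.5, 0.8, 1.0)]
        assert all(b >= a - 1e-12 for a, b in zip(posts, posts[1:]))


class TestTrace:
    def test_replay_reproduces_posteriors_exactly(self, net, table, worked_record):
        result = propagate(net, quantify_record(net, worked_record, table=table))
        for hyp, entry in result.trace.items():
            assert replay_entry(entry) == result.posteriors[hyp]

    def test_explain_walks_down_to_symptoms(self, net, table, worked_record):
        result = propagate(net, quantify_record(net, worked_record, table=table))
        text = explain(result, "HT")
        for fragment in ("HT", "SPa", "DPa", "MAPa", "MDPa", "prior 0.02", "LS=200"):
            assert fragment in text

    def test_explain_recurses_through_intermediates(self, net, table, worked_record):
        result = propagate(net, quantify_record(net, worked_record, table=table))
        text = explain(result, "HPT")
        assert "Low_BV" in text and "BVa" in text

    def test_prior_retained_trace_is_minimal(self, net, table):
        from hbfin import PatientRecord

        result = propagate(net, quantify_record(net, PatientRecord(), table=table))
        text = explain(result, "HT")
        assert "prior retained" in text

    def test_unknown_hypothesis_rejected(self, net, table, worked_record):
        result = propagate(net, quantify_record(net, worked_record, table=table))
        with pytest.raises(InferenceError, match="Hx"):
            explain(result, "Hx")
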