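"""Decision-tree stage: classification, adaptation, and stroke linkage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teecea.decision_tree import (
    TestPerformance,
    adaptation_probs,
    classify,
    concentrated_embolic_policy,
    outcome_for_strategy,
    proportional_stroke_policy,
    simulate_classification,
    stroke_and_death_probs,
)
from teecea.mortality import stratify_mortality
from teecea.params import Subgroup

TEE = TestPerformance(0.97, 0.80)
MP = TestPerformance(0.31, 0.98)


class TestClassify:
    def test_joint_cells_are_products(self):
        cls = classify(0.10, TEE)
        assert cls.p_tp == pytest.approx(0.097)
        assert cls.p_fp == pytest.approx(0.18)
        assert cls.p_fn == pytest.approx(0.003)
        assert cls.p_tn == pytest.approx(0.72)

    def test_zero_prevalence_has_no_diseased_cells(self):
        cls = classify(0.0, TEE)
        assert cls.p_tp == cls.p_fn == 0.0

    def test_perfect_test(self):
        cls = classify(0.3, TestPerformance(1.0, 1.0))
        assert cls.p_tp == pytest.approx(0.3)
        assert cls.p_tn == pytest.approx(0.7)

    @given(
        prevalence=st.floats(0, 1),
        sens=st.floats(0, 1),
        spec=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=100)
    def test_cells_sum_to_one_and_partition_prevalence(self, prevalence, sens, spec):
        cls = classify(prevalence, TestPerformance(sens, spec))
        assert abs(cls.p_tp + cls.p_fn + cls.p_fp + cls.p_tn - 1) < 1e-12
        assert abs(cls.p_tp + cls.p_fn - prevalence) < 1e-12


class TestAdaptation:
    @pytest.mark.parametrize(
        "prevalence,perf,expected_major_pct",
        [
            (0.10, TEE, 0.26),
            (0.20, TEE, 0.52),
            (0.10, MP, 0.08),
        ],
    )
    def test_major_adaptation_cells(self, prevalence, perf, expected_major_pct):
        adapt = adaptation_probs(classify(prevalence, perf), 0.027)
        assert round(100 * adapt.p_major_adapt, 2) == expected_major_pct

    def test_minor_adaptation_complements_major_among_detected(self):
        adapt = adaptation_probs(classify(0.10, MP), 0.027)
        assert adapt.p_minor_true == pytest.approx(0.10 * 0.31 * 0.973)
        assert adapt.p_minor_fp == pytest.approx(0.90 * 0.02)

    def test_zero_prevalence_means_no_true_adaptations(self):
        adapt = adaptation_probs(classify(0.0, TEE), 0.027)
        assert adapt.p_minor_true == adapt.p_major_adapt == 0.0
        assert adapt.p_minor_fp == pytest.approx(0.20)


def _subgroup(prevalence=0.20, m=0.0161, sex="male", age=65):
    return Subgroup(sex=sex, age_at_surgery=age, prevalence=prevalence, euroscore_avg_mortality=m)


def _enumeration_oracle(subgroup, em, cls, params):
    """Brute-force total stroke risk: explicit sum over the four
    classification cells, each with its stratum risk and adaptation rule."""
    k = params.p_death_is_stroke / (1.0 - params.p_stroke_nonfatal)
    total = 0.0
    for cell, weight in (("tp", cls.p_tp), ("fn", cls.p_fn), ("fp", cls.p_fp), ("tn", cls.p_tn)):
        diseased = cell in ("tp", "fn")
        m_i = em.m_athero if diseased else em.m_no_athero
        t_i = m_i * k
        embolic = params.p_stroke_embolic * t_i
        nonembolic = (1.0 - params.p_stroke_embolic) * t_i
        if cell == "tp":  # adapted, embolic portion reduced
            embolic *= params.rr_adaptation
        total += weight * (embolic + nonembolic)
    return total


class TestStrokeLinkage:
    def test_matches_enumeration_oracle(self, params, arteriopathy_or):
        sg = _subgroup()
        em = stratify_mortality(sg.euroscore_avg_mortality, sg.prevalence, arteriopathy_or)
        cls = classify(sg.prevalence, MP)
        out = stroke_and_death_probs(sg, em, cls, params)
        expected = _enumeration_oracle(sg, em, cls, params)
        assert abs(out.p_stroke_total - expected) < 1e-12

    def test_outcomes_sum_to_one(self, params, arteriopathy_or):
        for perf in (TEE, MP):
            sg = _subgroup()
            em = stratify_mortality(sg.euroscore_avg_mortality, sg.prevalence, arteriopathy_or)
            out = stroke_and_death_probs(sg, em, classify(sg.prevalence, perf), params)
            total = (
                out.p_stroke_nonfatal
                + out.p_stroke_fatal
                + out.p_death_other
                + out.p_no_complication
            )
            assert abs(total - 1.0) < 1e-12

    def test_unit_relative_risk_equalizes_strategies(self, params, arteriopathy_or):
        neutral = params.replace(rr_adaptation=1.0)
        sg = _subgroup()
        em = stratify_mortality(sg.euroscore_avg_mortality, sg.prevalence, arteriopathy_or)
        out_tee = stroke_and_death_probs(sg, em, classify(sg.prevalence, TEE), neutral)
        out_mp = stroke_and_death_probs(sg, em, classify(sg.prevalence, MP), neutral)
        assert out_tee.p_stroke_total == pytest.approx(out_mp.p_stroke_total, abs=1e-15)

    def test_blind_tests_are_equivalent_regardless_of_effect(self, params, arteriopathy_or):
        sg = _subgroup()
        em = stratify_mortality(sg.euroscore_avg_mortality, sg.prevalence, arteriopathy_or)
        blind_a = classify(sg.prevalence, TestPerformance(0.0, 0.80))
        blind_b = classify(sg.prevalence, TestPerformance(0.0, 0.98))
        out_a = stroke_and_death_probs(sg, em, blind_a, params)
        out_b = stroke_and_death_probs(sg, em, blind_b, params)
        assert out_a.p_stroke_total == pytest.approx(out_b.p_stroke_total, abs=1e-15)

    def test_stroke_risk_decreases_with_sensitivity(self, params, arteriopathy_or):
        sg = _subgroup()
        em = stratify_mortality(sg.euroscore_avg_mortality, sg.prevalence, arteriopathy_or)
        risks = [
            stroke_and_death_probs(
                sg, em, classify(sg.prevalence, TestPerformance(s, 0.9)), params
            ).p_stroke_total
            for s in (0.0, 0.3, 0.6, 0.9)
        ]
        assert risks == sorted(risks, reverse=True)
        assert risks[0] > risks[-1]

    def test_stroke_risk_increases_with_prevalence(self, params, arteriopathy_or):
        # hold the per-stratum mortalities fixed and let only the mix vary,
        # so a larger atherosclerosis fraction must mean more strokes
        from teecea.mortality import EarlyMortality, _or_transform

        m_no = 0.012
        m_ath = _or_transform(m_no, arteriopathy_or)
        risks = []
        for prev in (0.1, 0.2, 0.4):
            m_avg = (1 - prev) * m_no + prev * m_ath
            em = EarlyMortality(m_avg, m_no, m_ath, arteriopathy_or)
            sg = _subgroup(prevalence=prev, m=m_avg)
            risks.append(
                stroke_and_death_probs(sg, em, classify(prev, MP), params).p_stroke_total
            )
        assert risks == sorted(risks)
        assert risks[0] < risks[-1]

    def test_concentrated_policy_preserves_unadapted_cohort_total(
        self, params, arteriopathy_or
    ):
        sg = _subgroup()
        em = stratify_mortality(sg.euroscore_avg_mortality, sg.prevalence, arteriopathy_or)
        blind = classify(sg.prevalence, TestPerformance(0.0, 1.0))
        k = params.p_death_is_stroke / (1.0 - params.p_stroke_nonfatal)
        out = stroke_and_death_probs(sg, em, blind, params, policy=concentrated_embolic_policy)
        assert out.p_stroke_total == pytest.approx(em.m_avg * k, abs=1e-14)

    def test_concentrated_policy_yields_larger_strategy_contrast(
        self, params, arteriopathy_or
    ):
        sg = _subgroup()
        deltas = {}
        for policy in (proportional_stroke_policy, concentrated_embolic_policy):
            tee = outcome_for_strategy(sg, params, "tee", arteriopathy_or, policy)
            mp = outcome_for_strategy(sg, params, "mp", arteriopathy_or, policy)
            deltas[policy.__name__] = mp.p_stroke_total - tee.p_stroke_total
        assert deltas["concentrated_embolic_policy"] > deltas["proportional_stroke_policy"] > 0


class TestMicrosimulation:
    def test_counts_partition_the_cohort(self):
        rng = np.random.default_rng(3)
        res = simulate_classification(5000, 0.2, MP, 0.027, rng)
        assert res.n_tp + res.n_fn + res.n_fp + res.n_tn == 5000
        assert res.n_major + res.n_minor_true == res.n_tp

    def test_minor_adaptation_fraction_within_monte_carlo_error(self):
        rng = np.random.default_rng(42)
        res = simulate_classification(10_000, 0.10, MP, 0.027, rng)
        expected = 0.10 * 0.31 * 0.973
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(res.frac_minor_true - expected) < 3 * se

    def test_seeded_runs_are_reproducible(self):
        a = simulate_classification(1000, 0.2, TEE, 0.027, np.random.default_rng(5))
        b = simulate_classification(1000, 0.2, TEE, 0.027, np.random.default_rng(5))
        assert a == b
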