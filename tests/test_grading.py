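import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

from diaflow import (CriterionStatus, DiastolicGrade, GradingError,
                     default_cutoffs, diagnose, evaluate_diagnosis_criteria,
                     grade_dysfunction, grade_subject, grade_subject_detailed)
from diaflow.core import ModalityMeasurements

from conftest import make_record

POS = CriterionStatus.POSITIVE
NEG = CriterionStatus.NEGATIVE
UNAVAIL = CriterionStatus.UNAVAILABLE


def echo_m(**kw):
    base = dict(ef=60.0, lavi=30.0, e_peak=80.0, a_peak=72.0,
                e_prime_septal=10.0, e_prime_lateral=13.0, tr_peak=2.0)
    base.update(kw)
    return ModalityMeasurements(**base)


def flow_m(**kw):
    base = dict(ef=65.0, lavi=40.0, e_peak=80.0, a_peak=72.0,
                e_prime_septal=10.0, e_prime_lateral=13.0, t_vortex=5.0)
    base.update(kw)
    return ModalityMeasurements(**base)


class TestDiagnosisCriteria:
    def test_all_negative_case(self, echo_cutoffs):
        # E/e' = 80/((8+11)/2) = 8.4, septal 8, lateral 11, TR 2.0, LAVI 30
        m = echo_m(e_prime_septal=8.0, e_prime_lateral=11.0)
        crit = evaluate_diagnosis_criteria(m, echo_cutoffs)
        assert all(s is NEG for s in crit.values())

    def test_undetectable_tr_is_unavailable_not_negative(self, echo_cutoffs):
        # E/e' = 90/6 = 15 > 14, septal e' = 6 < 7, TR absent, LAVI 30
        m = echo_m(e_peak=90.0, e_prime_septal=6.0, e_prime_lateral=None,
                   tr_peak=None)
        crit = evaluate_diagnosis_criteria(m, echo_cutoffs)
        assert crit["avg_E_over_eprime"] is POS
        assert crit["reduced_eprime"] is POS
        assert crit["elevated_pa_pressure"] is UNAVAIL
        assert crit["enlarged_la"] is NEG

    def test_tvortex_above_surrogate_cutoff_is_positive(self, flow_cutoffs):
        crit = evaluate_diagnosis_criteria(flow_m(t_vortex=20.0), flow_cutoffs)
        assert crit["elevated_pa_pressure"] is POS

    def test_reduced_eprime_triggers_on_either_site(self, echo_cutoffs):
        septal = echo_m(e_prime_septal=6.9, e_prime_lateral=13.0)
        lateral = echo_m(e_prime_septal=10.0, e_prime_lateral=9.9)
        assert evaluate_diagnosis_criteria(septal, echo_cutoffs)[
            "reduced_eprime"] is POS
        assert evaluate_diagnosis_criteria(lateral, echo_cutoffs)[
            "reduced_eprime"] is POS

    def test_missing_both_eprimes_raises(self, echo_cutoffs):
        m = echo_m(e_prime_septal=None, e_prime_lateral=None)
        with pytest.raises(GradingError):
            evaluate_diagnosis_criteria(m, echo_cutoffs)


class TestDiagnose:
    @pytest.mark.parametrize("statuses,expected", [
        ([NEG, NEG, NEG, NEG], "normal"),            # unanimous negative
        ([POS, POS, NEG, NEG], "indeterminate"),     # exactly half
        ([POS, POS, POS, NEG], "dysfunction"),       # majority
        ([POS, POS, NEG, UNAVAIL], "dysfunction"),   # 2 of 3 available
        ([POS, NEG, UNAVAIL, UNAVAIL], "indeterminate"),
        ([NEG, NEG, POS, UNAVAIL], "normal"),
    ])
    def test_majority_over_available(self, statuses, expected):
        names = ("avg_E_over_eprime", "reduced_eprime",
                 "elevated_pa_pressure", "enlarged_la")
        assert diagnose(dict(zip(names, statuses))).value == expected

    def test_fewer_than_two_available_raises(self):
        crit = {"a": POS, "b": UNAVAIL, "c": UNAVAIL, "d": UNAVAIL}
        with pytest.raises(GradingError):
            diagnose(crit)

    def test_criterion_order_invariance(self):
        names = ("avg_E_over_eprime", "reduced_eprime",
                 "elevated_pa_pressure", "enlarged_la")
        statuses = [POS, NEG, POS, UNAVAIL]
        base = diagnose(dict(zip(names, statuses)))
        import itertools
        for perm in itertools.permutations(range(4)):
            d = dict((names[i], statuses[i]) for i in perm)
            assert diagnose(d) == base


class TestGradeDysfunction:
    def test_impaired_relaxation_branch(self, echo_cutoffs):
        m = echo_m(e_peak=45.0, a_peak=45.0 / 0.7)  # E/A = 0.7, E = 45
        assert grade_dysfunction(m, echo_cutoffs) is DiastolicGrade.GRADE1

    def test_restrictive_branch(self, echo_cutoffs):
        m = echo_m(e_peak=100.0, a_peak=40.0)  # E/A = 2.5
        assert grade_dysfunction(m, echo_cutoffs) is DiastolicGrade.GRADE3

    def test_three_criterion_majority_gives_grade2(self, flow_cutoffs):
        # E/A = 1.2, E/e' = 16, t_vortex = 20, LAVI = 50: all 3 positive
        m = flow_m(e_peak=96.0, a_peak=80.0, e_prime_septal=6.0,
                   e_prime_lateral=6.0, t_vortex=20.0, lavi=50.0)
        assert grade_dysfunction(m, flow_cutoffs) is DiastolicGrade.GRADE2

    def test_split_with_unavailable_is_indeterminate(self, echo_cutoffs):
        # E/A = 1.0, E/e' = 15 (positive), LAVI 30 (negative), TR absent
        m = echo_m(e_peak=90.0, a_peak=90.0, e_prime_septal=6.0,
                   e_prime_lateral=6.0, tr_peak=None)
        assert grade_dysfunction(m, echo_cutoffs) is DiastolicGrade.INDETERMINATE

    def test_low_ea_with_high_e_proceeds_to_criteria(self, echo_cutoffs):
        # E/A <= 0.8 but E > 50 cm/s: not the impaired-relaxation shortcut
        m = echo_m(e_peak=60.0, a_peak=80.0, e_prime_septal=6.0,
                   e_prime_lateral=6.0, lavi=50.0, tr_peak=3.2)
        assert grade_dysfunction(m, echo_cutoffs) is DiastolicGrade.GRADE2

    def test_undefined_ea_raises(self, echo_cutoffs):
        with pytest.raises(GradingError):
            grade_dysfunction(echo_m(a_peak=None), echo_cutoffs)


class TestGradeSubject:
    def test_normal_path(self, flow_cutoffs):
        r = make_record(flow={"ef": 62.0, "lavi": 40.0, "t_vortex": 3.0})
        assert grade_subject(r, "flow4d", flow_cutoffs) is DiastolicGrade.NORMAL

    def test_depressed_ef_routes_directly_to_grading(self, flow_cutoffs):
        r = make_record(flow={"ef": 41.0, "e_peak": 100.0, "a_peak": 40.0})
        assert grade_subject(r, "flow4d", flow_cutoffs) is DiastolicGrade.GRADE3
        assert grade_subject_detailed(r, "flow4d", flow_cutoffs).route == \
            "depressed_ef"

    def test_myocardial_disease_routes_directly(self, echo_cutoffs):
        r = make_record(disease=True,
                        echo={"ef": 55.0, "e_peak": 45.0, "a_peak": 45.0 / 0.7})
        assert grade_subject(r, "echo", echo_cutoffs) is DiastolicGrade.GRADE1
        assert grade_subject_detailed(r, "echo", echo_cutoffs).route == \
            "myocardial_disease"

    def test_dysfunction_via_diagnosis_gets_at_least_grade1(self, echo_cutoffs):
        # 3 of 4 diagnosis criteria positive, but the 3-criterion grading
        # block splits 1 vs 1 with TR available... construct an even split:
        # E/e' positive, PA negative, LA positive -> grade2; instead make
        # E/e' positive, PA negative, LA negative -> >=2 negative grade1;
        # the bump matters when grading yields indeterminate, which needs
        # an unavailable criterion - impossible here with TR present. So
        # check the composition result is a dysfunction grade, never
        # normal/indeterminate.
        r = make_record(echo={"ef": 60.0, "e_peak": 90.0, "a_peak": 75.0,
                              "e_prime_septal": 5.0, "e_prime_lateral": 6.0,
                              "lavi": 40.0, "tr_peak": 2.0})
        g = grade_subject(r, "echo", echo_cutoffs)
        assert g >= DiastolicGrade.GRADE1

    def test_determinism(self, default_cohort, echo_cutoffs):
        grades1 = [grade_subject(r, "echo", echo_cutoffs) for r in default_cohort]
        grades2 = [grade_subject(r, "echo", echo_cutoffs) for r in default_cohort]
        assert grades1 == grades2


class TestBoundarySharpness:
    """Values exactly at a cutoff sit on the non-positive side; an epsilon
    across the cutoff flips exactly that criterion."""

    EPS = 1e-6

    @pytest.mark.parametrize("field,cutoff,positive_above", [
        ("e_over_eprime", 14.0, True),
        ("lavi", 34.0, True),
        ("tr", 2.8, True),
        ("septal", 7.0, False),
        ("lateral", 10.0, False),
    ])
    def test_diagnosis_cutoff_flip(self, echo_cutoffs, field, cutoff,
                                   positive_above):
        def build(value):
            kw = {}
            if field == "e_over_eprime":
                kw = dict(e_peak=value * 10.0, e_prime_septal=10.0,
                          e_prime_lateral=10.0)
            elif field == "lavi":
                kw = dict(lavi=value)
            elif field == "tr":
                kw = dict(tr_peak=value)
            elif field == "septal":
                kw = dict(e_prime_septal=value, e_prime_lateral=13.0)
            elif field == "lateral":
                kw = dict(e_prime_septal=10.0, e_prime_lateral=value)
            return echo_m(**kw)

        name = {"e_over_eprime": "avg_E_over_eprime", "lavi": "enlarged_la",
                "tr": "elevated_pa_pressure", "septal": "reduced_eprime",
                "lateral": "reduced_eprime"}[field]
        at = evaluate_diagnosis_criteria(build(cutoff), echo_cutoffs)
        assert at[name] is NEG  # strict inequality: the tie is non-positive
        flipped_value = cutoff + self.EPS if positive_above else cutoff - self.EPS
        across = evaluate_diagnosis_criteria(build(flipped_value), echo_cutoffs)
        assert across[name] is POS
        # only the intended criterion changed
        changed = [k for k in at if at[k] is not across[k]]
        assert changed == [name]

    def test_ea_boundaries(self, echo_cutoffs):
        # E/A exactly 0.8 with E <= 50 -> grade1 (<=); just above enters
        # the criterion block; E/A exactly 2.0 -> grade3 (>=)
        # at E/A = 0.8 exactly the shortcut wins even with positive criteria
        m_low = echo_m(e_peak=40.0, a_peak=50.0, lavi=50.0,
                       e_prime_septal=5.0, tr_peak=3.2)
        assert grade_dysfunction(m_low, echo_cutoffs) is DiastolicGrade.GRADE1
        # an epsilon above 0.8 enters the criterion block -> grade2 here
        m_mid = echo_m(e_peak=40.0, a_peak=50.0 - 1e-6, lavi=50.0,
                       e_prime_septal=5.0, e_prime_lateral=5.0, tr_peak=3.2)
        assert grade_dysfunction(m_mid, echo_cutoffs) is DiastolicGrade.GRADE2
        m_exact2 = echo_m(e_peak=100.0, a_peak=50.0)  # E/A = 2.0
        assert grade_dysfunction(m_exact2, echo_cutoffs) is DiastolicGrade.GRADE3

    def test_ef_routing_boundary(self, echo_cutoffs):
        at = make_record(echo={"ef": 50.0})
        below = make_record(echo={"ef": 50.0 - 1e-9, "e_peak": 45.0,
                                  "a_peak": 45.0 / 0.7})
        assert grade_subject_detailed(at, "echo", echo_cutoffs).route == \
            "diagnosis"
        assert grade_subject_detailed(below, "echo", echo_cutoffs).route == \
            "depressed_ef"


FINITE = dict(allow_nan=False, allow_infinity=False)


class TestCompleteness:
    @given(
        ef=st.floats(1.0, 90.0, **FINITE),
        lavi=st.floats(5.0, 120.0, **FINITE),
        e=st.floats(10.0, 200.0, **FINITE),
        a=st.floats(10.0, 200.0, **FINITE),
        es=st.floats(1.0, 25.0, **FINITE),
        el=st.floats(1.0, 25.0, **FINITE),
        tr=st.one_of(st.none(), st.floats(0.5, 5.0, **FINITE)),
        tv=st.floats(0.0, 60.0, **FINITE),
        disease=st.booleans(),
    )
    @settings(max_examples=300, derandomize=True)
    def test_every_complete_vector_maps_to_one_grade(
            self, ef, lavi, e, a, es, el, tr, tv, disease):
        """No fall-through: any measurement vector with E, A, EF, LAVI and
        both e' present yields exactly one of the five grades, for both
        modalities."""
        r = make_record(disease=disease,
                        echo=dict(ef=ef, lavi=lavi, e_peak=e, a_peak=a,
                                  e_prime_septal=es, e_prime_lateral=el,
                                  tr_peak=tr),
                        flow=dict(ef=ef, lavi=lavi, e_peak=e, a_peak=a,
                                  e_prime_septal=es, e_prime_lateral=el,
                                  t_vortex=tv))
        for modality in ("echo", "flow4d"):
            g = grade_subject(r, modality, default_cutoffs(modality))
            assert g in DiastolicGrade


class TestCrossModalityConsistency:
    @given(
        ef=st.floats(20.0, 80.0, **FINITE),
        lavi=st.floats(10.0, 80.0, **FINITE),
        e=st.floats(20.0, 150.0, **FINITE),
        a=st.floats(20.0, 150.0, **FINITE),
        es=st.floats(2.0, 15.0, **FINITE),
        el=st.floats(2.0, 15.0, **FINITE),
        tr=st.floats(1.0, 4.0, **FINITE),
        disease=st.booleans(),
    )
    @settings(max_examples=300, derandomize=True)
    def test_bias_shifted_noiseless_subject_grades_identically(
            self, ef, lavi, e, a, es, el, tr, disease):
        """4D values = echo values + the published biases on EF/LAVI,
        identical velocities, t_vortex exactly on the segmented model:
        echo cutoffs on echo values and 4D cutoffs on 4D values agree."""
        from hypothesis import assume
        from diaflow import SegmentedModelFit, predict_tvortex, tr_to_ptr

        # keep away from cutoff ties and from the narrow TR band where the
        # integer-rounded surrogate cutoff (15 %) is not exactly equivalent
        # to TR = 2.8 m/s (the model maps t_vortex 15 % to TR 2.784 m/s)
        assume(not 2.78 < tr < 2.81)
        for v, cut in ((ef, 50.0), (lavi, 34.0), (e, 50.0), (es, 7.0),
                       (el, 10.0), (tr, 2.8)):
            assume(abs(v - cut) > 1e-6)
        assume(a > 0)
        ea = e / a
        assume(abs(ea - 0.8) > 1e-6 and abs(ea - 2.0) > 1e-6)
        eep = e / ((es + el) / 2)
        assume(abs(eep - 14.0) > 1e-6)

        model = SegmentedModelFit(ptr0=18.4, slope=1.19, r_fit=1.0, n=0, sse=0.0)
        tv = float(predict_tvortex(model, tr_to_ptr(tr)))
        r = make_record(disease=disease,
                        echo=dict(ef=ef, lavi=lavi, e_peak=e, a_peak=a,
                                  e_prime_septal=es, e_prime_lateral=el,
                                  tr_peak=tr),
                        flow=dict(ef=ef + 5.0, lavi=lavi + 13.0, e_peak=e,
                                  a_peak=a, e_prime_septal=es,
                                  e_prime_lateral=el, t_vortex=min(tv, 100.0)))
        g_echo = grade_subject(r, "echo", default_cutoffs("echo"))
        g_flow = grade_subject(r, "flow4d", default_cutoffs("flow4d"))
        assert g_echo == g_flow
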