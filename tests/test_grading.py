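"""Antral grading and the risk flowchart, checked against a brute-force oracle."""

import itertools

import pytest

from gastrus import (
    AntralGrade,
    Content,
    FiredRule,
    PatientRecord,
    Phase,
    PositionMeasurement,
    Risk,
    ScanRecord,
    Sex,
    SurgeryType,
    SurgicalAccess,
    antral_grade,
    assess_patient,
    classify_risk,
    prediction_confusion,
)
from gastrus.grading import RiskAssessment
from gastrus.records import NOT_DETECTED

E, L, S, M, U = Content.empty, Content.liquid, Content.solid, Content.mixed, Content.unknown
FLUID = {L, M}


class TestAntralGrade:
    @pytest.mark.parametrize(
        "sup,rld,grade",
        [
            (E, E, AntralGrade.G0),
            (E, L, AntralGrade.G1),
            (L, L, AntralGrade.G2),
            (M, M, AntralGrade.G2),  # mixed content is fluid-bearing
            (S, E, AntralGrade.G0),  # solid is not fluid
            (S, M, AntralGrade.G1),
            (U, L, AntralGrade.G1),  # minimum grade consistent with fluid RLD
            (U, E, AntralGrade.indeterminate),
            (E, U, AntralGrade.indeterminate),
            (U, U, AntralGrade.indeterminate),
            (L, E, AntralGrade.indeterminate),  # supine-only fluid is ungradable
        ],
    )
    def test_grading_table(self, sup, rld, grade):
        assert antral_grade(sup, rld) is grade

    def test_more_fluid_never_lowers_the_grade(self):
        rank = {AntralGrade.G0: 0, AntralGrade.G1: 1, AntralGrade.G2: 2}
        known = [E, L, S, M]
        for sup, rld in itertools.product(known, known):
            g_before = antral_grade(sup, rld)
            for pos in (0, 1):
                contents = [sup, rld]
                if contents[pos] in FLUID:
                    continue
                contents[pos] = L
                g_after = antral_grade(*contents)
                if g_before in rank and g_after in rank:
                    assert rank[g_after] >= rank[g_before]

    def test_invalid_content_rejected(self):
        from gastrus import DomainError

        with pytest.raises(DomainError):
            antral_grade("liquid", E)


def _patient(weight=80.0, adverse=False, pid="P1"):
    return PatientRecord(
        patient_id=pid,
        age=50,
        sex=Sex.male,
        weight_kg=weight,
        bmi=25.0,
        surgery_type=SurgeryType.colorectal,
        surgical_access=SurgicalAccess.open,
        prior_abdominal_surgery=False,
        adverse_outcome=adverse,
    )


def _measurement(content, csa=None):
    if content is U:
        return NOT_DETECTED
    return PositionMeasurement(detected=True, content=content, csa_traced_cm2=csa)


def _scan(sup, rld, rld_csa=None, pid="P1"):
    return ScanRecord(
        patient_id=pid,
        phase=Phase.postoperative,
        pod=1,
        supine=_measurement(sup),
        rld=_measurement(rld, rld_csa),
    )


def _csa_for_per_kg(per_kg, weight=80.0, age=50):
    """RLD CSA making the predicted volume exactly per_kg mL/kg."""
    return (per_kg * weight + 1.28 * age - 27.0) / 14.6


def _oracle(sup, rld, per_kg):
    """Literal transcription of the aspiration-risk flowchart.

    per_kg is the weight-normalized predicted volume, or None when it cannot
    be computed (no RLD CSA or no weight).
    """
    if (sup is not U and sup in {S, M}) or (rld is not U and rld in {S, M}):
        return Risk.high
    if sup in FLUID and rld in FLUID:
        return Risk.high  # Grade 2
    if per_kg is not None and per_kg > 1.5:
        return Risk.high
    # Grade 2 stays possible only while the RLD content is unknown alongside
    # a fluid or unknown supine; unknown supine with fluid RLD is graded G1
    # by the conservative convention, so it does not block a low call.
    g2_possible = rld is U and (sup is U or sup in FLUID)
    if not g2_possible and per_kg is not None and per_kg <= 1.5:
        return Risk.low
    return Risk.indeterminate


class TestClassifyRisk:
    def test_grade2_is_high_regardless_of_volume(self):
        a = classify_risk(_scan(L, L, rld_csa=0.5), _patient())
        assert a.risk is Risk.high and a.fired_rule is FiredRule.grade2_fluid

    def test_solid_content_is_high(self):
        a = classify_risk(_scan(S, E), _patient())
        assert a.risk is Risk.high and a.fired_rule is FiredRule.solid_content

    def test_low_risk_worked_example(self):
        # empty both positions, RLD CSA 5 cm^2, age 50, weight 72 -> 0.5 mL/kg
        a = classify_risk(_scan(E, E, rld_csa=5.0), _patient(weight=72.0))
        assert a.risk is Risk.low and a.fired_rule is FiredRule.below_threshold
        assert a.volume.volume_ml == pytest.approx(36.0)
        assert a.volume.volume_ml_per_kg == pytest.approx(0.5)

    def test_threshold_is_strict(self):
        csa = _csa_for_per_kg(1.5)
        assert classify_risk(_scan(E, E, rld_csa=csa), _patient()).risk is Risk.low
        csa_eps = _csa_for_per_kg(1.51)
        a = classify_risk(_scan(E, E, rld_csa=csa_eps), _patient())
        assert a.risk is Risk.high and a.fired_rule is FiredRule.volume_over_threshold

    def test_missing_data_is_indeterminate_not_error(self):
        a = classify_risk(_scan(U, U), _patient())
        assert a.risk is Risk.indeterminate
        assert a.fired_rule is FiredRule.insufficient_data

    def test_rld_csa_falls_back_to_diameters(self):
        scan = ScanRecord(
            patient_id="P1",
            phase=Phase.postoperative,
            pod=1,
            supine=_measurement(E),
            rld=PositionMeasurement(detected=True, content=E, d1_mm=25.0, d2_mm=25.0),
        )
        a = classify_risk(scan, _patient())
        assert a.risk is Risk.low and a.volume is not None

    def test_exhaustive_truth_table_matches_oracle(self):
        """All 5x5 contents x volume availability x weight presence."""
        contents = [E, L, S, M, U]
        per_kg_options = [None, 0.0, 1.5, 1.51]
        for sup, rld, per_kg, has_weight in itertools.product(
            contents, contents, per_kg_options, [True, False]
        ):
            weight = 80.0 if has_weight else None
            # the volume branch needs a detected RLD and a known weight
            if rld is U or per_kg is None:
                csa, effective_per_kg = None, None
            else:
                csa = _csa_for_per_kg(per_kg)
                effective_per_kg = per_kg if has_weight else None
            got = classify_risk(_scan(sup, rld, rld_csa=csa), _patient(weight=weight))
            want = _oracle(sup, rld, effective_per_kg)
            assert got.risk is want, (sup, rld, per_kg, has_weight, got)

    def test_raising_volume_never_turns_high_into_low(self):
        for per_kg in [0.0, 0.5, 1.0, 1.4, 1.6, 2.5, 4.0]:
            prev = None
            a = classify_risk(
                _scan(E, E, rld_csa=_csa_for_per_kg(per_kg)), _patient()
            ).risk
            if prev is not None and prev is Risk.high:
                assert a is Risk.high
            prev = a


class TestPatientAggregation:
    def test_any_high_postoperative_scan_makes_patient_high(self):
        p = _patient()
        scans = [_scan(E, E, rld_csa=5.0), _scan(L, L)]
        assert assess_patient(p, scans).risk is Risk.high

    def test_all_indeterminate_scans_make_patient_indeterminate(self):
        p = _patient()
        assert assess_patient(p, [_scan(U, U), _scan(U, U)]).risk is Risk.indeterminate

    def test_preoperative_scans_ignored_by_default(self):
        p = _patient()
        pre = ScanRecord(
            patient_id="P1", phase=Phase.preoperative, supine=_measurement(L), rld=_measurement(L)
        )
        assert assess_patient(p, [pre, _scan(E, E, rld_csa=5.0)]).risk is Risk.low


class TestPredictionConfusion:
    def _assessment(self, risk):
        rule = {
            Risk.high: FiredRule.grade2_fluid,
            Risk.low: FiredRule.below_threshold,
            Risk.indeterminate: FiredRule.insufficient_data,
        }[risk]
        return RiskAssessment(grade=AntralGrade.indeterminate, risk=risk, fired_rule=rule)

    def test_one_of_six_adverse_gives_16_7_percent(self):
        patients = [_patient(pid=f"A{i}", adverse=True) for i in range(6)]
        patients += [_patient(pid=f"N{i}") for i in range(3)]
        assessments = [("A0", self._assessment(Risk.high))]
        assessments += [(f"A{i}", self._assessment(Risk.low)) for i in range(1, 6)]
        assessments += [(f"N{i}", self._assessment(Risk.low)) for i in range(3)]
        c = prediction_confusion(assessments, patients)
        assert (c.true_pos, c.false_neg, c.true_neg) == (1, 5, 3)
        assert c.prediction_rate_pct == pytest.approx(100 / 6, abs=1e-9)

    def test_all_adverse_flagged_gives_100_percent(self):
        patients = [_patient(pid=f"A{i}", adverse=True) for i in range(4)]
        c = prediction_confusion(
            [(p.patient_id, self._assessment(Risk.high)) for p in patients], patients
        )
        assert c.prediction_rate_pct == 100.0

    def test_no_adverse_patients_rate_absent_counts_present(self):
        patients = [_patient(pid=f"N{i}") for i in range(3)]
        c = prediction_confusion(
            [(p.patient_id, self._assessment(Risk.low)) for p in patients], patients
        )
        assert c.prediction_rate_pct is None
        assert c.true_neg == 3

    def test_indeterminate_excluded_from_rate(self):
        patients = [
            _patient(pid="A0", adverse=True),
            _patient(pid="A1", adverse=True),
        ]
        c = prediction_confusion(
            [("A0", self._assessment(Risk.high)), ("A1", self._assessment(Risk.indeterminate))],
            patients,
        )
        assert c.indeterminate == 1
        assert c.prediction_rate_pct == pytest.approx(100.0)
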