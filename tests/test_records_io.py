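"""Record validation and CSV round-trip behaviour."""

import pytest
from hypothesis import given, strategies as st

from gastrus import (
    Content,
    PatientRecord,
    Phase,
    PositionMeasurement,
    ReferentialError,
    ScanRecord,
    SchemaError,
    Sex,
    SurgeryType,
    SurgicalAccess,
    ValidationError,
    read_cohort,
    write_cohort,
)
from gastrus.records import NOT_DETECTED


def _patient(**kw):
    base = dict(
        patient_id="P1",
        age=60,
        sex=Sex.male,
        weight_kg=80.0,
        bmi=26.0,
        surgery_type=SurgeryType.colorectal,
        surgical_access=SurgicalAccess.open,
        prior_abdominal_surgery=False,
        adverse_outcome=False,
    )
    base.update(kw)
    return PatientRecord(**base)


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"age": -1},
            {"weight_kg": 0.0},
            {"weight_kg": -5.0},
            {"bmi": 0.0},
            {"patient_id": ""},
        ],
    )
    def test_patient_invariant_violations_rejected(self, kw):
        with pytest.raises(ValidationError):
            _patient(**kw)

    def test_optional_fields_may_be_absent(self):
        p = _patient(weight_kg=None, bmi=None)
        assert p.weight_kg is None and p.bmi is None

    def test_undetected_position_carries_nothing(self):
        with pytest.raises(ValidationError):
            PositionMeasurement(detected=False, content=Content.liquid)
        with pytest.raises(ValidationError):
            PositionMeasurement(detected=False, d1_mm=20.0)

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValidationError):
            PositionMeasurement(detected=True, content=Content.empty, d1_mm=-1.0)

    def test_preoperative_scan_cannot_carry_pod(self):
        with pytest.raises(ValidationError):
            ScanRecord(
                patient_id="P1",
                phase=Phase.preoperative,
                pod=2,
                supine=NOT_DETECTED,
                rld=NOT_DETECTED,
            )

    def test_postoperative_scan_requires_pod(self):
        with pytest.raises(ValidationError):
            ScanRecord(
                patient_id="P1",
                phase=Phase.postoperative,
                pod=None,
                supine=NOT_DETECTED,
                rld=NOT_DETECTED,
            )


class TestIO:
    def _tiny_cohort(self):
        patients = [
            _patient(patient_id="P1"),
            _patient(patient_id="P2", weight_kg=None, bmi=None, sex=Sex.female),
        ]
        scans = [
            ScanRecord(
                patient_id="P1",
                phase=Phase.preoperative,
                supine=PositionMeasurement(
                    detected=True, content=Content.empty, d1_mm=24.1, d2_mm=26.1
                ),
                rld=PositionMeasurement(
                    detected=True, content=Content.liquid, csa_traced_cm2=5.4
                ),
            ),
            ScanRecord(
                patient_id="P1",
                phase=Phase.postoperative,
                pod=1,
                supine=NOT_DETECTED,
                rld=NOT_DETECTED,
            ),
            ScanRecord(
                patient_id="P2",
                phase=Phase.postoperative,
                pod=3,
                supine=NOT_DETECTED,
                rld=PositionMeasurement(detected=True, content=Content.mixed),
            ),
        ]
        return patients, scans

    def test_round_trip_identity(self, tmp_path):
        patients, scans = self._tiny_cohort()
        pp, sp = write_cohort(patients, scans, tmp_path)
        back_p, back_s = read_cohort(pp, sp)
        assert back_p == patients and back_s == scans

    def test_empty_cohort_round_trips_as_header_only(self, tmp_path):
        pp, sp = write_cohort([], [], tmp_path)
        assert len(pp.read_text().strip().splitlines()) == 1
        assert len(sp.read_text().strip().splitlines()) == 1
        assert read_cohort(pp, sp) == ([], [])

    def test_missing_optionals_serialized_as_empty_cells(self, tmp_path):
        patients = [_patient(patient_id="P1", weight_kg=None, bmi=None)]
        pp, _ = write_cohort(patients, [], tmp_path)
        text = pp.read_text()
        assert "NaN" not in text and "nan" not in text
        assert ",,," in text.splitlines()[1] or ",," in text.splitlines()[1]

    def test_missing_column_is_schema_error(self, tmp_path):
        patients, scans = self._tiny_cohort()
        pp, sp = write_cohort(patients, scans, tmp_path)
        lines = pp.read_text().splitlines()
        lines[0] = lines[0].replace("age,", "")
        lines[1:] = [",".join(l.split(",")[:1] + l.split(",")[2:]) for l in lines[1:]]
        pp.write_text("\n".join(lines))
        with pytest.raises(SchemaError, match="age"):
            read_cohort(pp, sp)

    def test_unknown_patient_is_referential_error(self, tmp_path):
        patients, scans = self._tiny_cohort()
        pp, sp = write_cohort(patients, scans, tmp_path)
        sp.write_text(sp.read_text().replace("P2", "P99"))
        with pytest.raises(ReferentialError, match="P99"):
            read_cohort(pp, sp)

    def test_invalid_enum_names_row_and_field(self, tmp_path):
        patients, scans = self._tiny_cohort()
        pp, sp = write_cohort(patients, scans, tmp_path)
        pp.write_text(pp.read_text().replace("colorectal", "Colon"))
        with pytest.raises(ValidationError, match="surgery_type"):
            read_cohort(pp, sp)

    def test_preop_pod_rejected_on_read(self, tmp_path):
        patients, scans = self._tiny_cohort()
        pp, sp = write_cohort(patients, scans, tmp_path)
        lines = sp.read_text().splitlines()
        parts = lines[1].split(",")
        assert parts[1] == "preoperative"
        parts[2] = "2"
        lines[1] = ",".join(parts)
        sp.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="row 0"):
            read_cohort(pp, sp)


# -- property: randomized valid cohorts survive a write/read cycle unchanged --

_contents = st.sampled_from([Content.empty, Content.liquid, Content.solid, Content.mixed])
_measure = st.one_of(st.none(), st.floats(0.0, 60.0, allow_nan=False))


@st.composite
def _position(draw):
    if draw(st.booleans()):
        return NOT_DETECTED
    return PositionMeasurement(
        detected=True,
        content=draw(_contents),
        d1_mm=draw(_measure),
        d2_mm=draw(_measure),
        csa_traced_cm2=draw(_measure),
    )


@st.composite
def _cohort(draw):
    n = draw(st.integers(1, 4))
    patients = [
        PatientRecord(
            patient_id=f"P{i}",
            age=draw(st.integers(0, 99)),
            sex=draw(st.sampled_from(list(Sex))),
            weight_kg=draw(st.one_of(st.none(), st.floats(30.0, 150.0, allow_nan=False, exclude_min=True))),
            bmi=draw(st.one_of(st.none(), st.floats(10.0, 50.0, allow_nan=False))),
            surgery_type=draw(st.sampled_from(list(SurgeryType))),
            surgical_access=draw(st.sampled_from(list(SurgicalAccess))),
            prior_abdominal_surgery=draw(st.booleans()),
            adverse_outcome=draw(st.booleans()),
        )
        for i in range(n)
    ]
    scans = []
    for _ in range(draw(st.integers(0, 6))):
        pre = draw(st.booleans())
        scans.append(
            ScanRecord(
                patient_id=draw(st.sampled_from([p.patient_id for p in patients])),
                phase=Phase.preoperative if pre else Phase.postoperative,
                pod=None if pre else draw(st.integers(1, 9)),
                supine=draw(_position()),
                rld=draw(_position()),
            )
        )
    return patients, scans


@given(_cohort())
def test_round_trip_identity_on_random_cohorts(tmp_path_factory, cohort):
    patients, scans = cohort
    out = tmp_path_factory.mktemp("rt")
    pp, sp = write_cohort(patients, scans, out)
    assert read_cohort(pp, sp) == (patients, scans)
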