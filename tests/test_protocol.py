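"""Eligibility, volume doubling time, nodule triage and workflow wiring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screenbank as sb
from screenbank import model as m
from screenbank.protocol import (
    NON_GROWING,
    TriageAction,
    add_months,
    monitoring_interval_months,
)


class TestPackYears:
    @pytest.mark.parametrize(
        "cigs,years,expected",
        [(20, 20, 20.0), (0, 40, 0.0), (25, 37.9, 47.375), (40, 10, 20.0)],
    )
    def test_values(self, cigs, years, expected):
        assert sb.pack_years(cigs, years) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(sb.DomainError):
            sb.pack_years(-1, 10)


class TestEligibility:
    def test_boundaries_inclusive(self):
        assert sb.check_eligibility(50, 20)
        assert not sb.check_eligibility(49, 60)
        assert not sb.check_eligibility(80, 19.9)

    @pytest.mark.parametrize("age", [49, 50, 51])
    @pytest.mark.parametrize("py", [19, 20, 21])
    def test_exhaustive_grid_matches_conjunction(self, age, py):
        assert sb.check_eligibility(age, py) == ((age >= 50) and (py >= 20))


class TestVolumeDoublingTime:
    def test_exact_doubling_returns_interval(self):
        assert sb.volume_doubling_time(100.0, 200.0, 100.0) == pytest.approx(100.0)

    def test_closed_form_case(self):
        expected = 90 * math.log(2) / math.log(1.5)
        assert sb.volume_doubling_time(100, 150, 90) == pytest.approx(expected, abs=1e-9)

    def test_non_growing_sentinel(self):
        assert sb.volume_doubling_time(100, 100, 30) == NON_GROWING
        assert sb.volume_doubling_time(100, 80, 30) == NON_GROWING

    def test_domain_errors(self):
        for args in [(0, 100, 30), (100, 0, 30), (100, 200, 0)]:
            with pytest.raises(sb.DomainError):
                sb.volume_doubling_time(*args)

    @settings(max_examples=200, derandomize=True)
    @given(
        v1=st.floats(1e-3, 1e6), ratio=st.floats(1.001, 50), dt=st.floats(1, 3650),
        scale=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, v1, ratio, dt, scale):
        base = sb.volume_doubling_time(v1, v1 * ratio, dt)
        scaled = sb.volume_doubling_time(v1 * scale, v1 * ratio * scale, dt)
        assert scaled == pytest.approx(base, rel=1e-12)


def _triage_oracle(diameter, vdt, high_suspicion):
    """Independent re-statement of the printed management rules."""
    fast = vdt is not None and 30.0 <= vdt <= 400.0
    if diameter > 8.0 or fast:
        return "INVASIVE_WORKUP" if high_suspicion else "CT_PET"
    if 5.0 <= diameter <= 8.0:
        return "REPEAT_LDCT_3_6M"
    return "ANNUAL_ROUTINE"


class TestTriage:
    @pytest.mark.parametrize(
        "diameter,vdt,expected",
        [
            (6.0, None, TriageAction.REPEAT_LDCT_3_6M),
            (9.0, None, TriageAction.CT_PET),
            (6.0, 200.0, TriageAction.CT_PET),  # growth rule dominates size rule
            (3.0, None, TriageAction.ANNUAL_ROUTINE),
            (5.0, None, TriageAction.REPEAT_LDCT_3_6M),  # inclusive lower bound
            (8.0, None, TriageAction.REPEAT_LDCT_3_6M),  # 8 mm is not "above 8"
            (8.0, 500.0, TriageAction.REPEAT_LDCT_3_6M),  # VDT outside window
            (4.0, 30.0, TriageAction.CT_PET),  # window inclusive
            (4.0, 400.0, TriageAction.CT_PET),
        ],
    )
    def test_rule_table(self, diameter, vdt, expected):
        assert sb.triage_nodule(diameter, vdt).action is expected

    def test_high_suspicion_escalates_to_workup(self):
        d = sb.triage_nodule(9.0, None, pet_or_growth_high_suspicion=True)
        assert d.action is TriageAction.INVASIVE_WORKUP
        # the flag has no effect below the CT-PET branch
        d2 = sb.triage_nodule(6.0, None, pet_or_growth_high_suspicion=True)
        assert d2.action is TriageAction.REPEAT_LDCT_3_6M

    def test_randomized_grid_matches_independent_restatement(self, rng):
        """Total function over a randomized (diameter, VDT, suspicion) grid,
        always agreeing with a brute-force restatement of the rules."""
        for _ in range(500):
            diameter = float(rng.uniform(0.5, 20.0))
            vdt = None if rng.random() < 0.3 else float(rng.uniform(5, 800))
            high = bool(rng.random() < 0.3)
            got = sb.triage_nodule(diameter, vdt, high).action.value
            assert got == _triage_oracle(diameter, vdt, high)

    def test_monitoring_interval_split(self):
        assert monitoring_interval_months(7.0) == 3
        assert monitoring_interval_months(5.5) == 6


class TestExamTypeClassification:
    def test_partition_and_agreement_with_recorded_attribute(self, small_cohort):
        """Graph-derived exam types agree with the generator's recorded
        attribute and the three classes partition all acquisitions."""
        store = small_cohort.store
        rows = store._all(
            "SELECT event_id, attributes FROM events WHERE event_type = 'IMAGE_ACQUISITION'"
        )
        counts = {t: 0 for t in m.ExamType}
        import json

        for r in rows:
            derived = sb.classify_exam_type(r["event_id"], store)
            recorded = json.loads(r["attributes"])["exam_type"]
            assert derived.value == recorded
            counts[derived] += 1
        assert sum(counts.values()) == len(rows)
        assert counts[m.ExamType.BASELINE] == len(small_cohort.donors)

    def test_unwired_acquisition_rejected(self, seeded_store):
        seeded_store.register(
            m.Event("A1", "D1", m.EventType.IMAGE_ACQUISITION, "2005-02-01")
        )
        seeded_store.register(
            m.Event("A2", "D1", m.EventType.IMAGE_ACQUISITION, "2006-02-01")
        )
        assert sb.classify_exam_type("A1", seeded_store) is m.ExamType.BASELINE
        with pytest.raises(sb.WorkflowError):
            sb.classify_exam_type("A2", seeded_store)  # no causal implication

    def test_non_acquisition_event_rejected(self, seeded_store):
        with pytest.raises(sb.DomainError):
            sb.classify_exam_type("EV-recr", seeded_store)


class TestWireWorkflow:
    def _timeline(self, store, with_biopsy):
        store.register(m.Collection("imaging", "Imaging", m.CollectionKind.IMAGING))
        store.register(m.SampleDonor("D1", "P0001", m.Sex.M, "55-59", "2005-01-10"))
        events = [
            ("H", m.EventType.PATIENT_HISTORY, "2005-01-10", {}),
            ("R", m.EventType.RECRUITMENT, "2005-01-10", {}),
            ("ACQ1", m.EventType.IMAGE_ACQUISITION, "2005-02-01",
             {"exam_type": "BASELINE"}),
            ("ANA1", m.EventType.IMAGING_ANALYSIS, "2005-02-01", {}),
            ("ACQ2", m.EventType.IMAGE_ACQUISITION, "2005-05-01",
             {"exam_type": "MONITORING_FOLLOWUP"}),
        ]
        if with_biopsy:
            events += [
                ("ANA2", m.EventType.IMAGING_ANALYSIS, "2005-05-01", {}),
                ("SAMP", m.EventType.BIOLOGICAL_SAMPLING, "2005-06-01", {}),
                ("BSA", m.EventType.BIOLOGICAL_SAMPLE_ANALYSIS, "2005-06-15",
                 {"pathological_result": "malignant"}),
                ("DIAG", m.EventType.DIAGNOSIS, "2005-06-22", {"grade": 2}),
            ]
        for eid, etype, date, attrs in events:
            store.register(m.Event(eid, "D1", etype, date, attrs))
        return store

    def test_suspicious_finding_with_biopsy_wires_full_chain(self, store):
        self._timeline(store, with_biopsy=True)
        imps = sb.wire_workflow("D1", store)
        assert sorted(i.label for i in imps) == [
            "analyses->diagnosis",
            "analysis->monitoring-acquisition",
            "analysis->sampling",
            "history->recruitment",
            "recruitment->acquisition",
            "sampling->analysis",
        ]
        from conftest import brute_force_has_cycle

        assert not brute_force_has_cycle(store.implication_edges())
        assert sb.validate_store(store) == []

    def test_diagnosis_gets_both_analysis_causes(self, store):
        self._timeline(store, with_biopsy=True)
        sb.wire_workflow("D1", store)
        diag_causes = {e.event_id for _, e in store.causes_of("DIAG")}
        assert diag_causes == {"ANA2", "BSA"}

    def test_clean_timeline_has_only_protocol_implications(self, store):
        self._timeline(store, with_biopsy=False)
        store._conn.execute(
            "UPDATE events SET attributes = '{\"exam_type\": \"ROUTINE_FOLLOWUP\"}' "
            "WHERE event_id = 'ACQ2'"
        )
        store._conn.commit()
        imps = sb.wire_workflow("D1", store)
        labels = sorted(i.label for i in imps)
        assert labels == [
            "history->recruitment",
            "recruitment->acquisition",
            "recruitment->acquisition",
        ]

    def test_missing_recruitment_is_workflow_error(self, store):
        store.register(m.SampleDonor("D1", "P0001"))
        store.register(
            m.Event("H", "D1", m.EventType.PATIENT_HISTORY, "2005-01-10")
        )
        with pytest.raises(sb.WorkflowError):
            sb.wire_workflow("D1", store)

    def test_wiring_is_incremental(self, store):
        self._timeline(store, with_biopsy=False)
        sb.wire_workflow("D1", store)
        assert sb.wire_workflow("D1", store) == []  # nothing left to wire


def test_add_months_clamps_day():
    import datetime

    assert add_months(datetime.date(2005, 1, 31), 1) == datetime.date(2005, 2, 28)
    assert add_months(datetime.date(2004, 11, 30), 3) == datetime.date(2005, 2, 28)
    assert add_months(datetime.date(2004, 1, 31), 1) == datetime.date(2004, 2, 29)
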