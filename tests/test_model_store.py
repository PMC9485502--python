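"""Core data-model contracts: registration, linkage cardinalities,
implication rules and the full-scan validator."""

import numpy as np
import pytest

import screenbank as sb
from screenbank import model as m

from conftest import brute_force_has_cycle


class TestRegister:
    def test_first_donor_accepted(self, store):
        assert store.register(m.SampleDonor("D1", "P0001")) == "D1"

    def test_duplicate_pseudonym_rejected(self, store):
        store.register(m.SampleDonor("D1", "P0001"))
        with pytest.raises(sb.ConflictError):
            store.register(m.SampleDonor("D2", "P0001"))

    def test_duplicate_series_uid_rejected(self, seeded_store):
        sample = m.DICOMSeriesSample(
            "S1", "D1", "imaging", m.SampleKind.DIGITAL_IMAGING,
            series_instance_uid="1.2.3.4", slice_thickness_mm=2.5,
        )
        seeded_store.register(sample)
        clone = m.DICOMSeriesSample(
            "S2", "D1", "imaging", m.SampleKind.DIGITAL_IMAGING,
            series_instance_uid="1.2.3.4", slice_thickness_mm=2.5,
        )
        with pytest.raises(sb.ConflictError):
            seeded_store.register(clone)

    def test_event_with_absent_donor_rejected(self, store):
        with pytest.raises(sb.ReferentialError):
            store.register(m.Event("E1", "nobody", m.EventType.RECRUITMENT, "2005-01-01"))

    def test_undeclared_event_attribute_rejected(self, seeded_store):
        with pytest.raises(sb.ScreenbankError):
            seeded_store.register(
                m.Event("E-bad", "D1", m.EventType.DIAGNOSIS, "2010-01-01",
                        {"storage_temperature": -80})
            )

    def test_sample_kind_must_match_collection_kind(self, seeded_store):
        bad = m.BiologicalSample("B1", "D1", "imaging", m.SampleKind.BIOLOGICAL)
        with pytest.raises(sb.CardinalityError):
            seeded_store.register(bad)

    def test_nonpositive_slice_thickness_rejected(self):
        with pytest.raises(sb.DomainError):
            m.DICOMSeriesSample(
                "S1", "D1", "imaging", m.SampleKind.DIGITAL_IMAGING,
                series_instance_uid="1.2", slice_thickness_mm=0.0,
            )


class TestSampleEventLink:
    @pytest.fixture
    def acq(self, seeded_store):
        seeded_store.register(
            m.Event("EV-acq", "D1", m.EventType.IMAGE_ACQUISITION, "2005-02-01")
        )
        return "EV-acq"

    def _series(self, store, sid, uid):
        store.register(
            m.DICOMSeriesSample(
                sid, "D1", "imaging", m.SampleKind.DIGITAL_IMAGING,
                series_instance_uid=uid, slice_thickness_mm=2.5,
            )
        )
        return sid

    def test_many_samples_share_one_acquisition_event(self, seeded_store, acq):
        s1 = self._series(seeded_store, "S1", "1.1")
        s2 = self._series(seeded_store, "S2", "1.2")
        assert seeded_store.link_sample_event(s1, acq) == (s1, acq)
        assert seeded_store.link_sample_event(s2, acq) == (s2, acq)

    def test_event_with_zero_samples_is_valid(self, seeded_store, acq):
        report = sb.validate_store(seeded_store)
        assert not [v for v in report if v.entity_id == acq and "sample" in v.rule_id]

    def test_second_acquisition_event_rejected(self, seeded_store, acq):
        seeded_store.register(
            m.Event("EV-acq2", "D1", m.EventType.IMAGE_ACQUISITION, "2006-02-01")
        )
        s1 = self._series(seeded_store, "S1", "1.1")
        seeded_store.link_sample_event(s1, acq)
        with pytest.raises(sb.CardinalityError):
            seeded_store.link_sample_event(s1, "EV-acq2")

    def test_imaging_sample_needs_acquisition_event_type(self, seeded_store):
        s1 = self._series(seeded_store, "S1", "1.1")
        with pytest.raises(sb.CardinalityError):
            seeded_store.link_sample_event(s1, "EV-recr")


class TestImplications:
    @pytest.fixture
    def events(self, seeded_store):
        for eid, etype, date in [
            ("E-ana", m.EventType.IMAGING_ANALYSIS, "2005-06-01"),
            ("E-samp", m.EventType.BIOLOGICAL_SAMPLING, "2005-07-01"),
        ]:
            seeded_store.register(m.Event(eid, "D1", etype, date))
        return seeded_store

    def test_analysis_causes_sampling(self, events):
        imp = events.add_implication(["E-ana"], ["E-samp"], label="analysis->sampling")
        assert imp.cause_event_refs == ["E-ana"]
        assert imp.effect_event_refs == ["E-samp"]

    def test_empty_cause_list_rejected(self, events):
        with pytest.raises(sb.CardinalityError):
            events.add_implication([], ["E-samp"])

    def test_temporal_inversion_rejected(self, events):
        with pytest.raises(sb.ChronologyError):
            events.add_implication(["E-samp"], ["E-ana"])

    def test_same_event_on_both_sides_rejected(self, events):
        with pytest.raises(sb.CardinalityError):
            events.add_implication(["E-ana"], ["E-ana"])

    def test_cycle_rejected_matching_brute_force(self, seeded_store):
        # same-day events so chronology admits both directions
        seeded_store.register(m.Event("A", "D1", m.EventType.IMAGING_ANALYSIS, "2005-06-01"))
        seeded_store.register(m.Event("B", "D1", m.EventType.DIAGNOSIS, "2005-06-01"))
        seeded_store.add_implication(["A"], ["B"])
        assert not brute_force_has_cycle(seeded_store.implication_edges())
        with pytest.raises(sb.CycleError):
            seeded_store.add_implication(["B"], ["A"])
        assert brute_force_has_cycle(seeded_store.implication_edges() + [("B", "A")])

    def test_random_small_graphs_acyclicity_matches_enumeration(self, seeded_store, rng):
        """The store's accept/reject decision agrees with exhaustive path
        enumeration on random <=12-event graphs."""
        n = 12
        for i in range(n):
            seeded_store.register(
                m.Event(f"N{i}", "D1", m.EventType.IMAGING_ANALYSIS, "2005-06-01")
            )
        edges: list[tuple[str, str]] = []
        for _ in range(40):
            a, b = rng.choice(n, size=2, replace=False)
            cand = (f"N{a}", f"N{b}")
            would_cycle = brute_force_has_cycle(edges + [cand])
            try:
                seeded_store.add_implication([cand[0]], [cand[1]])
                accepted = True
            except sb.CycleError:
                accepted = False
            assert accepted == (not would_cycle)
            if accepted:
                edges.append(cand)


class TestValidateStore:
    def test_simulated_cohort_is_clean(self, small_cohort):
        assert sb.validate_store(small_cohort.store) == []

    def test_diagnosis_without_analysis_cause_flagged(self, seeded_store):
        seeded_store.register(
            m.Event("E-diag", "D1", m.EventType.DIAGNOSIS, "2010-01-01")
        )
        rules = {v.rule_id for v in sb.validate_store(seeded_store)}
        assert "diagnosis.analysis-cause" in rules

    def test_dangling_donor_ref_counted_once(self):
        """Hand-built 5-entity store with one dangling donor reference
        yields exactly one violation (independent full-scan count)."""
        store = sb.Store()
        store.register(m.Collection("imaging", "Imaging", m.CollectionKind.IMAGING))
        store.register(m.SampleDonor("D1", "P0001"))
        store.register(m.Event("E1", "D1", m.EventType.RECRUITMENT, "2005-01-01"))
        payload = store.export_json()
        payload["events"].append(
            {"event_id": "E2", "donor_ref": "GHOST", "event_type": "PATIENT_HISTORY",
             "event_date": "2005-01-01", "attributes": "{}"}
        )
        rebuilt = sb.Store.import_json(payload)
        report = sb.validate_store(rebuilt)
        assert len(report) == 1
        assert report[0].entity_id == "E2"
        assert report[0].rule_id == "event.donor-resolves"

    def test_validation_is_idempotent_and_pure(self, small_cohort):
        store = small_cohort.store
        before = store.content_hash()
        first = sb.validate_store(store)
        second = sb.validate_store(store)
        assert first == second
        assert store.content_hash() == before


class TestExportImport:
    def test_round_trip_identical(self, small_cohort):
        payload = small_cohort.store.export_json()
        rebuilt = sb.Store.import_json(payload)
        assert rebuilt.export_json() == payload
        assert rebuilt.content_hash() == small_cohort.store.content_hash()

    def test_referenced_event_deletion_refused(self, seeded_store):
        seeded_store.register(
            m.Event("E-hist", "D1", m.EventType.PATIENT_HISTORY, "2005-01-01")
        )
        seeded_store.add_implication(["E-hist"], ["EV-recr"])
        with pytest.raises(sb.CardinalityError):
            seeded_store.delete_event("E-hist")
        # an unreferenced event deletes fine
        seeded_store.register(
            m.Event("E-free", "D1", m.EventType.IMAGING_ANALYSIS, "2006-01-01")
        )
        seeded_store.delete_event("E-free")
        assert not seeded_store.has_event("E-free")
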