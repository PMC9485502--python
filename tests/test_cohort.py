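"""Synthetic-cohort generator: determinism, protocol compliance and
calibration of the emitted distributions."""

import numpy as np
import pydicom
import pytest

import screenbank as sb
from screenbank import model as m
from screenbank.cohort import (
    CohortConfig,
    sample_diameter,
    sample_texture,
    simulate_cohort,
    simulate_donor,
    write_synthetic_dicom,
)


class TestConfig:
    def test_mixtures_must_sum_to_one(self):
        with pytest.raises(sb.DomainError):
            CohortConfig(texture_probs=(0.9, 0.2, 0.1))

    def test_probabilities_bounded(self):
        with pytest.raises(sb.DomainError):
            CohortConfig(benign_given_biopsy=1.5)


class TestSimulateDonor:
    def test_every_donor_is_screening_eligible(self, rng):
        cfg = CohortConfig()
        for i in range(200):
            rec = simulate_donor(cfg, rng, index=i + 1)
            py = sb.pack_years(rec.cigarettes_per_day, rec.smoking_duration_years)
            assert sb.check_eligibility(rec.age_years, py)

    def test_identity_never_enters_the_store(self, store, rng):
        rec = simulate_donor(CohortConfig(), rng, index=1, store=store)
        dump = store.export_json_str()
        assert rec.identity["hospital_id"] not in dump
        assert rec.identity["name_parts"][1] not in dump
        assert rec.identity["birth_date_dicom"] not in dump
        assert rec.donor.age_range in dump  # binned label, not birth date

    def test_seed_determinism(self):
        a = simulate_cohort(CohortConfig(n_donors=8), seed=1)
        b = simulate_cohort(CohortConfig(n_donors=8), seed=1)
        c = simulate_cohort(CohortConfig(n_donors=8), seed=2)
        assert a.store.content_hash() == b.store.content_hash()
        assert a.store.content_hash() != c.store.content_hash()

    def test_female_duration_mean_recovers_configured_value(self):
        """Empirical mean of female smoking durations lies within 3 standard
        errors of the configured population mean (CLT bound)."""
        cfg = CohortConfig()
        rng = np.random.default_rng(1)
        store = sb.Store()
        n = 2000
        for i in range(n):
            simulate_donor(cfg, rng, index=i + 1, sex=m.Sex.F, store=store)
        table = sb.patient_history_summary(store)
        mean = table.loc[table.sex == "F", "duration_mean"].iloc[0]
        assert abs(mean - cfg.smoking_duration_f[0]) < 3 * cfg.smoking_duration_f[1] / np.sqrt(n)


class TestSimulateScreening:
    def test_nodule_free_donor_gets_ten_annual_scans(self):
        cfg = CohortConfig(n_donors=3, nodule_incidence_per_visit=0.0,
                           p_other_finding_per_visit=0.0)
        cohort = simulate_cohort(cfg, seed=4)
        for rec in cohort.donors:
            acqs = cohort.store.events_of_donor(
                rec.donor.donor_id, m.EventType.IMAGE_ACQUISITION
            )
            assert len(acqs) == 10
            kinds = {a.attributes["exam_type"] for a in acqs}
            assert kinds <= {"BASELINE", "ROUTINE_FOLLOWUP"}

    def test_persistent_large_nodule_leads_to_biopsy_and_diagnosis(self):
        """A donor guaranteed a malignant nodule ends up with a CT-PET→biopsy
        path: biological sampling, pathology result and a diagnosis event."""
        cfg = CohortConfig(
            n_donors=6, nodule_incidence_per_visit=1.5, p_malignant_lesion=1.0,
            benign_given_biopsy=0.0,
        )
        cohort = simulate_cohort(cfg, seed=8)
        store = cohort.store
        n_samp = store._one(
            "SELECT COUNT(*) AS n FROM events WHERE event_type = 'BIOLOGICAL_SAMPLING'"
        )["n"]
        n_bsa = store._one(
            "SELECT COUNT(*) AS n FROM events WHERE event_type = 'BIOLOGICAL_SAMPLE_ANALYSIS'"
        )["n"]
        n_diag = store._one(
            "SELECT COUNT(*) AS n FROM events WHERE event_type = 'DIAGNOSIS'"
        )["n"]
        assert n_samp == n_bsa == n_diag > 0
        assert sb.validate_store(store) == []

    def test_random_donor_timelines_always_validate(self):
        cohort = simulate_cohort(CohortConfig(n_donors=40), seed=11)
        assert sb.validate_store(cohort.store) == []

    def test_acquisition_parameters_from_configured_menu(self, small_cohort):
        rows = small_cohort.store._all("SELECT * FROM dicom_series")
        cfg = small_cohort.config
        for r in rows:
            assert r["tube_current_ma"] in cfg.tube_current_mA
            assert r["kvp"] in cfg.kvp_choices
            assert r["convolution_kernel"] in cfg.kernel_choices
            assert r["slice_thickness_mm"] in cfg.slice_thickness_choices


class TestSyntheticDicom:
    def test_series_files_parse_and_share_uid(self, tmp_path, small_cohort):
        meta = small_cohort.donors[0].series_meta[0]
        files = write_synthetic_dicom(meta, tmp_path, np.random.default_rng(0))
        assert len(files) == meta["n_instances"]
        uids = {str(pydicom.dcmread(f).SeriesInstanceUID) for f in files}
        assert uids == {meta["series_instance_uid"]}

    def test_planted_identity_caught_by_scan(self, tmp_path, small_cohort):
        rec = small_cohort.donors[0]
        files = write_synthetic_dicom(rec.series_meta[0], tmp_path, np.random.default_rng(0))
        hits = sb.scan_for_identifiers(files, [rec.identity["hospital_id"]])
        assert hits  # the identity is really planted (incl. a private tag)

    def test_slice_thickness_tag_matches_menu(self, tmp_path, small_cohort):
        meta = small_cohort.donors[0].series_meta[0]
        files = write_synthetic_dicom(meta, tmp_path, np.random.default_rng(0))
        ds = pydicom.dcmread(files[0])
        assert float(ds.SliceThickness) in (2.5, 1.25)


class TestMixtureCalibration:
    def test_texture_and_diameter_mixtures_recovered(self):
        """Empirical lesion mixtures at n=10000 fall within 3 binomial
        standard errors of the configured proportions."""
        cfg = CohortConfig()
        rng = np.random.default_rng(7)
        n = 10000
        textures = [sample_texture(rng, cfg) for _ in range(n)]
        diameters = [sample_diameter(rng, cfg) for _ in range(n)]
        solid = sum(t is m.TextureType.SOLID for t in textures) / n
        for observed, p in [
            (solid, cfg.texture_probs[0]),
            (sum(d < 4 for d in diameters) / n, cfg.diameter_bin_probs[0]),
        ]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < 3 * se

    def test_diameter_bins_respect_boundaries(self, rng):
        cfg = CohortConfig()
        draws = [sample_diameter(rng, cfg) for _ in range(2000)]
        assert all(d > 0 for d in draws)
        assert any(d < 4 for d in draws)
        assert any(d > 10 for d in draws)


def test_full_pipeline_generate_deid_ingest_annotate_validate(tmp_path):
    """End-to-end property: simulate → write DICOM → pseudonymize → ingest
    into a fresh store → annotate a lesion → wire → zero violations."""
    cohort = simulate_cohort(CohortConfig(n_donors=2), seed=13)
    from screenbank.cohort import write_cohort_dicom

    written = write_cohort_dicom(cohort, tmp_path / "raw")
    ledger = sb.PseudonymLedger(tmp_path / "ledger.json")
    fresh = sb.Store()
    # donors registered with ledger pseudonyms, then series ingested
    series_dirs = []
    for rec in cohort.donors:
        pseud = ledger.pseudonym_for(rec.identity["hospital_id"])
        fresh.register(
            m.SampleDonor(rec.donor.donor_id, pseud, rec.donor.sex,
                          rec.donor.age_range, rec.donor.enrollment_date)
        )
        fresh.register(
            m.Event(f"EV-hist-{rec.donor.donor_id}", rec.donor.donor_id,
                    m.EventType.PATIENT_HISTORY, rec.donor.enrollment_date)
        )
        fresh.register(
            m.Event(f"EV-recr-{rec.donor.donor_id}", rec.donor.donor_id,
                    m.EventType.RECRUITMENT, rec.donor.enrollment_date)
        )
    for files in written.values():
        audit = sb.pseudonymize_series(files, tmp_path / "deid", ledger)
        series_dirs.append(audit["outputs"][0].rsplit("/", 1)[0])
    for d in series_dirs:
        sb.ingest_series(d, fresh)
    # leak scan over everything ingested
    all_out = [p for d in series_dirs for p in __import__("pathlib").Path(d).glob("*.dcm")]
    assert sb.scan_for_identifiers(all_out, cohort.planted_identifiers) == []
    # annotate one lesion on the first ingested series
    row = fresh._one("SELECT sample_id, n_instances FROM dicom_series LIMIT 1")
    mask = np.zeros((row["n_instances"], 32, 32), dtype=np.uint8)
    mask[0, 10:14, 10:14] = 1
    sb.store_segmentation(mask, (0.7, 0.7, 2.5), row["sample_id"], "L-e2e", "AUTOMATIC",
                          fresh, tmp_path / "artifacts")
    for rec in cohort.donors:
        sb.wire_workflow(rec.donor.donor_id, fresh)
    assert sb.validate_store(fresh) == []
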