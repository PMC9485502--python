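"""Synthetic longitudinal screening-cohort generator.

Emulates a ten-year annual low-dose-CT lung-screening program over heavy
smokers: sex-stratified smoking histories, protocol-driven visit scheduling
(baseline, routine, monitoring follow-ups), pulmonary nodules drawn from
published texture/diameter/lobe mixtures, exponential lesion growth,
CT-PET-triggered biopsies with pathology outcomes, and minimal valid DICOM
series with deliberately planted identities so the de-identification
leak-scan has something to catch.

Everything is driven by one ``numpy`` generator, so a fixed seed yields a
byte-identical store export.  Calibrated quantities (smoking duration,
cigarettes/day, texture and diameter mixtures, benign-biopsy fraction) come
from published cohort summaries; quantities no summary reports (per-visit
nodule incidence, malignant fraction) are desk-scale defaults documented as
such.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from scipy.stats import truncnorm

from . import model as m
from . import protocol as proto
from .deid import age_to_range, export_layout
from .errors import DomainError
from .store import Store

#: Numeric organizational root for deterministic synthetic UIDs.
_UID_ROOT = "1.2.826.0.1.3680043.10.424"


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the simulated cohort.

    Distribution parameters marked *published* reproduce the real screening
    cohort's reported summaries; the remaining rates are generator defaults
    chosen for desk-scale realism (they make monitoring follow-ups and
    biopsies occur at usable frequency) and are explicitly not calibrated to
    any published count.
    """

    n_donors: int = 100
    sex_ratio_female: float = 0.5
    # published smoking-history parameters (years; per day)
    smoking_duration_f: tuple[float, float] = (37.9, 6.1)
    smoking_duration_m: tuple[float, float] = (39.9, 6.4)
    cigarettes_per_day: tuple[float, float] = (24.9, 10.29)
    cigarettes_min: float = 1.0
    # published lesion mixtures
    texture_probs: tuple[float, float, float] = (0.825, 0.119, 0.056)  # solid/part/non
    diameter_bin_probs: tuple[float, float, float] = (0.507, 0.453, 0.040)
    diameter_bin_ranges: tuple[tuple[float, float], ...] = (
        (1.5, 4.0),
        (4.0, 10.0),
        (10.0, 25.0),
    )
    # near-uniform lobe spread, right-upper-leaning
    lobe_probs: tuple[float, float, float, float, float] = (0.24, 0.18, 0.19, 0.20, 0.19)
    benign_given_biopsy: float = 0.16  # published
    # generator defaults, not calibrated to published counts
    nodule_incidence_per_visit: float = 0.22
    p_malignant_lesion: float = 0.10
    p_other_finding_per_visit: float = 0.08
    vdt_malignant_days: tuple[float, float] = (30.0, 400.0)  # log-uniform
    vdt_benign_days: tuple[float, float] = (600.0, 2000.0)  # when benign lesions grow at all
    p_benign_growing: float = 0.3
    measurement_noise_mm: float = 0.1
    study_years: int = 10
    enrollment_age_range: tuple[int, int] = (50, 75)
    enrollment_years: tuple[int, int] = (2004, 2008)
    # acquisition parameter menu
    tube_current_mA: tuple[float, ...] = (30.0,)
    kvp_choices: tuple[float, ...] = (120.0, 140.0)
    kernel_choices: tuple[str, ...] = ("STANDARD", "LUNG")
    slice_thickness_choices: tuple[float, ...] = (2.5, 1.25)
    n_slices: int = 4
    image_size: int = 32
    protocol: proto.ProtocolConfig = field(default_factory=proto.ProtocolConfig)

    def __post_init__(self) -> None:
        for name in ("texture_probs", "diameter_bin_probs", "lobe_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9:
                raise DomainError(f"{name} must sum to 1, got {sum(probs)}")
            if any(not 0 <= p <= 1 for p in probs):
                raise DomainError(f"{name} entries must be probabilities")
        if not 0 <= self.benign_given_biopsy <= 1:
            raise DomainError("benign_given_biopsy must be in [0, 1]")


@lru_cache(maxsize=32)
def _smoking_calibration(
    dur_mean: float,
    dur_sd: float,
    cig_mean: float,
    cig_sd: float,
    cig_min: float,
    pack_year_min: float,
) -> tuple[float, float]:
    """Location parameters whose *eligible* sub-population matches the
    published smoking means.

    The published duration and cigarettes/day statistics describe donors who
    are all screening-eligible (>= ``pack_year_min`` pack-years), so drawing
    from normals at the published locations and rejecting ineligible draws
    would inflate both means.  This solves, by fixed-point iteration over a
    truncated-normal product quadrature, for the underlying locations whose
    conditional-on-eligibility means equal the published values; the spreads
    stay at the published standard deviations.
    """
    from scipy.stats import norm

    def grid(loc: float, sd: float, lower: float, n: int = 601) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(max(lower, loc - 8 * sd), loc + 8 * sd, n)
        w = norm.pdf(x, loc, sd)
        return x, w / w.sum()

    loc_d, loc_c = dur_mean, cig_mean
    for _ in range(100):
        xd, wd = grid(loc_d, dur_sd, 0.0)
        xc, wc = grid(loc_c, cig_sd, cig_min)
        weight = np.outer(wd, wc)
        weight[np.outer(xd, xc) / 20.0 < pack_year_min] = 0.0
        weight /= weight.sum()
        m_d = float(weight.sum(axis=1) @ xd)
        m_c = float(weight.sum(axis=0) @ xc)
        if abs(m_d - dur_mean) < 1e-9 and abs(m_c - cig_mean) < 1e-9:
            break
        loc_d += dur_mean - m_d
        loc_c += cig_mean - m_c
    return loc_d, loc_c


def _draw_truncated(rng: np.random.Generator, loc: float, sd: float, lower: float) -> float:
    a = (lower - loc) / sd
    return float(truncnorm.rvs(a, np.inf, loc=loc, scale=sd, random_state=rng))


def sample_texture(rng: np.random.Generator, config: CohortConfig) -> m.TextureType:
    idx = rng.choice(3, p=config.texture_probs)
    return (m.TextureType.SOLID, m.TextureType.PART_SOLID, m.TextureType.NON_SOLID)[idx]


def sample_diameter(rng: np.random.Generator, config: CohortConfig) -> float:
    """Diameter from the published bin mixture with uniform within-bin draw."""
    idx = rng.choice(3, p=config.diameter_bin_probs)
    lo, hi = config.diameter_bin_ranges[idx]
    if idx == 0:
        # the [0,4) bin must stay strictly below 4 mm
        return float(rng.uniform(lo, np.nextafter(hi, lo)))
    return float(rng.uniform(lo, hi))


def sample_lobe(rng: np.random.Generator, config: CohortConfig) -> m.Lobe:
    idx = rng.choice(5, p=config.lobe_probs)
    return (m.Lobe.RUL, m.Lobe.RML, m.Lobe.RLL, m.Lobe.LUL, m.Lobe.LLL)[idx]


def sample_pathological_result(
    rng: np.random.Generator, config: CohortConfig
) -> m.PathologicalResult:
    if rng.random() < config.benign_given_biopsy:
        return m.PathologicalResult.BENIGN
    return m.PathologicalResult.MALIGNANT


@dataclass
class LesionState:
    """Ground-truth trajectory of one simulated lesion."""

    lesion_ref: str
    appeared_day: int
    d0_mm: float
    texture: m.TextureType
    lobe: m.Lobe
    coords_mm: tuple[float, float, float]
    malignant: bool
    vdt_days: float | None  # None: static
    observations: list[tuple[int, float]] = field(default_factory=list)
    diagnosed: bool = False
    #: set once a repeat scan has confirmed no fast growth; the lesion then
    #: returns to the annual schedule instead of re-triggering monitoring
    monitored_stable: bool = False

    def true_diameter(self, day: int) -> float:
        if self.vdt_days is None or day <= self.appeared_day:
            return self.d0_mm
        # volume doubles every vdt_days => diameter doubles every 3*vdt_days
        return self.d0_mm * 2.0 ** ((day - self.appeared_day) / (3.0 * self.vdt_days))


@dataclass
class DonorRecord:
    """One simulated donor: stored entities plus the (never-stored) identity
    used only to plant identifiers in raw DICOM files."""

    donor: m.SampleDonor
    identity: dict[str, str]
    age_years: int
    smoking_duration_years: float
    cigarettes_per_day: float
    history_event_id: str = ""
    recruitment_event_id: str = ""
    series_meta: list[dict[str, Any]] = field(default_factory=list)
    lesions: list[LesionState] = field(default_factory=list)


@dataclass
class SimulatedCohort:
    store: Store
    config: CohortConfig
    donors: list[DonorRecord]

    @property
    def planted_identifiers(self) -> list[str]:
        """All identity strings planted in raw DICOM (leak-scan needles)."""
        out: list[str] = []
        for d in self.donors:
            out.extend([d.identity["hospital_id"], *d.identity["name_parts"]])
            out.append(d.identity["birth_date_dicom"])
        return out


def _ensure_collections(store: Store) -> None:
    if not store._exists("collections", "collection_id", "imaging"):
        store.register(m.Collection("imaging", "Imaging Sample Collection", m.CollectionKind.IMAGING))
    if not store._exists("collections", "collection_id", "biological"):
        store.register(
            m.Collection("biological", "Biological Sample Collection", m.CollectionKind.BIOLOGICAL)
        )


def simulate_donor(
    config: CohortConfig,
    rng: np.random.Generator,
    index: int = 1,
    sex: m.Sex | str | None = None,
    store: Store | None = None,
) -> DonorRecord:
    """Draw one eligible donor with patient-history and recruitment events.

    Smoking duration is sex-stratified; eligibility (age >= 50, >= 20
    pack-years) is enforced by rejection sampling, so every emitted donor
    passes the screening eligibility check.  If ``store`` is given the donor
    and events are registered (recruitment wiring is added later by
    :func:`protocol.wire_workflow`).
    """
    sex = m.Sex(sex) if sex is not None else (
        m.Sex.F if rng.random() < config.sex_ratio_female else m.Sex.M
    )
    dur_mean, dur_sd = (
        config.smoking_duration_f if sex is m.Sex.F else config.smoking_duration_m
    )
    cig_mean, cig_sd = config.cigarettes_per_day
    loc_d, loc_c = _smoking_calibration(
        dur_mean, dur_sd, cig_mean, cig_sd, config.cigarettes_min,
        config.protocol.eligibility_min_pack_years,
    )
    age = int(rng.integers(config.enrollment_age_range[0], config.enrollment_age_range[1] + 1))
    while True:
        duration = _draw_truncated(rng, loc_d, dur_sd, 0.0)
        cigs = _draw_truncated(rng, loc_c, cig_sd, config.cigarettes_min)
        if proto.check_eligibility(age, proto.pack_years(cigs, duration), config.protocol):
            break

    year = int(rng.integers(config.enrollment_years[0], config.enrollment_years[1] + 1))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    enrollment = _dt.date(year, month, day)
    birth = _dt.date(enrollment.year - age, month, day)

    donor_id = f"D{index:05d}"
    pseudonym = f"P{index:04d}"
    donor = m.SampleDonor(
        donor_id=donor_id,
        pseudonym=pseudonym,
        sex=sex,
        age_range=age_to_range(age),
        enrollment_date=enrollment.isoformat(),
    )
    risk_types = [m.RiskType.SMOKING_HISTORY.value]
    if rng.random() < 0.20:
        risk_types.append(m.RiskType.RESPIRATORY_DISORDERS.value)
    if rng.random() < 0.10:
        risk_types.append(m.RiskType.ONCOLOGIC_HISTORY.value)
    if rng.random() < 0.15:
        risk_types.append(m.RiskType.CHEMICAL_EXPOSURE.value)

    history = m.Event(
        event_id=f"EV-hist-{donor_id}",
        donor_ref=donor_id,
        event_type=m.EventType.PATIENT_HISTORY,
        event_date=enrollment.isoformat(),
        attributes={
            "risk_types": sorted(risk_types),
            "smoking_duration_years": round(duration, 3),
            "cigarettes_per_day": round(cigs, 3),
        },
    )
    recruitment = m.Event(
        event_id=f"EV-recr-{donor_id}",
        donor_ref=donor_id,
        event_type=m.EventType.RECRUITMENT,
        event_date=enrollment.isoformat(),
        attributes={
            "eligibility_age_years": age,
            "eligibility_pack_years": round(proto.pack_years(cigs, duration), 3),
        },
    )
    given = f"DONOR{index:05d}"
    record = DonorRecord(
        donor=donor,
        identity={
            "name": f"SYNTHETIC^{given}",
            "name_parts": ["SYNTHETIC", given],
            "hospital_id": f"HOSP{index:06d}",
            "birth_date_dicom": birth.strftime("%Y%m%d"),
        },
        age_years=age,
        smoking_duration_years=duration,
        cigarettes_per_day=cigs,
        history_event_id=history.event_id,
        recruitment_event_id=recruitment.event_id,
    )
    if store is not None:
        store.register(donor)
        store.register(history)
        store.register(recruitment)
    return record


def _new_lesion(
    config: CohortConfig, rng: np.random.Generator, donor_id: str, idx: int, day: int
) -> LesionState:
    malignant = bool(rng.random() < config.p_malignant_lesion)
    if malignant:
        lo, hi = config.vdt_malignant_days
        vdt: float | None = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    elif rng.random() < config.p_benign_growing:
        lo, hi = config.vdt_benign_days
        vdt = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        vdt = None
    return LesionState(
        lesion_ref=f"L-{donor_id}-{idx:03d}",
        appeared_day=day,
        d0_mm=sample_diameter(rng, config),
        texture=sample_texture(rng, config),
        lobe=sample_lobe(rng, config),
        coords_mm=tuple(float(c) for c in rng.uniform(-150, 150, size=3)),
        malignant=malignant,
        vdt_days=vdt,
    )


def _sphere_volume(d_mm: float) -> float:
    return math.pi / 6.0 * d_mm**3


def simulate_screening(
    record: DonorRecord,
    config: CohortConfig,
    rng: np.random.Generator,
    store: Store,
) -> None:
    """Run one donor through the ten-year screening protocol.

    Schedules one baseline plus up to nine annual routine scans; per-visit
    nodules drive the triage rules, which insert 3/6-month monitoring
    follow-ups and, for lesions flagged high-suspicion at CT-PET, a biopsy
    with pathology outcome and unified diagnosis.  A malignant diagnosis
    exits the donor from further screening.  All events, samples, sub-events
    and causal implications are registered; the resulting donor subgraph
    passes the store validator.
    """
    _ensure_collections(store)
    donor_id = record.donor.donor_id
    pseudonym = record.donor.pseudonym
    enroll = _dt.date.fromisoformat(record.donor.enrollment_date)

    # (day, exam_type, monitoring depth); kept sorted by day
    schedule: list[tuple[int, m.ExamType, int]] = [(0, m.ExamType.BASELINE, 0)]
    schedule += [
        (365 * k, m.ExamType.ROUTINE_FOLLOWUP, 0) for k in range(1, config.study_years)
    ]
    scan_no = 0
    lesion_count = 0
    biopsy_count = 0
    exited = False

    while schedule and not exited:
        schedule.sort(key=lambda t: t[0])
        day, exam_type, depth = schedule.pop(0)
        scan_no += 1
        date = enroll + _dt.timedelta(days=day)
        acq_id = f"EV-acq-{donor_id}-{scan_no:02d}"
        store.register(
            m.Event(acq_id, donor_id, m.EventType.IMAGE_ACQUISITION, date.isoformat(),
                    {"exam_type": exam_type.value})
        )
        series_uid = f"{_UID_ROOT}.{donor_id[1:].lstrip('0') or '0'}.{scan_no}"
        study_uid = series_uid + ".0"
        thickness = float(rng.choice(config.slice_thickness_choices))
        meta = {
            "series_instance_uid": series_uid,
            "study_instance_uid": study_uid,
            "study_date": date.isoformat(),
            "modality": "CT",
            "tube_current_mA": float(rng.choice(config.tube_current_mA)),
            "kvp": float(rng.choice(config.kvp_choices)),
            "convolution_kernel": str(rng.choice(config.kernel_choices)),
            "slice_thickness_mm": thickness,
            "n_instances": config.n_slices,
            "patient_sex": record.donor.sex.value if record.donor.sex != m.Sex.UNKNOWN else "O",
            **record.identity,
        }
        record.series_meta.append(meta)
        sample = m.DICOMSeriesSample(
            sample_id=f"S-{series_uid}",
            donor_ref=donor_id,
            collection_ref="imaging",
            sample_kind=m.SampleKind.DIGITAL_IMAGING,
            series_instance_uid=series_uid,
            study_instance_uid=study_uid,
            study_date=date.isoformat(),
            modality="CT",
            tube_current_mA=meta["tube_current_mA"],
            kvp=meta["kvp"],
            convolution_kernel=meta["convolution_kernel"],
            slice_thickness_mm=thickness,
            n_instances=config.n_slices,
            storage_path=export_layout(pseudonym, date.isoformat(), series_uid),
        )
        store.register(sample)
        store.link_sample_event(sample.sample_id, acq_id)

        for _ in range(int(rng.poisson(config.nodule_incidence_per_visit))):
            lesion_count += 1
            record.lesions.append(_new_lesion(config, rng, donor_id, lesion_count, day))

        active = [l for l in record.lesions if not l.diagnosed]
        has_other = rng.random() < config.p_other_finding_per_visit
        if not active and not has_other:
            continue

        ana_id = f"EV-ana-{donor_id}-{scan_no:02d}"
        store.register(
            m.Event(ana_id, donor_id, m.EventType.IMAGING_ANALYSIS, date.isoformat())
        )
        if has_other:
            candidates = [t for t in m.OtherFindingType if t is not m.OtherFindingType.OTHER]
            ftype = candidates[int(rng.integers(len(candidates)))]
            store.register(
                m.other_finding(f"SUB-oth-{donor_id}-{scan_no:02d}", ana_id, ftype)
            )

        decisions: list[tuple[LesionState, proto.TriageDecision, float]] = []
        for les in active:
            measured = max(
                0.5,
                les.true_diameter(day) + float(rng.normal(0.0, config.measurement_noise_mm)),
            )
            les.observations.append((day, measured))
            store.register(
                m.nodule_finding(
                    subevent_id=f"SUB-nod-{les.lesion_ref}-{scan_no:02d}",
                    parent_event_ref=ana_id,
                    lesion_ref=les.lesion_ref,
                    diameter_mm=round(measured, 2),
                    texture_type=les.texture,
                    lobe=les.lobe,
                    lesion_coordinates_mm=les.coords_mm,
                    image_number=int(rng.integers(1, config.n_slices + 1)),
                )
            )
            vdt: float | None = None
            if len(les.observations) >= 2:
                (d1, diam1), (d2, diam2) = les.observations[-2], les.observations[-1]
                if d2 > d1:
                    vdt_val = proto.volume_doubling_time(
                        _sphere_volume(diam1), _sphere_volume(diam2), d2 - d1
                    )
                    vdt = None if math.isinf(vdt_val) else vdt_val
            decision = proto.triage_nodule(
                measured, vdt, pet_or_growth_high_suspicion=les.malignant,
                config=config.protocol,
            )
            if (
                exam_type is m.ExamType.MONITORING_FOLLOWUP
                and len(les.observations) >= 2
                and decision.action is proto.TriageAction.REPEAT_LDCT_3_6M
            ):
                les.monitored_stable = True
            decisions.append((les, decision, measured))

        workup = [d for d in decisions if d[1].action is proto.TriageAction.INVASIVE_WORKUP]
        repeats = [
            d for d in decisions
            if d[1].action is proto.TriageAction.REPEAT_LDCT_3_6M and not d[0].monitored_stable
        ]
        if workup:
            les, _, _ = max(workup, key=lambda t: t[2])
            biopsy_count += 1
            sampling_date = date + _dt.timedelta(days=30)
            samp_id = f"EV-biosamp-{donor_id}-{biopsy_count}"
            store.register(
                m.Event(samp_id, donor_id, m.EventType.BIOLOGICAL_SAMPLING,
                        sampling_date.isoformat(), {"procedure": "CT-guided biopsy"})
            )
            bio_sample = m.BiologicalSample(
                sample_id=f"BS-{donor_id}-{biopsy_count}",
                donor_ref=donor_id,
                collection_ref="biological",
                sample_kind=m.SampleKind.BIOLOGICAL,
                material_type="tissue",
                collection_procedure="CT-guided biopsy",
            )
            store.register(bio_sample)
            store.link_sample_event(bio_sample.sample_id, samp_id)
            result = sample_pathological_result(rng, config)
            bsa_date = sampling_date + _dt.timedelta(days=14)
            bsa_id = f"EV-bsa-{donor_id}-{biopsy_count}"
            store.register(
                m.Event(bsa_id, donor_id, m.EventType.BIOLOGICAL_SAMPLE_ANALYSIS,
                        bsa_date.isoformat(), {"pathological_result": result.value})
            )
            diag_date = bsa_date + _dt.timedelta(days=7)
            diag_attrs: dict[str, Any] = {"lesion_ref": les.lesion_ref}
            if result is m.PathologicalResult.MALIGNANT:
                diag_attrs["grade"] = int(rng.integers(1, 4))
            store.register(
                m.Event(f"EV-diag-{donor_id}-{biopsy_count}", donor_id,
                        m.EventType.DIAGNOSIS, diag_date.isoformat(), diag_attrs)
            )
            les.diagnosed = True
            if result is m.PathologicalResult.MALIGNANT:
                exited = True
        elif repeats and depth < config.protocol.max_monitoring_chain:
            _, _, diam = max(repeats, key=lambda t: t[2])
            months = proto.monitoring_interval_months(diam, config.protocol)
            follow_day = (proto.add_months(date, months) - enroll).days
            schedule.append((follow_day, m.ExamType.MONITORING_FOLLOWUP, depth + 1))

    proto.wire_workflow(donor_id, store)


def simulate_cohort(
    config: CohortConfig | None = None, seed: int = 0, store: Store | None = None
) -> SimulatedCohort:
    """Generate a full cohort into a store (in-memory unless given)."""
    config = config or CohortConfig()
    store = store or Store()
    rng = np.random.default_rng(seed)
    _ensure_collections(store)
    donors = []
    for i in range(1, config.n_donors + 1):
        rec = simulate_donor(config, rng, index=i, store=store)
        simulate_screening(rec, config, rng, store)
        donors.append(rec)
    return SimulatedCohort(store=store, config=config, donors=donors)


# -- DICOM fixture writing ---------------------------------------------------


def write_synthetic_dicom(
    series_meta: dict[str, Any], out_dir: str | Path, rng: np.random.Generator | None = None
) -> list[Path]:
    """Write one minimal multi-slice CT series with a planted identity.

    Pixel content is schematic (tiny deterministic gradient + noise grids);
    the headers carry the configured acquisition parameters and the donor's
    raw name/id/birth date plus a private tag, so that a pre-deid identifier
    scan finds them and the post-deid scan must not.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = rng or np.random.default_rng(abs(hash(series_meta["series_instance_uid"])) % 2**31)
    n = int(series_meta.get("n_instances", 4))
    size = int(series_meta.get("image_size", 32))
    study_date = str(series_meta["study_date"]).replace("-", "")
    paths: list[Path] = []
    for k in range(n):
        sop_uid = f"{series_meta['series_instance_uid']}.{k + 1}"
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.PatientName = series_meta["name"]
        ds.PatientID = series_meta["hospital_id"]
        ds.PatientBirthDate = series_meta["birth_date_dicom"]
        ds.PatientSex = series_meta.get("patient_sex", "O")
        ds.StudyDate = study_date
        ds.SeriesDate = study_date
        ds.StudyInstanceUID = series_meta["study_instance_uid"]
        ds.SeriesInstanceUID = series_meta["series_instance_uid"]
        ds.Modality = series_meta.get("modality", "CT")
        ds.KVP = series_meta.get("kvp", 120.0)
        ds.XRayTubeCurrent = int(series_meta.get("tube_current_mA", 30))
        ds.ConvolutionKernel = series_meta.get("convolution_kernel", "STANDARD")
        ds.SliceThickness = series_meta.get("slice_thickness_mm", 2.5)
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * float(ds.SliceThickness)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [0.7, 0.7]
        ds.Rows = ds.Columns = size
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        pix = (
            np.linspace(0, 1024, size * size).reshape(size, size)
            + rng.integers(0, 64, size=(size, size))
        ).astype(np.uint16)
        ds.PixelData = pix.tobytes()
        # private block carrying the raw id: must be stripped by deid
        block = ds.private_block(0x0011, "SYNTH-COHORT", create=True)
        block.add_new(0x01, "LO", series_meta["hospital_id"])
        p = out_dir / f"{sop_uid}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def write_cohort_dicom(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, list[Path]]:
    """Write every simulated series as raw (identified) DICOM files.

    Returns a mapping series UID → file paths, grouped so the
    de-identification step can be applied series by series.
    """
    out_dir = Path(out_dir)
    written: dict[str, list[Path]] = {}
    for rec in cohort.donors:
        for meta in rec.series_meta:
            sdir = out_dir / rec.identity["hospital_id"] / meta["series_instance_uid"]
            rng = np.random.default_rng(
                int(meta["series_instance_uid"].rsplit(".", 2)[-2] or 0) * 1000
                + int(meta["series_instance_uid"].rsplit(".", 1)[-1])
            )
            written[meta["series_instance_uid"]] = write_synthetic_dicom(meta, sdir, rng)
    return written


# -- bulk attribute populations (parameter-recovery harnesses) ---------------


def populate_nodule_findings(
    store: Store, n: int, config: CohortConfig, rng: np.random.Generator
) -> None:
    """Register ``n`` nodule findings drawn from the published mixtures.

    A single carrier donor and imaging-analysis event host the sub-events;
    this isolates the lesion-attribute distributions for parameter-recovery
    checks without running the full longitudinal simulation.
    """
    _ensure_collections(store)
    donor = m.SampleDonor("D-lesions", "P-lesions", m.Sex.UNKNOWN, "50-54", "2005-01-01")
    store.register(donor)
    ana = m.Event("EV-ana-lesions", donor.donor_id, m.EventType.IMAGING_ANALYSIS, "2005-01-01")
    store.register(ana)
    rows = []
    for i in range(n):
        rows.append(
            m.nodule_finding(
                subevent_id=f"SUB-nod-bulk-{i:06d}",
                parent_event_ref=ana.event_id,
                lesion_ref=f"L-bulk-{i:06d}",
                diameter_mm=round(sample_diameter(rng, config), 4),
                texture_type=sample_texture(rng, config),
                lobe=sample_lobe(rng, config),
            )
        )
    for r in rows:
        store.register(r)


def populate_biopsy_outcomes(
    store: Store, n: int, config: CohortConfig, rng: np.random.Generator
) -> None:
    """Register ``n`` biological-sample-analysis events with pathology
    outcomes drawn from the published benign-given-biopsy probability."""
    _ensure_collections(store)
    donor = m.SampleDonor("D-biopsies", "P-biopsies", m.Sex.UNKNOWN, "50-54", "2005-01-01")
    store.register(donor)
    for i in range(n):
        result = sample_pathological_result(rng, config)
        store.register(
            m.Event(
                f"EV-bsa-bulk-{i:06d}",
                donor.donor_id,
                m.EventType.BIOLOGICAL_SAMPLE_ANALYSIS,
                "2005-06-01",
                {"pathological_result": result.value},
            )
        )
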