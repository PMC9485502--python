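"""Pseudonymization and ingestion of DICOM series.

De-identification here is GDPR-style *pseudonymization*, not anonymization:
direct identifiers (patient name, institutional patient id) are replaced with
a subject-specific pseudonym kept in a separate ledger; the birth date is
masked indirectly as an age-range label; private tags are stripped; objects
with burned-in identifying pixel data (screenshots, dose reports) are dropped
from the export.  Study dates and instance UIDs are retained, because the
export folder layout keys on them (``pseudonym/study-date/series-uid``).

The pseudonym ledger is the re-identification key and is therefore a separate
artifact that must never travel with the de-identified output.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pydicom
from pydicom.dataset import Dataset

from . import model as m
from .errors import ConsistencyError, DeidRequiredError, DomainError, ReferentialError
from .store import Store

#: SOP classes whose pixel data routinely contains burned-in text.
SECONDARY_CAPTURE_SOP_CLASSES = (
    "1.2.840.10008.5.1.4.1.1.7",  # Secondary Capture (and its multi-frame family)
    "1.2.840.10008.5.1.4.1.1.7.1",
    "1.2.840.10008.5.1.4.1.1.7.2",
    "1.2.840.10008.5.1.4.1.1.7.3",
    "1.2.840.10008.5.1.4.1.1.7.4",
    "1.2.840.10008.5.1.4.1.1.88.67",  # X-Ray Radiation Dose SR
)

#: Identifier-bearing elements replaced or emptied beyond name/id/birth date.
DEFAULT_CLEAR_TAGS = (
    "AccessionNumber",
    "OtherPatientIDs",
    "PatientAddress",
    "PatientTelephoneNumbers",
    "ReferringPhysicianName",
    "InstitutionName",
    "InstitutionAddress",
)


@dataclass
class DeidPolicy:
    """Configuration of the pseudonymization recipe."""

    age_bin_width_years: int = 5
    burned_in_blocklist: tuple[str, ...] = ("secondary_capture", "dose_report")
    strip_private_tags: bool = True  # always on; kept explicit for the audit trail
    clear_tags: tuple[str, ...] = DEFAULT_CLEAR_TAGS
    remap_uids: bool = False

    def __post_init__(self) -> None:
        if self.age_bin_width_years < 1:
            raise DomainError("age_bin_width_years must be >= 1")
        if not self.burned_in_blocklist:
            raise DomainError("burned-in blocklist must be non-empty")


class PseudonymLedger:
    """Injective mapping original patient id → pseudonym.

    Once assigned, an id always maps to the same pseudonym.  The ledger is
    persisted as its own JSON file, separate from the de-identified output,
    and must never be co-exported with it.
    """

    def __init__(self, path: str | Path | None = None) -> None:
        self.path = Path(path) if path is not None else None
        self._map: dict[str, str] = {}
        self._created: dict[str, str] = {}
        if self.path is not None and self.path.exists():
            payload = json.loads(self.path.read_text())
            self._map = dict(payload["mapping"])
            self._created = dict(payload.get("created", {}))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self._map

    def pseudonym_for(self, patient_id: str) -> str:
        """Return (assigning if new) the pseudonym for a patient id."""
        pid = str(patient_id)
        if pid not in self._map:
            pseudonym = f"P{len(self._map) + 1:04d}"
            # injectivity: sequential assignment can never reuse a pseudonym
            assert pseudonym not in self._map.values()
            self._map[pid] = pseudonym
            self._created[pid] = _dt.datetime.now(_dt.timezone.utc).isoformat()
            self._save()
        return self._map[pid]

    def identifiers(self) -> list[str]:
        """All original identifiers known to the ledger (leak-scan keys)."""
        return sorted(self._map)

    def _save(self) -> None:
        if self.path is not None:
            self.path.write_text(
                json.dumps({"mapping": self._map, "created": self._created}, indent=1)
            )


def age_to_range(age_years: int, bin_width: int = 5) -> str:
    """Bin an exact age into its half-open ``[k*w, (k+1)*w)`` label.

    The label spells the inclusive integer range, e.g. ``age_to_range(52, 5)``
    → ``"50-54"``; a boundary age belongs to its own bin (50 → "50-54").
    """
    if bin_width < 1:
        raise DomainError("bin_width must be >= 1")
    if not 0 <= age_years <= 120:
        raise DomainError(f"age {age_years} outside [0, 120]")
    lo = (int(age_years) // bin_width) * bin_width
    return f"{lo}-{lo + bin_width - 1}"


_UNSAFE = re.compile(r"[^A-Za-z0-9._\-]")


def export_layout(pseudonym: str, study_date: str, series_uid: str) -> str:
    """Relative export path ``pseudonym/ISO-date/series-uid``.

    Pure function; path components are sanitized to filesystem-safe
    characters (anything else becomes ``_``).
    """
    parts = [pseudonym, str(study_date), series_uid]
    if not all(parts):
        raise DomainError("pseudonym, study_date and series_uid must be non-empty")
    return "/".join(_UNSAFE.sub("_", p) for p in parts)


def _is_blocklisted(ds: Dataset, policy: DeidPolicy) -> str | None:
    """Reason string if the object belongs to a burned-in category."""
    sop = str(getattr(ds, "SOPClassUID", ""))
    desc = str(getattr(ds, "SeriesDescription", "")).lower()
    if "secondary_capture" in policy.burned_in_blocklist:
        if sop in SECONDARY_CAPTURE_SOP_CLASSES or getattr(ds, "Modality", "") == "SC":
            return "secondary-capture object (burned-in risk)"
    if "dose_report" in policy.burned_in_blocklist:
        if "dose report" in desc or "dose_report" in desc:
            return "dose-report object (burned-in risk)"
    return None


def _age_at(ds: Dataset) -> int | None:
    birth = getattr(ds, "PatientBirthDate", "") or ""
    ref = getattr(ds, "StudyDate", "") or getattr(ds, "SeriesDate", "") or ""
    if len(birth) != 8 or len(ref) != 8:
        return None
    b = _dt.date(int(birth[:4]), int(birth[4:6]), int(birth[6:8]))
    r = _dt.date(int(ref[:4]), int(ref[4:6]), int(ref[6:8]))
    return r.year - b.year - ((r.month, r.day) < (b.month, b.day))


def pseudonymize_series(
    files: Sequence[str | Path],
    out_dir: str | Path,
    ledger: PseudonymLedger,
    policy: DeidPolicy | None = None,
) -> dict[str, Any]:
    """Write a de-identified copy of one series under the export layout.

    Returns an audit record: output paths, excluded files with reasons, the
    pseudonym used and the age-range written.  Pixel data of retained CT
    instances is untouched.  Running twice over the same input with the same
    ledger and policy yields byte-identical output.
    """
    policy = policy or DeidPolicy()
    out_dir = Path(out_dir)
    datasets: list[tuple[Path, Dataset]] = []
    for f in files:
        p = Path(f)
        try:
            ds = pydicom.dcmread(p)
        except Exception as exc:  # pragma: no cover - message path
            raise ConsistencyError(f"cannot parse DICOM file {p}: {exc}") from exc
        datasets.append((p, ds))
    if not datasets:
        raise DomainError("no input files")

    patient_ids = {str(ds.get("PatientID", "")) for _, ds in datasets}
    if len(patient_ids) != 1:
        raise ConsistencyError(f"mixed patient ids in one series: {sorted(patient_ids)}")
    original_id = patient_ids.pop()
    pseudonym = ledger.pseudonym_for(original_id)

    audit: dict[str, Any] = {
        "pseudonym": pseudonym,
        "outputs": [],
        "excluded": [],
        "age_range": None,
    }
    for path, ds in sorted(datasets, key=lambda t: str(t[0])):
        reason = _is_blocklisted(ds, policy)
        if reason is not None:
            audit["excluded"].append({"file": str(path), "reason": reason})
            continue
        age = _age_at(ds)
        if age is not None:
            audit["age_range"] = age_to_range(age, policy.age_bin_width_years)
        ds.PatientName = pseudonym
        ds.PatientID = pseudonym
        if "PatientBirthDate" in ds:
            ds.PatientBirthDate = ""
        if audit["age_range"] is not None:
            ds.PatientComments = f"age_range={audit['age_range']}"
        for tag in policy.clear_tags:
            if tag in ds:
                setattr(ds, tag, "")
        ds.remove_private_tags()
        ds.PatientIdentityRemoved = "NO"  # pseudonymized, not anonymized
        ds.DeidentificationMethod = (
            f"pseudonym;age-bin={policy.age_bin_width_years}y;no-private-tags"
        )
        study_date = str(getattr(ds, "StudyDate", "") or "19000101")
        iso = f"{study_date[:4]}-{study_date[4:6]}-{study_date[6:8]}"
        rel = export_layout(pseudonym, iso, str(ds.SeriesInstanceUID))
        dest_dir = out_dir / rel
        dest_dir.mkdir(parents=True, exist_ok=True)
        dest = dest_dir / f"{ds.SOPInstanceUID}.dcm"
        ds.save_as(dest, enforce_file_format=True)
        audit["outputs"].append(str(dest))
    return audit


def scan_for_identifiers(
    files: Iterable[str | Path], identifiers: Sequence[str]
) -> list[tuple[str, str, str]]:
    """Exhaustive element-value scan for identifier substrings.

    Every element of every dataset (including nested sequences) is rendered
    to text and searched for each identifier.  Returns (file, tag, needle)
    hits; an empty list certifies no leak of the given identifiers.
    """
    needles = [s for s in identifiers if s]
    hits: list[tuple[str, str, str]] = []

    def walk(ds: Dataset, fname: str) -> None:
        for elem in ds.iterall():
            if elem.VR == "SQ":
                continue  # items are covered by iterall
            text = str(elem.value)
            for needle in needles:
                if needle in text:
                    hits.append((fname, str(elem.tag), needle))

    for f in files:
        ds = pydicom.dcmread(f)
        walk(ds, str(f))
        walk(ds.file_meta, str(f))
    return hits


def _deid_gate(ds: Dataset, path: Path) -> None:
    if str(getattr(ds, "PatientBirthDate", "") or ""):
        raise DeidRequiredError(f"{path}: birth date still present; run deid first")
    for elem in ds.iterall():
        if elem.tag.is_private:
            raise DeidRequiredError(f"{path}: private tag {elem.tag} still present")


def ingest_series(
    series_dir: str | Path,
    store: Store,
    collection_id: str = "imaging",
    donor_id: str | None = None,
) -> str:
    """Record one de-identified series directory in the store.

    Header fields (modality, kVp, tube current, kernel, slice thickness,
    instance count) populate a DICOM-series sample row; the sample is linked
    to an image-acquisition event for that donor and study date, created if
    absent.  Ingesting the same directory twice is a no-op returning the
    existing sample id.  Input that still carries a birth date or private
    tags is refused.
    """
    series_dir = Path(series_dir)
    paths = sorted(series_dir.glob("*.dcm"))
    if not paths:
        raise DomainError(f"no DICOM files in {series_dir}")
    datasets = [pydicom.dcmread(p) for p in paths]
    for ds, p in zip(datasets, paths):
        _deid_gate(ds, p)
    ds0 = datasets[0]
    series_uid = str(ds0.SeriesInstanceUID)
    uids = {str(d.SeriesInstanceUID) for d in datasets}
    if uids != {series_uid}:
        raise ConsistencyError(f"multiple series UIDs in {series_dir}: {sorted(uids)}")

    existing = store._one(
        "SELECT sample_id FROM dicom_series WHERE series_instance_uid = ?", (series_uid,)
    )
    if existing is not None:
        return existing["sample_id"]

    pseudonym = str(ds0.PatientID)
    if donor_id is None:
        row = store._one("SELECT donor_id FROM donors WHERE pseudonym = ?", (pseudonym,))
        if row is None:
            raise ReferentialError(
                f"no registered donor with pseudonym {pseudonym!r}; register first"
            )
        donor_id = row["donor_id"]

    study_date = str(getattr(ds0, "StudyDate", "") or "19000101")
    iso_date = f"{study_date[:4]}-{study_date[4:6]}-{study_date[6:8]}"

    if not store._exists("collections", "collection_id", collection_id):
        store.register(
            m.Collection(collection_id, "Imaging Sample Collection", m.CollectionKind.IMAGING)
        )

    acq_row = store._one(
        "SELECT event_id FROM events WHERE donor_ref = ? AND event_type = ? AND event_date = ?",
        (donor_id, m.EventType.IMAGE_ACQUISITION.value, iso_date),
    )
    if acq_row is not None:
        acq_id = acq_row["event_id"]
    else:
        acq_id = f"EV-acq-{pseudonym}-{iso_date}"
        store.register(
            m.Event(acq_id, donor_id, m.EventType.IMAGE_ACQUISITION, iso_date)
        )

    sample = m.DICOMSeriesSample(
        sample_id=f"S-{series_uid}",
        donor_ref=donor_id,
        collection_ref=collection_id,
        sample_kind=m.SampleKind.DIGITAL_IMAGING,
        series_instance_uid=series_uid,
        study_instance_uid=str(getattr(ds0, "StudyInstanceUID", "")),
        study_date=iso_date,
        modality=str(getattr(ds0, "Modality", "")),
        tube_current_mA=float(getattr(ds0, "XRayTubeCurrent", 0) or 0) or None,
        kvp=float(getattr(ds0, "KVP", 0) or 0) or None,
        convolution_kernel=str(getattr(ds0, "ConvolutionKernel", "")),
        slice_thickness_mm=float(getattr(ds0, "SliceThickness", 0) or 0) or None,
        n_instances=len(datasets),
        storage_path=export_layout(pseudonym, iso_date, series_uid),
    )
    sample_id = store.register(sample)
    store.link_sample_event(sample_id, acq_id)
    return sample_id
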