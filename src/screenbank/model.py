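"""Domain types of the imaging-extended biobank data model.

The model keeps the three classic biobank components — sample donor, sample,
event — and adds two connective components: *sub-events* (children/products of
a parent event, e.g. a nodule annotation produced by an imaging-analysis
event) and *implications* (directed cause→effect links between events, e.g. a
suspicious imaging finding causing a biopsy).  The generic ``Sample`` carries
only a reduced core attribute set so that biological and digital-imaging
samples can live in the same repository; modality-specific attributes live on
the variants (``DICOMSeriesSample``, ``BiologicalSample``).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Sequence


class Sex(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class SampleKind(str, Enum):
    BIOLOGICAL = "BIOLOGICAL"
    DIGITAL_IMAGING = "DIGITAL_IMAGING"


class CollectionKind(str, Enum):
    BIOLOGICAL = "BIOLOGICAL"
    IMAGING = "IMAGING"


class EventType(str, Enum):
    RECRUITMENT = "RECRUITMENT"
    PATIENT_HISTORY = "PATIENT_HISTORY"
    IMAGE_ACQUISITION = "IMAGE_ACQUISITION"
    IMAGING_ANALYSIS = "IMAGING_ANALYSIS"
    BIOLOGICAL_SAMPLING = "BIOLOGICAL_SAMPLING"
    BIOLOGICAL_SAMPLE_ANALYSIS = "BIOLOGICAL_SAMPLE_ANALYSIS"
    DIAGNOSIS = "DIAGNOSIS"


class SubEventType(str, Enum):
    PULMONARY_NODULE_ID = "PULMONARY_NODULE_ID"
    OTHER_FINDING_ID = "OTHER_FINDING_ID"
    POST_PROCESSING = "POST_PROCESSING"


class ExamType(str, Enum):
    BASELINE = "BASELINE"
    ROUTINE_FOLLOWUP = "ROUTINE_FOLLOWUP"
    MONITORING_FOLLOWUP = "MONITORING_FOLLOWUP"


class RiskType(str, Enum):
    RESPIRATORY_DISORDERS = "respiratory_disorders"
    ONCOLOGIC_HISTORY = "oncologic_history"
    SMOKING_HISTORY = "smoking_history"
    CHEMICAL_EXPOSURE = "chemical_exposure"


class PathologicalResult(str, Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"
    INCONCLUSIVE = "inconclusive"


class TextureType(str, Enum):
    SOLID = "SOLID"
    PART_SOLID = "PART_SOLID"
    NON_SOLID = "NON_SOLID"


class Lobe(str, Enum):
    """Lung lobe codes: right upper/middle/lower, left upper/lower."""

    RUL = "RUL"
    RML = "RML"
    RLL = "RLL"
    LUL = "LUL"
    LLL = "LLL"


class RoiGenerationAlgorithm(str, Enum):
    MANUAL = "MANUAL"
    AUTOMATIC = "AUTOMATIC"


class OtherFindingType(str, Enum):
    EMPHYSEMA = "EMPHYSEMA"
    LYMPHADENOPATHY = "LYMPHADENOPATHY"
    APICAL_SCAR = "APICAL_SCAR"
    PLEURAL_THICKENING = "PLEURAL_THICKENING"
    PNEUMOTHORAX = "PNEUMOTHORAX"
    PNEUMONIA = "PNEUMONIA"
    OTHER = "OTHER"


#: Attribute keys admitted per event type.  The model deliberately restricts
#: event attributes to a declared registry so that extended attribute lists
#: can be added without a schema migration; call
#: :func:`register_event_attribute` to extend a type's vocabulary.
EVENT_ATTRIBUTE_REGISTRY: dict[EventType, set[str]] = {
    EventType.RECRUITMENT: {"eligibility_age_years", "eligibility_pack_years"},
    EventType.PATIENT_HISTORY: {
        "risk_types",
        "smoking_duration_years",
        "cigarettes_per_day",
    },
    EventType.IMAGE_ACQUISITION: {"exam_type"},
    EventType.IMAGING_ANALYSIS: {"report_text"},
    EventType.BIOLOGICAL_SAMPLING: {"procedure"},
    EventType.BIOLOGICAL_SAMPLE_ANALYSIS: {"pathological_result"},
    EventType.DIAGNOSIS: {"grade", "lesion_ref"},
}

SUBEVENT_ATTRIBUTE_REGISTRY: dict[SubEventType, set[str]] = {
    SubEventType.PULMONARY_NODULE_ID: {
        "diameter_mm",
        "texture_type",
        "lobe",
        "lesion_coordinates_mm",
        "location_type",
        "image_number",
    },
    SubEventType.OTHER_FINDING_ID: {"finding_type", "note"},
    SubEventType.POST_PROCESSING: {
        "roi_generation_algorithm",
        "volume_mm3",
        "seg_ref",
        "sr_ref",
    },
}


def register_event_attribute(event_type: EventType, key: str) -> None:
    """Extend the attribute vocabulary of an event type."""
    EVENT_ATTRIBUTE_REGISTRY[event_type].add(key)


def register_subevent_attribute(subevent_type: SubEventType, key: str) -> None:
    """Extend the attribute vocabulary of a sub-event type."""
    SUBEVENT_ATTRIBUTE_REGISTRY[subevent_type].add(key)


def _iso(d: _dt.date | str) -> str:
    if isinstance(d, _dt.date):
        return d.isoformat()
    return _dt.date.fromisoformat(str(d)).isoformat()


@dataclass
class SampleDonor:
    """A person sourcing biological and/or imaging samples.

    ``age_range`` is always a binned label (e.g. ``"50-54"``), never an exact
    birth date — the repository stores pseudonymized records only.
    """

    donor_id: str
    pseudonym: str
    sex: Sex = Sex.UNKNOWN
    age_range: str = ""
    enrollment_date: str = ""

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if self.enrollment_date:
            self.enrollment_date = _iso(self.enrollment_date)


@dataclass
class Collection:
    collection_id: str
    name: str
    kind: CollectionKind
    description: str = ""

    def __post_init__(self) -> None:
        self.kind = CollectionKind(self.kind)


@dataclass
class Sample:
    """Generic sample with the reduced core attribute set."""

    sample_id: str
    donor_ref: str
    collection_ref: str
    sample_kind: SampleKind
    acquisition_event_ref: str | None = None

    def __post_init__(self) -> None:
        self.sample_kind = SampleKind(self.sample_kind)


@dataclass
class DICOMSeriesSample(Sample):
    """Imaging-sample variant: one DICOM series of a CT study."""

    series_instance_uid: str = ""
    study_instance_uid: str = ""
    study_date: str = ""
    modality: str = "CT"
    tube_current_mA: float | None = None
    kvp: float | None = None
    convolution_kernel: str = ""
    slice_thickness_mm: float | None = None
    n_instances: int = 0
    storage_path: str = ""

    def __post_init__(self) -> None:
        self.sample_kind = SampleKind.DIGITAL_IMAGING
        if self.study_date:
            self.study_date = _iso(self.study_date)
        if self.slice_thickness_mm is not None and self.slice_thickness_mm <= 0:
            from .errors import DomainError

            raise DomainError(
                f"slice_thickness_mm must be > 0, got {self.slice_thickness_mm}"
            )


@dataclass
class BiologicalSample(Sample):
    """Biological-sample variant (tissue from an invasive procedure)."""

    material_type: str = ""
    collection_procedure: str = ""
    sampling_event_ref: str | None = None

    def __post_init__(self) -> None:
        self.sample_kind = SampleKind.BIOLOGICAL


@dataclass
class Event:
    """A timestamped occurrence linked to a donor and optionally samples."""

    event_id: str
    donor_ref: str
    event_type: EventType
    event_date: str
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_type = EventType(self.event_type)
        self.event_date = _iso(self.event_date)


@dataclass
class SubEvent:
    """A child/product of a parent event (e.g. one annotated finding)."""

    subevent_id: str
    parent_event_ref: str
    subevent_type: SubEventType
    lesion_ref: str | None = None
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subevent_type = SubEventType(self.subevent_type)


@dataclass
class Implication:
    """Directed cause→effect link between events.

    At least one cause and one effect are required; an event may participate
    in many implications or none.
    """

    implication_id: str
    cause_event_refs: Sequence[str]
    effect_event_refs: Sequence[str]
    label: str = ""

    def __post_init__(self) -> None:
        self.cause_event_refs = list(self.cause_event_refs)
        self.effect_event_refs = list(self.effect_event_refs)


def nodule_finding(
    subevent_id: str,
    parent_event_ref: str,
    lesion_ref: str,
    diameter_mm: float,
    texture_type: TextureType | str,
    lobe: Lobe | str,
    lesion_coordinates_mm: tuple[float, float, float] | None = None,
    location_type: str | None = None,
    image_number: int | None = None,
) -> SubEvent:
    """Build a pulmonary-nodule-identification sub-event.

    Attributes follow the Lung-RADS reporting vocabulary: ``diameter_mm``,
    texture class (solid / part-solid / non-solid), lung lobe, and the lesion
    coordinates in the patient reference frame.
    """
    from .errors import DomainError

    if diameter_mm <= 0:
        raise DomainError(f"diameter_mm must be > 0, got {diameter_mm}")
    attrs: dict[str, Any] = {
        "diameter_mm": float(diameter_mm),
        "texture_type": TextureType(texture_type).value,
        "lobe": Lobe(lobe).value,
    }
    if lesion_coordinates_mm is not None:
        attrs["lesion_coordinates_mm"] = [float(c) for c in lesion_coordinates_mm]
    if location_type is not None:
        attrs["location_type"] = location_type
    if image_number is not None:
        attrs["image_number"] = int(image_number)
    return SubEvent(
        subevent_id=subevent_id,
        parent_event_ref=parent_event_ref,
        subevent_type=SubEventType.PULMONARY_NODULE_ID,
        lesion_ref=lesion_ref,
        attributes=attrs,
    )


def other_finding(
    subevent_id: str,
    parent_event_ref: str,
    finding_type: OtherFindingType | str,
    note: str | None = None,
) -> SubEvent:
    """Build an other-finding-identification sub-event (non-nodule finding)."""
    from .errors import DomainError

    ftype = OtherFindingType(finding_type)
    if ftype is OtherFindingType.OTHER and not note:
        raise DomainError("finding_type OTHER requires a free-text note")
    attrs: dict[str, Any] = {"finding_type": ftype.value}
    if note:
        attrs["note"] = note
    return SubEvent(
        subevent_id=subevent_id,
        parent_event_ref=parent_event_ref,
        subevent_type=SubEventType.OTHER_FINDING_ID,
        attributes=attrs,
    )


def event_attributes_valid(event_type: EventType, attributes: Mapping[str, Any]) -> list[str]:
    """Return the attribute keys not admitted for ``event_type``."""
    allowed = EVENT_ATTRIBUTE_REGISTRY[EventType(event_type)]
    return sorted(set(attributes) - allowed)


def subevent_attributes_valid(
    subevent_type: SubEventType, attributes: Mapping[str, Any]
) -> list[str]:
    """Return the attribute keys not admitted for ``subevent_type``."""
    allowed = SUBEVENT_ATTRIBUTE_REGISTRY[SubEventType(subevent_type)]
    return sorted(set(attributes) - allowed)
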