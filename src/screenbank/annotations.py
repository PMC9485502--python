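"""Lesion annotation storage: segmentation objects, structured reports and
contour-derived volume.

Each lesion contour is serialized as a DICOM segmentation object (binary
voxel mask aligned to its source CT series) and described by a DICOM
structured report holding the measurement set (at minimum the volume in mm³)
plus references to both the segmentation and the source series.  A JSON
sidecar mirrors each SR; the sidecar is the normative representation for
round-trip checks, since no particular SR template is mandated.  The
measurements feed a post-processing sub-event that coexists with the
pulmonary-nodule-identification sub-event of the same lesion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import model as m
from .errors import DomainError, GeometryError, ReferentialError
from .store import Store

_SEG_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.66.4"  # Segmentation Storage
_SR_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.88.33"  # Comprehensive SR

#: Known measurement concepts (code value, scheme, meaning == name).
_KNOWN_CODES = {
    "volume": ("G-D705", "SRT", "volume"),
}
_LOCAL_SCHEME = "99SCREENBANK"


def compute_volume(mask: np.ndarray, voxel_spacing_mm: Sequence[float]) -> float:
    """Contour volume in mm³: foreground voxel count × voxel volume."""
    spacing = tuple(float(s) for s in voxel_spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise DomainError(f"voxel spacing must be 3 positive numbers, got {spacing}")
    mask = np.asarray(mask)
    n_fg = int(np.count_nonzero(mask))
    voxel_volume = spacing[0] * spacing[1] * spacing[2]
    return n_fg * voxel_volume


@dataclass
class StructuredReportRecord:
    """In-memory form of one measurement report."""

    sr_id: str
    referenced_series_uid: str
    referenced_seg_id: str
    measurements: list[dict[str, Any]] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for meas in self.measurements:
            if "unit" not in meas or not meas["unit"]:
                raise DomainError(f"measurement {meas.get('name')!r} has no unit")

    def to_json(self) -> dict[str, Any]:
        return {
            "sr_id": self.sr_id,
            "referenced_series_uid": self.referenced_series_uid,
            "referenced_seg_id": self.referenced_seg_id,
            "measurements": self.measurements,
            "metadata": self.metadata,
        }

    @classmethod
    def from_json(cls, payload: dict[str, Any]) -> "StructuredReportRecord":
        return cls(
            sr_id=payload["sr_id"],
            referenced_series_uid=payload["referenced_series_uid"],
            referenced_seg_id=payload["referenced_seg_id"],
            measurements=list(payload.get("measurements", [])),
            metadata=dict(payload.get("metadata", {})),
        )


def _file_dataset(sop_class: str, sop_instance: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    return ds


def write_seg(
    mask: np.ndarray,
    voxel_spacing_mm: Sequence[float],
    source_series_uid: str,
    lesion_ref: str,
    algorithm: m.RoiGenerationAlgorithm | str,
    path: str | Path,
    seg_uid: str | None = None,
) -> str:
    """Serialize a binary mask as a (minimal-profile) segmentation object.

    Frames are stored one byte per voxel along the slice axis; the profile
    is lossless and voxel-exact on round-trip.  Returns the SEG SOP instance
    UID, which serves as the seg_id.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise GeometryError(f"mask must be 3-D (slices, rows, cols), got shape {mask.shape}")
    sx, sy, sz = (float(s) for s in voxel_spacing_mm)
    if min(sx, sy, sz) <= 0:
        raise DomainError("voxel spacing must be strictly positive")
    seg_uid = seg_uid or generate_uid()
    ds = _file_dataset(_SEG_SOP_CLASS, seg_uid)
    ds.Modality = "SEG"
    ds.SeriesInstanceUID = generate_uid()
    ds.NumberOfFrames = int(mask.shape[0])
    ds.Rows, ds.Columns = int(mask.shape[1]), int(mask.shape[2])
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelSpacing = [sy, sx]
    ds.SpacingBetweenSlices = sz
    seq = Dataset()
    seq.SeriesInstanceUID = source_series_uid
    ds.ReferencedSeriesSequence = [seq]
    segment = Dataset()
    segment.SegmentNumber = 1
    segment.SegmentLabel = lesion_ref
    segment.SegmentAlgorithmType = m.RoiGenerationAlgorithm(algorithm).value
    ds.SegmentSequence = [segment]
    ds.PixelData = (mask != 0).astype(np.uint8).tobytes()
    ds.save_as(Path(path), enforce_file_format=True)
    return seg_uid


def read_seg(path: str | Path) -> dict[str, Any]:
    """Read a segmentation object back into mask + geometry + metadata."""
    ds = pydicom.dcmread(path)
    shape = (int(ds.NumberOfFrames), int(ds.Rows), int(ds.Columns))
    mask = np.frombuffer(ds.PixelData, dtype=np.uint8).reshape(shape).copy()
    sy, sx = (float(v) for v in ds.PixelSpacing)
    return {
        "seg_id": str(ds.SOPInstanceUID),
        "mask": mask,
        "voxel_spacing_mm": (sx, sy, float(ds.SpacingBetweenSlices)),
        "source_series_uid": str(ds.ReferencedSeriesSequence[0].SeriesInstanceUID),
        "lesion_ref": str(ds.SegmentSequence[0].SegmentLabel),
        "algorithm": str(ds.SegmentSequence[0].SegmentAlgorithmType),
    }


def _concept_code(name: str) -> tuple[str, str, str]:
    if name in _KNOWN_CODES:
        return _KNOWN_CODES[name]
    # short stable code value (SH VR caps at 16 chars); name kept as meaning
    digest = hashlib.sha1(name.encode()).hexdigest()[:10].upper()
    return (f"M{digest}", _LOCAL_SCHEME, name)


def _code_item(value: str, scheme: str, meaning: str) -> Dataset:
    c = Dataset()
    c.CodeValue = value
    c.CodingSchemeDesignator = scheme
    c.CodeMeaning = meaning
    return c


def write_sr(record: StructuredReportRecord, path: str | Path) -> str:
    """Serialize a measurement report as a structured-report object.

    The content tree is a single measurement group: a tracking-identifier
    TEXT item, UIDREF items for the source series and the segmentation, and
    one NUM item per measurement (units as code meaning).  A JSON sidecar
    with identical content is written next to the file.
    """
    ds = _file_dataset(_SR_SOP_CLASS, record.sr_id)
    ds.Modality = "SR"
    ds.SeriesInstanceUID = generate_uid()
    ds.ValueType = "CONTAINER"
    ds.ConceptNameCodeSequence = [
        _code_item("126000", "DCM", "Imaging Measurement Report")
    ]
    ds.ContinuityOfContent = "SEPARATE"
    content: list[Dataset] = []

    lesion = record.metadata.get("lesion_ref")
    if lesion:
        item = Dataset()
        item.RelationshipType = "HAS OBS CONTEXT"
        item.ValueType = "TEXT"
        item.ConceptNameCodeSequence = [_code_item("112039", "DCM", "Tracking Identifier")]
        item.TextValue = str(lesion)
        content.append(item)

    algo = record.metadata.get("algorithm")
    if algo:
        item = Dataset()
        item.RelationshipType = "HAS CONCEPT MOD"
        item.ValueType = "TEXT"
        item.ConceptNameCodeSequence = [
            _code_item("111001", "DCM", "Algorithm Name")
        ]
        item.TextValue = str(algo)
        content.append(item)

    for code, ref_name, uid in (
        ("SRCSERIES", "Source series for segmentation", record.referenced_series_uid),
        ("REFSEG", "Referenced segmentation", record.referenced_seg_id),
    ):
        item = Dataset()
        item.RelationshipType = "INFERRED FROM"
        item.ValueType = "UIDREF"
        item.ConceptNameCodeSequence = [_code_item(code, _LOCAL_SCHEME, ref_name)]
        item.UID = uid
        content.append(item)

    for meas in record.measurements:
        item = Dataset()
        item.RelationshipType = "CONTAINS"
        item.ValueType = "NUM"
        item.ConceptNameCodeSequence = [_code_item(*_concept_code(meas["name"]))]
        mv = Dataset()
        mv.NumericValue = f"{float(meas['value']):.10g}"  # DS caps at 16 chars
        mv.MeasurementUnitsCodeSequence = [
            _code_item(meas["unit"], "UCUM", meas["unit"])
        ]
        item.MeasuredValueSequence = [mv]
        content.append(item)
    ds.ContentSequence = content
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    path.with_suffix(".json").write_text(json.dumps(record.to_json(), indent=1))
    return record.sr_id


def read_sr(path: str | Path) -> StructuredReportRecord:
    """Parse a structured report back into a record.

    Unknown measurement names are preserved verbatim (the code meaning is
    the name).  A missing referenced-series item is a reference error; the
    record is otherwise parsed leniently.
    """
    ds = pydicom.dcmread(path)
    series_uid = ""
    seg_id = ""
    measurements: list[dict[str, Any]] = []
    metadata: dict[str, Any] = {}
    for item in getattr(ds, "ContentSequence", []):
        vt = getattr(item, "ValueType", "")
        name = item.ConceptNameCodeSequence[0].CodeMeaning
        if vt == "UIDREF":
            if "series" in name.lower():
                series_uid = str(item.UID)
            else:
                seg_id = str(item.UID)
        elif vt == "TEXT":
            if name == "Tracking Identifier":
                metadata["lesion_ref"] = str(item.TextValue)
            elif name == "Algorithm Name":
                metadata["algorithm"] = str(item.TextValue)
        elif vt == "NUM":
            mv = item.MeasuredValueSequence[0]
            measurements.append(
                {
                    "name": str(name),
                    "value": float(mv.NumericValue),
                    "unit": str(mv.MeasurementUnitsCodeSequence[0].CodeValue),
                }
            )
    if not series_uid:
        raise ReferentialError(f"{path}: structured report lacks a referenced series")
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        # the sidecar mirror is normative: full-precision values, free-form
        # metadata; the DICOM content tree is the interchange rendering
        payload = json.loads(sidecar.read_text())
        record = StructuredReportRecord.from_json(payload)
        record.metadata.update(metadata)
        return record
    return StructuredReportRecord(
        sr_id=str(ds.SOPInstanceUID),
        referenced_series_uid=series_uid,
        referenced_seg_id=seg_id,
        measurements=measurements,
        metadata=metadata,
    )


def resolve_sr_references(record: StructuredReportRecord, store: Store) -> str:
    """Link an SR record to the store; returns the source sample id.

    Parsing and linking are two phases: a report referencing an unknown
    series still parses, but fails here with a reference error.
    """
    row = store._one(
        "SELECT sample_id FROM dicom_series WHERE series_instance_uid = ?",
        (record.referenced_series_uid,),
    )
    if row is None:
        raise ReferentialError(
            f"SR {record.sr_id!r} references unknown series "
            f"{record.referenced_series_uid!r}"
        )
    return row["sample_id"]


def store_segmentation(
    mask: np.ndarray,
    voxel_spacing_mm: Sequence[float],
    source_sample_id: str,
    lesion_ref: str,
    algorithm: m.RoiGenerationAlgorithm | str,
    store: Store,
    artifacts_dir: str | Path,
    analysis_event_id: str | None = None,
) -> tuple[m.SubEvent, StructuredReportRecord]:
    """Persist a lesion contour: SEG + SR files plus a post-processing
    sub-event whose attributes mirror the SR content.

    The source series must already be ingested; the mask slice count must
    match the series instance count.  If the lesion has no
    pulmonary-nodule-identification sub-event yet, one is auto-created (its
    diameter taken as the volume-equivalent sphere diameter) so the two
    sub-events coexist.
    """
    algorithm = m.RoiGenerationAlgorithm(algorithm)
    row = store._one("SELECT * FROM dicom_series WHERE sample_id = ?", (source_sample_id,))
    if row is None:
        raise ReferentialError(f"series sample {source_sample_id!r} not ingested")
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise GeometryError(f"mask must be 3-D, got shape {mask.shape}")
    if row["n_instances"] and mask.shape[0] != row["n_instances"]:
        raise GeometryError(
            f"mask has {mask.shape[0]} slices but series has {row['n_instances']} instances"
        )
    srow = store._one("SELECT * FROM samples WHERE sample_id = ?", (source_sample_id,))
    donor_id = srow["donor_ref"]
    series_uid = row["series_instance_uid"]
    study_date = row["study_date"]

    if analysis_event_id is None:
        arow = store._one(
            "SELECT event_id FROM events WHERE donor_ref = ? AND event_type = ? "
            "AND event_date = ?",
            (donor_id, m.EventType.IMAGING_ANALYSIS.value, study_date),
        )
        if arow is not None:
            analysis_event_id = arow["event_id"]
        else:
            analysis_event_id = f"EV-ana-{source_sample_id}"
            store.register(
                m.Event(analysis_event_id, donor_id, m.EventType.IMAGING_ANALYSIS, study_date)
            )

    volume = compute_volume(mask, voxel_spacing_mm)

    nodule_exists = store._one(
        """SELECT s.subevent_id FROM subevents s JOIN events e
           ON e.event_id = s.parent_event_ref
           WHERE e.donor_ref = ? AND s.subevent_type = ? AND s.lesion_ref = ?""",
        (donor_id, m.SubEventType.PULMONARY_NODULE_ID.value, lesion_ref),
    )
    if nodule_exists is None:
        eq_diam = (6.0 * volume / np.pi) ** (1.0 / 3.0) if volume > 0 else 1.0
        store.register(
            m.nodule_finding(
                subevent_id=f"SUB-nod-{lesion_ref}-{analysis_event_id}",
                parent_event_ref=analysis_event_id,
                lesion_ref=lesion_ref,
                diameter_mm=max(eq_diam, 0.5),
                texture_type=m.TextureType.SOLID,
                lobe=m.Lobe.RUL,
            )
        )

    artifacts_dir = Path(artifacts_dir)
    artifacts_dir.mkdir(parents=True, exist_ok=True)
    seg_uid = generate_uid()
    seg_path = artifacts_dir / f"seg-{lesion_ref}-{seg_uid[-8:]}.dcm"
    write_seg(mask, voxel_spacing_mm, series_uid, lesion_ref, algorithm, seg_path, seg_uid)
    sr_uid = generate_uid()
    record = StructuredReportRecord(
        sr_id=sr_uid,
        referenced_series_uid=series_uid,
        referenced_seg_id=seg_uid,
        measurements=[{"name": "volume", "value": volume, "unit": "mm3"}],
        metadata={"lesion_ref": lesion_ref, "algorithm": algorithm.value},
    )
    sr_path = artifacts_dir / f"sr-{lesion_ref}-{sr_uid[-8:]}.dcm"
    write_sr(record, sr_path)

    sub = m.SubEvent(
        subevent_id=f"SUB-pp-{lesion_ref}-{seg_uid[-8:]}",
        parent_event_ref=analysis_event_id,
        subevent_type=m.SubEventType.POST_PROCESSING,
        lesion_ref=lesion_ref,
        attributes={
            "roi_generation_algorithm": algorithm.value,
            "volume_mm3": volume,
            "seg_ref": seg_uid,
            "sr_ref": sr_uid,
        },
    )
    store.register(sub)
    return sub, record


def mask_from_rtstruct_points(
    contours: Sequence[Sequence[tuple[float, float]]],
    slice_indices: Sequence[int],
    grid_shape: tuple[int, int, int],
    voxel_spacing_mm: Sequence[float],
) -> np.ndarray:
    """Rasterize planar contour point lists (RT-STRUCT style) into a mask.

    Each contour is a polygon of (x, y) points in mm on one slice; read-only
    conversion support for the alternative contour encoding.  Voxel centres
    inside the polygon (even-odd rule) are foreground.
    """
    sx, sy, _ = (float(s) for s in voxel_spacing_mm)
    nz, ny, nx = grid_shape
    mask = np.zeros(grid_shape, dtype=np.uint8)
    yy, xx = np.mgrid[0:ny, 0:nx]
    px = (xx + 0.5) * sx
    py = (yy + 0.5) * sy
    for poly, k in zip(contours, slice_indices):
        if not 0 <= k < nz:
            raise GeometryError(f"slice index {k} outside grid of {nz} slices")
        poly_arr = np.asarray(poly, dtype=float)
        inside = np.zeros((ny, nx), dtype=bool)
        n = len(poly_arr)
        for i in range(n):  # even-odd ray casting against each polygon edge
            x1, y1 = poly_arr[i]
            x2, y2 = poly_arr[(i + 1) % n]
            crosses = (y1 <= py) != (y2 <= py)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < xint)
        mask[k] |= inside.astype(np.uint8)
    return mask
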