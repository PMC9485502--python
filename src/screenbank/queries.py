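"""Aggregation queries and provenance tracing over a populated store.

``summarize`` reproduces the cohort-overview style tables: counts and
proportions over a categorical dimension (nodule texture, diameter bin,
lobe, exam type, pathology outcome) or grouped volume statistics per
segmentation modality.  ``trace_provenance`` walks the implication graph
backwards from a diagnosis to its root events.  All queries are pure reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import model as m
from .errors import DomainError, ReferentialError
from .store import Store

#: Fixed category orders for deterministic tables.
_CATEGORY_ORDER = {
    "texture": [t.value for t in m.TextureType],
    "lobe": [l.value for l in m.Lobe],
    "exam_type": [e.value for e in m.ExamType],
    "pathological_result": [p.value for p in m.PathologicalResult],
}

#: Diameter bins: [0, 4) mm, [4, 10] mm, (10, inf) mm.
DIAMETER_BIN_EDGES = (4.0, 10.0)
DIAMETER_BIN_LABELS = ("<4", "4-10", ">10")


def diameter_bin(diameter_mm: float, edges: tuple[float, float] = DIAMETER_BIN_EDGES) -> str:
    """Bin a diameter: strictly below the first edge, inclusive middle band,
    strictly above the second edge."""
    lo, hi = edges
    if diameter_mm < lo:
        return DIAMETER_BIN_LABELS[0]
    if diameter_mm <= hi:
        return DIAMETER_BIN_LABELS[1]
    return DIAMETER_BIN_LABELS[2]


def _subevent_attr_values(store: Store, subevent_type: m.SubEventType, key: str) -> list[Any]:
    rows = store._all(
        "SELECT attributes FROM subevents WHERE subevent_type = ? ORDER BY subevent_id",
        (subevent_type.value,),
    )
    return [json.loads(r["attributes"]).get(key) for r in rows]


def _event_attr_values(store: Store, event_type: m.EventType, key: str) -> list[Any]:
    rows = store._all(
        "SELECT attributes FROM events WHERE event_type = ? ORDER BY event_id",
        (event_type.value,),
    )
    return [json.loads(r["attributes"]).get(key) for r in rows]


def _proportion_table(values: list[Any], order: list[str], name: str) -> pd.DataFrame:
    counts = {cat: 0 for cat in order}
    for v in values:
        if v in counts:
            counts[v] += 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            name: order,
            "count": [counts[c] for c in order],
        }
    )
    df["proportion"] = df["count"] / total if total else 0.0
    return df


def summarize(store: Store, dimension: str) -> pd.DataFrame:
    """Cohort summary table over one dimension.

    Categorical dimensions (``texture``, ``diameter_bin``, ``lobe``,
    ``exam_type``, ``pathological_result``) return count + proportion rows in
    a fixed category order; ``modality_volume`` returns count/mean/sd/min/max
    of lesion volume per segmentation modality (manual vs automatic).
    """
    if dimension == "texture":
        vals = _subevent_attr_values(store, m.SubEventType.PULMONARY_NODULE_ID, "texture_type")
        return _proportion_table(vals, _CATEGORY_ORDER["texture"], "texture")
    if dimension == "diameter_bin":
        vals = _subevent_attr_values(store, m.SubEventType.PULMONARY_NODULE_ID, "diameter_mm")
        bins = [diameter_bin(v) for v in vals if v is not None]
        return _proportion_table(bins, list(DIAMETER_BIN_LABELS), "diameter_bin")
    if dimension == "lobe":
        vals = _subevent_attr_values(store, m.SubEventType.PULMONARY_NODULE_ID, "lobe")
        return _proportion_table(vals, _CATEGORY_ORDER["lobe"], "lobe")
    if dimension == "exam_type":
        vals = _event_attr_values(store, m.EventType.IMAGE_ACQUISITION, "exam_type")
        return _proportion_table(vals, _CATEGORY_ORDER["exam_type"], "exam_type")
    if dimension == "pathological_result":
        vals = _event_attr_values(
            store, m.EventType.BIOLOGICAL_SAMPLE_ANALYSIS, "pathological_result"
        )
        return _proportion_table(vals, _CATEGORY_ORDER["pathological_result"],
                                 "pathological_result")
    if dimension == "modality_volume":
        rows = store._all(
            "SELECT attributes FROM subevents WHERE subevent_type = ? ORDER BY subevent_id",
            (m.SubEventType.POST_PROCESSING.value,),
        )
        recs = [json.loads(r["attributes"]) for r in rows]
        out = []
        for algo in [a.value for a in m.RoiGenerationAlgorithm]:
            vols = np.array(
                [r["volume_mm3"] for r in recs if r.get("roi_generation_algorithm") == algo]
            )
            out.append(
                {
                    "modality": algo,
                    "count": int(vols.size),
                    "mean": float(vols.mean()) if vols.size else np.nan,
                    "sd": float(vols.std(ddof=1)) if vols.size > 1 else np.nan,
                    "min": float(vols.min()) if vols.size else np.nan,
                    "max": float(vols.max()) if vols.size else np.nan,
                }
            )
        return pd.DataFrame(out)
    raise DomainError(
        f"unknown dimension {dimension!r}; expected texture, diameter_bin, lobe, "
        "exam_type, pathological_result or modality_volume"
    )


def patient_history_summary(store: Store) -> pd.DataFrame:
    """Smoking-exposure statistics per donor sex.

    One row per sex with donor count and mean/sd of the smoking-history
    duration (years) and cigarettes/day carried by patient-history events.
    """
    rows = store._all(
        """SELECT d.sex AS sex, e.attributes AS attrs
           FROM events e JOIN donors d ON d.donor_id = e.donor_ref
           WHERE e.event_type = ? ORDER BY e.event_id""",
        (m.EventType.PATIENT_HISTORY.value,),
    )
    data: dict[str, dict[str, list[float]]] = {}
    for r in rows:
        attrs = json.loads(r["attrs"])
        bucket = data.setdefault(r["sex"], {"duration": [], "cigs": []})
        if attrs.get("smoking_duration_years") is not None:
            bucket["duration"].append(float(attrs["smoking_duration_years"]))
        if attrs.get("cigarettes_per_day") is not None:
            bucket["cigs"].append(float(attrs["cigarettes_per_day"]))
    out = []
    for sex in [s.value for s in m.Sex]:
        if sex not in data:
            continue
        dur = np.array(data[sex]["duration"])
        cig = np.array(data[sex]["cigs"])
        out.append(
            {
                "sex": sex,
                "n": int(dur.size),
                "duration_mean": float(dur.mean()) if dur.size else np.nan,
                "duration_sd": float(dur.std(ddof=1)) if dur.size > 1 else np.nan,
                "cigarettes_mean": float(cig.mean()) if cig.size else np.nan,
                "cigarettes_sd": float(cig.std(ddof=1)) if cig.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class ProvenanceTrace:
    """All cause paths from a diagnosis back to its root events."""

    diagnosis_id: str
    paths: tuple[tuple[str, ...], ...]  # each path: diagnosis ... root
    samples: tuple[str, ...]  # sample ids attached to events on any path

    @property
    def events(self) -> set[str]:
        return {e for p in self.paths for e in p}


def trace_provenance(diagnosis_event_id: str, store: Store) -> ProvenanceTrace:
    """Walk the implication graph backwards from a diagnosis event.

    Returns every cause path (depth-first, deterministic order) from the
    diagnosis to root events (those with no causes), plus the samples
    attached to any event on a path.  Paths are chronologically
    non-increasing walking backwards.
    """
    ev = store.get_event(diagnosis_event_id)
    if ev.event_type is not m.EventType.DIAGNOSIS:
        raise DomainError(f"event {diagnosis_event_id!r} is not a diagnosis event")

    reverse: dict[str, list[str]] = {}
    for cause, effect in store.implication_edges():
        reverse.setdefault(effect, []).append(cause)
    for causes in reverse.values():
        causes.sort()

    paths: list[tuple[str, ...]] = []

    def dfs(node: str, acc: list[str]) -> None:
        preds = reverse.get(node, [])
        if not preds:
            paths.append(tuple(acc))
            return
        for p in preds:
            if p in acc:  # cycle guard; a valid store is acyclic
                continue
            dfs(p, acc + [p])

    dfs(diagnosis_event_id, [diagnosis_event_id])

    on_path = {e for p in paths for e in p}
    sample_rows = store._all(
        "SELECT sample_id, acquisition_event_ref FROM samples "
        "WHERE acquisition_event_ref IS NOT NULL ORDER BY sample_id"
    )
    samples = tuple(
        r["sample_id"] for r in sample_rows if r["acquisition_event_ref"] in on_path
    )
    return ProvenanceTrace(
        diagnosis_id=diagnosis_event_id, paths=tuple(sorted(paths)), samples=samples
    )


def acquisition_partition_ok(store: Store) -> bool:
    """Check that exam types partition all acquisition events exactly."""
    table = summarize(store, "exam_type")
    total = store._one(
        "SELECT COUNT(*) AS n FROM events WHERE event_type = ?",
        (m.EventType.IMAGE_ACQUISITION.value,),
    )["n"]
    return int(table["count"].sum()) == total
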