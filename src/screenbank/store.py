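"""Embedded relational store for the extended biobank data model.

The store is a single SQLite database (file-backed or in-memory) with
declared foreign keys.  Writes go through :meth:`Store.register` /
:meth:`Store.link_sample_event` / :meth:`Store.add_implication`, which raise
typed errors on contract violations; :func:`validate_store` re-checks every
invariant by a full scan and returns violations as a report instead of
raising, so that imported or hand-edited stores can be audited.

Deletion of referenced entities is refused rather than cascaded: a provenance
repository must not silently lose causal chains.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import sqlite3
from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import networkx as nx

from . import model as m
from .errors import (
    CardinalityError,
    ChronologyError,
    ConflictError,
    CycleError,
    ReferentialError,
    ScreenbankError,
)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS donors (
    donor_id TEXT PRIMARY KEY,
    pseudonym TEXT NOT NULL UNIQUE,
    sex TEXT NOT NULL,
    age_range TEXT,
    enrollment_date TEXT
);
CREATE TABLE IF NOT EXISTS collections (
    collection_id TEXT PRIMARY KEY,
    name TEXT,
    kind TEXT NOT NULL,
    description TEXT
);
CREATE TABLE IF NOT EXISTS samples (
    sample_id TEXT PRIMARY KEY,
    donor_ref TEXT NOT NULL REFERENCES donors(donor_id),
    collection_ref TEXT NOT NULL REFERENCES collections(collection_id),
    sample_kind TEXT NOT NULL,
    acquisition_event_ref TEXT REFERENCES events(event_id)
);
CREATE TABLE IF NOT EXISTS dicom_series (
    sample_id TEXT PRIMARY KEY REFERENCES samples(sample_id),
    series_instance_uid TEXT UNIQUE,
    study_instance_uid TEXT,
    study_date TEXT,
    modality TEXT,
    tube_current_ma REAL,
    kvp REAL,
    convolution_kernel TEXT,
    slice_thickness_mm REAL,
    n_instances INTEGER,
    storage_path TEXT
);
CREATE TABLE IF NOT EXISTS biological_samples (
    sample_id TEXT PRIMARY KEY REFERENCES samples(sample_id),
    material_type TEXT,
    collection_procedure TEXT,
    sampling_event_ref TEXT REFERENCES events(event_id)
);
CREATE TABLE IF NOT EXISTS events (
    event_id TEXT PRIMARY KEY,
    donor_ref TEXT NOT NULL REFERENCES donors(donor_id),
    event_type TEXT NOT NULL,
    event_date TEXT NOT NULL,
    attributes TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS subevents (
    subevent_id TEXT PRIMARY KEY,
    parent_event_ref TEXT NOT NULL REFERENCES events(event_id),
    subevent_type TEXT NOT NULL,
    lesion_ref TEXT,
    attributes TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS implications (
    implication_id TEXT PRIMARY KEY,
    label TEXT
);
CREATE TABLE IF NOT EXISTS implication_causes (
    implication_id TEXT NOT NULL REFERENCES implications(implication_id),
    event_id TEXT NOT NULL REFERENCES events(event_id),
    UNIQUE (implication_id, event_id)
);
CREATE TABLE IF NOT EXISTS implication_effects (
    implication_id TEXT NOT NULL REFERENCES implications(implication_id),
    event_id TEXT NOT NULL REFERENCES events(event_id),
    UNIQUE (implication_id, event_id)
);
"""

_TABLES = (
    "donors",
    "collections",
    "samples",
    "dicom_series",
    "biological_samples",
    "events",
    "subevents",
    "implications",
    "implication_causes",
    "implication_effects",
)


@dataclass(frozen=True)
class Violation:
    """One violated invariant found by :func:`validate_store`."""

    entity_id: str
    rule_id: str
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {"entity_id": self.entity_id, "rule_id": self.rule_id, "message": self.message}
        )


class Store:
    """SQLite-backed repository of donors, samples, events and implications."""

    def __init__(self, path: str = ":memory:") -> None:
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.row_factory = sqlite3.Row
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- low-level helpers -------------------------------------------------

    def _one(self, sql: str, args: Sequence[Any] = ()) -> sqlite3.Row | None:
        return self._conn.execute(sql, args).fetchone()

    def _all(self, sql: str, args: Sequence[Any] = ()) -> list[sqlite3.Row]:
        return self._conn.execute(sql, args).fetchall()

    def _exists(self, table: str, key: str, value: str) -> bool:
        return self._one(f"SELECT 1 FROM {table} WHERE {key} = ?", (value,)) is not None

    def has_donor(self, donor_id: str) -> bool:
        return self._exists("donors", "donor_id", donor_id)

    def has_event(self, event_id: str) -> bool:
        return self._exists("events", "event_id", event_id)

    def has_sample(self, sample_id: str) -> bool:
        return self._exists("samples", "sample_id", sample_id)

    def get_event(self, event_id: str) -> m.Event:
        row = self._one("SELECT * FROM events WHERE event_id = ?", (event_id,))
        if row is None:
            raise ReferentialError(f"event {event_id!r} not found")
        return m.Event(
            event_id=row["event_id"],
            donor_ref=row["donor_ref"],
            event_type=m.EventType(row["event_type"]),
            event_date=row["event_date"],
            attributes=json.loads(row["attributes"]),
        )

    def get_donor(self, donor_id: str) -> m.SampleDonor:
        row = self._one("SELECT * FROM donors WHERE donor_id = ?", (donor_id,))
        if row is None:
            raise ReferentialError(f"donor {donor_id!r} not found")
        return m.SampleDonor(
            donor_id=row["donor_id"],
            pseudonym=row["pseudonym"],
            sex=m.Sex(row["sex"]),
            age_range=row["age_range"] or "",
            enrollment_date=row["enrollment_date"] or "",
        )

    def events_of_donor(self, donor_id: str, event_type: m.EventType | None = None) -> list[m.Event]:
        sql = "SELECT event_id FROM events WHERE donor_ref = ?"
        args: list[Any] = [donor_id]
        if event_type is not None:
            sql += " AND event_type = ?"
            args.append(m.EventType(event_type).value)
        sql += " ORDER BY event_date, event_id"
        return [self.get_event(r["event_id"]) for r in self._all(sql, args)]

    def subevents_of_event(self, event_id: str) -> list[m.SubEvent]:
        rows = self._all(
            "SELECT * FROM subevents WHERE parent_event_ref = ? ORDER BY subevent_id",
            (event_id,),
        )
        return [
            m.SubEvent(
                subevent_id=r["subevent_id"],
                parent_event_ref=r["parent_event_ref"],
                subevent_type=m.SubEventType(r["subevent_type"]),
                lesion_ref=r["lesion_ref"],
                attributes=json.loads(r["attributes"]),
            )
            for r in rows
        ]

    # -- registration ------------------------------------------------------

    def register(self, entity: Any) -> str:
        """Persist a domain record after checking its invariants.

        Returns the stored id.  Raises :class:`ConflictError` on duplicate
        unique keys and :class:`ReferentialError` on dangling references.
        """
        if isinstance(entity, m.SampleDonor):
            return self._register_donor(entity)
        if isinstance(entity, m.Collection):
            return self._register_collection(entity)
        if isinstance(entity, m.DICOMSeriesSample):
            return self._register_dicom_series(entity)
        if isinstance(entity, m.BiologicalSample):
            return self._register_biological_sample(entity)
        if isinstance(entity, m.Event):
            return self._register_event(entity)
        if isinstance(entity, m.SubEvent):
            return self._register_subevent(entity)
        if isinstance(entity, m.Implication):
            return self.add_implication(
                entity.cause_event_refs,
                entity.effect_event_refs,
                label=entity.label,
                implication_id=entity.implication_id,
            ).implication_id
        raise TypeError(f"cannot register entity of type {type(entity).__name__}")

    def _register_donor(self, d: m.SampleDonor) -> str:
        if self.has_donor(d.donor_id):
            raise ConflictError(f"donor id {d.donor_id!r} already registered")
        if self._exists("donors", "pseudonym", d.pseudonym):
            raise ConflictError(f"pseudonym {d.pseudonym!r} already in use")
        self._conn.execute(
            "INSERT INTO donors VALUES (?,?,?,?,?)",
            (d.donor_id, d.pseudonym, d.sex.value, d.age_range, d.enrollment_date),
        )
        self._conn.commit()
        return d.donor_id

    def _register_collection(self, c: m.Collection) -> str:
        if self._exists("collections", "collection_id", c.collection_id):
            raise ConflictError(f"collection {c.collection_id!r} already registered")
        self._conn.execute(
            "INSERT INTO collections VALUES (?,?,?,?)",
            (c.collection_id, c.name, c.kind.value, c.description),
        )
        self._conn.commit()
        return c.collection_id

    def _check_sample_core(self, s: m.Sample) -> None:
        if self.has_sample(s.sample_id):
            raise ConflictError(f"sample {s.sample_id!r} already registered")
        if not self.has_donor(s.donor_ref):
            raise ReferentialError(f"sample {s.sample_id!r}: donor {s.donor_ref!r} not found")
        col = self._one(
            "SELECT kind FROM collections WHERE collection_id = ?", (s.collection_ref,)
        )
        if col is None:
            raise ReferentialError(
                f"sample {s.sample_id!r}: collection {s.collection_ref!r} not found"
            )
        expected = (
            m.CollectionKind.IMAGING
            if s.sample_kind is m.SampleKind.DIGITAL_IMAGING
            else m.CollectionKind.BIOLOGICAL
        )
        if col["kind"] != expected.value:
            raise CardinalityError(
                f"sample {s.sample_id!r} of kind {s.sample_kind.value} cannot join "
                f"collection of kind {col['kind']}"
            )
        if s.acquisition_event_ref is not None and not self.has_event(s.acquisition_event_ref):
            raise ReferentialError(
                f"sample {s.sample_id!r}: acquisition event "
                f"{s.acquisition_event_ref!r} not found"
            )

    def _insert_sample_row(self, s: m.Sample) -> None:
        self._conn.execute(
            "INSERT INTO samples VALUES (?,?,?,?,?)",
            (
                s.sample_id,
                s.donor_ref,
                s.collection_ref,
                s.sample_kind.value,
                s.acquisition_event_ref,
            ),
        )

    def _register_dicom_series(self, s: m.DICOMSeriesSample) -> str:
        self._check_sample_core(s)
        if self._exists("dicom_series", "series_instance_uid", s.series_instance_uid):
            raise ConflictError(f"series UID {s.series_instance_uid!r} already registered")
        self._insert_sample_row(s)
        self._conn.execute(
            "INSERT INTO dicom_series VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            (
                s.sample_id,
                s.series_instance_uid,
                s.study_instance_uid,
                s.study_date,
                s.modality,
                s.tube_current_mA,
                s.kvp,
                s.convolution_kernel,
                s.slice_thickness_mm,
                s.n_instances,
                s.storage_path,
            ),
        )
        self._conn.commit()
        return s.sample_id

    def _register_biological_sample(self, s: m.BiologicalSample) -> str:
        self._check_sample_core(s)
        if s.sampling_event_ref is not None:
            ev = self._one(
                "SELECT event_type FROM events WHERE event_id = ?", (s.sampling_event_ref,)
            )
            if ev is None:
                raise ReferentialError(
                    f"sample {s.sample_id!r}: sampling event {s.sampling_event_ref!r} not found"
                )
            if ev["event_type"] != m.EventType.BIOLOGICAL_SAMPLING.value:
                raise CardinalityError(
                    f"sample {s.sample_id!r}: sampling_event_ref must be a "
                    f"BIOLOGICAL_SAMPLING event, got {ev['event_type']}"
                )
        self._insert_sample_row(s)
        self._conn.execute(
            "INSERT INTO biological_samples VALUES (?,?,?,?)",
            (s.sample_id, s.material_type, s.collection_procedure, s.sampling_event_ref),
        )
        self._conn.commit()
        return s.sample_id

    def _register_event(self, e: m.Event) -> str:
        if self.has_event(e.event_id):
            raise ConflictError(f"event {e.event_id!r} already registered")
        if not self.has_donor(e.donor_ref):
            raise ReferentialError(f"event {e.event_id!r}: donor {e.donor_ref!r} not found")
        bad = m.event_attributes_valid(e.event_type, e.attributes)
        if bad:
            raise ScreenbankError(
                f"event {e.event_id!r}: attributes {bad} not admitted for "
                f"type {e.event_type.value}"
            )
        self._conn.execute(
            "INSERT INTO events VALUES (?,?,?,?,?)",
            (
                e.event_id,
                e.donor_ref,
                e.event_type.value,
                e.event_date,
                json.dumps(e.attributes, sort_keys=True),
            ),
        )
        self._conn.commit()
        return e.event_id

    def _register_subevent(self, s: m.SubEvent) -> str:
        if self._exists("subevents", "subevent_id", s.subevent_id):
            raise ConflictError(f"sub-event {s.subevent_id!r} already registered")
        if not self.has_event(s.parent_event_ref):
            raise ReferentialError(
                f"sub-event {s.subevent_id!r}: parent event {s.parent_event_ref!r} not found"
            )
        bad = m.subevent_attributes_valid(s.subevent_type, s.attributes)
        if bad:
            raise ScreenbankError(
                f"sub-event {s.subevent_id!r}: attributes {bad} not admitted for "
                f"type {s.subevent_type.value}"
            )
        self._conn.execute(
            "INSERT INTO subevents VALUES (?,?,?,?,?)",
            (
                s.subevent_id,
                s.parent_event_ref,
                s.subevent_type.value,
                s.lesion_ref,
                json.dumps(s.attributes, sort_keys=True),
            ),
        )
        self._conn.commit()
        return s.subevent_id

    # -- sample/event linkage ----------------------------------------------

    def link_sample_event(self, sample_id: str, event_id: str) -> tuple[str, str]:
        """Attach a sample to its acquisition/sampling event.

        Many samples may share one event; a sample gains at most one such
        event; events with zero samples remain valid.
        """
        srow = self._one("SELECT * FROM samples WHERE sample_id = ?", (sample_id,))
        if srow is None:
            raise ReferentialError(f"sample {sample_id!r} not found")
        erow = self._one("SELECT * FROM events WHERE event_id = ?", (event_id,))
        if erow is None:
            raise ReferentialError(f"event {event_id!r} not found")
        kind = m.SampleKind(srow["sample_kind"])
        required = (
            m.EventType.IMAGE_ACQUISITION
            if kind is m.SampleKind.DIGITAL_IMAGING
            else m.EventType.BIOLOGICAL_SAMPLING
        )
        if erow["event_type"] != required.value:
            raise CardinalityError(
                f"sample {sample_id!r} ({kind.value}) requires a {required.value} "
                f"event, got {erow['event_type']}"
            )
        current = srow["acquisition_event_ref"]
        if current is not None and current != event_id:
            raise CardinalityError(
                f"sample {sample_id!r} already linked to acquisition event {current!r}"
            )
        self._conn.execute(
            "UPDATE samples SET acquisition_event_ref = ? WHERE sample_id = ?",
            (event_id, sample_id),
        )
        if kind is m.SampleKind.BIOLOGICAL:
            self._conn.execute(
                "UPDATE biological_samples SET sampling_event_ref = ? WHERE sample_id = ?",
                (event_id, sample_id),
            )
        self._conn.commit()
        return (sample_id, event_id)

    # -- implications -------------------------------------------------------

    def implication_edges(self) -> list[tuple[str, str]]:
        """All cause→effect event-id pairs implied by stored implications."""
        rows = self._all(
            """SELECT c.event_id AS cause, e.event_id AS effect
               FROM implication_causes c
               JOIN implication_effects e ON c.implication_id = e.implication_id
               ORDER BY c.implication_id, cause, effect"""
        )
        return [(r["cause"], r["effect"]) for r in rows]

    def implications(self) -> list[m.Implication]:
        out = []
        for row in self._all("SELECT * FROM implications ORDER BY implication_id"):
            iid = row["implication_id"]
            causes = [
                r["event_id"]
                for r in self._all(
                    "SELECT event_id FROM implication_causes WHERE implication_id = ? "
                    "ORDER BY event_id",
                    (iid,),
                )
            ]
            effects = [
                r["event_id"]
                for r in self._all(
                    "SELECT event_id FROM implication_effects WHERE implication_id = ? "
                    "ORDER BY event_id",
                    (iid,),
                )
            ]
            out.append(m.Implication(iid, causes, effects, label=row["label"] or ""))
        return out

    def causes_of(self, event_id: str) -> list[tuple[str, m.Event]]:
        """(label, cause event) pairs for implications having this effect."""
        rows = self._all(
            """SELECT i.label AS label, c.event_id AS cause
               FROM implication_effects e
               JOIN implications i ON i.implication_id = e.implication_id
               JOIN implication_causes c ON c.implication_id = e.implication_id
               WHERE e.event_id = ? ORDER BY c.event_id""",
            (event_id,),
        )
        return [(r["label"], self.get_event(r["cause"])) for r in rows]

    def add_implication(
        self,
        cause_ids: Iterable[str],
        effect_ids: Iterable[str],
        label: str = "",
        implication_id: str | None = None,
    ) -> m.Implication:
        """Store a cause→effect implication, keeping the global graph acyclic."""
        causes = list(cause_ids)
        effects = list(effect_ids)
        if not causes or not effects:
            raise CardinalityError("an implication needs >= 1 cause and >= 1 effect")
        if set(causes) & set(effects):
            raise CardinalityError(
                "an event cannot be both cause and effect of the same implication"
            )
        cause_events = [self.get_event(c) for c in causes]
        effect_events = [self.get_event(e) for e in effects]
        for ce in cause_events:
            for ee in effect_events:
                if ce.event_date > ee.event_date:
                    raise ChronologyError(
                        f"cause {ce.event_id!r} ({ce.event_date}) dated after "
                        f"effect {ee.event_id!r} ({ee.event_date})"
                    )
        g = nx.DiGraph(self.implication_edges())
        g.add_edges_from((c, e) for c in causes for e in effects)
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError("implication would introduce a cause-effect cycle")
        if implication_id is None:
            n = self._one("SELECT COUNT(*) AS n FROM implications")["n"]
            implication_id = f"I{n + 1:06d}"
        if self._exists("implications", "implication_id", implication_id):
            raise ConflictError(f"implication {implication_id!r} already registered")
        self._conn.execute(
            "INSERT INTO implications VALUES (?,?)", (implication_id, label)
        )
        self._conn.executemany(
            "INSERT INTO implication_causes VALUES (?,?)",
            [(implication_id, c) for c in causes],
        )
        self._conn.executemany(
            "INSERT INTO implication_effects VALUES (?,?)",
            [(implication_id, e) for e in effects],
        )
        self._conn.commit()
        return m.Implication(implication_id, causes, effects, label=label)

    # -- deletion (refused when referenced) ---------------------------------

    def delete_event(self, event_id: str) -> None:
        """Delete an event; refused if anything references it."""
        if not self.has_event(event_id):
            raise ReferentialError(f"event {event_id!r} not found")
        referenced = (
            self._one("SELECT 1 FROM subevents WHERE parent_event_ref = ?", (event_id,))
            or self._one("SELECT 1 FROM samples WHERE acquisition_event_ref = ?", (event_id,))
            or self._one(
                "SELECT 1 FROM biological_samples WHERE sampling_event_ref = ?", (event_id,)
            )
            or self._one("SELECT 1 FROM implication_causes WHERE event_id = ?", (event_id,))
            or self._one("SELECT 1 FROM implication_effects WHERE event_id = ?", (event_id,))
        )
        if referenced:
            raise CardinalityError(
                f"event {event_id!r} is referenced and cannot be deleted"
            )
        self._conn.execute("DELETE FROM events WHERE event_id = ?", (event_id,))
        self._conn.commit()

    # -- export / import ----------------------------------------------------

    def export_json(self) -> dict[str, list[dict[str, Any]]]:
        """Dump the full entity graph as plain dicts (stable ordering)."""
        out: dict[str, list[dict[str, Any]]] = {}
        for table in _TABLES:
            pk = self._conn.execute(f"SELECT * FROM {table} LIMIT 0").description
            cols = [c[0] for c in pk]
            order = ", ".join(cols)
            rows = self._all(f"SELECT * FROM {table} ORDER BY {order}")
            out[table] = [dict(zip(cols, tuple(r))) for r in rows]
        return out

    def export_json_str(self) -> str:
        return json.dumps(self.export_json(), sort_keys=True, indent=1)

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON export (determinism checks)."""
        return hashlib.sha256(self.export_json_str().encode()).hexdigest()

    @classmethod
    def import_json(cls, payload: dict[str, list[dict[str, Any]]], path: str = ":memory:") -> "Store":
        """Rebuild a store from an exported entity graph.

        Rows are inserted verbatim (no contract checks) so that a defective
        export can be audited afterwards with :func:`validate_store`.
        """
        store = cls(path)
        for table in _TABLES:
            for row in payload.get(table, []):
                cols = list(row)
                sql = (
                    f"INSERT INTO {table} ({', '.join(cols)}) "
                    f"VALUES ({', '.join('?' for _ in cols)})"
                )
                store._conn.execute(sql, [row[c] for c in cols])
        store._conn.commit()
        return store


# -- validation --------------------------------------------------------------


def _parse_date(s: str) -> _dt.date | None:
    try:
        return _dt.date.fromisoformat(s)
    except (TypeError, ValueError):
        return None


def validate_store(store: Store) -> list[Violation]:
    """Full-scan audit of every model invariant.

    Violations are reported, never thrown; an empty report means the store
    satisfies all referential, cardinality, chronology and acyclicity rules.
    The function is a pure read: it is idempotent and leaves the store
    untouched.
    """
    v: list[Violation] = []
    donors = {r["donor_id"] for r in store._all("SELECT donor_id FROM donors")}
    collections = {
        r["collection_id"]: r["kind"]
        for r in store._all("SELECT collection_id, kind FROM collections")
    }
    events = {r["event_id"]: r for r in store._all("SELECT * FROM events")}

    seen_pseud: dict[str, str] = {}
    for r in store._all("SELECT donor_id, pseudonym FROM donors"):
        if r["pseudonym"] in seen_pseud:
            v.append(
                Violation(r["donor_id"], "donor.pseudonym-unique",
                          f"pseudonym {r['pseudonym']!r} also used by {seen_pseud[r['pseudonym']]!r}")
            )
        seen_pseud[r["pseudonym"]] = r["donor_id"]

    # samples
    for r in store._all("SELECT * FROM samples"):
        sid = r["sample_id"]
        if r["donor_ref"] not in donors:
            v.append(Violation(sid, "sample.donor-resolves",
                               f"donor {r['donor_ref']!r} not found"))
        kind = r["sample_kind"]
        ckind = collections.get(r["collection_ref"])
        if ckind is None:
            v.append(Violation(sid, "sample.collection-resolves",
                               f"collection {r['collection_ref']!r} not found"))
        else:
            expected = "IMAGING" if kind == "DIGITAL_IMAGING" else "BIOLOGICAL"
            if ckind != expected:
                v.append(Violation(sid, "sample.collection-kind",
                                   f"{kind} sample in {ckind} collection"))
        aref = r["acquisition_event_ref"]
        if aref is not None:
            erow = events.get(aref)
            if erow is None:
                v.append(Violation(sid, "sample.acquisition-resolves",
                                   f"acquisition event {aref!r} not found"))
            else:
                required = (
                    "IMAGE_ACQUISITION" if kind == "DIGITAL_IMAGING" else "BIOLOGICAL_SAMPLING"
                )
                if erow["event_type"] != required:
                    v.append(Violation(sid, "sample.acquisition-type",
                                       f"linked event is {erow['event_type']}, expected {required}"))

    seen_uid: dict[str, str] = {}
    for r in store._all("SELECT * FROM dicom_series"):
        sid = r["sample_id"]
        uid = r["series_instance_uid"]
        if uid in seen_uid:
            v.append(Violation(sid, "series.uid-unique",
                               f"series UID {uid!r} also used by {seen_uid[uid]!r}"))
        seen_uid[uid] = sid
        if r["slice_thickness_mm"] is not None and r["slice_thickness_mm"] <= 0:
            v.append(Violation(sid, "series.thickness-positive",
                               f"slice_thickness_mm = {r['slice_thickness_mm']}"))

    for r in store._all("SELECT * FROM biological_samples"):
        sid = r["sample_id"]
        sref = r["sampling_event_ref"]
        if sref is not None:
            erow = events.get(sref)
            if erow is None:
                v.append(Violation(sid, "biosample.sampling-resolves",
                                   f"sampling event {sref!r} not found"))
            elif erow["event_type"] != "BIOLOGICAL_SAMPLING":
                v.append(Violation(sid, "biosample.sampling-type",
                                   f"sampling event is {erow['event_type']}"))

    # events
    for eid, r in events.items():
        if r["donor_ref"] not in donors:
            v.append(Violation(eid, "event.donor-resolves",
                               f"donor {r['donor_ref']!r} not found"))
        if _parse_date(r["event_date"]) is None:
            v.append(Violation(eid, "event.date-valid",
                               f"event_date {r['event_date']!r} not an ISO date"))
        try:
            etype = m.EventType(r["event_type"])
        except ValueError:
            v.append(Violation(eid, "event.type-known", f"unknown type {r['event_type']!r}"))
            continue
        bad = m.event_attributes_valid(etype, json.loads(r["attributes"]))
        if bad:
            v.append(Violation(eid, "event.attrs-admitted",
                               f"attributes {bad} not admitted for {etype.value}"))

    # sub-events; collect nodule lesion identities per parent analysis event
    nodule_lesions: set[tuple[str, str]] = set()  # (donor, lesion_ref)
    postproc: list[sqlite3.Row] = []
    for r in store._all("SELECT * FROM subevents"):
        sid = r["subevent_id"]
        parent = events.get(r["parent_event_ref"])
        if parent is None:
            v.append(Violation(sid, "subevent.parent-resolves",
                               f"parent event {r['parent_event_ref']!r} not found"))
            continue
        try:
            stype = m.SubEventType(r["subevent_type"])
        except ValueError:
            v.append(Violation(sid, "subevent.type-known",
                               f"unknown type {r['subevent_type']!r}"))
            continue
        bad = m.subevent_attributes_valid(stype, json.loads(r["attributes"]))
        if bad:
            v.append(Violation(sid, "subevent.attrs-admitted",
                               f"attributes {bad} not admitted for {stype.value}"))
        if stype is m.SubEventType.PULMONARY_NODULE_ID and r["lesion_ref"]:
            nodule_lesions.add((parent["donor_ref"], r["lesion_ref"]))
        if stype is m.SubEventType.POST_PROCESSING:
            postproc.append(r)

    for r in postproc:
        parent = events.get(r["parent_event_ref"])
        if parent is None:
            continue
        key = (parent["donor_ref"], r["lesion_ref"])
        if r["lesion_ref"] is None or key not in nodule_lesions:
            v.append(Violation(r["subevent_id"], "postproc.paired-nodule",
                               "post-processing sub-event has no pulmonary-nodule "
                               f"identification for lesion {r['lesion_ref']!r}"))

    # implications
    impls = store.implications()
    for imp in impls:
        iid = imp.implication_id
        if not imp.cause_event_refs or not imp.effect_event_refs:
            v.append(Violation(iid, "implication.cardinality",
                               "needs >= 1 cause and >= 1 effect"))
        overlap = set(imp.cause_event_refs) & set(imp.effect_event_refs)
        if overlap:
            v.append(Violation(iid, "implication.disjoint",
                               f"events {sorted(overlap)} are both cause and effect"))
        for c in imp.cause_event_refs:
            if c not in events:
                v.append(Violation(iid, "implication.cause-resolves",
                                   f"cause event {c!r} not found"))
        for e in imp.effect_event_refs:
            if e not in events:
                v.append(Violation(iid, "implication.effect-resolves",
                                   f"effect event {e!r} not found"))
        for c in imp.cause_event_refs:
            for e in imp.effect_event_refs:
                if c in events and e in events:
                    if events[c]["event_date"] > events[e]["event_date"]:
                        v.append(Violation(iid, "implication.chronology",
                                           f"cause {c!r} dated after effect {e!r}"))

    g = nx.DiGraph(store.implication_edges())
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        v.append(Violation(cyc[0][0], "implication.acyclic",
                           f"cause-effect cycle through {[e[0] for e in cyc]}"))

    # workflow integration rules
    effect_causes: dict[str, set[str]] = {}
    for imp in impls:
        for e in imp.effect_event_refs:
            types = {
                events[c]["event_type"] for c in imp.cause_event_refs if c in events
            }
            effect_causes.setdefault(e, set()).update(types)

    for eid, r in events.items():
        ctypes = effect_causes.get(eid, set())
        if r["event_type"] == "DIAGNOSIS":
            if not ctypes & {"IMAGING_ANALYSIS", "BIOLOGICAL_SAMPLE_ANALYSIS"}:
                v.append(Violation(eid, "diagnosis.analysis-cause",
                                   "diagnosis has no causal implication from an "
                                   "imaging or biological-sample analysis event"))
        if r["event_type"] == "IMAGE_ACQUISITION":
            if not ctypes & {"RECRUITMENT", "IMAGING_ANALYSIS"}:
                v.append(Violation(eid, "acquisition.traceable",
                                   "image acquisition traces to neither recruitment "
                                   "nor an imaging-analysis event"))

    return v
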