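"""Screening-protocol logic: eligibility, nodule triage, exam-type
classification and causal wiring of a donor timeline.

The encoded management protocol for indeterminate pulmonary nodules is:
annual low-dose CT for eligible heavy smokers; nodules of 5–8 mm trigger a
repeat LDCT after 3 or 6 months; nodules above 8 mm, or fast-growing ones
(volume doubling time between 30 and 400 days), go to combined CT-PET; high
suspicion of malignancy on PET or growth then leads to biopsy/invasive
work-up.  Eligibility requires age >= 50 years and >= 20 pack-years, both
thresholds inclusive.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from enum import Enum

from . import model as m
from .errors import DomainError, WorkflowError
from .store import Store

#: Sentinel for a non-growing lesion (no finite positive doubling time).
NON_GROWING = math.inf


@dataclass(frozen=True)
class ProtocolConfig:
    """Tunable thresholds of the nodule-management rules.

    Boundary semantics make the printed ranges exhaustive and
    non-overlapping: the 5–8 mm repeat-LDCT band is inclusive on both ends,
    the CT-PET size rule is strictly above 8 mm, and the fast-growth VDT
    window [30, 400] days is inclusive.
    """

    eligibility_min_age_years: float = 50.0
    eligibility_min_pack_years: float = 20.0
    repeat_ldct_min_mm: float = 5.0
    repeat_ldct_max_mm: float = 8.0
    ct_pet_min_mm: float = 8.0  # strict: diameter > ct_pet_min_mm
    fast_growth_vdt_days: tuple[float, float] = (30.0, 400.0)
    # the protocol schedules the repeat scan "after 3 or 6 months": shorter
    # interval for the larger (6-8 mm) nodules, longer for 5-6 mm ones
    monitoring_interval_months_large: int = 3
    monitoring_interval_months_small: int = 6
    monitoring_split_mm: float = 6.0
    max_monitoring_chain: int = 3


class TriageAction(str, Enum):
    ANNUAL_ROUTINE = "ANNUAL_ROUTINE"
    REPEAT_LDCT_3_6M = "REPEAT_LDCT_3_6M"
    CT_PET = "CT_PET"
    INVASIVE_WORKUP = "INVASIVE_WORKUP"


@dataclass(frozen=True)
class TriageDecision:
    """Exactly one management action per (lesion, time point), with the
    rule id that produced it."""

    action: TriageAction
    rationale: str


def pack_years(cigarettes_per_day: float, duration_years: float) -> float:
    """Cumulative smoking exposure: (cigarettes/day ÷ 20) × years smoked."""
    if cigarettes_per_day < 0 or duration_years < 0:
        raise DomainError("cigarettes_per_day and duration_years must be >= 0")
    return (cigarettes_per_day / 20.0) * duration_years


def check_eligibility(
    age_years: float, py: float, config: ProtocolConfig | None = None
) -> bool:
    """Screening eligibility: age >= 50 and >= 20 pack-years (inclusive)."""
    config = config or ProtocolConfig()
    if age_years < 0 or py < 0:
        raise DomainError("age and pack-years must be >= 0")
    return (
        age_years >= config.eligibility_min_age_years
        and py >= config.eligibility_min_pack_years
    )


def volume_doubling_time(v1_mm3: float, v2_mm3: float, delta_days: float) -> float:
    """Volume doubling time under exponential growth.

    VDT = Δt·ln2 / ln(v2/v1).  A non-growing lesion (v2 <= v1) returns the
    ``NON_GROWING`` sentinel (infinity) rather than a negative or undefined
    time.  Scale-invariant in the volumes.
    """
    if v1_mm3 <= 0 or v2_mm3 <= 0:
        raise DomainError("volumes must be > 0")
    if delta_days <= 0:
        raise DomainError("delta_days must be > 0")
    if v2_mm3 <= v1_mm3:
        return NON_GROWING
    return delta_days * math.log(2.0) / math.log(v2_mm3 / v1_mm3)


def triage_nodule(
    diameter_mm: float,
    vdt_days: float | None = None,
    pet_or_growth_high_suspicion: bool = False,
    config: ProtocolConfig | None = None,
) -> TriageDecision:
    """Management action for one nodule at one time point.

    Rule order: (1) diameter above 8 mm OR VDT within [30, 400] days →
    CT-PET (growth dominates size); (2) diameter within [5, 8] mm → repeat
    LDCT after 3/6 months; (3) otherwise annual routine.  If the CT-PET (or
    growth) result flags high suspicion of malignancy, the action escalates
    to invasive work-up.  With no prior volume, the growth rule is skipped.
    """
    config = config or ProtocolConfig()
    if diameter_mm <= 0:
        raise DomainError("diameter_mm must be > 0")
    lo, hi = config.fast_growth_vdt_days
    fast_growing = vdt_days is not None and lo <= vdt_days <= hi
    if diameter_mm > config.ct_pet_min_mm or fast_growing:
        if pet_or_growth_high_suspicion:
            return TriageDecision(TriageAction.INVASIVE_WORKUP, "R4-high-suspicion-biopsy")
        rule = "R1b-fast-growth-ct-pet" if fast_growing and diameter_mm <= config.ct_pet_min_mm else "R1a-size-ct-pet"
        return TriageDecision(TriageAction.CT_PET, rule)
    if config.repeat_ldct_min_mm <= diameter_mm <= config.repeat_ldct_max_mm:
        return TriageDecision(TriageAction.REPEAT_LDCT_3_6M, "R2-indeterminate-repeat-ldct")
    return TriageDecision(TriageAction.ANNUAL_ROUTINE, "R3-annual-routine")


def monitoring_interval_months(diameter_mm: float, config: ProtocolConfig | None = None) -> int:
    """Repeat-LDCT interval: 3 months for the larger band, 6 for the smaller."""
    config = config or ProtocolConfig()
    if diameter_mm >= config.monitoring_split_mm:
        return config.monitoring_interval_months_large
    return config.monitoring_interval_months_small


def classify_exam_type(
    acquisition_event: m.Event | str, store: Store
) -> m.ExamType:
    """Derive the exam type of an image acquisition from graph position.

    BASELINE iff it is the earliest acquisition of the donor's longitudinal
    series; MONITORING_FOLLOWUP iff an imaging-analysis event causes it via
    an implication; ROUTINE_FOLLOWUP otherwise (recruitment as sole cause).
    An acquisition with no causal implication at all cannot be traced to the
    protocol and raises a workflow error.
    """
    ev = (
        acquisition_event
        if isinstance(acquisition_event, m.Event)
        else store.get_event(acquisition_event)
    )
    if ev.event_type is not m.EventType.IMAGE_ACQUISITION:
        raise DomainError(f"event {ev.event_id!r} is not an image acquisition")
    acquisitions = store.events_of_donor(ev.donor_ref, m.EventType.IMAGE_ACQUISITION)
    if not acquisitions:  # pragma: no cover - ev itself is one
        raise WorkflowError("donor has no acquisitions")
    earliest = min(acquisitions, key=lambda e: (e.event_date, e.event_id))
    if ev.event_id == earliest.event_id:
        return m.ExamType.BASELINE
    cause_types = {c.event_type for _, c in store.causes_of(ev.event_id)}
    if m.EventType.IMAGING_ANALYSIS in cause_types:
        return m.ExamType.MONITORING_FOLLOWUP
    if m.EventType.RECRUITMENT in cause_types:
        return m.ExamType.ROUTINE_FOLLOWUP
    raise WorkflowError(
        f"acquisition {ev.event_id!r} traces to neither recruitment nor an "
        "imaging-analysis event"
    )


def wire_workflow(donor_id: str, store: Store) -> list[m.Implication]:
    """Emit the causal implications that wire a donor's timeline.

    Creates (where the corresponding events exist and are not yet wired):
    patient-history → recruitment; recruitment → baseline/routine
    acquisitions; imaging-analysis → monitoring acquisition (matched by the
    acquisition's exam_type attribute); imaging-analysis → biological
    sampling; biological sampling → sample analysis; {imaging-analysis,
    biological-sample-analysis} → diagnosis.
    """
    events = store.events_of_donor(donor_id)
    by_type: dict[m.EventType, list[m.Event]] = {}
    for e in events:
        by_type.setdefault(e.event_type, []).append(e)

    recruitments = by_type.get(m.EventType.RECRUITMENT, [])
    if not recruitments:
        raise WorkflowError(f"donor {donor_id!r} has no recruitment event")
    recruitment = recruitments[0]

    wired_effects: set[str] = set()
    for imp in store.implications():
        wired_effects.update(imp.effect_event_refs)

    out: list[m.Implication] = []

    def emit(causes: list[str], effects: list[str], label: str) -> None:
        out.append(store.add_implication(causes, effects, label=label))

    histories = by_type.get(m.EventType.PATIENT_HISTORY, [])
    if histories and recruitment.event_id not in wired_effects:
        emit([histories[0].event_id], [recruitment.event_id], "history->recruitment")

    analyses = sorted(
        by_type.get(m.EventType.IMAGING_ANALYSIS, []),
        key=lambda e: (e.event_date, e.event_id),
    )

    def analysis_before(date: str) -> m.Event | None:
        # strictly earlier: an exam's own same-day analysis can't be its cause
        prior = [a for a in analyses if a.event_date < date]
        return prior[-1] if prior else None

    for acq in by_type.get(m.EventType.IMAGE_ACQUISITION, []):
        if acq.event_id in wired_effects:
            continue
        exam_type = acq.attributes.get("exam_type")
        cause: m.Event | None
        if exam_type == m.ExamType.MONITORING_FOLLOWUP.value:
            cause = analysis_before(acq.event_date)
            label = "analysis->monitoring-acquisition"
            if cause is None:
                raise WorkflowError(
                    f"monitoring acquisition {acq.event_id!r} has no prior "
                    "imaging-analysis event"
                )
        else:
            cause, label = recruitment, "recruitment->acquisition"
        emit([cause.event_id], [acq.event_id], label)

    samplings = sorted(
        by_type.get(m.EventType.BIOLOGICAL_SAMPLING, []),
        key=lambda e: (e.event_date, e.event_id),
    )
    for sampling in samplings:
        if sampling.event_id in wired_effects:
            continue
        cause = analysis_before(sampling.event_date)
        if cause is None:
            raise WorkflowError(
                f"biological sampling {sampling.event_id!r} has no prior "
                "imaging-analysis event"
            )
        emit([cause.event_id], [sampling.event_id], "analysis->sampling")

    bio_analyses = sorted(
        by_type.get(m.EventType.BIOLOGICAL_SAMPLE_ANALYSIS, []),
        key=lambda e: (e.event_date, e.event_id),
    )
    for bsa in bio_analyses:
        if bsa.event_id in wired_effects:
            continue
        prior = [s for s in samplings if s.event_date <= bsa.event_date]
        if prior:
            emit([prior[-1].event_id], [bsa.event_id], "sampling->analysis")

    for diag in by_type.get(m.EventType.DIAGNOSIS, []):
        if diag.event_id in wired_effects:
            continue
        causes = []
        img = analysis_before(diag.event_date)
        if img is not None:
            causes.append(img.event_id)
        prior_bio = [b for b in bio_analyses if b.event_date <= diag.event_date]
        if prior_bio:
            causes.append(prior_bio[-1].event_id)
        if not causes:
            raise WorkflowError(
                f"diagnosis {diag.event_id!r} has no prior analysis event"
            )
        emit(causes, [diag.event_id], "analyses->diagnosis")
    return out


def add_months(date: _dt.date, months: int) -> _dt.date:
    """Calendar-safe month shift (clamps the day within the target month)."""
    month_index = date.month - 1 + months
    year = date.year + month_index // 12
    month = month_index % 12 + 1
    day = min(date.day, [31, 29 if year % 4 == 0 and (year % 100 != 0 or year % 400 == 0) else 28,
                         31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1])
    return _dt.date(year, month, day)
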