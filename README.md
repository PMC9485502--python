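# screenbank

A structured-repository engine for longitudinal lung-cancer-screening
cohorts that integrates **radiological imaging samples** and **non-digital
biological samples** in one provenance-aware database.

It is aimed at research data managers and imaging scientists who need to
turn a screening archive (DICOM series, lesion annotations, biopsy results,
smoking histories) into a queryable repository with explicit cause–effect
links between clinical events — e.g. *a suspicious nodule on CT caused a
biopsy, whose pathology result fed a unified diagnosis* — without exposing
any direct patient identifiers.

## The data model

The repository follows the biobank convention of three core components —
**SampleDonor**, **Sample**, **Event** — with the sample component reduced
to a minimal attribute set so that biological samples and DICOM-series
samples are variants of one generic type. Two connective components make
heterogeneous data navigable:

- **SubEvent** — a child/product of a parent event. An imaging-analysis
  event owns pulmonary-nodule-identification sub-events (Lung-RADS
  attributes: diameter, solid/part-solid/non-solid texture, lobe, lesion
  coordinates), other-finding sub-events (emphysema, lymphadenopathy, …)
  and post-processing sub-events (lesion volume in mm³ from a DICOM-SEG
  contour, described by a DICOM-SR measurement report).
- **Implication** — a directed cause→effect link between events, with ≥ 1
  cause and ≥ 1 effect, cause dates ≤ effect dates, and a globally acyclic
  graph. A diagnosis can have both an imaging analysis and a pathology
  analysis as causes.

Around the model sit four functional layers:

1. **Pseudonymization & ingestion** (`screenbank.deid`) — patient name/ID
   replaced by a ledger pseudonym, birth date masked as an age-range label
   (default 5-year bins), private tags stripped, burned-in objects
   (screenshots, dose reports) dropped; exports to
   `pseudonym/study-date/series-uid/` and records header fields in the store.
2. **Annotation storage** (`screenbank.annotations`) — voxel masks as
   DICOM-SEG objects, measurements as DICOM-SR with a JSON sidecar;
   volume = foreground voxels × voxel volume.
3. **Protocol logic** (`screenbank.protocol`) — screening eligibility
   (age ≥ 50 and ≥ 20 pack-years, pack-years = cigarettes/day ÷ 20 × years);
   nodule triage (5–8 mm → repeat LDCT in 3/6 months; > 8 mm or volume
   doubling time VDT = Δt·ln2 / ln(V₂/V₁) in [30, 400] days → CT-PET; high
   suspicion → biopsy); exam-type classification (baseline / routine /
   monitoring follow-up) from graph position; and the causal wiring of a
   donor timeline.
4. **Synthetic cohort generator** (`screenbank.cohort`) — a fully synthetic
   ten-year screening cohort (donors, histories, nodules with exponential
   growth, protocol-driven visits, biopsies, and minimal CT DICOM files with
   deliberately planted identities) calibrated to published cohort summary
   statistics, so the entire pipeline is testable with no real patient data.

## Worked example

```python
import screenbank as sb

cohort = sb.simulate_cohort(sb.CohortConfig(n_donors=100), seed=1)
store = cohort.store

print(len(sb.validate_store(store)))          # 0 — every invariant holds
print(sb.summarize(store, "exam_type"))
print(sb.patient_history_summary(store))
```

```text
          exam_type  count  proportion
           BASELINE    100       0.103
   ROUTINE_FOLLOWUP    808       0.830
MONITORING_FOLLOWUP     65       0.067

sex   n  duration_mean  duration_sd  cigarettes_mean  cigarettes_sd
  F  35          37.50          4.5            23.62           7.42
  M  65          39.66          6.7            25.04           8.57
```

Every donor contributes one baseline scan; ~83% of acquisitions are annual
routine follow-ups and ~7% are 3/6-month monitoring follow-ups triggered by
an indeterminate nodule. Smoking histories recover the configured
sex-stratified means (37.9 y for women, 39.9 y for men) at cohort scale.

Protocol calls are plain functions:

```python
sb.triage_nodule(6.0, vdt_days=200.0)
# TriageDecision(action=CT_PET, rationale='R1b-fast-growth-ct-pet')
sb.volume_doubling_time(100, 150, 90)   # 153.86 days
```

and a biopsy-confirmed diagnosis can be traced back through the implication
graph:

```python
trace = sb.trace_provenance("EV-diag-D00006-1", store)
# ('EV-diag-D00006-1', 'EV-bsa-D00006-1', 'EV-biosamp-D00006-1', 'EV-ana-D00006-02')
# ('EV-diag-D00006-1', 'EV-ana-D00006-02')
```

A CLI mirrors the library: `screenbank simulate | deid | ingest | annotate |
validate | summarize | trace` (see `screenbank --help`).

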