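# Methods

This note documents the models, rules and numerical choices behind
`screenbank`: what the repository engine enforces, what the synthetic
cohort generator emulates, how it is calibrated, and what its tests do and
do not demonstrate about real screening data.

## 1. Repository model and invariants

The store is a single SQLite database with declared foreign keys. Writes go
through typed registration functions that raise on contract violations;
`validate_store` re-checks everything by a full scan and *reports* (never
throws), so imported or hand-edited stores can be audited. The enforced
rules are:

- uniqueness: donor ids, pseudonyms, series instance UIDs;
- referential integrity: every donor/collection/event/parent reference
  resolves; biological samples link only to biological-sampling events,
  imaging samples only to image-acquisition events;
- cardinality: a sample has at most one acquisition event (many samples may
  share one event; events with zero samples are valid); an implication has
  ≥ 1 cause and ≥ 1 effect, with disjoint cause/effect sets;
- chronology: every cause is dated ≤ every effect. Equal dates are allowed
  because same-day reporting (scan, analysis and report on one day) is
  routine in radiology; strict precedence would reject real workflows;
- acyclicity: the global cause→effect graph is a DAG, checked on every
  insertion and re-checked by the validator;
- workflow integration: a diagnosis event must have a causal implication
  from an imaging or pathology analysis; an image acquisition must trace to
  recruitment or to an imaging analysis; a post-processing sub-event must
  coexist with a nodule-identification sub-event for the same lesion.

Deletion of referenced entities is refused rather than cascaded: a
provenance repository must not silently lose links in a causal chain.
Event and sub-event attributes are restricted to a per-type registry
(extensible at runtime via `register_event_attribute`), so richer attribute
lists can be added without a schema migration.

### Implication wiring

`wire_workflow` emits, per donor: patient-history → recruitment;
recruitment → baseline/routine acquisition; imaging-analysis → monitoring
acquisition; imaging-analysis → biological sampling; biological sampling →
sample analysis; {imaging analysis, sample analysis} → diagnosis (one
implication with two causes — the unified diagnosis). The cause chosen for
a monitoring acquisition, sampling or diagnosis is the latest *strictly
earlier* imaging analysis: an exam's own same-day analysis can never be its
own cause. Provenance roots are events with no incoming implication;
analysis events are roots in this wiring, since no implication type leads
into an analysis.

## 2. De-identification

The pipeline implements GDPR-style *pseudonymization*, not anonymization:

- patient name and institutional ID → ledger pseudonym (`P0001`, …). The
  ledger is injective, append-only, and persisted as a separate artifact
  that must never travel with the de-identified output (it is the
  re-identification key);
- birth date cleared; the age at the study date is written back only as a
  half-open age-range label, default width 5 years (`[50, 55)` → `"50-54"`).
  The width is configurable; 1-year bins would defeat the masking;
- all private tags removed; a configurable list of indirect identifiers
  (accession number, addresses, physician/institution names) is emptied —
  this list is a conservative extension, not a fidelity claim;
- secondary-capture objects and dose reports are excluded (burned-in pixel
  text), detected by SOP class / series description, not OCR;
- study dates and instance UIDs are retained: the export layout
  `pseudonym/ISO-date/series-uid` keys on them, and longitudinal analyses
  need real intervals. An optional UID-remap flag exists for stricter
  profiles.

The safety property tested is *identifier non-leakage*: an exhaustive scan
of every element value (including nested sequences and file meta) of every
exported file finds no ledger key, planted name fragment or birth date.
This guarantees header hygiene only — it says nothing about pixel content,
which is why burned-in object categories are dropped wholesale.

## 3. Annotations

Lesion volume is the foreground voxel count times the voxel volume
(sx·sy·sz), computed as `count × voxel_volume` so it is exactly
reproducible by independent summation. Masks are stored as a minimal-profile
DICOM segmentation object (one byte per voxel, lossless round-trip, source
series referenced); measurements as a DICOM-SR measurement group with a
JSON sidecar. No SR template is fixed by the upstream conventions this
package follows, so **the JSON sidecar is the normative representation**:
it carries full-precision values and free-form metadata, while the SR
content tree is the DICOM interchange rendering (numeric values formatted
to the 16-character DS limit). Parsing and linking are two phases: an SR
referencing an unknown series still parses; the reference error surfaces at
link time. RT-STRUCT-style planar contours are accepted read-only and
rasterized by even-odd point-in-polygon over voxel centres; mask
resampling across frames of reference is out of scope.

## 4. Protocol rules

Eligibility: age ≥ 50 and ≥ 20 pack-years, both inclusive. Triage, in rule
order:

1. diameter > 8 mm **or** VDT ∈ [30, 400] days → CT-PET (growth dominates
   size); with a high-suspicion PET/growth flag → invasive work-up. The PET
   outcome is an *input flag*, not computed — PET data are not modelled;
2. 5 mm ≤ diameter ≤ 8 mm → repeat LDCT after 3 months (≥ 6 mm) or
   6 months (< 6 mm); the interval assignment is configurable since only
   "3 or 6 months" is specified;
3. otherwise → annual routine.

Boundary semantics (5–8 inclusive, > 8 strict, [30, 400] inclusive) make
the printed ranges exhaustive and non-overlapping. VDT uses the standard
exponential-growth form Δt·ln 2 / ln(V₂/V₁); a non-growing lesion
(V₂ ≤ V₁) returns an infinite sentinel rather than a negative time, and the
statistic is scale-invariant in the volumes. With a single time point the
growth rule is skipped (VDT needs two volumes).

Exam types are derived from graph position: baseline iff earliest
acquisition of the donor; monitoring iff caused by an imaging analysis;
routine otherwise. Monitoring chains are allowed up to depth 3, after which
the donor returns to the annual schedule (whether a monitoring exam may
trigger another is unspecified upstream; the cap is this package's choice).

## 5. Synthetic cohort generator

The generator emulates a ten-year annual LDCT screening program over heavy
smokers. Published summary statistics of the emulated cohort fix these
parameters:

| quantity | value |
|---|---|
| smoking duration, women | Normal(37.9, 6.1) y, truncated > 0 |
| smoking duration, men | Normal(39.9, 6.4) y, truncated > 0 |
| cigarettes/day | Normal(24.9, 10.29), truncated ≥ 1 |
| nodule texture | solid .825 / part-solid .119 / non-solid .056 |
| nodule diameter | < 4 mm .507 / 4–10 mm .453 / > 10 mm .040, uniform within bin |
| lobe weights | near-uniform, right-upper-leaning (.24/.18/.19/.20/.19) |
| benign fraction among biopsies | 0.16 |
| acquisition menu | 30 mA; 120/140 kVp; standard/lung kernel; 2.5/1.25 mm |

Quantities with no published value are desk-scale defaults, documented as
such and **not** calibrated to any printed count: per-visit new-nodule
incidence (Poisson, mean 0.22), malignant fraction per lesion (0.10),
enrollment age (uniform 50–75; only the ≥ 50 floor is published), sex ratio
(0.5), other-finding rate (0.08/visit), measurement noise (0.1 mm SD).
Malignant lesions grow exponentially with VDT log-uniform in [30, 400] d —
inside the protocol's discriminating window — benign lesions are static or
grow with VDT in [600, 2000] d. Pathology outcomes are drawn independently
at the published benign rate (they are not coupled to the lesion's latent
malignancy; the published rate already reflects who reaches biopsy).

### Eligibility-aware calibration

Every emitted donor must pass eligibility, enforced by rejection sampling.
Conditioning on ≥ 20 pack-years inflates the smoking means (drawing at the
published locations and rejecting would shift cigarettes/day from 24.9 to
≈ 26.4). Because the published statistics describe the *enrolled* — hence
eligible — cohort, the generator solves for underlying location parameters
whose conditional-on-eligibility means equal the published values, by
fixed-point iteration over a truncated-normal product quadrature (601-point
grids, ±8 σ, converged to 1e-9; spreads stay at the published SDs). The
correction is ≈ −1.6 for cigarettes/day and ≈ −0.25 y for durations.

### Visit simulation

Each donor gets a baseline plus nine annual scans. Nodules appear per
visit, are measured with noise, and feed the triage rules, which insert
monitoring follow-ups and, on a high-suspicion CT-PET, a biopsy (+30 d),
pathology analysis (+14 d) and diagnosis (+7 d). A lesion whose repeat scan
shows no fast growth is marked stable and returns to the annual schedule. A
malignant diagnosis exits the donor from further screening. All events,
samples, sub-events and implications are registered and wired; a fixed seed
yields a byte-identical store export (hash-stable). Synthetic DICOM series
are 4 slices of 32×32 schematic pixels with valid UIDs, the configured
acquisition tags, and a deliberately planted identity (name, hospital ID,
birth date, and a private tag) so the de-identification leak scan has
something to catch.

### What the generator does *not* emulate

No realistic CT image content, no PET, no inter-reader variability, no
missed visits or dropout, no correlation between smoking exposure and
malignancy, and no attempt to reproduce the real cohort's totals (thousands
of donors, tens of thousands of series). Passing tests therefore certify
the *engine* — schema contracts, de-identification hygiene, protocol logic,
round-trips, and distributional calibration — not clinical realism of the
image data.

## 6. Problem sizes and determinism

Parameter-recovery checks use 5000 donors per sex for the duration means,
10000 donors for cigarettes/day, 10000 lesions for the texture/diameter
mixtures and 5000 biopsy outcomes — sizes at which three standard errors
resolve the published one-decimal precision. Graph-contract checks run 100
simulated donors against brute-force path enumeration on each donor
subgraph; leak scans run a 20-donor cohort end to end. All randomness flows
from `numpy` generators seeded explicitly; the acceptance script derives
one independent stream per statistic from its `--seed` argument.

## 7. Known limitations

- The SEG/SR writers implement a deliberately minimal profile (uncompressed
  byte frames, single measurement group); they are not a general-purpose
  DICOM-SEG/SR toolkit and interoperability with external SR consumers is
  untested.
- Header-level de-identification only; pixel-level identity (burned-in
  text outside the excluded categories) is not inspected.
- Lesion identity across time points relies on generator-assigned stable
  keys; no image-based lesion matching is performed.
- The store targets single-user embedded use; there is no server, locking
  model or access control.
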