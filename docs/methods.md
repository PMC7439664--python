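# Methods

This note documents the models, the curated constants, the numerical and
design choices, and the limits of what the synthetic-data tests can show.

## Scope and model

The package screens adult outpatient prescriptions (kidney-transplant
follow-up care) for drug–laboratory interactions in four categories:

1. **Renal dosing** — the trigger is the Cockcroft–Gault creatinine
   clearance computed from the latest in-window serum creatinine:
   `CrCl = (140 − age)·W / (72·S_Cr)`, ×0.85 for women; ml/min.
2. **Hepatic dosing** — a two-tier classification (*impaired* / *severe*)
   triangulated from liver enzymes, bilirubin, cirrhosis history and the
   Child-Pugh score.
3. **Pregnancy contraindications** — triggered by an active pregnancy
   record or a positive βHCG test.
4. **Laboratory monitoring** — standing reminders with baseline / offset /
   repeat-interval schedules.

Evaluation is a pure function of (patient, labs, prescriptions, knowledge
base, as-of instant, config).  The as-of instant is always explicit —
nothing reads the wall clock — so any historical evaluation is exactly
reproducible.

## Curated rule constants

The seeded knowledge base covers eight high-volume transplant-clinic
medications with 25 rules; all numeric thresholds and recommendation texts
are stored exactly as curated from the drug references (e.g. allopurinol
CrCl bands [10, 20), [3, 10), (0, 3); captopril −25% for [10, 50) and −50%
below 10; hydrochlorothiazide contraindicated below 30; mycophenolate
capped at 1 g twice daily below 25).  Comparisons are implemented exactly
as printed: strict where strict (`ALT > 40` does not fire at 40.0),
inclusive where inclusive (`10 ≤ CrCl` fires at 10.0).

Choices made where the source material is silent (all overridable in the
KB file, which is plain YAML):

* **ALT units** — references print ALT variously as "U/mL" and "U/L"; the
  numerals are identical and the spelling is treated as typographic, so
  both normalise to U/L.
* **Azathioprine's qualitative renal trigger** ("if renal impairment …
  exists", no number given) is operationalised as CrCl < 60 ml/min, the
  conventional moderate-impairment boundary.  Oliguria is not modeled —
  urine output is not among the engine's inputs.
* **"Periodically" monitoring** (omeprazole Mg/B12; hydrochlorothiazide
  electrolytes) defaults to a 6-month repeat.  "1–2 weeks after the start"
  is implemented as a 14-day offset, "8 to 10 days" as 10 days — the later
  end of each printed range, so prompts never fire before the earliest
  clinically intended draw.
* **Severity mapping** — actions that stop a medication or change its dose
  (avoid, discontinue, adjust_*) are level 1 (red, interruptive); dose
  initiation and cautions level 2 (orange); monitoring and supplementation
  level 3 (yellow).  Severities are stored per rule, so a curator can
  override the mapping without code changes.
* **Losartan volume depletion** has no structured field; the CrCl < 30 atom
  triggers a level-2 caution whose text carries the volume-depletion
  condition for the clinician to judge.

## Physiologic calculators

* **Cockcroft–Gault** is compared *unnormalised* (raw ml/min) against
  thresholds that references print per 1.73 m²; this mirrors common clinic
  practice, and CrCl is in any case an estimate, not a measured GFR.  An
  optional DuBois BSA normalisation toggle exists (default off), as does a
  toggle to feed Hume lean body mass instead of actual weight (default
  actual).  Ages ≥ 140 or < 18 are domain errors, not negative clearances.
* **Hume lean body mass** (1966 coefficients) requires height; without it
  LBM is *unavailable* (an error), never silently zero.
* **Child-Pugh** uses the standard bands — bilirubin <2 / 2–3 / >3 mg/dl,
  albumin >3.5 / 2.8–3.5 / <2.8 g/dl, INR <1.7 / 1.7–2.3 / >2.3, plus
  ascites and encephalopathy grades — 1–3 points each, classes A (5–6),
  B (7–9), C (10–15).  Boundary values score the middle band, the common
  clinical convention.
* **Hepatic tier**: severe ⇐ any severe lab criterion, or cirrhosis
  history alone, or Child-Pugh class C; the last two contributions are
  reconstructions of clinical intent and are individually configurable.
  "No liver data in window" is distinguished from "data normal" by an
  explicit marker, and yields tier *normal* (absence of evidence is not
  impairment).

## Time semantics

All windows are calendar months through one shared utility:
the 6-month lab lookback is the half-open interval `(as_of − 6 mo, as_of]`
(a result exactly six months old is excluded — conservative freshness);
pregnancy alerts expire at exactly `detected + 9 mo` (boundary exclusive)
or the instant a termination is recorded.  Renal rules simply do not fire
without an in-window creatinine; no "order a Cr" prompt is emitted, because
routine Cr monitoring is already part of transplant follow-up protocols and
reminding for it would only add alert noise.

## Synthetic data

Two generators make the package fully testable offline:

* **Boundary fixtures** — for every numeric rule threshold *t*, patients at
  {t−ε, t, t+ε} with ε = 10⁻⁶ of the threshold's unit; renal targets are
  reached by back-solving serum creatinine through the same published
  formula (the inversion is purely arithmetic; the forward evaluation is
  always recomputed independently).  The base fixture patient is a
  50-year-old, 72-kg, 170-cm adult evaluated at a fixed instant, for which
  the clearance arithmetic is exact in floating point.  Pregnancy,
  cirrhosis, Child-Pugh, sex-specific and stale-lab scenarios complete the
  grid (185 fixtures for the seeded KB).  Expected alert sets come from a
  hand-written brute-force oracle (`oracle.py`) that re-derives everything
  with thresholds inlined and never touches the engine or the KB classes —
  engine-vs-oracle agreement is the package's sensitivity/specificity
  harness, and both are held at exactly 100%.
* **Profiled cohorts** — seeded random bundles matching a transplant-clinic
  census: 56% male; ages truncated-normal on [20, 73] with mean 47.44;
  weights on [45, 135] with mean 72.07; Cr/AST/ALT normal(1.57±0.66,
  19.64±8.16, 21.14±13.24) truncated at zero; medication prevalences
  (mycophenolate 0.74, cyclosporine 0.71, sirolimus 0.23, diltiazem 0.51,
  calcium 0.50, omeprazole 0.39, losartan 0.34, atorvastatin 0.27).  The
  census states means and ranges but no distribution family; truncated
  normals with the range at ≈ mean ± 2.5 sd are a modeling choice.  Heights
  (not in the census) are drawn per sex around 172/160 cm; 5% of women
  under 50 carry a recent positive pregnancy record and 1% of patients a
  cirrhosis history — plausible clinic rates, stated here because no source
  value exists.  All attributes are sampled independently; real renal/
  hepatic labs correlate with age and with each other, so cohort-level alert
  mixes are indicative, not epidemiologic.  Sampling is fully determined by
  the seed (numpy `default_rng` + scipy truncated normals).

**What passing tests show — and don't.**  The fixture grid proves the
engine implements the curated rules *exactly* (every threshold, boundary
and combination); the cohort runs show the end-to-end pipeline behaves
sensibly at realistic value ranges (monitoring-dominated alert mix, renal
alerts rare).  Neither says anything about rule *coverage* of real-world
DLIs, about data-quality failure modes of a live EHR feed, or about
clinician response — those need prospective evaluation on real records.

## Numerical and degenerate-input choices

* ε for boundary probing is 10⁻⁶; where back-solved creatinine cannot land
  a clearance bit-exactly on a threshold, both the engine and the oracle
  recompute the clearance from the same stored creatinine, so expectation
  and behaviour cannot diverge by construction.
* Floating-point rule comparisons are raw (no tolerance): the KB stores
  thresholds as printed and the derived quantities are compared strictly,
  which is what the boundary fixtures verify.
* Unknown medications validate with a warning and generate no alerts;
  unknown analytes warn on ingestion and, if referenced by a rule, raise a
  configuration error naming the rule at evaluation time.
* Negative lab values, pregnancy on non-female records, paediatric ages and
  malformed dates are validation *findings* (never engine exceptions), so a
  whole batch is diagnosable in one pass.

## Problem sizes

The default verification runs are deliberately desk-scale: 185 boundary
fixtures, 10,000-patient cohorts for moment recovery, and a 100-patient
cohort for the end-to-end alert mix.  The whole suite and the acceptance
script each complete in seconds on one CPU.

## Known limitations

* The seeded KB contains the eight-medication subset; the schema (and the
  reserved `adjust_exact_table` action kind) anticipates the full clinic
  formulary, including a CrCl+LBM dose table for digoxin whose content is
  not shipped.
* Drug–drug interactions and drug interference with lab-test
  *interpretation* are out of scope by design.
* The cirrhosis and Child-Pugh contributions to the severe hepatic tier are
  clinical-intent reconstructions (configurable), not verbatim curated
  rules.
* `should_reappear` re-evaluates the rule at the new prescription event;
  any richer per-event workflow (e.g. immediate re-evaluation on revision)
  is the host system's concern.
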