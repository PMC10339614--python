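# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic data do and do not
emulate, and the choices made where the design was genuinely open.

## Identifier validation and pseudonymised linkage

NHS and CHI numbers are 10-digit identifiers whose last digit is a
modulus-11 check over the first nine (weights 10 down to 2; required
check = 11 − (Σwᵢdᵢ mod 11), with 11 mapped to 0 and a remainder of 1 —
required check 10 — meaning no valid number exists). Canonicalisation
before any validation or hashing strips the spaces and hyphens of the
conventional 3-3-4 print grouping and nothing else. CHI numbers are
treated identically to NHS numbers; the validator does not distinguish
them.

Linkage is deterministic: records agree on a person exactly when their
salted digests agree, where the digest is the uppercase-hex SHA-256 of
the canonicalised identifier bytes followed by the salt bytes. The salt
makes digests project-specific, so pooled outputs cannot be joined
against another project's pseudonymised data. This is an emulation of
the salted-digest procedure used by CSV pseudonymisation tools;
bit-compatibility with any external tool is *not* claimed, and the test
suite carries its own frozen vector (SHA-256 of `9990000018` +
`cluster-salt`) computed with an independent tool.

Records with missing or invalid identifiers are never linked: each
forms a singleton cluster flagged unlinkable. This accepts that a child
missing an identifier in one study appears as two people; the
reconciliation report against externally asserted duplicate lists
exists to surface such misses (confirmed / missed = identifier-error
suspect / digest-discovered / unresolvable). Cluster IDs are sequential
opaque tokens in input order — deliberately not derived from the
digest, so shared cluster-level outputs cannot be dictionary-attacked
back to identifiers.

A consequence of the check-digit arithmetic worth recording: because 11
is prime and all weights are units mod 11, *every* single-digit
substitution in a valid number breaks the check digit. A mistyped digit
therefore always produces an invalid (unlinkable) identifier, never a
silent false link to another person; single-digit typos split clusters
but cannot merge them. Transpositions or multi-digit errors could in
principle produce a different valid number; the corruption model only
plants substitutions.

## The common data model

The CDM covers demographics (date of birth, gender, binary ethnicity),
JIA classification (the eight ILAR subtypes, dates of diagnosis and
symptom onset), serology (ANA, RF, HLA-B27, plus uveitis history), the
eight core outcome variables per visit (active and limited joint counts
0–71, CHAQ 0–3, ESR mm/h, CRP mg/L, physician and patient/parent
globals 0–10, pain VAS 0–10, with height/weight carried but unused by
any downstream filter), and treatment episodes (drug, class, start/stop
dates, route, dose, stop reason).

Mapping tables ship as editable YAML with defaults for the four study
dialects. Granularity is reduced to the most inclusive shared coding —
e.g. any granular non-Caucasian ethnic category collapses to
`Non-Caucasian`. Unknown source codes are hard errors naming the code
and study: harmonisation is where coding errors creep in, and silent
coercion would hide them. ESR and CRP units are fixed (mm/h, mg/L) with
no conversion; dialects must already agree.

The availability matrix records which variables a study never
collected: pain VAS and stop reason are unavailable in CHARMS, date of
diagnosis in CAPS and CHARMS, date of symptom onset and treatment route
in BCRD and BSPAR-Et; everything else is available everywhere. A
variable unavailable for a study is missing for 100 % of that study's
mapped records and flagged *structural*, so missingness reports can
separate study design from incomplete data entry.

## Time points, duplicate resolution, cohort construction

Month arithmetic is fixed in days for reproducibility: 3 months = 91
days, 6 months = 183, 12 months = 365; windows inclusive at both ends.
The baseline (T1) extract takes the latest visit in [−91, 0] days from
drug start; the six-month (T2) extract the visit in [+91, +365] closest
to day 183. An equidistant T2 pair resolves to the earlier visit —
earlier data are less affected by subsequent treatment changes. The T2
window is configurable (e.g. a stricter 4–8-month variant), and
widening it can only add T2 data, never change cohort membership.

Duplicate treatment records of one person for one drug class are kept
or dropped whole; merging fields across records from different studies
would mix time points and was rejected. The retained record is the one
whose study ranks highest in the precedence order, default
CHARMS > BSPAR-Et > BCRD > CAPS. Only the top of this order is
clinically forced (the treatment-response study carries the lowest
core-variable missingness); the rest of the order is a documented,
configurable choice. Two records from the same study fall back to fewer
missing core outcome variables at baseline, then earliest start date,
then record ID — fully deterministic.

Inclusion criteria are screened on the retained record, with failures
accumulated rather than short-circuited: (1) ILAR subtype present;
(2) treatment-naïve, meaning no same-class episode anywhere in the
pooled *linked* data starts before the index episode — linkage exists
precisely to reveal prior exposure recorded in another study; (3) the
index course continued ≥ 91 days (a missing stop date counts as
ongoing); (4) at least one core outcome variable observed at the T1
extract. Anchoring criterion (4) at baseline is an interpretation: the
criteria precede time-point analysis and baseline is the natural
anchor. Naïvety is same-class only; prior exposure to a different
biologic class does not exclude.

Every build checks the conservation ledger exactly — candidate records
= cohort rows + duplicates removed + persons excluded — and person-level
uniqueness within a cohort. A person may appear in both the MTX and the
TNFi cohorts, having started the two drugs at different times.

## Composite outcome measures

JADAS = PGA + PGE + min(AJC, cap) + clamp((ESR − 20)/10, 0, 10), with
cap 10/27/71 by variant (maxima 40/57/101). Only the ESR form is
implemented; which joint-count variant a given analysis should use is
left as the `variant` parameter. ACR Pedi 30/50/70 evaluates the six
core variables (PGA, PGE, CHAQ, AJC, LJC, ESR): responder iff ≥ 3
improved by at least the level percentage and ≤ 1 worsened by more than
30 %. A zero baseline admits no improvement and counts as worsening iff
the follow-up value is positive — division by zero needs a documented
rule. Both scores are complete-case only: a missing component returns
an explicitly incomputable result naming its gaps. Imputation is out of
scope.

## The synthetic generator

The generator models the *structure* of four-registry data, not disease
biology: clinical values are independent draws from calibrated marginal
distributions and do not progress or respond to treatment. Passing
tests therefore demonstrate correctness of linkage, mapping, windowing,
deduplication and accounting — not that any clinical estimate derived
from these fixtures generalises to real registries.

Two modes. In `exact_count` mode a membership table fixes, per pattern,
how many individuals span how many studies with how many records; the
realised histogram equals the table exactly. The calibrated
configuration plants 5435 individuals and 7013 treatment records: 4131
singletons, 197 individuals with repeat records within one study, 961
across two studies, 142 across three, 4 across four, plus 124 extra
within-study repeat records distributed uniformly at random among
multi-record individuals (the within-person record-count distribution
beyond the pattern counts is a modelling choice — no published
breakdown exists). `stochastic` mode instead enrols each person in each
study by independent probabilities.

Key parameters and defaults:

* **Identifiers** — valid modulus-11 numbers from the reserved,
  never-allocated `999` test range; never real NHS numbers.
  `identifier_corruption_rate` (default 0) replaces a stored digit per
  affected (person, study); `identifier_missing_rate` (default 0)
  blanks it. Both are recorded in the planted-truth ledger.
* **Entry points** — CAPS enrols at diagnosis and anchors its visit
  schedule there; the other three anchor at the start of the treatment
  course that brought the child in. Which of a child's courses a study
  records follows its design focus (biologics registers prefer the
  TNFi course; CAPS and CHARMS the MTX course).
* **Visits** — nominal per-study offsets (biologics registers and CAPS
  at 0/183/365/730 days; CHARMS at 0/91/183) plus uniform ±30-day
  jitter, exercising window selection with realistic scatter.
* **Demographics** — female 0.676, Caucasian 0.873, age at onset
  Normal(6.6, 4.3) years truncated at 0, ILAR subtype categorical
  (systemic 0.076 … undifferentiated 0.048, missing 0.029): calibrated
  so synthetic characteristics tables resemble a published harmonised
  MTX cohort without claiming to reproduce it.
* **Treatment** — P(MTX) = 0.8; P(TNFi | MTX) = 0.45 (TNFi follows MTX
  by 120–720 days), TNFi drug mix etanercept-dominated; 12 % of courses
  stop inside 91 days (exercising the continuation criterion) and 35 %
  later. For 5 % of multi-study individuals one study records an
  *earlier* course of the same class instead of the shared one, so
  cross-study naïvety screening has true positives while record counts
  stay exact.
* **Missingness** — per-variable random blanking of collected values,
  defaults spanning 10–60 % (AJC 0.12 … HLA-B27 0.55); structural
  missingness arises from the dialects themselves, whose files simply
  lack the unavailable columns.
* **Dates** — ISO-8601 calendar dates; all offsets in days.

All randomness flows from one integer seed through named child streams
(membership, identifiers, demographics, treatment, visits, missingness,
corruption), and identical (config, seed) pairs yield byte-identical
CSV outputs — asserted byte-wise in the tests and, at pipeline level,
via the SHA-256 manifest.

## Numerical and degenerate-input conventions

Empty string is the one missing-value encoding in CSV; empty inputs
yield empty outputs (an empty record set gives an all-zero duplication
summary with the undefined percentage reported as 0; an empty cohort
gives reports flagged undefined rather than NaN percentages silently).
Duplication percentages are rounded to one decimal. Ties anywhere
(visit selection, precedence fallbacks) break deterministically as
documented above. Unparseable CSV rows are moved to an error sidecar
with a reason, never dropped silently.

## Problem sizes

The calibrated fixture (5435 individuals, 7013 records, ~20 000 visit
rows) generates in a few seconds and drives both the analysis scripts
and the acceptance checks; unit and property tests run on a 60-person
four-study fixture with planted overlap, corruption variants of the
same, and single-study fixtures of up to 2000 individuals for
missingness-recovery bounds. These sizes were chosen as the smallest
that make the planted structure non-trivial at every stage.

## Known limitations

* Linkage is deterministic only; no probabilistic or fuzzy matching on
  names or dates of birth, exactly as in the procedure modelled.
* Single-digit corruption can only split, never falsely merge,
  clusters (see above); the generator does not plant transposition
  errors that could in principle collide.
* No unit conversion, free-text cleaning or identifier repair.
* Scores are complete-case; no imputation.
* The generator's clinical values are cross-sectionally plausible but
  longitudinally exchangeable; response-rate style summaries computed
  from synthetic cohorts are placeholders, not predictions.
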