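# Methods

This note documents the conventions, algorithms, and design decisions
behind `bidscurate`, and what its synthetic test data do and do not show
about real datasets.

## Scope and model of the data

The package operates at the *organizational* level of a neuroimaging
dataset: folder and filename structure, sidecar JSON metadata, phenotype
tables, and the accounting derived from them. Image content is opaque —
NIfTI payloads are never read beyond their existence — and no processing
pipelines are run. A dataset is modeled as a BIDS tree: `sub-<label>`
folders, optional `ses-<label>` subfolders, datatype folders (`anat`,
`func`, `dwi`, ...), image files with paired sidecar JSON, plus
`participants.tsv` and a `phenotype` folder at the root.

## Subject-level phenotype documents

Wide per-study tables are split into one JSON document per participant
with top-level keys `participant_id`, `demographics`, `sessions`, and
`schema_version`. Session keys are BIDS session labels (`"01"`, `"02"`,
...); numeric visit identifiers are zero-padded to two digits on ingest.
Values are stored as typed scalars (string, integer, real, categorical
code, date-offset). Missing values are simply absent keys; regenerated
tables write `n/a`, the BIDS missing-value convention. These choices make
two properties hold exactly, and the test suite enforces them: the number
of non-missing cells is conserved by deconstruction, and
deconstruct → regenerate → deconstruct is the identity.

A variable dictionary accompanies the documents. Each entry holds the
canonical name, level (demographic vs session), value type, optional
accepted categorical codes, aliases, and a provenance list of
(source study, source file, original variable name) records. Aliases are
global within a dictionary: no alias may equal any other entry's canonical
name or alias. This is stricter than strictly necessary but guarantees
that any requested name resolves to exactly one variable, which is what
makes alias-transparent table generation safe. Categorical codes are
validated at table-generation time (the last moment before values leave
the store), not at ingest, so foreign raw tables can be loaded first and
cleaned via the dictionary.

Merging dictionaries across studies is deliberately conservative: only
explicitly declared equivalences are condensed (provenance concatenated,
superseded canonical names retained as aliases); an undeclared name clash
between studies is an error, never a silent merge. Semantic harmonization
of clinical instruments — deciding *whether* two scores are equivalent —
is out of scope; the machinery only records and applies such decisions.

## Pseudonymization

Identifying information is anything that narrows the search for a
participant. The transforms:

- **Date anchoring.** Every calendar date becomes an integer study day,
  with day 0 the participant's baseline/screening visit. Offsets are exact
  calendar-day differences, so pairwise intervals are preserved and
  longitudinal modeling is unaffected. Pre-baseline events yield negative
  days. Each participant must have exactly one baseline; when formally
  separate studies are combined for the same participant, the caller
  anchors to the earliest baseline (the alternative — per-study anchors —
  would leak the inter-study gap structure and complicate joins).
- **Time quantization.** Times of day are rounded to the nearest quarter
  hour using integer microsecond arithmetic; exact 7.5-minute ties round
  up, and 23:52:30 or later wraps to 00:00:00 (the date component lives
  only in study days, so the wrap loses nothing). The worst-case error is
  450 s by construction and is property-tested.
- **Recoding.** Institutions and scanner serials receive letter codes
  (`Institution A` ... `Scanner ZZ`; capacity 702 per category),
  participant IDs a fixed prefix plus a zero-padded index (`T00042`,
  capacity 10^width). Codes are drawn from a seed-shuffled sequence, so an
  assignment is deterministic given seed and insertion order; a
  sorted-input mode gives order independence when reproducibility across
  runs matters more than streaming. Maps are append-only and injective,
  re-coding an assigned value or an existing code is a no-op, and the maps
  are persisted *outside* the distributed dataset as the re-linkage key.

`scrub_sidecar` applies a policy of `remove_fields` and `transform_fields`
(disjoint by construction). The default policy removes person-name-like
DICOM residues, anchors `AcquisitionDate`/`AcquisitionDateTime` (the
datetime's time-of-day is not retained in that field — scan time lives in
`AcquisitionTime`, which is quantized), and recodes institution and
device fields. A transform that cannot parse its value drops the field
and flags it in the audit rather than keeping it raw: failing closed is
the only safe behavior for identifying data. Scrubbing is idempotent, so
re-running a deidentification pass over a partially processed dataset is
harmless.

`audit_dataset` is the independent verification pass: it flags fields
from the identifying-name list, institution/serial fields whose value
does not match the code grammar, any string containing a calendar-date
pattern, and any time with sub-quarter-hour precision. On fixtures it
achieves recall and precision 1.0 against the planted-identifier
manifest; on real data it is a screen, not a proof — free-text fields can
hide identifiers no pattern catches.

## Filename grammar, QC marking, rosters

Names are rendered in the fixed entity order `sub, ses, acq, run, suffix`;
parsing tolerates extra entities and canonicalizes on render. Values are
alphanumeric. Scans that failed quality control carry a `BAD` prefix on
the suffix (`..._BADT1w.nii.gz`). This deviates from standard BIDS (a
`desc-` entity would be the conforming spelling) but reproduces the
convention of the distributed HD datasets byte-for-byte, which matters
more here than validator compliance. Marking and unmarking are mutually
inverse, and marking an already-marked name is an error so accidental
double application cannot corrupt names. QC ratings are 1–5 ordinals
(1–2 fail, 3–5 pass) with free-text comments; judgment overrules are a
manual re-mark, not a rule.

Rosters count subject folders, `ses-` folders containing at least one
file, and parseable image files per suffix with QC-failed scans excluded.
Phenotype-only participants (a subject folder holding just the phenotype
document) count as participants with zero sessions, which is why group
counts may sum to less than the participant total. Aggregation is a
component-wise sum and assumes disjoint cohorts — studies that followed
the same participants must be combined into one dataset *before*
summarization, which is exactly how the published per-dataset figures
were produced.

## Template-cohort selection

The published record states the balancing intent and the resulting
composition but no algorithm, so the objective and optimizer here are this
package's own design. Imbalance is the equal-weight sum over the chosen
factors (site, sex, clinical status, decade of age) of the population
variance of per-stratum selection counts, with strata taken from the whole
candidate pool so empty strata count as zeros; 0 therefore means perfect
balance within the quota constraints. Age decades are left-closed bins
([40, 50) → `40-49`). Status quotas are hard constraints: the optimizer
initializes each status group from a seed-shuffled order and hill-climbs
by swapping a selected against an unselected candidate of the same status
(first improvement), restarting 10 times and keeping the best score with
ties resolved toward the earlier restart. Given pool, request, and seed
the result is deterministic, and input order does not matter because
candidates are sorted by ID before shuffling. On pools of ≤ 12 the greedy
optimum matches exhaustive enumeration in ≥ 95% of 200 random instances
(observed ≥ 99% across acceptance seeds) and never violates a quota.
Summary tables report per-group N, mean ± sd age (sample sd, n−1
denominator, one decimal), and F/M counts; single-member groups report
sd 0.0 with a degenerate-sample flag.

One note on the published template composition: the narrative text and
the summary table of the source disagree on which group has 18 vs 19
members; this package follows the table (control 19, premanifest 18,
manifest 23), whose totals (N = 60, F/M = 33/27) are internally
consistent.

## Synthetic fixtures

The generator emulates the structural features Level-1 curation actually
exercises: multi-subject, multi-session trees with per-modality run
counts; sidecars with clean quarter-hour times and study-day fields; a
visit calendar (baseline plus roughly-annual follow-ups with ±30-day
jitter, baselines spread over 2009–2012); wide phenotype tables with
aliases and provenance-mapped column names; QC failures; planted
identifiers covering every scrub category (institution name and address,
scanner serial, station, datetime, over-precise time, date-in-comment,
patient name); and optional structural defects (orphan sidecar, malformed
filename, missing sidecar, unlisted subject). Every fixture ships a
ground-truth manifest checked for internal consistency, and tests compare
module outputs to the manifest exactly, never approximately. Image
payloads are minimal 4×4×4 int16 volumes; gzip members are written with a
zeroed timestamp so identical specs and seeds give byte-identical trees.

What fixtures do **not** emulate: realistic image content, DICOM
encapsulation (header maps stand in for DICOM headers), free-text
clinical notes, inconsistent site-specific metadata vocabularies, or the
scale of real studies. Passing tests therefore demonstrate that the
conventions and algorithms are implemented correctly, not that a real
dataset is fully deidentified or BIDS-valid.

The multi-study generator mirrors the combine-before-counting rule:
carried-over subjects keep one folder with continuous session numbering
(study A's sessions 01..m, study B's m+1..), so the combined participant
count is |A| + |B| − |carryover|.

## Numerical and degenerate-input choices

- Quantization uses exact integer microseconds; no floating-point ties.
- Hill-climbing accepts a swap only if it improves the score by more than
  1e-12, preventing float-noise cycling.
- Empty document sets generate empty tables with correct headers; empty
  datasets summarize to all-zero rosters; empty roster lists aggregate to
  zeros.
- Conflicting duplicate values (same participant/variable, or same
  participant/session/variable) are rejected, never last-write-wins;
  equal duplicates are tolerated.
- Unknown variable names are rejected with near-match suggestions
  (difflib) rather than a bare failure.

## Problem sizes

The shipped test and acceptance workloads use desk-scale sizes chosen to
exercise every code path with exact oracles: toy trees of 3–10 subjects,
100 random phenotype studies, 10,000 random times, 200 random cohort
instances on pools of 8–12 (small enough for exhaustive enumeration to
stay the reference). The algorithms themselves have no scale assumptions
beyond O(n²) swaps per hill-climbing pass in cohort selection, which is
comfortable at realistic pool sizes (hundreds of candidates).

## Known limitations

- The audit's date/time regexes are tuned for ISO-like and slash formats;
  exotic locale formats in free text can escape detection.
- Recoding capacity is bounded (702 letter codes per category); studies
  with more institutions need a wider code grammar.
- `validate_tree` implements the subset of BIDS rules these conventions
  exercise, not full validator parity.
- Phenotype value typing covers scalars only; nested instruments would
  need a schema extension.
- The CAP (CAG-by-age product) progression score used to stratify some
  published cohorts is treated as a given group label; its formula is not
  implemented here.
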