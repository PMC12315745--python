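# bidscurate

A Level-1 curation toolkit for multi-study neuroimaging datasets organized
in BIDS (Brain Imaging Data Structure). It was built around the needs of
Huntington's disease (HD) research, where a handful of large natural-history
studies — collected over two decades, at dozens of sites, in incompatible
formats — must be harmonized into consistently named, pseudonymized,
well-accounted BIDS datasets before any big-data analysis can start.

The package is for data managers and researchers who curate or consume such
datasets. It covers the data-management layer only: file and variable
conventions, metadata, and accounting. It never touches voxel values and it
runs no image-processing pipelines.

## What it does

- **Subject-level phenotype store** (`bidscurate.phenotype`). Wide per-study
  clinical/demographic/cognitive tables are *deconstructed* into one
  hierarchical JSON document per participant (a `demographics` section for
  visit-invariant values, a `sessions` section keyed by visit), stored in the
  subject's BIDS folder next to the imaging data. A variable dictionary
  carries canonical names, aliases (e.g. `gender` → `sex`), accepted
  categorical codes, and per-variable provenance (source study, source file,
  original variable name). BIDS phenotype tables are *regenerated* on demand
  for any subset of variables, requested by canonical name or alias, with
  missing cells written as `n/a`. Updating a dataset is adding or removing a
  subject folder and regenerating. Dictionaries from several studies can be
  merged, condensing declared-equivalent variables into single entries with
  concatenated provenance.
- **Pseudonymization** (`bidscurate.deid`). Calendar dates become integer
  *study days* (day 0 = the participant's baseline/screening visit, so all
  pairwise intervals are preserved exactly); scan times are rounded to the
  nearest quarter hour; institutions, scanner serials, and participant IDs
  get consistent pseudonymous codes (`Institution Y`, `T00042`) from
  append-only, seeded recoding maps kept outside the distributed data.
  `scrub_sidecar` applies a configurable policy to sidecar JSON and is
  idempotent; `audit_dataset` sweeps a tree for residual dates,
  over-precise times, and identifying fields.
- **Filename grammar and rosters** (`bidscurate.layout`). Construction and
  parsing of `sub-*_ses-*_acq-*_run-*_<suffix>` names, including the
  `BAD`-prefixed suffix that marks scans failing quality control
  (`sub-123456789_ses-01_run-01_BADT1w.nii.gz`); 1–5 QC rating records
  (1–2 fail, 3–5 pass); tree validation (grammar, image/sidecar pairing,
  `participants.tsv` cross-checks); and dataset rosters — participants,
  sessions, scans per modality with QC-failed scans excluded — that
  aggregate across datasets.
- **Template-cohort selection** (`bidscurate.cohort`). Quota-exact,
  balance-optimized selection of the participant subset used to build an
  anatomical population template, stratified by site, sex, clinical status,
  and decade of age. Imbalance is the equal-weight sum over factors of the
  variance of per-stratum selection counts; a seeded multi-restart
  hill-climber with within-status swaps minimizes it (verified against
  exhaustive search on small pools).
- **Synthetic fixtures** (`bidscurate.fixtures`). Deterministic toy studies
  — real NIfTI files, sidecars, phenotype tables, optional planted
  identifiers and structural defects — with a ground-truth manifest, so
  everything above is testable without any real data.
- **Published accounting** (`bidscurate.published`). The printed per-dataset
  participant/session/group figures of the six distributed HD datasets, as
  roster inputs for aggregation and consistency checks.

## Worked example

```python
import random
from pathlib import Path
from bidscurate import FixtureSpec, make_fixture, summarize_roster, quantize_time
from bidscurate.cohort import (CandidateParticipant, CohortRequest,
                               select_balanced_cohort, tabulate_cohort)

# a toy study: 3 subjects x 2 sessions, T1w + bold, one scan failed QC
root = Path("demo_bids")
manifest = make_fixture(FixtureSpec(n_subjects=3, sessions_per_subject=2,
                                    n_qc_failures=1, seed=7), root)
print(summarize_roster(root, dataset_label="TOY").to_frame().to_string(index=False))
```

```
          quantity  count
      participants      3
          sessions      6
        scans[T1w]      6
       scans[bold]      5
    group[control]      1
   group[manifest]      1
group[premanifest]      1
```

Twelve scans were generated but the QC-failed bold scan is excluded from the
roster, so only 11 are counted. Time quantization:

```python
print(quantize_time("14:37:12"))   # -> 14:30:00
```

Selecting a 60-participant template cohort (19 controls, 18 premanifest,
23 manifest) from a random pool of 120 candidates:

```python
rng = random.Random(1)
pool = [CandidateParticipant(f"P{i:03d}", site=f"S{i % 4 + 1}", sex=rng.choice("FM"),
                             clinical_status=rng.choice(["control", "premanifest",
                                                         "manifest"]),
                             age=round(rng.uniform(25, 65), 1))
        for i in range(120)]
request = CohortRequest(total_n=60, status_quotas={"control": 19, "premanifest": 18,
                                                   "manifest": 23}, seed=1)
selection = select_balanced_cohort(pool, request)
print(tabulate_cohort(selection, pool).to_string(index=False))
print(f"imbalance score: {selection.imbalance_score:.3f}")
```

```
clinical_status  n  age_mean  age_sd  n_female  n_male flag
        control 19      43.6    13.1         8      11
    premanifest 18      48.0    13.9        13       5
       manifest 23      43.6    12.4         9      14
          Total 60      44.9    13.0        30      30
imbalance score: 4.667
```

Quotas are met exactly; the residual imbalance reflects what this random
pool allows (a perfectly balanceable pool scores 0). Ages are mean ± sample
standard deviation per clinical group.

The same operations are available from the shell:

```sh
bidscurate fixture make --seed 7 --out demo_bids
bidscurate layout summarize --bids demo_bids
bidscurate deid audit --bids demo_bids
bidscurate cohort select --pool pool.tsv --n 60 \
    --quotas control=19,premanifest=18,manifest=23 --seed 1
```

## Documentation

`docs/methods.md` describes the conventions, the algorithms, the synthetic
data generator, and the package's design choices and limitations.
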