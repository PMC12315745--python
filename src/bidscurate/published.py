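"""Published accounting of the six distributed Huntington's disease BIDS datasets.

These are the printed per-dataset figures that accompany the public
releases: participant and session totals plus the clinical-group
breakdown of each cohort.  They serve as input manifests for roster
arithmetic (aggregation across datasets, group-sum consistency checks);
nothing here is computed, only recorded.

Group-count notes: in TRACK-HD/ON two participants are phenotype-only and
in IMAGE-HD seven are, so group counts (which cover imaging participants)
sum to less than the participant total there.  PREDICT-HD gene carriers
are stratified by CAG-by-age product (CAP) into low/medium/high; SHIELD-HD
recruited only gene-expansion carriers, split into three progression
groups by CAP score.
"""

from __future__ import annotations

from .layout import DatasetRoster

__all__ = [
    "published_rosters",
    "PREDICT_CARRIER_GROUPS",
    "TEMPLATE_COHORT_COMPOSITION",
]

_PUBLISHED = {
    "TRACK-HD/ON": {
        "n_participants": 446,
        "n_sessions": 2024,
        "group_counts": {"control": 156, "premanifest": 165, "manifest": 123},
    },
    "PREDICT-HD": {
        "n_participants": 1377,
        "n_sessions": 4329,
        "group_counts": {
            "control": 297,
            "carrier_low_cap": 287,
            "carrier_medium_cap": 358,
            "carrier_high_cap": 427,
            "unknown_genotype": 8,
        },
    },
    "IMAGE-HD": {
        "n_participants": 119,
        "n_sessions": 290,
        "group_counts": {"control": 36, "premanifest": 40, "manifest": 36},
    },
    "HD-YAS": {
        "n_participants": 123,
        "n_sessions": 123,
        "group_counts": {"control": 61, "premanifest": 62},
    },
    "SHIELD-HD": {
        "n_participants": 62,
        "n_sessions": 183,
        "group_counts": {"cap_group_1": 19, "cap_group_2": 21, "cap_group_3": 22},
    },
    "PEARL-HD/LONGPDE10": {
        "n_participants": 89,
        "n_sessions": 124,
        "group_counts": {"control": 45, "carrier": 44},
    },
}

#: group labels making up the PREDICT-HD gene-carrier subgroup
PREDICT_CARRIER_GROUPS = ("carrier_low_cap", "carrier_medium_cap", "carrier_high_cap")

#: composition of the 60-participant anatomical template cohort:
#: clinical status -> (N, n_female, n_male, mean age, sd age)
TEMPLATE_COHORT_COMPOSITION = {
    "control": (19, 12, 7, 48.0, 12.4),
    "premanifest": (18, 9, 9, 42.0, 12.5),
    "manifest": (23, 12, 11, 49.0, 10.8),
}


def published_rosters() -> list[DatasetRoster]:
    """The six per-dataset rosters as :class:`DatasetRoster` objects."""
    return [DatasetRoster(dataset_label=label, **spec)
            for label, spec in _PUBLISHED.items()]
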