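"""Balanced selection of a template-building cohort.

An anatomical population template is averaged from a subset of
participants; the subset should honor fixed quotas per clinical status
(control / premanifest / manifest) while staying as balanced as possible
across site, sex, and decade of age.  Balance is scored as the
equal-weight sum, over the chosen factors, of the population variance of
the per-stratum selection counts; 0 means every stratum of every factor
holds the same number of selected participants.  The optimizer is a
seeded multi-restart hill climber that swaps selected against unselected
candidates within the same clinical status, so quotas hold by
construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CandidateParticipant",
    "CohortRequest",
    "CohortSelection",
    "InfeasibleQuotaError",
    "age_decade",
    "imbalance_score",
    "select_balanced_cohort",
    "tabulate_cohort",
]

FACTORS = ("site", "sex", "clinical_status", "age_decade")
_STATUS_ORDER = ("control", "premanifest", "manifest")


class InfeasibleQuotaError(ValueError):
    pass


def age_decade(age: float) -> str:
    """Decade bin of an age; left-closed ([40, 50) -> '40-49')."""
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


@dataclass(frozen=True)
class CandidateParticipant:
    participant_id: str
    site: str
    sex: str
    clinical_status: str
    age: float

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for f_ in ("participant_id", "site", "clinical_status"):
            if not getattr(self, f_):
                raise ValueError(f"{f_} must be non-empty")

    def factor_value(self, factor: str) -> str:
        if factor == "age_decade":
            return age_decade(self.age)
        return getattr(self, factor)


@dataclass(frozen=True)
class CohortRequest:
    total_n: int
    status_quotas: Mapping[str, int]
    balance_factors: tuple[str, ...] = FACTORS
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "status_quotas", dict(self.status_quotas))
        object.__setattr__(self, "balance_factors", tuple(self.balance_factors))
        if sum(self.status_quotas.values()) != self.total_n:
            raise ValueError("status quotas must sum to total_n")
        bad = set(self.balance_factors) - set(FACTORS)
        if bad:
            raise ValueError(f"unknown balance factors {sorted(bad)}")


@dataclass
class CohortSelection:
    selected: frozenset[str]
    imbalance_score: float
    stratum_tallies: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected": sorted(self.selected),
            "imbalance_score": self.imbalance_score,
            "stratum_tallies": {f: dict(sorted(t.items()))
                                for f, t in self.stratum_tallies.items()},
        }


def _tallies(members: Iterable[CandidateParticipant],
             pool: Sequence[CandidateParticipant],
             factors: Sequence[str]) -> dict[str, dict[str, int]]:
    levels = {f: sorted({p.factor_value(f) for p in pool}) for f in factors}
    tallies = {f: {lv: 0 for lv in levels[f]} for f in factors}
    for p in members:
        for f in factors:
            tallies[f][p.factor_value(f)] += 1
    return tallies


def imbalance_score(members: Iterable[CandidateParticipant],
                    pool: Sequence[CandidateParticipant],
                    factors: Sequence[str]) -> float:
    """Equal-weight sum over factors of the variance of stratum counts.

    Strata are the factor levels observed anywhere in the candidate pool,
    so levels left unselected still count as zeros.
    """
    score = 0.0
    for f, tally in _tallies(members, pool, factors).items():
        counts = np.array(list(tally.values()), dtype=float)
        score += float(np.var(counts))
    return score


def _check_feasible(by_status: Mapping[str, list], quotas: Mapping[str, int]) -> None:
    for status, quota in quotas.items():
        have = len(by_status.get(status, []))
        if have < quota:
            raise InfeasibleQuotaError(
                f"status {status!r}: quota {quota} but only {have} candidates")


def select_balanced_cohort(
    pool: Sequence[CandidateParticipant],
    request: CohortRequest,
    n_restarts: int = 10,
) -> CohortSelection:
    """Select a quota-exact cohort minimizing the imbalance score.

    Deterministic given ``(pool, request)``: candidates are ordered by id,
    then shuffled by the request seed; each restart hill-climbs with
    within-status swaps until no swap improves the score, and the best
    restart wins (ties keep the earlier restart).
    """
    ids = [p.participant_id for p in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant_id in pool")
    if len(pool) < request.total_n:
        raise InfeasibleQuotaError(
            f"pool of {len(pool)} smaller than requested total_n {request.total_n}")
    by_status: dict[str, list[CandidateParticipant]] = {}
    for p in sorted(pool, key=lambda p: p.participant_id):
        by_status.setdefault(p.clinical_status, []).append(p)
    _check_feasible(by_status, request.status_quotas)

    rng = random.Random(request.seed)
    factors = request.balance_factors
    pool_sorted = sorted(pool, key=lambda p: p.participant_id)

    best_members: list[CandidateParticipant] | None = None
    best_score = float("inf")
    for _ in range(max(1, n_restarts)):
        selected: list[CandidateParticipant] = []
        unselected: list[CandidateParticipant] = []
        for status, quota in request.status_quotas.items():
            cands = list(by_status.get(status, []))
            rng.shuffle(cands)
            selected.extend(cands[:quota])
            unselected.extend(cands[quota:])
        score = imbalance_score(selected, pool_sorted, factors)
        improved = True
        while improved:
            improved = False
            for i, s in enumerate(selected):
                for j, u in enumerate(unselected):
                    if u.clinical_status != s.clinical_status:
                        continue
                    trial = selected[:i] + [u] + selected[i + 1:]
                    trial_score = imbalance_score(trial, pool_sorted, factors)
                    if trial_score < score - 1e-12:
                        selected, unselected = trial, (
                            unselected[:j] + [s] + unselected[j + 1:])
                        score = trial_score
                        improved = True
                        break
                if improved:
                    break
        if score < best_score - 1e-12:
            best_score, best_members = score, selected
    assert best_members is not None
    return CohortSelection(
        selected=frozenset(p.participant_id for p in best_members),
        imbalance_score=best_score,
        stratum_tallies=_tallies(best_members, pool_sorted, factors),
    )


def _status_order(statuses: Iterable[str]) -> list[str]:
    statuses = set(statuses)
    ordered = [s for s in _STATUS_ORDER if s in statuses]
    return ordered + sorted(statuses - set(ordered))


def tabulate_cohort(selection: CohortSelection,
                    pool: Sequence[CandidateParticipant]) -> pd.DataFrame:
    """Demographic summary table: per-status N, mean +/- sd age, F/M, total row.

    The sd uses the n-1 denominator; groups of one report sd 0.0 and are
    flagged as degenerate.
    """
    by_id = {p.participant_id: p for p in pool}
    missing = selection.selected - set(by_id)
    if missing:
        raise ValueError(f"selected ids not in pool: {sorted(missing)[:5]}")
    members = [by_id[i] for i in sorted(selection.selected)]

    def row(label: str, group: list[CandidateParticipant]) -> dict:
        ages = np.array([p.age for p in group], dtype=float)
        degenerate = len(group) < 2
        sd = 0.0 if degenerate else float(np.std(ages, ddof=1))
        return {
            "clinical_status": label,
            "n": len(group),
            "age_mean": round(float(ages.mean()), 1) if len(group) else float("nan"),
            "age_sd": round(sd, 1),
            "n_female": sum(p.sex == "F" for p in group),
            "n_male": sum(p.sex == "M" for p in group),
            "flag": "degenerate-sample" if degenerate else "",
        }

    rows = [row(status, [p for p in members if p.clinical_status == status])
            for status in _status_order(p.clinical_status for p in members)]
    rows.append(row("Total", members))
    return pd.DataFrame(rows)
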