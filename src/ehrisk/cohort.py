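"""Cohort construction and 1:1 matched case-control selection.

The analytic cohort is every patient with at least one outpatient visit in
the study window (fiscal years 2010-2017 by default); the earliest such visit
is the enrollment date.  Cases are cohort members whose underlying cause of
death is a suicide code (U03, X60-X84, Y87.0) before calendar 2018.  Controls
are matched 1:1 without replacement on fiscal year of enrollment and the year
of the case's endpoint; the control's index date is its first outpatient
visit in that year, the case's index date is its death date.

Matching runs over cases in seeded-random order, picking uniformly among
eligible unused controls and rescuing exhausted cases through augmenting
paths, so the produced matching always has maximum cardinality.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "CohortDefinition", "fiscal_year", "fiscal_year_window",
    "build_cohort", "identify_cases", "match_controls", "is_suicide_cause",
]

logger = logging.getLogger(__name__)

OUTPATIENT_CODE = "outpatient_visit"

DEFAULT_SUICIDE_CODES = frozenset(
    {"U03", "Y87.0"} | {f"X{i}" for i in range(60, 85)}
)


def fiscal_year(d) -> int:
    """US federal fiscal year of a date, labeled by its ending calendar year.

    FY2010 runs 1 Oct 2009 through 30 Sep 2010.
    """
    d = pd.Timestamp(d)
    return d.year + 1 if d.month >= 10 else d.year


def fiscal_year_window(fy_start: int, fy_end: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last calendar dates of the inclusive fiscal-year span."""
    return pd.Timestamp(date(fy_start - 1, 10, 1)), pd.Timestamp(date(fy_end, 9, 30))


@dataclass
class CohortDefinition:
    study_window_fy: tuple[int, int] = (2010, 2017)
    death_observation_end: date = date(2018, 12, 31)
    #: cases must die strictly before this date
    case_death_before: date = date(2018, 1, 1)
    suicide_codes: frozenset[str] = field(default_factory=lambda: DEFAULT_SUICIDE_CODES)
    #: stratum convention for the endpoint year: "fiscal" or "calendar"
    endpoint_year: str = "fiscal"

    def __post_init__(self) -> None:
        if self.study_window_fy[0] >= self.study_window_fy[1]:
            raise ValueError("study window FY start must precede end")
        if not self.suicide_codes:
            raise ValueError("suicide_codes must be non-empty")

    def year_of(self, d) -> int:
        if self.endpoint_year == "fiscal":
            return fiscal_year(d)
        return pd.Timestamp(d).year


def is_suicide_cause(code: str, suicide_codes: frozenset[str] = DEFAULT_SUICIDE_CODES) -> bool:
    """True when an underlying-cause ICD-10 code falls in the suicide set.

    Codes with a decimal extension match on their root unless the set entry
    itself carries the decimal (Y87.0 matches only Y87.0, but X72.1 matches
    the X72 root).
    """
    if not code:
        return False
    code = code.strip().upper()
    if code in suicide_codes:
        return True
    root = re.split(r"\.", code)[0]
    return root in suicide_codes


def _outpatient_visits(events: pd.DataFrame) -> pd.DataFrame:
    vis = events[events["feature_code"] == OUTPATIENT_CODE]
    return vis[["patient_id", "event_date"]]


def build_cohort(patients: pd.DataFrame, events: pd.DataFrame,
                 definition: CohortDefinition | None = None) -> pd.DataFrame:
    """Cohort membership with enrollment dates.

    Returns the subset of ``patients`` having at least one outpatient visit in
    the study window, with ``enrollment_date`` set to the earliest in-window
    visit and ``enrollment_fy`` added.  Patients with no in-window visit are
    silently excluded.
    """
    definition = definition or CohortDefinition()
    lo, hi = fiscal_year_window(*definition.study_window_fy)
    vis = _outpatient_visits(events)
    vis = vis[(vis["event_date"] >= lo) & (vis["event_date"] <= hi)]
    if vis.empty:
        out = patients.iloc[0:0].copy()
        out["enrollment_fy"] = pd.Series(dtype=int)
        return out
    first = vis.groupby("patient_id")["event_date"].min().rename("enrollment_date")
    out = patients.drop(columns=["enrollment_date"], errors="ignore").merge(
        first, left_on="id", right_index=True, how="inner")
    out["enrollment_fy"] = out["enrollment_date"].map(fiscal_year)
    return out.reset_index(drop=True)


def identify_cases(cohort: pd.DataFrame, definition: CohortDefinition | None = None) -> list[str]:
    """Ids of cohort members who died by suicide before the case cutoff."""
    definition = definition or CohortDefinition()
    cutoff = pd.Timestamp(definition.case_death_before)
    dead = cohort["death_date"].notna() & (cohort["death_date"] < cutoff)
    is_case = dead & cohort["underlying_cause"].map(
        lambda c: is_suicide_cause(c, definition.suicide_codes))
    return cohort.loc[is_case, "id"].tolist()


def match_controls(cohort: pd.DataFrame, events: pd.DataFrame, case_ids,
                   definition: CohortDefinition | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, list[str]]:
    """1:1 matched case-control pairs without replacement.

    Returns ``(pairs, unmatched_case_ids)``.  ``pairs`` has columns
    ``case_id, control_id, case_index_date, control_index_date,
    enrollment_fy, endpoint_year``.  The control pool is every cohort member
    that is not a suicide death; eligibility requires the same enrollment
    fiscal year and an outpatient visit in the year of the case's endpoint.
    Cases in seeded-random order pick uniformly among unused eligible
    controls; augmenting paths reassign earlier picks when that leaves a case
    stranded, so the matching is cardinality-maximal.  An empty or exhausted
    pool yields unmatched cases with a logged warning, not an exception.
    """
    definition = definition or CohortDefinition()
    rng = np.random.default_rng(seed)
    case_ids = list(case_ids)
    suicide = cohort["underlying_cause"].map(
        lambda c: is_suicide_cause(c, definition.suicide_codes)) & cohort["death_date"].notna()
    pool = cohort[~suicide & ~cohort["id"].isin(case_ids)]

    cases = cohort[cohort["id"].isin(case_ids)].set_index("id")

    # first outpatient visit per (pool patient, endpoint-convention year)
    vis = _outpatient_visits(events)
    vis = vis[vis["patient_id"].isin(pool["id"])].copy()
    vis["year"] = vis["event_date"].map(definition.year_of)
    first_visit = vis.groupby(["patient_id", "year"])["event_date"].min()

    pool_fy = pool.set_index("id")["enrollment_fy"]
    # controls indexed by (enrollment FY, year with a visit)
    by_stratum: dict[tuple[int, int], list[str]] = {}
    for (pid, year) in first_visit.index:
        by_stratum.setdefault((int(pool_fy[pid]), int(year)), []).append(pid)

    matched: dict[str, str] = {}   # control_id -> case_id
    assigned: dict[str, str] = {}  # case_id -> control_id
    strata: dict[str, tuple[int, int]] = {}
    adjacency: dict[str, list[str]] = {}

    order = rng.permutation(len(case_ids))
    for k in order:
        cid = case_ids[k]
        row = cases.loc[cid]
        stratum = (int(row["enrollment_fy"]), definition.year_of(row["death_date"]))
        strata[cid] = stratum
        neigh = by_stratum.get(stratum, [])
        adjacency[cid] = neigh
        free = [c for c in neigh if c not in matched]
        if free:
            pick = free[int(rng.integers(len(free)))]
            matched[pick] = cid
            assigned[cid] = pick
        else:
            # augmenting path: try to free an eligible control
            if _augment(cid, adjacency, matched, assigned, rng, set()):
                pass
    unmatched = [c for c in case_ids if c not in assigned]
    if unmatched:
        logger.warning("match_controls: %d of %d cases unmatched", len(unmatched), len(case_ids))

    rows = []
    for cid, ctrl in assigned.items():
        fy, year = strata[cid]
        rows.append({
            "case_id": cid,
            "control_id": ctrl,
            "case_index_date": cases.loc[cid, "death_date"],
            "control_index_date": first_visit[(ctrl, year)],
            "enrollment_fy": fy,
            "endpoint_year": year,
        })
    cols = ["case_id", "control_id", "case_index_date", "control_index_date",
            "enrollment_fy", "endpoint_year"]
    pairs = pd.DataFrame(rows, columns=cols)
    if len(pairs):
        pairs = pairs.sort_values("case_id", kind="stable").reset_index(drop=True)
    return pairs, unmatched


def _augment(case_id: str, adjacency: dict[str, list[str]], matched: dict[str, str],
             assigned: dict[str, str], rng: np.random.Generator, visited: set[str]) -> bool:
    neigh = adjacency.get(case_id, [])
    idx = rng.permutation(len(neigh))
    for j in idx:
        ctrl = neigh[int(j)]
        if ctrl in visited:
            continue
        visited.add(ctrl)
        owner = matched.get(ctrl)
        if owner is None or _augment(owner, adjacency, matched, assigned, rng, visited):
            matched[ctrl] = case_id
            assigned[case_id] = ctrl
            return True
    return False
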