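"""ALRI episode detection and severity grading from daily symptom diaries.

The diary case definition: an episode is two or more consecutive days with
maternal report of fever and fast/difficult breathing, with both symptoms
reported on at least one day and at least one of them on every episode day;
consecutive episodes must be separated by at least 7 symptom-free days.
Runs of symptomatic days separated by 1-6 symptom-free days therefore belong
to the same episode (the interior gap days are retained and flagged).

Severe ALRI adds at least one of: tachypnea (respiratory rate >50/min at age
>=12 months, >60/min below 12 months), chest retractions, unconsciousness,
or auscultated crackles in at least one lung quadrant, observed at a case
examination during the episode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlriEpisode",
    "CaseExam",
    "detect_episodes",
    "detect_episodes_from_flags",
    "classify_severe",
    "episode_summary",
]


@dataclass
class AlriEpisode:
    """One detected episode (dates inclusive; gap days flagged)."""

    child_id: object
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    n_days: int
    gap_days: list = field(default_factory=list)
    severe: bool | None = None
    severity_criteria: frozenset = frozenset()
    examined: bool = False


@dataclass(frozen=True)
class CaseExam:
    """Clinical case examination triggered by reported breathing difficulty."""

    child_id: object
    exam_date: pd.Timestamp
    age_months: float
    respiratory_rate: float
    chest_retractions: bool = False
    unconscious: bool = False
    crackles_any_quadrant: bool = False
    oxygen_saturation: float | None = None

    def __post_init__(self) -> None:
        if self.respiratory_rate <= 0:
            raise ValueError("respiratory_rate must be positive")
        if not 0 <= self.age_months < 36:
            raise ValueError("age_months must lie in [0, 36)")


def detect_episodes_from_flags(
    fever: Sequence[bool],
    fast_difficult_breathing: Sequence[bool],
    missing: Sequence[bool] | None = None,
    max_merge_gap: int = 6,
    require_cooccurrence: bool = True,
    bridge_missing: int = 0,
) -> list[tuple[int, int, list[int]]]:
    """Core detector on aligned per-day boolean arrays (day index 0-based).

    Returns ``(start, end, gap_days)`` triples, ordered and disjoint.

    Algorithm: (1) maximal runs of days with fever or fast/difficult
    breathing; (2) runs separated by at most ``max_merge_gap`` symptom-free
    days are merged into one candidate (so accepted episodes are separated by
    at least ``max_merge_gap + 1`` symptom-free days); (3) a candidate
    qualifies if its calendar span is at least 2 days and — under the default
    co-occurrence reading — both symptoms are reported together on at least
    one day (``require_cooccurrence=False`` weakens this to each symptom on
    some day).  Missing days break runs and block merging unless
    ``bridge_missing`` allows gaps of up to that many missing days.
    """
    fever = np.asarray(fever, dtype=bool)
    fdb = np.asarray(fast_difficult_breathing, dtype=bool)
    if fever.shape != fdb.shape:
        raise ValueError("symptom arrays must have equal length")
    n = len(fever)
    miss = (
        np.zeros(n, dtype=bool) if missing is None else np.asarray(missing, dtype=bool)
    )
    symptomatic = (fever | fdb) & ~miss

    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if symptomatic[i]:
            j = i
            while j + 1 < n and symptomatic[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    # merge runs across short symptom-free gaps
    merged: list[list[tuple[int, int]]] = []
    for run in runs:
        if merged:
            prev_end = merged[-1][-1][1]
            gap = np.arange(prev_end + 1, run[0])
            gap_missing = miss[gap]
            mergeable = (
                len(gap) <= max_merge_gap
                and int(gap_missing.sum()) <= bridge_missing
            )
            if mergeable:
                merged[-1].append(run)
                continue
        merged.append([run])

    episodes: list[tuple[int, int, list[int]]] = []
    for group in merged:
        start, end = group[0][0], group[-1][1]
        if end - start + 1 < 2:
            continue
        days = np.arange(start, end + 1)
        sympt_days = days[symptomatic[days]]
        if require_cooccurrence:
            ok = bool((fever[sympt_days] & fdb[sympt_days]).any())
        else:
            ok = bool(fever[sympt_days].any() and fdb[sympt_days].any())
        if not ok:
            continue
        gap_days = [int(d) for d in days if not symptomatic[d]]
        episodes.append((int(start), int(end), gap_days))
    return episodes


def detect_episodes(
    diary: pd.DataFrame,
    max_merge_gap: int = 6,
    require_cooccurrence: bool = True,
    bridge_missing: int = 0,
) -> list[AlriEpisode]:
    """Detect ALRI episodes in one child's diary table.

    ``diary`` needs columns ``child_id``, ``date``, ``fever``,
    ``fast_difficult_breathing``; days must be contiguous and unique.  Days
    whose core-symptom fields are missing (NA) are treated as missing diary
    days.
    """
    required = {"child_id", "date", "fever", "fast_difficult_breathing"}
    if not required <= set(diary.columns):
        raise ValueError(f"diary missing columns: {sorted(required - set(diary.columns))}")
    if len(diary) == 0:
        return []
    if diary["child_id"].nunique() != 1:
        raise ValueError("detect_episodes expects a single child's diary")
    diary = diary.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(diary["date"])
    if dates.duplicated().any():
        raise ValueError("duplicated diary days")
    deltas = dates.diff().dropna().dt.days
    if len(deltas) and not (deltas == 1).all():
        raise ValueError("diary days must be contiguous")
    missing = diary["fever"].isna() | diary["fast_difficult_breathing"].isna()
    fever = diary["fever"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    fdb = (
        diary["fast_difficult_breathing"]
        .astype("boolean")
        .fillna(False)
        .to_numpy(dtype=bool)
    )
    child_id = diary["child_id"].iloc[0]
    base = dates.iloc[0]
    out = []
    for start, end, gaps in detect_episodes_from_flags(
        fever,
        fdb,
        missing=missing.to_numpy(),
        max_merge_gap=max_merge_gap,
        require_cooccurrence=require_cooccurrence,
        bridge_missing=bridge_missing,
    ):
        out.append(
            AlriEpisode(
                child_id=child_id,
                start_date=base + pd.Timedelta(days=start),
                end_date=base + pd.Timedelta(days=end),
                n_days=end - start + 1,
                gap_days=[base + pd.Timedelta(days=g) for g in gaps],
            )
        )
    return out


def classify_severe(
    episode: AlriEpisode, exams: Sequence[CaseExam] | pd.DataFrame
) -> AlriEpisode:
    """Grade an episode severe/non-severe from case examinations.

    Severe iff any exam dated inside the episode window shows tachypnea for
    age (RR strictly >50 at >=12 months, strictly >60 below 12 months),
    chest retractions, unconsciousness, or crackles in any quadrant.  Exams
    outside the window are ignored with a warning; an episode with no exam is
    graded non-severe and flagged unexamined.
    """
    if isinstance(exams, pd.DataFrame):
        exams = [
            CaseExam(
                child_id=r.child_id,
                exam_date=pd.Timestamp(r.exam_date),
                age_months=float(r.age_months),
                respiratory_rate=float(r.respiratory_rate),
                chest_retractions=bool(r.chest_retractions),
                unconscious=bool(r.unconscious),
                crackles_any_quadrant=bool(r.crackles_any_quadrant),
            )
            for r in exams.itertuples()
        ]
    criteria: set[str] = set()
    examined = False
    for exam in exams:
        if exam.child_id != episode.child_id:
            continue
        if not episode.start_date <= exam.exam_date <= episode.end_date:
            warnings.warn(
                f"exam on {exam.exam_date.date()} outside episode window "
                f"{episode.start_date.date()}..{episode.end_date.date()}; ignored",
                stacklevel=2,
            )
            continue
        examined = True
        tachypnea = (exam.age_months >= 12 and exam.respiratory_rate > 50) or (
            exam.age_months < 12 and exam.respiratory_rate > 60
        )
        if tachypnea:
            criteria.add("tachypnea")
        if exam.chest_retractions:
            criteria.add("retractions")
        if exam.unconscious:
            criteria.add("unconsciousness")
        if exam.crackles_any_quadrant:
            criteria.add("crackles")
    episode.severe = bool(criteria)
    episode.severity_criteria = frozenset(criteria)
    episode.examined = examined
    return episode


def episodes_to_frame(episodes: Sequence[AlriEpisode]) -> pd.DataFrame:
    """Episode table: child_id, start, end, days, severe, criteria."""
    return pd.DataFrame(
        {
            "child_id": [e.child_id for e in episodes],
            "start_date": [e.start_date for e in episodes],
            "end_date": [e.end_date for e in episodes],
            "n_days": [e.n_days for e in episodes],
            "severe": [e.severe for e in episodes],
            "examined": [e.examined for e in episodes],
            "criteria": ["|".join(sorted(e.severity_criteria)) for e in episodes],
        }
    )


def episode_summary(
    diary: pd.DataFrame, episodes_by_child: dict | None = None, **detect_kwargs
) -> pd.DataFrame:
    """Child-level incidence: episodes per child-year at risk.

    Reported with both at-risk denominators — total diary days, and diary
    days excluding episode days — since the field definition of person-time
    does not fix the adjustment.
    """
    rows = []
    for child_id, child_diary in diary.groupby("child_id", sort=True):
        eps = (
            episodes_by_child.get(child_id, [])
            if episodes_by_child is not None
            else detect_episodes(child_diary, **detect_kwargs)
        )
        n_days = len(child_diary)
        ep_days = sum(e.n_days for e in eps)
        rows.append(
            {
                "child_id": child_id,
                "n_episodes": len(eps),
                "days_observed": n_days,
                "rate_per_child_year": len(eps) * 365.0 / n_days if n_days else np.nan,
                "rate_per_child_year_at_risk": (
                    len(eps) * 365.0 / (n_days - ep_days) if n_days > ep_days else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
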