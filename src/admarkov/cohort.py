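"""Longitudinal cohort tables: validation, baseline filters, transition counts.

The input is panel data — one row per subject-visit with the subject id,
the visit time in months from baseline and the diagnosis assigned at that
visit (CN, MCI, AD or the baseline-only SMC category; the EMCI/LMCI
sublabels are accepted and merged into MCI).  An optional ``withdrew``
column (0/1 on the last visit) distinguishes genuine withdrawal from
administrative end of follow-up; when absent, a subject who is never seen
again after a visit is counted as withdrawing in the next interval.

Transition counting follows the interval maximum-likelihood setup: the
observation period is divided into one-year intervals, every consecutive
pair of yearly assessments contributes one transition, and observed
transitions that the model structure excludes (direct CN→AD, any exit from
AD other than withdrawal) are tallied in a separate report rather than in
the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .states import DiseaseState, ALLOWED_MASK

__all__ = [
    "DataError",
    "ExclusionReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
    "apply_baseline_filters",
    "count_transitions",
    "TransitionCountReport",
    "write_transition_counts",
    "read_transition_counts",
]

DIAGNOSIS_ALIASES = {"EMCI": "MCI", "LMCI": "MCI"}
VALID_DIAGNOSES = ("CN", "MCI", "AD", "SMC")

COHORT_COLUMNS = ["subject_id", "visit_month", "diagnosis"]


class DataError(ValueError):
    """The cohort table violates a structural requirement."""


def validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Normalise and validate a long-format cohort table.

    Maps EMCI/LMCI to MCI, checks diagnosis labels (raising
    :class:`DataError` that names the offending row), enforces unique
    (subject_id, visit_month) pairs, non-negative integer months, and
    strictly increasing visit months within each subject in file order.
    """
    missing = [c for c in COHORT_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"cohort table missing columns {missing}")
    df = records.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["diagnosis"] = df["diagnosis"].astype(str).str.strip().replace(DIAGNOSIS_ALIASES)

    bad = ~df["diagnosis"].isin(VALID_DIAGNOSES)
    if bad.any():
        row = df.index[bad][0]
        raise DataError(
            f"unknown diagnosis label {df.loc[row, 'diagnosis']!r} at row {row} "
            f"(subject {df.loc[row, 'subject_id']})"
        )

    months = pd.to_numeric(df["visit_month"], errors="coerce")
    if months.isna().any() or (months < 0).any() or (months % 1 != 0).any():
        raise DataError("visit_month must be a non-negative integer for every row")
    df["visit_month"] = months.astype(int)

    dup = df.duplicated(subset=["subject_id", "visit_month"])
    if dup.any():
        row = df.index[dup][0]
        raise DataError(
            f"duplicate (subject_id, visit_month) at row {row} "
            f"(subject {df.loc[row, 'subject_id']}, month {df.loc[row, 'visit_month']})"
        )

    decreasing = df.groupby("subject_id", sort=False)["visit_month"].diff() <= 0
    if decreasing.any():
        row = df.index[decreasing.fillna(False)][0]
        raise DataError(
            f"non-monotone visit months for subject {df.loc[row, 'subject_id']} "
            f"at row {row}"
        )

    if "withdrew" in df.columns:
        df["withdrew"] = df["withdrew"].astype(int)
        if not df["withdrew"].isin([0, 1]).all():
            raise DataError("withdrew flag must be 0 or 1")
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (``subject_id,visit_month,diagnosis``)."""
    return validate_cohort(pd.read_csv(path))


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# baseline filters


@dataclass
class ExclusionReport:
    """Counts per baseline exclusion rule."""

    total_subjects: int
    excluded_smc: int
    excluded_screening_only: int
    retained: int

    def to_dict(self) -> dict:
        return {
            "total_subjects": self.total_subjects,
            "excluded_smc": self.excluded_smc,
            "excluded_screening_only": self.excluded_screening_only,
            "retained": self.retained,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_baseline_filters(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop baseline-SMC and screening-only subjects.

    Subjects whose earliest visit carries an SMC diagnosis are excluded
    first; among the remainder, subjects with a single visit (a screening
    visit and nothing after) are excluded.  A subject matching both rules
    is attributed to the SMC rule.  When the table carries a ``withdrew``
    column, a single-visit subject whose flag is set is a documented
    first-interval withdrawal, not a screening-only subject, and is
    retained (dropping such subjects would bias withdrawal probabilities
    downward).
    """
    df = validate_cohort(records)
    if df.empty:
        return df, ExclusionReport(0, 0, 0, 0)

    grouped = df.sort_values("visit_month").groupby("subject_id", sort=False)
    baseline_dx = grouped["diagnosis"].first()
    n_visits = grouped.size()

    smc_ids = set(baseline_dx.index[baseline_dx == "SMC"])
    screening_ids = set(n_visits.index[n_visits == 1]) - smc_ids
    if "withdrew" in df.columns:
        flagged = set(
            grouped["withdrew"].max().pipe(lambda s: s.index[s == 1])
        )
        screening_ids -= flagged
    keep = ~df["subject_id"].isin(smc_ids | screening_ids)

    report = ExclusionReport(
        total_subjects=int(baseline_dx.size),
        excluded_smc=len(smc_ids),
        excluded_screening_only=len(screening_ids),
        retained=int(baseline_dx.size) - len(smc_ids) - len(screening_ids),
    )
    return df.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# transition counting


@dataclass
class TransitionCountReport:
    """Side information from transition counting.

    ``excluded_transitions`` tallies observed transitions that the model
    structure forbids (e.g. AD→MCI reversals); they are reported, never
    silently dropped.  ``unassigned_visits`` counts visits that fall
    outside the snapping window of every scheduled assessment.
    ``skipped_gaps`` counts subject-interval pairs spanned by a missing
    intermediate assessment (no transition is counted for them).
    """

    excluded_transitions: dict = field(default_factory=dict)
    unassigned_visits: int = 0
    skipped_gaps: int = 0

    def to_dict(self) -> dict:
        return {
            "excluded_transitions": {
                f"{i}->{j}": n for (i, j), n in self.excluded_transitions.items()
            },
            "unassigned_visits": self.unassigned_visits,
            "skipped_gaps": self.skipped_gaps,
        }


_CLINICAL = {"CN", "MCI", "AD"}


def _is_allowed(src: str, dst: str) -> bool:
    return bool(ALLOWED_MASK[DiseaseState[src], DiseaseState[dst]])


def count_transitions(
    records: pd.DataFrame,
    interval_months: int = 12,
    window_months: int = 3,
) -> tuple[pd.DataFrame, TransitionCountReport]:
    """Count one-interval transitions from a filtered cohort table.

    Visits within ``window_months`` of a scheduled assessment time are
    snapped to it; two visits snapping to the same assessment is a
    :class:`DataError`.  For each consecutive pair of observed yearly
    assessments one transition is counted.  A subject's exit into
    withdrawal is counted in the interval after their last visit — always,
    when the table has no ``withdrew`` column, or only when the last
    visit's flag is set, when it does (end of planned follow-up then
    contributes no withdrawal).  Forbidden observed transitions go to the
    report's ``excluded_transitions``.

    Returns a tidy counts table with columns ``interval``, ``from``,
    ``to``, ``count`` (interval ``t`` covers year ``t−1`` → ``t``).
    """
    df = validate_cohort(records)
    has_flag = "withdrew" in df.columns
    counts: dict[tuple[int, str, str], int] = {}
    report = TransitionCountReport()

    for subject, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("visit_month")
        by_year: dict[int, str] = {}
        withdrew_after_last = not has_flag
        for row in sub.itertuples(index=False):
            if row.diagnosis not in _CLINICAL:
                raise DataError(
                    f"non-clinical diagnosis {row.diagnosis!r} for subject "
                    f"{subject}: apply baseline filters before counting"
                )
            month = row.visit_month
            year = round(month / interval_months)
            if abs(month - year * interval_months) > window_months:
                report.unassigned_visits += 1
                continue
            if year in by_year:
                raise DataError(
                    f"two visits of subject {subject} snap to assessment "
                    f"year {year}"
                )
            by_year[year] = row.diagnosis
            if has_flag:
                withdrew_after_last = bool(row.withdrew)
        if not by_year:
            continue
        years = sorted(by_year)
        for prev, cur in zip(years, years[1:]):
            if cur - prev > 1:
                report.skipped_gaps += cur - prev
                continue
            src, dst = by_year[prev], by_year[cur]
            if src in _CLINICAL and dst in _CLINICAL and not _is_allowed(src, dst):
                key = (src, dst)
                report.excluded_transitions[key] = (
                    report.excluded_transitions.get(key, 0) + 1
                )
                continue
            counts[(cur, src, dst)] = counts.get((cur, src, dst), 0) + 1
        if withdrew_after_last:
            last = years[-1]
            key = (last + 1, by_year[last], "WITHDRAWN")
            counts[key] = counts.get(key, 0) + 1

    rows = [
        {"interval": t, "from": src, "to": dst, "count": n}
        for (t, src, dst), n in sorted(counts.items())
    ]
    frame = pd.DataFrame(rows, columns=["interval", "from", "to", "count"])
    return frame, report


def write_transition_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False)


def read_transition_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("interval", "from", "to", "count") if c not in df.columns]
    if missing:
        raise DataError(f"transition-count table missing columns {missing}")
    return df
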