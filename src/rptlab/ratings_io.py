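"""Reading, validating and screening picture-rating tables.

The canonical input is a long-format table — one row per rating — with
columns ``participant_id, cohort, category, picture_id, rating`` where
ratings are integers on the 7-point scale −3 (dislike very much) .. +3
(like very much). CSV and XLSX are accepted, plus a wide format (one
column per picture) that is converted to long on read.

Participant-level quality screening applies up to four exclusion criteria:

1. straightlining — identical response across an entire section (here,
   the 48-picture rating block, or per section when section labels exist);
2. illness count — ten or more self-reported clinician-diagnosed illnesses;
3. minimal rating variance — all 48 ratings the same or varying by at most
   one point;
4. education/time mismatch — education level and years of education
   disagree AND the questionnaire was completed faster than a threshold
   (500 s by default; 800 s for large-cohort runs).

Criteria 1 and 3 need only the ratings; 2 and 4 need metadata and are
recorded "not evaluable" (never silently excluding) when it is absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rpt_variables import RATING_MAX, RATING_MIN

DEFAULT_CATEGORIES = (
    "sports", "disasters", "cute_animals", "aggressive_animals",
    "nature", "bathing_suits",
)

RATING_COLUMNS = ("participant_id", "cohort", "category", "picture_id", "rating")
META_COLUMNS = (
    "participant_id", "age_group", "completion_seconds",
    "education_level", "education_years", "n_diagnosed_illnesses",
)

SCREEN_CRITERIA = (
    "straightlining", "illness_count", "minimal_rating_variance",
    "education_time_mismatch",
)


class RatingsSchemaError(ValueError):
    """A required column is missing or unmappable."""


class RatingsValidationError(ValueError):
    """Row-level content failed validation; offending row indices attached."""

    def __init__(self, message: str, rows: Sequence[int] = ()) -> None:
        super().__init__(message)
        self.rows = list(rows)


@dataclass
class ParseResult:
    records: pd.DataFrame
    completeness: pd.DataFrame  # participant_id, category, n_pictures, complete

    @property
    def n_participants(self) -> int:
        return self.records["participant_id"].nunique()


def _read_table(source, sheet_name=0) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    path = Path(source)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, sheet_name=sheet_name)
    return pd.read_csv(path)


def parse_ratings(
    table_source,
    schema_config: Mapping[str, str] | None = None,
    n_pictures: int = 8,
    sheet_name=0,
) -> ParseResult:
    """Read and validate a long-format ratings table.

    ``schema_config`` maps canonical column names to source column names,
    e.g. ``{"participant_id": "subject"}``. Raises :class:`RatingsSchemaError`
    for missing columns and :class:`RatingsValidationError` for non-integer
    or out-of-range ratings and duplicate (participant, picture) pairs; the
    completeness frame marks (participant, category) groups that do not have
    exactly ``n_pictures`` rows.
    """
    df = _read_table(table_source, sheet_name)
    mapping = dict(schema_config or {})
    rename = {src: canon for canon, src in mapping.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in ("participant_id", "category", "picture_id", "rating")
               if c not in df.columns]
    if missing:
        raise RatingsSchemaError(f"missing required column(s): {', '.join(missing)}")
    if "cohort" not in df.columns:
        df["cohort"] = "default"

    df = df.loc[:, list(RATING_COLUMNS)].copy()
    raw = pd.to_numeric(df["rating"], errors="coerce")
    non_integer = raw.isna() | (raw != np.floor(raw))
    if non_integer.any():
        rows = df.index[non_integer].tolist()
        raise RatingsValidationError(f"non-integer rating(s) at rows {rows}", rows)
    out_of_range = (raw < RATING_MIN) | (raw > RATING_MAX)
    if out_of_range.any():
        rows = df.index[out_of_range].tolist()
        raise RatingsValidationError(
            f"rating(s) outside {RATING_MIN}..{RATING_MAX} at rows {rows}", rows)
    df["rating"] = raw.astype(int)

    dup = df.duplicated(subset=["participant_id", "picture_id"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise RatingsValidationError(
            f"duplicate (participant_id, picture_id) pairs at rows {rows}", rows)

    counts = (
        df.groupby(["participant_id", "category"], observed=True)
        .size().rename("n_pictures").reset_index()
    )
    counts["complete"] = counts["n_pictures"] == n_pictures
    df = df.sort_values(["participant_id", "category", "picture_id"],
                        kind="stable").reset_index(drop=True)
    return ParseResult(records=df, completeness=counts)


def parse_ratings_wide(
    table_source,
    id_column: str = "participant_id",
    cohort: str = "default",
    category_sep: str = ":",
) -> ParseResult:
    """Read a wide table (one column per picture, named ``category:picture``)."""
    df = _read_table(table_source)
    if id_column not in df.columns:
        raise RatingsSchemaError(f"missing required column(s): {id_column}")
    value_cols = [c for c in df.columns if c != id_column and category_sep in str(c)]
    if not value_cols:
        raise RatingsSchemaError(
            f"no picture columns of the form 'category{category_sep}picture' found")
    long = df.melt(id_vars=[id_column], value_vars=value_cols,
                   var_name="_col", value_name="rating")
    parts = long["_col"].str.split(category_sep, n=1, expand=True)
    # full column name as picture_id keeps (participant, picture) unique
    long["category"], long["picture_id"] = parts[0], long["_col"]
    long["participant_id"] = long[id_column]
    long["cohort"] = cohort
    return parse_ratings(long[list(RATING_COLUMNS)])


def write_ratings(records: pd.DataFrame, path) -> None:
    records.loc[:, list(RATING_COLUMNS)].to_csv(path, index=False)


# --------------------------------------------------------------------------
# participant screening


@dataclass(frozen=True)
class ScreeningPolicy:
    """Which exclusion criteria to apply and their thresholds."""

    straightlining: bool = True
    illness_count: bool = True
    minimal_rating_variance: bool = True
    education_time_mismatch: bool = True
    completion_threshold_s: float = 500.0  # 800 for large-cohort runs
    illness_threshold: int = 10
    # education level -> plausible years-of-education band; configurable
    education_bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "less_than_high_school": (0, 11),
            "high_school": (12, 13),
            "some_college": (13, 15),
            "associate": (14, 15),
            "bachelor": (16, 17),
            "master": (18, 19),
            "doctorate": (20, 30),
        }
    )


@dataclass
class ScreeningReport:
    participant_id: str
    flags: dict[str, bool | None]  # None = not evaluable (metadata absent)
    excluded: bool
    reasons: list[str]


def _education_mismatch(level, years, bands) -> bool | None:
    if level is None or years is None:
        return None
    try:
        years = float(years)
    except (TypeError, ValueError):
        return None
    if isinstance(level, float) and np.isnan(level):
        return None
    if np.isnan(years):
        return None
    band = bands.get(str(level))
    if band is None:
        return None
    lo, hi = band
    return not (lo <= years <= hi)


def screen_participants(
    records: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    policy: ScreeningPolicy = ScreeningPolicy(),
    section_column: str | None = None,
) -> list[ScreeningReport]:
    """Apply the participant-level exclusion criteria.

    ``section_column``, when present in ``records``, partitions the rating
    block for the straightlining check; otherwise the whole block is one
    section. Exclusion is deterministic: a participant is excluded iff at
    least one enabled criterion fires. Criteria needing absent metadata are
    recorded as ``None`` ("not evaluable") and never exclude.
    """
    if records.empty:
        raise ValueError("empty record set")
    meta_idx = (meta.set_index(meta["participant_id"].astype(str))
                if meta is not None and len(meta) else None)
    reports: list[ScreeningReport] = []
    for pid, grp in records.groupby(records["participant_id"].astype(str), sort=True):
        ratings = grp["rating"].to_numpy()
        flags: dict[str, bool | None] = {}

        if policy.straightlining:
            if section_column and section_column in grp.columns:
                sections = [g["rating"].to_numpy()
                            for _, g in grp.groupby(section_column, observed=True)]
            else:
                sections = [ratings]
            flags["straightlining"] = any(
                len(s) > 1 and len(np.unique(s)) == 1 for s in sections)

        if policy.minimal_rating_variance:
            flags["minimal_rating_variance"] = bool(np.ptp(ratings) <= 1)

        row = None
        if meta_idx is not None and pid in meta_idx.index:
            row = meta_idx.loc[pid]

        if policy.illness_count:
            n_ill = None if row is None else row.get("n_diagnosed_illnesses")
            if n_ill is None or (isinstance(n_ill, float) and np.isnan(n_ill)):
                flags["illness_count"] = None
            else:
                flags["illness_count"] = bool(float(n_ill) >= policy.illness_threshold)

        if policy.education_time_mismatch:
            if row is None:
                flags["education_time_mismatch"] = None
            else:
                mismatch = _education_mismatch(
                    row.get("education_level"), row.get("education_years"),
                    policy.education_bands)
                secs = row.get("completion_seconds")
                fast = (None if secs is None or (isinstance(secs, float) and np.isnan(secs))
                        else bool(float(secs) < policy.completion_threshold_s))
                if mismatch is None or fast is None:
                    flags["education_time_mismatch"] = None
                else:
                    flags["education_time_mismatch"] = bool(mismatch and fast)

        reasons = [name for name, v in flags.items() if v is True]
        reports.append(ScreeningReport(pid, flags, bool(reasons), reasons))
    return reports


def screening_table(reports: Iterable[ScreeningReport]) -> pd.DataFrame:
    """One row per participant, one column per criterion flag."""
    rows = []
    for r in reports:
        row = {"participant_id": r.participant_id, "excluded": r.excluded,
               "reasons": ";".join(r.reasons)}
        for name in SCREEN_CRITERIA:
            v = r.flags.get(name)
            row[name] = "not_evaluable" if v is None else bool(v)
        rows.append(row)
    return pd.DataFrame(rows)


def screening_summary(reports: Sequence[ScreeningReport]) -> dict:
    """Machine-readable counts per criterion and overall."""
    counts = {name: sum(1 for r in reports if r.flags.get(name) is True)
              for name in SCREEN_CRITERIA}
    return {
        "n_participants": len(reports),
        "n_excluded": sum(r.excluded for r in reports),
        "n_retained": sum(not r.excluded for r in reports),
        "per_criterion": counts,
    }


def write_screening(reports: Sequence[ScreeningReport], csv_path, json_path=None) -> None:
    screening_table(reports).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(screening_summary(reports), indent=2))


def retained_records(records: pd.DataFrame,
                     reports: Sequence[ScreeningReport]) -> pd.DataFrame:
    keep = {r.participant_id for r in reports if not r.excluded}
    return records[records["participant_id"].astype(str).isin(keep)].reset_index(drop=True)
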