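"""Morphometric capture records: reading, validation, classification, filtering.

One row per captured manatee. Canonical internal units are meters and
kilograms (field protocols quote length classes in centimeters, so the
reader accepts ``cm_kg`` input via a flag and converts on read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MorphRecord",
    "FilterReport",
    "ReadResult",
    "RowIssue",
    "SchemaError",
    "EmptyAnalysisSetError",
    "CSV_COLUMNS",
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "assign_age_class",
    "merge_field_scores",
    "filter_analysis_set",
    "measurement_subsets",
]

#: Canonical CSV header, in write order.
CSV_COLUMNS = [
    "id", "country", "location", "habitat", "sex",
    "sl", "ug", "w", "field_score", "pregnant_late", "date",
]

HABITATS = ("coastal", "riverine")
SEXES = ("F", "M", "unknown")
FIELD_SCORES = ("C1", "C2", "C3", "C4", "C5", "unscored")

# Plausibility bounds (open intervals) for adult-to-calf manatees; values
# outside are flagged as measurement errors rather than silently dropped.
SL_BOUNDS_M = (0.3, 4.5)
UG_BOUNDS_M = (0.2, 4.0)
W_BOUNDS_KG = (5.0, 2000.0)

# Age-class boundaries (meters).  The printed classes are calves < 175 cm,
# subadults 175-225 cm, adults > 225 cm; both boundary lengths fall in the
# subadult interval.
CALF_MAX_SL_M = 1.75
SUBADULT_MAX_SL_M = 2.25


class SchemaError(ValueError):
    """Input file header does not match the documented column schema."""


class EmptyAnalysisSetError(ValueError):
    """Filtering retained zero records; downstream fits cannot proceed."""


@dataclass
class MorphRecord:
    """One animal's capture record.

    Measurements are optional (any of SL, UG, W may be missing in the
    field data); present measurements are in meters / kilograms.
    """

    id: str
    habitat: str
    sex: str = "unknown"
    country: str = ""
    location: str = ""
    sl_m: Optional[float] = None
    ug_m: Optional[float] = None
    w_kg: Optional[float] = None
    field_score: str = "unscored"
    pregnant_late: bool = False
    date: Optional[str] = None

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}, got {self.habitat!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.field_score not in FIELD_SCORES:
            raise ValueError(f"field_score must be one of {FIELD_SCORES}, got {self.field_score!r}")

    @property
    def age_class(self) -> Optional[str]:
        return assign_age_class(self.sl_m)

    @property
    def condition_group(self) -> str:
        return merge_field_scores(self.field_score)


@dataclass
class RowIssue:
    """A rejected input row: position, id if parseable, and why."""

    row: int
    id: str
    detail: str
    reason: str  # bucket used in FilterReport


@dataclass
class ReadResult:
    records: list[MorphRecord]
    rejected: list[RowIssue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)


@dataclass
class FilterReport:
    """Accounting of filtering: every input row is retained or excluded."""

    n_input: int
    n_retained: int
    n_excluded_by_reason: dict[str, int]

    @property
    def balanced(self) -> bool:
        return self.n_input == self.n_retained + sum(self.n_excluded_by_reason.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded_by_reason": dict(sorted(self.n_excluded_by_reason.items())),
        }


def assign_age_class(sl_m: Optional[float]) -> Optional[str]:
    """Age class from straight-line length: calf, subadult, or adult.

    Calves are shorter than 1.75 m, subadults span 1.75-2.25 m inclusive
    of both boundaries, adults exceed 2.25 m.  Returns ``None`` when the
    length is missing (classification unavailable, never defaulted).
    """
    if sl_m is None or pd.isna(sl_m):
        return None
    if sl_m <= 0:
        raise ValueError(f"sl_m must be positive, got {sl_m}")
    if sl_m < CALF_MAX_SL_M:
        return "calf"
    if sl_m <= SUBADULT_MAX_SL_M:
        return "subadult"
    return "adult"


_SCORE_GROUPS = {
    "C1": "thin", "C2": "thin",
    "C3": "ideal",
    "C4": "obese", "C5": "obese",
    "unscored": "unscored",
}


def merge_field_scores(score: str) -> str:
    """Collapse the five-point field score to thin / ideal / obese / unscored."""
    try:
        return _SCORE_GROUPS[score]
    except KeyError:
        raise SchemaError(f"unknown field score label {score!r}") from None


def _parse_float(raw: str, col: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "" or raw.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"non_numeric:{col}") from None


_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n", ""}


def read_records(path, units: str = "m_kg") -> ReadResult:
    """Read a morphometric CSV into validated :class:`MorphRecord` rows.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with header ``id,country,location,habitat,sex,
        sl,ug,w,field_score,pregnant_late,date``.
    units : {"m_kg", "cm_kg"}
        Whether lengths arrive in meters or centimeters (converted to
        meters on read; mass is kilograms either way).

    Returns
    -------
    ReadResult
        Validated records plus a side list of rejected rows with reasons;
        no row is silently lost.
    """
    if units not in ("m_kg", "cm_kg"):
        raise ValueError(f"units must be 'm_kg' or 'cm_kg', got {units!r}")
    length_div = 100.0 if units == "cm_kg" else 1.0

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    unknown = [c for c in raw.columns if c not in CSV_COLUMNS]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")

    records: list[MorphRecord] = []
    rejected: list[RowIssue] = []
    n_assumed_not_pregnant = 0

    for i, row in enumerate(raw.itertuples(index=False)):
        rid = str(row.id).strip()
        try:
            if not rid:
                raise _Invalid("missing_required_fields", "empty id")
            habitat = str(row.habitat).strip().lower()
            if habitat not in HABITATS:
                raise _Invalid("missing_required_fields", f"invalid habitat {row.habitat!r}")
            sex = str(row.sex).strip()
            if sex == "":
                sex = "unknown"
            if sex not in SEXES:
                raise _Invalid("missing_required_fields", f"invalid sex {row.sex!r}")
            score = str(row.field_score).strip()
            if score == "":
                score = "unscored"
            if score not in FIELD_SCORES:
                raise _Invalid("missing_required_fields", f"invalid field score {row.field_score!r}")

            try:
                sl = _parse_float(row.sl, "sl")
                ug = _parse_float(row.ug, "ug")
                w = _parse_float(row.w, "w")
            except ValueError as exc:
                raise _Invalid("invalid_measurement", str(exc)) from None
            if sl is not None:
                sl /= length_div
            if ug is not None:
                ug /= length_div

            for name, val, (lo, hi) in (
                ("sl", sl, SL_BOUNDS_M), ("ug", ug, UG_BOUNDS_M), ("w", w, W_BOUNDS_KG),
            ):
                if val is None:
                    continue
                if val <= 0:
                    raise _Invalid("invalid_measurement", f"nonpositive:{name}")
                if not (lo < val < hi):
                    raise _Invalid("invalid_measurement", f"implausible:{name}={val}")

            preg_raw = str(row.pregnant_late).strip().lower()
            if preg_raw in _TRUTHY:
                pregnant = True
            elif preg_raw in _FALSY:
                pregnant = False
                if preg_raw == "":
                    n_assumed_not_pregnant += 1
            else:
                raise _Invalid("invalid_measurement", f"invalid pregnant_late {row.pregnant_late!r}")

            date = str(row.date).strip() or None
            records.append(MorphRecord(
                id=rid, habitat=habitat, sex=sex,
                country=str(row.country).strip(), location=str(row.location).strip(),
                sl_m=sl, ug_m=ug, w_kg=w,
                field_score=score, pregnant_late=pregnant, date=date,
            ))
        except _Invalid as inv:
            rejected.append(RowIssue(row=i, id=rid, detail=inv.detail, reason=inv.reason))

    if n_assumed_not_pregnant:
        logger.info(
            "pregnant_late missing on %d row(s); assumed not late-pregnant",
            n_assumed_not_pregnant,
        )
    return ReadResult(records=records, rejected=rejected)


class _Invalid(Exception):
    def __init__(self, reason: str, detail: str):
        self.reason = reason
        self.detail = detail
        super().__init__(detail)


def records_to_frame(records: Iterable[MorphRecord]) -> pd.DataFrame:
    """Records as a DataFrame with canonical columns (meters / kilograms)."""
    rows = [{
        "id": r.id, "country": r.country, "location": r.location,
        "habitat": r.habitat, "sex": r.sex,
        "sl_m": r.sl_m, "ug_m": r.ug_m, "w_kg": r.w_kg,
        "field_score": r.field_score, "pregnant_late": r.pregnant_late,
        "date": r.date,
    } for r in records]
    cols = ["id", "country", "location", "habitat", "sex", "sl_m", "ug_m",
            "w_kg", "field_score", "pregnant_late", "date"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(frame: pd.DataFrame) -> list[MorphRecord]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(MorphRecord(
            id=str(row.id), habitat=row.habitat, sex=row.sex,
            country=getattr(row, "country", "") or "",
            location=getattr(row, "location", "") or "",
            sl_m=None if pd.isna(row.sl_m) else float(row.sl_m),
            ug_m=None if pd.isna(row.ug_m) else float(row.ug_m),
            w_kg=None if pd.isna(row.w_kg) else float(row.w_kg),
            field_score=row.field_score, pregnant_late=bool(row.pregnant_late),
            date=None if (getattr(row, "date", None) in (None, "") or pd.isna(getattr(row, "date"))) else str(row.date),
        ))
    return out


def write_records(records: Iterable[MorphRecord], path) -> None:
    """Write records as CSV in canonical meters/kilograms units.

    Deterministic column order; round-trips through :func:`read_records`
    at full float precision (repr-exact floats).
    """
    frame = records_to_frame(records)
    frame = frame.rename(columns={"sl_m": "sl", "ug_m": "ug", "w_kg": "w"})
    frame[CSV_COLUMNS].to_csv(path, index=False, float_format=None)


def filter_analysis_set(
    records: Sequence[MorphRecord],
    include_condition_groups: bool = False,
    exclude_ids: Iterable[str] = (),
    read_issues: Sequence[RowIssue] = (),
) -> tuple[list[MorphRecord], FilterReport]:
    """Apply the analysis inclusion rules.

    The main BCI analysis (default) keeps only animals with an ideal (C3)
    or unscored field condition and excludes late-pregnancy females.  With
    ``include_condition_groups=True`` (the field-condition factor model),
    thin and obese animals are re-incorporated; late-pregnancy exclusion
    still applies.  ``exclude_ids`` reproduces ad-hoc per-record exclusions
    (e.g. single atypically large animals) transparently.

    ``read_issues`` from :func:`read_records` may be passed so the report
    accounts for every raw input row.
    """
    exclude_ids = set(exclude_ids)
    reasons: dict[str, int] = {}
    for issue in read_issues:
        reasons[issue.reason] = reasons.get(issue.reason, 0) + 1

    retained: list[MorphRecord] = []
    for rec in records:
        if rec.id in exclude_ids:
            reasons["listed_exclusion"] = reasons.get("listed_exclusion", 0) + 1
            continue
        if rec.pregnant_late:
            reasons["late_pregnancy"] = reasons.get("late_pregnancy", 0) + 1
            continue
        group = rec.condition_group
        if not include_condition_groups and group in ("thin", "obese"):
            key = "thin_score" if group == "thin" else "obese_score"
            reasons[key] = reasons.get(key, 0) + 1
            continue
        retained.append(rec)

    report = FilterReport(
        n_input=len(records) + len(read_issues),
        n_retained=len(retained),
        n_excluded_by_reason=reasons,
    )
    return retained, report


def measurement_subsets(records: Sequence[MorphRecord]) -> dict[str, list[MorphRecord]]:
    """Partition-by-availability into the three index-specific subsets.

    A record may belong to several subsets: bci1 needs SL and UG, bci2
    needs W and SL, bci3 needs all three.
    """
    subsets: dict[str, list[MorphRecord]] = {"bci1": [], "bci2": [], "bci3": []}
    for rec in records:
        has_sl = rec.sl_m is not None
        has_ug = rec.ug_m is not None
        has_w = rec.w_kg is not None
        if has_sl and has_ug:
            subsets["bci1"].append(rec)
        if has_sl and has_w:
            subsets["bci2"].append(rec)
        if has_sl and has_ug and has_w:
            subsets["bci3"].append(rec)
    logger.info(
        "measurement subsets: bci1=%d bci2=%d bci3=%d",
        len(subsets["bci1"]), len(subsets["bci2"]), len(subsets["bci3"]),
    )
    return subsets
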