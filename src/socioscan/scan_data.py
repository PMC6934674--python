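"""Data model, I/O and validation for behavioural scan records.

The observation unit is a *scan*: an instantaneous survey of the group in
which each visible individual's location context (road/forest), behavioural
state and nearest neighbours (conspecifics within 1 m) are recorded.  Scans
are stored long-format, one row per (scan, individual).  Directed affiliative
interactions are kept in a separate record type because they carry an
actor/recipient orientation that scan rows do not.

File dialect: UTF-8 CSV, ISO-8601 dates, neighbour ids ";"-separated within
one cell.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AGE_CLASSES = ("adult", "subadult", "juvenile", "infant")
SEXES = ("male", "female")
CONTEXTS = ("road", "forest")
PERIODS = ("morning", "afternoon")
#: The behavioural states recognised in scan records.
STATES = (
    "affiliative",
    "aggressive",
    "grooming",
    "feeding",
    "foraging",
    "following",
    "locomote",
    "greeting",
    "rest",
    "sexual",
    "play",
)

SCAN_COLUMNS = ["scan_id", "date", "period", "individual_id", "context", "state", "neighbours"]
INTERACTION_COLUMNS = ["scan_id", "actor", "recipient", "context"]
ROSTER_COLUMNS = ["id", "age_class", "sex", "present_full_study"]


class ScanDataError(ValueError):
    """Base error for malformed or invalid scan data files."""


class FormatError(ScanDataError):
    """A required column is missing or a file is structurally unreadable."""


class ValidationError(ScanDataError):
    """One or more rows violate the record invariants.

    Attributes
    ----------
    errors : list of str
        One human-readable message per offending row, with line numbers.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} validation error(s): {preview}{more}")


@dataclass(frozen=True)
class Individual:
    """A roster entry: one group member with its age-sex classification."""

    id: str
    age_class: str
    sex: str
    present_full_study: bool = True

    def __post_init__(self):
        if self.age_class not in AGE_CLASSES:
            raise ValidationError([f"individual {self.id!r}: unknown age_class {self.age_class!r}"])
        if self.sex not in SEXES:
            raise ValidationError([f"individual {self.id!r}: unknown sex {self.sex!r}"])

    @property
    def age_sex_class(self) -> str:
        return f"{self.age_class} {self.sex}"


@dataclass
class Roster:
    """Ordered collection of :class:`Individual` with unique ids."""

    individuals: list[Individual]

    def __post_init__(self):
        ids = [ind.id for ind in self.individuals]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError([f"duplicate roster id(s): {dupes}"])

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == id:
                return ind
        raise KeyError(id)

    def age_sex_classes(self) -> dict[str, str]:
        return {ind.id: ind.age_sex_class for ind in self.individuals}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "age_class": [i.age_class for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "present_full_study": [i.present_full_study for i in self.individuals],
            }
        )


@dataclass(frozen=True)
class SightingCounts:
    """Per-individual scan counts for one context ('road', 'forest' or 'all')."""

    context: str
    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, id: str) -> int:
        return self.counts[id]


# ---------------------------------------------------------------------------
# readers / writers


def read_roster(path: str | Path) -> Roster:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ROSTER_COLUMNS, path)
    inds = [
        Individual(
            id=row.id,
            age_class=row.age_class,
            sex=row.sex,
            present_full_study=str(row.present_full_study).strip().lower() in ("true", "1", "yes"),
        )
        for row in df.itertuples()
    ]
    return Roster(inds)


def write_roster(roster: Roster, path: str | Path) -> None:
    roster.to_frame().to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_neighbours(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return frozenset()
    return frozenset(p.strip() for p in str(cell).split(";") if p.strip())


def read_scans(
    path: str | Path,
    roster: Roster,
    interactions_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate scan records (and optionally interaction records).

    Returns ``(scans, interactions)`` DataFrames; ``interactions`` is empty
    when no path is given.  Raises :class:`ValidationError` listing every
    offending row (1-based data line numbers) if any invariant fails.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, SCAN_COLUMNS, path)
    scans = validate_scans(raw, roster, source=str(path))
    if interactions_path is not None:
        iraw = pd.read_csv(interactions_path, dtype=str, keep_default_na=False)
        _require_columns(iraw, INTERACTION_COLUMNS, interactions_path)
        interactions = validate_interactions(iraw, roster, source=str(interactions_path))
    else:
        interactions = pd.DataFrame(columns=INTERACTION_COLUMNS)
    return scans, interactions


def validate_scans(raw: pd.DataFrame, roster: Roster, source: str = "<scans>") -> pd.DataFrame:
    known = set(roster.ids)
    errors: list[str] = []
    rows = []
    seen_pairs: set[tuple[int, str]] = set()
    for lineno, row in enumerate(raw.itertuples(index=False), start=2):
        prefix = f"{source}:{lineno}"
        try:
            scan_id = int(row.scan_id)
        except ValueError:
            errors.append(f"{prefix}: malformed scan_id {row.scan_id!r}")
            continue
        try:
            date = _dt.date.fromisoformat(str(row.date))
        except ValueError:
            errors.append(f"{prefix}: malformed date {row.date!r} (expected ISO-8601)")
            continue
        if row.period not in PERIODS:
            errors.append(f"{prefix}: unknown period {row.period!r}")
            continue
        if row.context not in CONTEXTS:
            errors.append(f"{prefix}: unknown context {row.context!r}")
            continue
        if row.state not in STATES:
            errors.append(f"{prefix}: unknown state {row.state!r}")
            continue
        if row.individual_id not in known:
            errors.append(f"{prefix}: unknown individual id {row.individual_id!r}")
            continue
        neighbours = _parse_neighbours(row.neighbours)
        unknown_n = sorted(neighbours - known)
        if unknown_n:
            errors.append(f"{prefix}: unknown neighbour id(s) {unknown_n} in scan {scan_id}")
            continue
        if row.individual_id in neighbours:
            errors.append(
                f"{prefix}: individual {row.individual_id!r} listed as its own neighbour in scan {scan_id}"
            )
            continue
        key = (scan_id, row.individual_id)
        if key in seen_pairs:
            errors.append(f"{prefix}: duplicate record for individual {row.individual_id!r} in scan {scan_id}")
            continue
        seen_pairs.add(key)
        rows.append((scan_id, date, row.period, row.individual_id, row.context, row.state, neighbours))
    if errors:
        raise ValidationError(errors)
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def validate_interactions(raw: pd.DataFrame, roster: Roster, source: str = "<interactions>") -> pd.DataFrame:
    known = set(roster.ids)
    errors: list[str] = []
    rows = []
    for lineno, row in enumerate(raw.itertuples(index=False), start=2):
        prefix = f"{source}:{lineno}"
        try:
            scan_id = int(row.scan_id)
        except ValueError:
            errors.append(f"{prefix}: malformed scan_id {row.scan_id!r}")
            continue
        if row.actor not in known or row.recipient not in known:
            bad = sorted({x for x in (row.actor, row.recipient) if x not in known})
            errors.append(f"{prefix}: unknown individual id(s) {bad}")
            continue
        if row.actor == row.recipient:
            errors.append(f"{prefix}: self-directed interaction for {row.actor!r} in scan {scan_id}")
            continue
        if row.context not in CONTEXTS:
            errors.append(f"{prefix}: unknown context {row.context!r}")
            continue
        rows.append((scan_id, row.actor, row.recipient, row.context))
    if errors:
        raise ValidationError(errors)
    return pd.DataFrame(rows, columns=INTERACTION_COLUMNS)


def write_scans(scans: pd.DataFrame, path: str | Path) -> None:
    out = scans.copy()
    out["neighbours"] = out["neighbours"].map(lambda s: ";".join(sorted(s)))
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def write_interactions(interactions: pd.DataFrame, path: str | Path) -> None:
    interactions.to_csv(path, index=False)


def validation_report(
    scans: pd.DataFrame, interactions: pd.DataFrame, roster: Roster, path: str | Path | None = None
) -> dict:
    """Summarise a validated dataset as a JSON-serialisable report."""
    report = {
        "n_individuals": len(roster),
        "n_scan_records": int(len(scans)),
        "n_scans": int(scans["scan_id"].nunique()) if len(scans) else 0,
        "n_interaction_records": int(len(interactions)),
        "records_by_context": scans["context"].value_counts().to_dict() if len(scans) else {},
        "date_range": [scans["date"].min().isoformat(), scans["date"].max().isoformat()] if len(scans) else None,
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# exclusions and tallies


def apply_exclusions(
    scans: pd.DataFrame, interactions: pd.DataFrame, roster: Roster
) -> tuple[pd.DataFrame, pd.DataFrame, Roster]:
    """Drop infants and part-time individuals, returning the analysis roster.

    Records *by* an excluded individual are dropped; excluded ids are pruned
    from other records' neighbour sets rather than dropping those rows, so
    the focal individual's sighting count (the association-index denominator)
    is preserved.
    """
    keep = [ind for ind in roster if ind.present_full_study and ind.age_class != "infant"]
    if not keep:
        raise ScanDataError("exclusions leave an empty analysis roster")
    analysis = Roster(keep)
    keep_ids = set(analysis.ids)
    out = scans[scans["individual_id"].isin(keep_ids)].copy()
    out["neighbours"] = out["neighbours"].map(lambda s: s & keep_ids)
    inter = interactions[
        interactions["actor"].isin(keep_ids) & interactions["recipient"].isin(keep_ids)
    ].reset_index(drop=True)
    return out.reset_index(drop=True), inter, analysis


def tally_sightings(scans: pd.DataFrame, context: str, roster: Roster) -> SightingCounts:
    """Number of distinct scans in which each individual was recorded.

    ``context`` is ``'road'``, ``'forest'`` or ``'all'``.  An individual seen
    with no neighbours still counts as one sighting.
    """
    if context not in (*CONTEXTS, "all"):
        raise ValueError(f"context must be one of {CONTEXTS + ('all',)}, got {context!r}")
    sub = scans if context == "all" else scans[scans["context"] == context]
    counts = sub.groupby("individual_id")["scan_id"].nunique() if len(sub) else pd.Series(dtype=int)
    return SightingCounts(context=context, counts={i: int(counts.get(i, 0)) for i in roster.ids})
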