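"""Domain types for cohort tables and variable rosters, plus file I/O.

A :class:`VariableRoster` declares, for every column of a participant x
variable table, its analysis role (``outcome`` / ``putative`` /
``covariate``), its measurement scale, the follow-up month it was
collected at, optional score bounds, and an optional subscale-family tag
(e.g. ``"CERQ"``) used by the factor-combination step.

A :class:`CohortTable` is the purely numeric rectangle the rest of the
package operates on.  Categorical variables are integer-coded (level
labels live in the roster) so that the whole table is one float matrix;
missing entries are ``NaN`` and are mirrored by ``missing_mask``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError

ROLES = ("outcome", "putative", "covariate")
SCALES = ("continuous", "binary", "ordinal", "categorical")

#: strings read as missing in CSV cells (the empty string is the write-side sentinel)
MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class RosterEntry:
    """Metadata for one column of a cohort table."""

    name: str
    role: str
    scale: str
    month: int = 0
    bounds: tuple[float, float] | None = None
    group: str | None = None
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("roster entry has an empty name")
        if self.role not in ROLES:
            raise ValidationError(
                f"variable {self.name!r}: role {self.role!r} not in {ROLES}"
            )
        if self.scale not in SCALES:
            raise ValidationError(
                f"variable {self.name!r}: scale {self.scale!r} not in {SCALES}"
            )
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo < hi:
                raise ValidationError(
                    f"variable {self.name!r}: bounds ({lo}, {hi}) must satisfy min < max"
                )
            object.__setattr__(self, "bounds", (float(lo), float(hi)))
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))

    def to_record(self) -> dict:
        rec: dict = {
            "name": self.name,
            "role": self.role,
            "scale": self.scale,
            "month": self.month,
        }
        if self.bounds is not None:
            rec["bounds"] = [self.bounds[0], self.bounds[1]]
        if self.group is not None:
            rec["group"] = self.group
        if self.levels is not None:
            rec["levels"] = list(self.levels)
        return rec

    @classmethod
    def from_record(cls, rec: Mapping) -> "RosterEntry":
        known = {"name", "role", "scale", "month", "bounds", "group", "levels"}
        extra = set(rec) - known
        if extra:
            raise SchemaError(f"unknown roster keys {sorted(extra)} in entry {rec.get('name')!r}")
        bounds = rec.get("bounds")
        return cls(
            name=str(rec["name"]),
            role=str(rec["role"]),
            scale=str(rec["scale"]),
            month=int(rec.get("month", 0)),
            bounds=tuple(bounds) if bounds is not None else None,
            group=rec.get("group"),
            levels=tuple(rec["levels"]) if rec.get("levels") is not None else None,
        )


@dataclass(frozen=True)
class VariableRoster:
    """Ordered, validated collection of :class:`RosterEntry`."""

    entries: tuple[RosterEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate variable names in roster: {sorted(dupes)}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RosterEntry]:
        return iter(self.entries)

    def __getitem__(self, name: str) -> RosterEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise SchemaError(f"unknown variable {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    # -- views --------------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def by_role(self, role: str) -> tuple[str, ...]:
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r}")
        return tuple(e.name for e in self.entries if e.role == role)

    def group_members(self, group: str) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.group == group)

    def drop(self, names: Iterable[str]) -> "VariableRoster":
        gone = set(names)
        unknown = gone - set(self.names)
        if unknown:
            raise SchemaError(f"unknown variables {sorted(unknown)}")
        return VariableRoster(tuple(e for e in self.entries if e.name not in gone))

    def replace_entries(self, entries: Sequence[RosterEntry]) -> "VariableRoster":
        return VariableRoster(tuple(entries))

    # -- file I/O -----------------------------------------------------------
    def to_records(self) -> list[dict]:
        return [e.to_record() for e in self.entries]

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "VariableRoster":
        return cls(tuple(RosterEntry.from_record(r) for r in records))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_records(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_records(), sort_keys=False))

    @classmethod
    def read(cls, path: str | Path) -> "VariableRoster":
        path = Path(path)
        text = path.read_text()
        records = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(records, list):
            raise SchemaError(f"roster file {path} must contain a list of entries")
        return cls.from_records(records)


@dataclass
class CohortTable:
    """Participant x variable matrix with missingness and roster metadata.

    ``values`` is float64, one column per roster entry in roster order;
    missing cells are ``NaN``.  The boolean ``missing_mask`` is derived
    from the values so the two can never disagree.
    """

    values: np.ndarray
    roster: VariableRoster
    participant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.participant_ids = tuple(str(i) for i in self.participant_ids)
        n, p = self.values.shape
        if p != len(self.roster):
            raise ValidationError(
                f"table has {p} columns but roster declares {len(self.roster)}"
            )
        if n != len(self.participant_ids):
            raise ValidationError(
                f"table has {n} rows but {len(self.participant_ids)} participant ids"
            )
        for j, e in enumerate(self.roster):
            if e.bounds is None:
                continue
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            lo, hi = e.bounds
            bad = obs[(obs < lo) | (obs > hi)]
            if bad.size:
                raise ValidationError(
                    f"variable {e.name!r}: value {bad[0]!r} outside bounds ({lo}, {hi})"
                )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.roster.index(name)]

    def with_values(self, values: np.ndarray, roster: VariableRoster | None = None,
                    participant_ids: Sequence[str] | None = None) -> "CohortTable":
        return CohortTable(
            values=values,
            roster=roster if roster is not None else self.roster,
            participant_ids=tuple(participant_ids) if participant_ids is not None
            else self.participant_ids,
        )


@dataclass(frozen=True)
class CompleteCaseReport:
    """Accounting for a complete-case filter: counts and one-decimal percents."""

    n_input: int
    retained: int
    excluded: int
    retained_percent: float
    excluded_percent: float


def _percent(numerator: int, denominator: int) -> float:
    """Percentage to one decimal with half-up rounding (presentation convention)."""
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def read_cohort(table_path: str | Path, roster_path: str | Path) -> CohortTable:
    """Read a CSV table plus its roster into a validated :class:`CohortTable`.

    The CSV must carry a header row whose names match the roster exactly
    (any column order; output is normalized to roster order).  Empty cells
    and ``NA`` denote missing values.
    """
    roster = VariableRoster.read(roster_path)
    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    have = list(df.columns)
    missing_cols = [n for n in roster.names if n not in have]
    extra_cols = [n for n in have if n not in roster.names]
    if missing_cols or extra_cols:
        raise SchemaError(
            f"table/roster mismatch: missing columns {missing_cols}, "
            f"extra columns {extra_cols}"
        )
    n = len(df)
    values = np.empty((n, len(roster)), dtype=float)
    for j, name in enumerate(roster.names):
        cells = df[name].tolist()
        for i, cell in enumerate(cells):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} at row {i}, column {name!r}"
                ) from None
    ids = tuple(f"P{i:04d}" for i in range(1, n + 1))
    return CohortTable(values=values, roster=roster, participant_ids=ids)


def write_cohort(table: CohortTable, table_path: str | Path) -> None:
    """Write the table as UTF-8 CSV; missing cells become empty strings.

    Values are printed with ``repr`` so a write -> read round trip is
    bit-exact on the float matrix.
    """
    cols = {}
    for j, name in enumerate(table.roster.names):
        col = table.values[:, j]
        cols[name] = ["" if np.isnan(v) else repr(float(v)) for v in col]
    pd.DataFrame(cols).to_csv(table_path, index=False)


def filter_complete_cases(
    table: CohortTable, required_variables: Sequence[str]
) -> tuple[CohortTable, CompleteCaseReport]:
    """Drop rows missing any of ``required_variables``; report the retention.

    The percent fields follow the cohort-paper presentation convention of
    one decimal place with half-up rounding (e.g. 235/303 -> 77.6).
    """
    idx = [table.roster.index(v) for v in required_variables]
    keep = ~np.isnan(table.values[:, idx]).any(axis=1) if idx else np.ones(
        table.n_rows, dtype=bool
    )
    retained = int(keep.sum())
    excluded = table.n_rows - retained
    report = CompleteCaseReport(
        n_input=table.n_rows,
        retained=retained,
        excluded=excluded,
        retained_percent=_percent(retained, table.n_rows) if table.n_rows else 0.0,
        excluded_percent=_percent(excluded, table.n_rows) if table.n_rows else 0.0,
    )
    filtered = table.with_values(
        table.values[keep],
        participant_ids=[p for p, k in zip(table.participant_ids, keep) if k],
    )
    return filtered, report
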