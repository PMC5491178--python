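"""Linked administrative-claims data model.

The study universe is a set of six linked tables that mirror the structure of
provincial health-administrative holdings: a person registry with coverage
eligibility (the population denominator), outpatient physician billing claims
(one diagnostic code per claim), same-day-surgery procedure records (up to 20
diagnostic codes, coded retrospectively by hospital coders), hospital
discharge abstracts, a physician-specialty registry, and an optional
reference-standard label table from chart review.

All tables are held as pandas DataFrames with documented canonical columns;
dates are ISO-8601 in files and ``datetime64[ns]`` in memory.  Coverage
eligibility is a list of half-open ``[start, end)`` intervals serialized as
``"start..end;start..end"`` in the registry CSV, which makes gap detection
for the continuous-eligibility rule unambiguous.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "LinkageError",
    "CodeConfig",
    "PersonRecord",
    "LinkedClaimsBundle",
    "SPECIALTIES",
    "GI_SPECIALTIES",
    "load_bundle",
    "write_bundle",
    "age_at",
    "age_in_months_at",
    "continuously_eligible",
    "merge_intervals",
]


class SchemaError(ValueError):
    """A table violates its declared schema (bad field, bad row)."""


class LinkageError(ValueError):
    """An event references a person or physician absent from its registry."""


SPECIALTIES = (
    "gastroenterology_adult",
    "gastroenterology_pediatric",
    "pediatrics",
    "family_medicine",
    "other",
)

#: Specialties whose outpatient contacts count as gastroenterologist visits.
GI_SPECIALTIES = frozenset({"gastroenterology_adult", "gastroenterology_pediatric"})

MAX_DIAGNOSTIC_CODES = 20

#: Canonical column order per table (write_bundle emits exactly this order).
TABLE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "registry": ("person_id", "birth_date", "sex", "region_flag", "eligibility_intervals"),
    "claims": ("person_id", "service_date", "physician_id", "diagnostic_code", "fee_code"),
    "procedures": ("person_id", "procedure_date", "facility_id", "intervention_codes", "diagnostic_codes"),
    "hospitalizations": ("person_id", "admission_date", "discharge_date", "diagnostic_codes"),
    "physicians": ("physician_id", "specialty"),
    "labels": ("person_id", "status", "diagnosis_date", "marsh_class"),
}

DATE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "registry": ("birth_date",),
    "claims": ("service_date",),
    "procedures": ("procedure_date",),
    "hospitalizations": ("admission_date", "discharge_date"),
    "physicians": (),
    "labels": ("diagnosis_date",),
}


@dataclass(frozen=True)
class CodeConfig:
    """Configured code sets and the code-match rule.

    Codes are matched by prefix by default ("579" matches "579", "579.0",
    "5790"), reconciling 3-character outpatient claim codes with the
    4-character ICD-9 celiac code 579.0.  Exact matching is available via
    ``match="exact"``.  The endoscopy fee/intervention sets are placeholders
    standing in for the jurisdictional fee schedule, which is configurable.
    """

    celiac_codes: tuple[str, ...] = ("579",)
    endoscopy_fee_codes: tuple[str, ...] = ("Z555", "Z715")
    endoscopy_intervention_codes: tuple[str, ...] = ("1OD16", "2OD71")
    match: str = "prefix"

    def __post_init__(self) -> None:
        if self.match not in ("prefix", "exact"):
            raise ValueError(f"unknown code match rule {self.match!r}")

    def matches(self, code: str, code_set: Sequence[str]) -> bool:
        code = str(code)
        if self.match == "exact":
            return code in set(code_set)
        return any(code.startswith(c.rstrip(".")) or c.startswith(code)
                   for c in (str(s) for s in code_set))

    def is_celiac(self, code: str) -> bool:
        # Prefix rule deliberately asymmetric for celiac: a 3-char claim code
        # "579" matches the configured "579"; "5790"/"579.0" also match.
        code = str(code).replace(".", "")
        if self.match == "exact":
            return code in {c.replace(".", "") for c in self.celiac_codes}
        return any(code.startswith(c.replace(".", "")) for c in self.celiac_codes)

    def any_celiac(self, codes: Iterable[str]) -> bool:
        return any(self.is_celiac(c) for c in codes)

    @classmethod
    def from_file(cls, path: str | Path) -> "CodeConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            celiac_codes=tuple(raw.get("celiac_codes", ("579",))),
            endoscopy_fee_codes=tuple(raw.get("endoscopy_fee_codes", ("Z555", "Z715"))),
            endoscopy_intervention_codes=tuple(
                raw.get("endoscopy_intervention_codes", ("1OD16", "2OD71"))),
            match=raw.get("match", "prefix"),
        )


@dataclass(frozen=True)
class PersonRecord:
    """One registry row: demographics plus coverage-eligibility intervals."""

    person_id: str
    birth_date: dt.date
    sex: str
    region_flag: bool = True
    eligibility_intervals: tuple[tuple[dt.date, dt.date], ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise SchemaError(f"person {self.person_id}: unknown sex {self.sex!r}")
        prev_end = None
        for start, end in self.eligibility_intervals:
            if start >= end:
                raise SchemaError(f"person {self.person_id}: empty interval {start}..{end}")
            if start < self.birth_date:
                raise SchemaError(
                    f"person {self.person_id}: eligibility starts before birth")
            if prev_end is not None and start < prev_end:
                raise SchemaError(
                    f"person {self.person_id}: overlapping/unsorted intervals")
            prev_end = end


@dataclass
class LinkedClaimsBundle:
    """The five linked administrative tables plus optional truth labels.

    Every ``person_id`` appearing in an event table must exist in the
    registry, and every ``physician_id`` in claims must exist in the
    physician table (deterministic linkage is assumed done upstream).
    """

    registry: pd.DataFrame
    claims: pd.DataFrame
    procedures: pd.DataFrame
    hospitalizations: pd.DataFrame
    physicians: pd.DataFrame
    labels: pd.DataFrame | None = None
    codes: CodeConfig = field(default_factory=CodeConfig)

    def validate(self) -> "LinkedClaimsBundle":
        for name in ("registry", "claims", "procedures", "hospitalizations", "physicians"):
            df = getattr(self, name)
            missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
            if missing:
                raise SchemaError(f"{name}: missing columns {missing}")
        if self.registry["person_id"].duplicated().any():
            dup = self.registry.loc[self.registry["person_id"].duplicated(), "person_id"].iloc[0]
            raise SchemaError(f"registry: duplicate person_id {dup!r}")
        if self.physicians["physician_id"].duplicated().any():
            raise SchemaError("physicians: duplicate physician_id")
        bad_sex = ~self.registry["sex"].isin(["male", "female"])
        if bad_sex.any():
            row = int(bad_sex.idxmax())
            raise SchemaError(
                f"registry: row {row}: unknown sex "
                f"{self.registry.loc[row, 'sex']!r}")
        known = set(self.registry["person_id"])
        for name in ("claims", "procedures", "hospitalizations"):
            df = getattr(self, name)
            orphan = ~df["person_id"].isin(known)
            if orphan.any():
                row = int(orphan.idxmax())
                raise LinkageError(
                    f"{name}: row {row}: person_id "
                    f"{df.loc[row, 'person_id']!r} not in registry")
        known_md = set(self.physicians["physician_id"])
        orphan = ~self.claims["physician_id"].isin(known_md)
        if orphan.any():
            row = int(orphan.idxmax())
            raise LinkageError(
                f"claims: row {row}: physician_id "
                f"{self.claims.loc[row, 'physician_id']!r} not in physician table")
        n_codes = self.procedures["diagnostic_codes"].map(_count_codes)
        bad = (n_codes > MAX_DIAGNOSTIC_CODES) | (n_codes == 0)
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"procedures: row {row}: {n_codes.loc[row]} diagnostic codes "
                f"(must be 1..{MAX_DIAGNOSTIC_CODES})")
        if self.labels is not None:
            pos = self.labels["status"] == "true_positive"
            bad = pos & (self.labels["diagnosis_date"].isna()
                         | ~self.labels["marsh_class"].isin(["3a", "3b", "3c"]))
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"labels: row {row}: true_positive requires diagnosis_date "
                    "and Marsh class 3a/3b/3c")
        return self

    def person(self, person_id: str) -> PersonRecord:
        row = self.registry.loc[self.registry["person_id"] == person_id]
        if row.empty:
            raise LinkageError(f"person_id {person_id!r} not in registry")
        r = row.iloc[0]
        return PersonRecord(
            person_id=r["person_id"],
            birth_date=_as_date(r["birth_date"]),
            sex=r["sex"],
            region_flag=bool(r["region_flag"]),
            eligibility_intervals=parse_intervals(r["eligibility_intervals"]),
        )

    def eligibility_table(self) -> pd.DataFrame:
        """Explode registry eligibility into one (person_id, start, end) per row."""
        rows = []
        for pid, spec in zip(self.registry["person_id"], self.registry["eligibility_intervals"]):
            for start, end in parse_intervals(spec):
                rows.append((pid, start, end))
        out = pd.DataFrame(rows, columns=["person_id", "start", "end"])
        out["start"] = pd.to_datetime(out["start"])
        out["end"] = pd.to_datetime(out["end"])
        return out

    def with_codes(self, codes: CodeConfig) -> "LinkedClaimsBundle":
        return replace(self, codes=codes)


def _count_codes(codes: object) -> int:
    if isinstance(codes, (list, tuple)):
        return len(codes)
    s = str(codes).strip()
    return 0 if not s else len(s.split(";"))


def split_codes(codes: object) -> list[str]:
    if isinstance(codes, (list, tuple)):
        return [str(c) for c in codes]
    s = str(codes).strip()
    return [] if not s else s.split(";")


def _as_date(value: object) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, pd.Timestamp):
        return value.date()
    return dt.date.fromisoformat(str(value))


def parse_intervals(spec: object) -> tuple[tuple[dt.date, dt.date], ...]:
    """Parse ``"2004-01-01..2012-01-01;..."`` into half-open interval tuples."""
    if spec is None or (isinstance(spec, float) and pd.isna(spec)):
        return ()
    s = str(spec).strip()
    if not s:
        return ()
    out = []
    for part in s.split(";"):
        try:
            start_s, end_s = part.split("..")
        except ValueError as exc:
            raise SchemaError(f"malformed eligibility interval {part!r}") from exc
        out.append((dt.date.fromisoformat(start_s), dt.date.fromisoformat(end_s)))
    return tuple(out)


def format_intervals(intervals: Iterable[tuple[dt.date, dt.date]]) -> str:
    return ";".join(f"{s.isoformat()}..{e.isoformat()}" for s, e in intervals)


def load_bundle(paths: Mapping[str, str | Path] | str | Path,
                codes: CodeConfig | None = None) -> LinkedClaimsBundle:
    """Load a bundle from CSV tables and validate all linkage invariants.

    ``paths`` is either a directory containing ``registry.csv`` etc., or an
    explicit table-name → path mapping.  ``labels.csv`` is optional.
    """
    if isinstance(paths, (str, Path)):
        d = Path(paths)
        paths = {name: d / f"{name}.csv" for name in TABLE_COLUMNS
                 if (d / f"{name}.csv").exists() or name != "labels"}
    tables: dict[str, pd.DataFrame | None] = {}
    for name in TABLE_COLUMNS:
        p = paths.get(name)
        if p is None or not Path(p).exists():
            if name == "labels":
                tables[name] = None
                continue
            raise SchemaError(f"missing table file for {name!r}")
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing columns {missing}")
        for col in DATE_COLUMNS[name]:
            raw = df[col].replace("", None)
            parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
            bad = parsed.isna() & raw.notna()
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{name}: row {row}: field {col!r}: unparseable date "
                    f"{df.loc[row, col]!r}")
            df[col] = parsed
        if name == "registry":
            df["region_flag"] = df["region_flag"].str.lower().isin(["true", "1", "yes"])
        tables[name] = df
    bundle = LinkedClaimsBundle(
        registry=tables["registry"],
        claims=tables["claims"],
        procedures=tables["procedures"],
        hospitalizations=tables["hospitalizations"],
        physicians=tables["physicians"],
        labels=tables["labels"],
        codes=codes or CodeConfig(),
    )
    return bundle.validate()


def write_bundle(bundle: LinkedClaimsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write all tables as CSV in canonical column order; returns path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in TABLE_COLUMNS:
        df = getattr(bundle, name)
        if df is None:
            continue
        df = df.copy()
        for col in DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            df[col] = df[col].fillna("")
        if name == "registry":
            df["region_flag"] = df["region_flag"].map({True: "true", False: "false"})
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, columns=list(TABLE_COLUMNS[name]))
        written[name] = path
    return written


def age_at(person: PersonRecord | dt.date, on: dt.date) -> int:
    """Completed years of age on a given date (floor).

    Accepts a PersonRecord or a bare birth date.  Raises on dates before
    birth.
    """
    birth = person.birth_date if isinstance(person, PersonRecord) else _as_date(person)
    on = _as_date(on)
    if on < birth:
        raise ValueError(f"date {on} precedes birth {birth}")
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def age_in_months_at(person: PersonRecord | dt.date, on: dt.date) -> int:
    """Completed months of age, for the six-month lower eligibility bound."""
    birth = person.birth_date if isinstance(person, PersonRecord) else _as_date(person)
    on = _as_date(on)
    if on < birth:
        raise ValueError(f"date {on} precedes birth {birth}")
    months = (on.year - birth.year) * 12 + (on.month - birth.month)
    if on.day < birth.day:
        months -= 1
    return months


def merge_intervals(
    intervals: Iterable[tuple[dt.date, dt.date]],
) -> tuple[tuple[dt.date, dt.date], ...]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    out: list[tuple[dt.date, dt.date]] = []
    for start, end in ivs:
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return tuple(out)


def continuously_eligible(person: PersonRecord, window: tuple[dt.date, dt.date]) -> bool:
    """True iff the union of coverage intervals covers the closed window.

    Intervals are half-open, so covering the inclusive window end requires an
    interval ending strictly after it; a one-day gap anywhere in the window
    fails.
    """
    start, end = (_as_date(window[0]), _as_date(window[1]))
    if start > end:
        raise ValueError("window start after end")
    for iv_start, iv_end in merge_intervals(person.eligibility_intervals):
        if iv_start <= start and iv_end > end:
            return True
    return False
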