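"""Declarative case-ascertainment algorithms over linked claims.

Each algorithm flags a person as a disease case when the administrative
record shows (1) an endoscopy and (2) a required number of celiac-coded
clinical contacts, optionally constrained to a window anchored at the
endoscopy date or required to follow it.  The two endoscopy sources differ
deliberately: outpatient fee-code billing captures endoscopy *for any
indication* (physicians bill before histology is back and a claim carries a
single diagnostic code), while same-day-surgery procedure records are coded
later by hospital coders and must themselves carry a celiac diagnostic code.
That asymmetry — identical contact logic, different endoscopy channel — is
what the validation quantifies.

The standard grid is 13 rule variants per endoscopy source (26 total):

=====  ==========================================================
row    rule
=====  ==========================================================
1      endoscopy + >=1 gastroenterologist celiac visit (any time)
2-6    endoscopy + >=2 GI celiac visits within 1..5 years
7      as row 1, a celiac-coded hospitalization also qualifies
8-12   as rows 2-6, hospitalization also qualifies
13     endoscopy + >=1 GI celiac visit strictly after the scope
=====  ==========================================================
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .data_model import (
    GI_SPECIALTIES,
    LinkageError,
    LinkedClaimsBundle,
    split_codes,
)

__all__ = [
    "AlgorithmSpec",
    "CaseRecord",
    "AscertainmentResult",
    "build_algorithm_grid",
    "get_algorithm",
    "find_endoscopies",
    "find_contacts",
    "apply_algorithm",
    "overlap",
    "grid_to_yaml",
    "grid_from_yaml",
]

SOURCES = ("ohip_any_indication", "sds_cd_coded")
CONTACT_TYPES = ("gi_outpatient_cd_visit", "cd_hospitalization")
SOURCE_SUFFIX = {"ohip_any_indication": "OHIP", "sds_cd_coded": "SDS"}


@dataclass(frozen=True)
class AlgorithmSpec:
    """One declarative case-identifying rule.

    ``window_years`` (if set) anchors a half-open window
    ``[scope_date, scope_date + k years)`` at each endoscopy; the required
    contacts must fall inside it.  ``require_contacts_after_scope`` demands
    contacts strictly later than the scope date (same-day contacts do not
    qualify).
    """

    algorithm_id: str
    endoscopy_source: str
    min_contacts: int = 1
    contact_event_types: frozenset[str] = frozenset({"gi_outpatient_cd_visit"})
    window_years: int | None = None
    require_contacts_after_scope: bool = False

    def __post_init__(self) -> None:
        if self.endoscopy_source not in SOURCES:
            raise ValueError(f"unknown endoscopy source {self.endoscopy_source!r}")
        if self.min_contacts < 1:
            raise ValueError("min_contacts must be >= 1")
        unknown = set(self.contact_event_types) - set(CONTACT_TYPES)
        if unknown:
            raise ValueError(f"unknown contact event types {sorted(unknown)}")
        if self.window_years is not None and self.min_contacts < 2:
            raise ValueError("window_years is defined only for min_contacts >= 2")
        if self.window_years is not None and not (1 <= self.window_years <= 5):
            raise ValueError("window_years must be in 1..5")

    def to_dict(self) -> dict:
        return {
            "algorithm_id": self.algorithm_id,
            "endoscopy_source": self.endoscopy_source,
            "min_contacts": self.min_contacts,
            "contact_event_types": sorted(self.contact_event_types),
            "window_years": self.window_years,
            "require_contacts_after_scope": self.require_contacts_after_scope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmSpec":
        return cls(
            algorithm_id=d["algorithm_id"],
            endoscopy_source=d["endoscopy_source"],
            min_contacts=int(d.get("min_contacts", 1)),
            contact_event_types=frozenset(d.get("contact_event_types",
                                                ["gi_outpatient_cd_visit"])),
            window_years=d.get("window_years"),
            require_contacts_after_scope=bool(d.get("require_contacts_after_scope", False)),
        )


@dataclass(frozen=True)
class CaseRecord:
    person_id: str
    index_date: dt.date
    algorithm_id: str
    scope_date: dt.date
    n_qualifying_contacts: int


@dataclass
class AscertainmentResult:
    """Cases flagged by one algorithm on one bundle."""

    algorithm_id: str
    cases: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["person_id", "index_date", "scope_date", "n_qualifying_contacts"]))

    @property
    def flagged_ids(self) -> frozenset[str]:
        return frozenset(self.cases["person_id"])

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def case_records(self, algorithm_id: str | None = None) -> list[CaseRecord]:
        aid = algorithm_id or self.algorithm_id
        return [
            CaseRecord(r.person_id, pd.Timestamp(r.index_date).date(), aid,
                       pd.Timestamp(r.scope_date).date(), int(r.n_qualifying_contacts))
            for r in self.cases.itertuples()
        ]


def build_algorithm_grid() -> list[AlgorithmSpec]:
    """The 26-variant grid: rows 1-13 for each endoscopy source."""
    grid: list[AlgorithmSpec] = []
    for source in SOURCES:
        suffix = SOURCE_SUFFIX[source]
        gi = frozenset({"gi_outpatient_cd_visit"})
        gi_or_hosp = frozenset(CONTACT_TYPES)
        grid.append(AlgorithmSpec(f"1-{suffix}", source, 1, gi))
        for k in range(1, 6):
            grid.append(AlgorithmSpec(f"{1 + k}-{suffix}", source, 2, gi, window_years=k))
        grid.append(AlgorithmSpec(f"7-{suffix}", source, 1, gi_or_hosp))
        for k in range(1, 6):
            grid.append(AlgorithmSpec(f"{7 + k}-{suffix}", source, 2, gi_or_hosp,
                                      window_years=k))
        grid.append(AlgorithmSpec(f"13-{suffix}", source, 1, gi,
                                  require_contacts_after_scope=True))
    return grid


def get_algorithm(algorithm_id: str,
                  grid: Iterable[AlgorithmSpec] | None = None) -> AlgorithmSpec:
    for spec in (grid if grid is not None else build_algorithm_grid()):
        if spec.algorithm_id == algorithm_id:
            return spec
    raise KeyError(f"unknown algorithm id {algorithm_id!r}")


def grid_to_yaml(grid: Iterable[AlgorithmSpec], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump([s.to_dict() for s in grid], sort_keys=False))


def grid_from_yaml(path: str | Path) -> list[AlgorithmSpec]:
    raw = yaml.safe_load(Path(path).read_text())
    return [AlgorithmSpec.from_dict(d) for d in raw]


# ---------------------------------------------------------------------------
# event extraction


def _scope_frame(bundle: LinkedClaimsBundle, source: str) -> pd.DataFrame:
    """All endoscopy events for a source as (person_id, date)."""
    codes = bundle.codes
    if source == "ohip_any_indication":
        # Fee-code match only; the single diagnostic code is ignored because
        # the billing claim predates histology.
        is_scope = bundle.claims["fee_code"].map(
            lambda c: codes.matches(c, codes.endoscopy_fee_codes))
        df = bundle.claims.loc[is_scope, ["person_id", "service_date"]]
        return df.rename(columns={"service_date": "date"})
    if source == "sds_cd_coded":
        proc = bundle.procedures
        is_endo = proc["intervention_codes"].map(
            lambda cs: any(codes.matches(c, codes.endoscopy_intervention_codes)
                           for c in split_codes(cs)))
        is_cd = proc["diagnostic_codes"].map(
            lambda cs: codes.any_celiac(split_codes(cs)))
        df = proc.loc[is_endo & is_cd, ["person_id", "procedure_date"]]
        return df.rename(columns={"procedure_date": "date"})
    raise ValueError(f"unknown endoscopy source {source!r}")


def _contact_frame(bundle: LinkedClaimsBundle, types: frozenset[str]) -> pd.DataFrame:
    """Qualifying contact events as (person_id, date), deduplicated."""
    codes = bundle.codes
    frames = []
    if "gi_outpatient_cd_visit" in types:
        claims = bundle.claims
        if len(claims):
            unknown = ~claims["physician_id"].isin(set(bundle.physicians["physician_id"]))
            if unknown.any():
                row = int(unknown.idxmax())
                raise LinkageError(
                    f"claims: row {row}: physician_id "
                    f"{claims.loc[row, 'physician_id']!r} has no specialty record")
        spec_map = dict(zip(bundle.physicians["physician_id"],
                            bundle.physicians["specialty"]))
        is_gi = claims["physician_id"].map(lambda p: spec_map.get(p) in GI_SPECIALTIES)
        is_cd = claims["diagnostic_code"].map(codes.is_celiac)
        df = claims.loc[is_gi & is_cd,
                        ["person_id", "service_date", "physician_id", "diagnostic_code"]]
        # Exact duplicate claims (same person, physician, date, code) are one contact.
        df = df.drop_duplicates()
        frames.append(df[["person_id", "service_date"]]
                      .rename(columns={"service_date": "date"}))
    if "cd_hospitalization" in types:
        hosp = bundle.hospitalizations
        is_cd = hosp["diagnostic_codes"].map(lambda cs: codes.any_celiac(split_codes(cs)))
        df = hosp.loc[is_cd, ["person_id", "admission_date"]].drop_duplicates()
        frames.append(df.rename(columns={"admission_date": "date"}))
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["person_id", "date"])
    return pd.concat(frames, ignore_index=True)


def find_endoscopies(bundle: LinkedClaimsBundle, source: str,
                     person_id: str) -> list[dt.date]:
    """Dated endoscopy events for one person under the given source."""
    df = _scope_frame(bundle, source)
    dates = df.loc[df["person_id"] == person_id, "date"]
    return sorted(pd.Timestamp(d).date() for d in dates)


def find_contacts(bundle: LinkedClaimsBundle, person_id: str,
                  types: Iterable[str] = ("gi_outpatient_cd_visit",)) -> list[dt.date]:
    """Dated qualifying contact events for one person."""
    df = _contact_frame(bundle, frozenset(types))
    dates = df.loc[df["person_id"] == person_id, "date"]
    return sorted(pd.Timestamp(d).date() for d in dates)


def _clip_to_window(df: pd.DataFrame,
                    study_window: tuple[dt.date, dt.date] | None) -> pd.DataFrame:
    if study_window is None or df.empty:
        return df
    start, end = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    dates = pd.to_datetime(df["date"])
    return df.loc[(dates >= start) & (dates <= end)]


def apply_algorithm(bundle: LinkedClaimsBundle, spec: AlgorithmSpec,
                    study_window: tuple[dt.date, dt.date] | None = None,
                    window_anchor: str = "scope") -> AscertainmentResult:
    """Flag every person whose record satisfies the rule.

    A person is flagged iff an endoscopy exists and at least ``min_contacts``
    qualifying contacts satisfy the ordering/window constraint; the assigned
    index date is the earliest endoscopy participating in a qualifying
    pattern (biopsy defines diagnosis).  ``window_anchor`` selects whether a
    k-year window is anchored at the scope date (default) or measured as the
    span between the contacts themselves ("span"); both readings appear in
    practice and only the anchoring differs.
    """
    if window_anchor not in ("scope", "span"):
        raise ValueError(f"unknown window_anchor {window_anchor!r}")
    scopes = _clip_to_window(_scope_frame(bundle, spec.endoscopy_source), study_window)
    contacts = _clip_to_window(_contact_frame(bundle, spec.contact_event_types),
                               study_window)
    empty = AscertainmentResult(spec.algorithm_id)
    if scopes.empty or contacts.empty:
        return empty
    scopes = scopes.copy()
    contacts = contacts.copy()
    scopes["date"] = pd.to_datetime(scopes["date"])
    contacts["date"] = pd.to_datetime(contacts["date"])

    if spec.window_years is None and not spec.require_contacts_after_scope:
        # Rule rows 1 and 7: contacts anywhere in the study window.
        n_contacts = contacts.groupby("person_id")["date"].count()
        eligible = n_contacts[n_contacts >= spec.min_contacts].index
        qual = scopes[scopes["person_id"].isin(eligible)]
        if qual.empty:
            return empty
        idx = qual.groupby("person_id")["date"].min().reset_index()
        idx = idx.merge(n_contacts.rename("n_qualifying_contacts"), on="person_id")
        cases = idx.rename(columns={"date": "index_date"})
        cases["scope_date"] = cases["index_date"]
        return AscertainmentResult(spec.algorithm_id, _order_cases(cases))

    if spec.window_years is not None and window_anchor == "span":
        return _apply_span_window(spec, scopes, contacts)

    # Scope-anchored window and/or ordering: pair every scope with every
    # contact of the same person and count contacts satisfying the constraint.
    pairs = scopes.merge(contacts, on="person_id", suffixes=("_scope", "_contact"))
    if pairs.empty:
        return empty
    ok = pd.Series(True, index=pairs.index)
    if spec.require_contacts_after_scope:
        ok &= pairs["date_contact"] > pairs["date_scope"]  # strictly after
    if spec.window_years is not None:
        horizon = pairs["date_scope"] + pd.DateOffset(years=spec.window_years)
        ok &= (pairs["date_contact"] >= pairs["date_scope"])
        ok &= (pairs["date_contact"] < horizon)
    pairs = pairs[ok]
    if pairs.empty:
        return empty
    per_scope = (pairs.groupby(["person_id", "date_scope"])["date_contact"]
                 .count().rename("n_qualifying_contacts").reset_index())
    per_scope = per_scope[per_scope["n_qualifying_contacts"] >= spec.min_contacts]
    if per_scope.empty:
        return empty
    first = (per_scope.sort_values(["person_id", "date_scope"])
             .groupby("person_id", as_index=False).first())
    cases = first.rename(columns={"date_scope": "index_date"})
    cases["scope_date"] = cases["index_date"]
    return AscertainmentResult(spec.algorithm_id, _order_cases(cases))


def _apply_span_window(spec: AlgorithmSpec, scopes: pd.DataFrame,
                       contacts: pd.DataFrame) -> AscertainmentResult:
    """Alternative window reading: m contacts mutually within k years."""
    m, k = spec.min_contacts, spec.window_years
    flagged: list[tuple[str, pd.Timestamp, int]] = []
    scope_people = set(scopes["person_id"])
    for pid, grp in contacts.groupby("person_id"):
        if pid not in scope_people:
            continue
        dates = sorted(grp["date"])
        hit = None
        for i in range(len(dates) - m + 1):
            if dates[i + m - 1] < dates[i] + pd.DateOffset(years=k):
                hit = i
                break
        if hit is not None:
            n_in = sum(1 for d in dates
                       if dates[hit] <= d < dates[hit] + pd.DateOffset(years=k))
            flagged.append((pid, scopes.loc[scopes["person_id"] == pid, "date"].min(), n_in))
    if not flagged:
        return AscertainmentResult(spec.algorithm_id)
    cases = pd.DataFrame(flagged, columns=["person_id", "index_date",
                                           "n_qualifying_contacts"])
    cases["scope_date"] = cases["index_date"]
    return AscertainmentResult(spec.algorithm_id, _order_cases(cases))


def _order_cases(cases: pd.DataFrame) -> pd.DataFrame:
    cases = cases[["person_id", "index_date", "scope_date", "n_qualifying_contacts"]]
    return cases.sort_values("person_id").reset_index(drop=True)


def overlap(result_a: AscertainmentResult,
            result_b: AscertainmentResult) -> tuple[int, int, int]:
    """Partition of flagged persons: (only A, both, only B)."""
    a, b = result_a.flagged_ids, result_b.flagged_ids
    return len(a - b), len(a & b), len(b - a)
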