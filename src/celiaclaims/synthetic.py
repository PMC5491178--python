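"""Synthetic linked-claims cohorts with known ground truth.

Real linked health-administrative data cannot leave its data custodian, so
validation logic is exercised on two kinds of synthetic input:

* :func:`simulate_population` draws a whole pediatric cohort whose event
  streams follow the clinical investigation sequence — screening visit,
  endoscopy, post-diagnosis gastroenterology follow-up — with the two
  endoscopy recording channels modelled *independently*: the outpatient fee
  claim is billed at procedure time for any indication, while the
  same-day-surgery record is coded later and carries the celiac code only
  with a configurable probability (the coder may have seen the biopsy
  result).  Non-cases contribute background endoscopy and a small stream of
  celiac-coded visits without biopsy confirmation (the gluten-sensitivity
  mis-coding channel), which is what generates false positives.

* :func:`build_validation_fixture` constructs, deterministically, a bundle
  on which a given algorithm attains an exact requested confusion table —
  the workhorse for checking the accuracy statistics against known counts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .algorithms import AlgorithmSpec
from .data_model import CodeConfig, LinkedClaimsBundle, format_intervals

__all__ = [
    "SimulationParams",
    "DEFAULT_SEED",
    "simulate_population",
    "build_validation_fixture",
]

DEFAULT_SEED = 20110629

#: Marsh-grade mix among biopsy-proven cases (3a/3b/3c).
MARSH_PROBS = {"3a": 0.157, "3b": 0.704, "3c": 0.139}

_DAY = pd.Timedelta(days=1)


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for a synthetic pediatric claims cohort.

    Defaults describe a population the size of a mid-size metropolitan
    pediatric cohort followed for seven years, with a true incidence of
    biopsy-proven disease around 7 per 100,000 person-years (within the
    2-54 range reported for comparable populations) so that roughly a
    hundred incident cases arise.
    """

    n_children: int = 235_320
    study_window: tuple[dt.date, dt.date] = (dt.date(2005, 1, 1), dt.date(2011, 12, 31))
    annual_incidence_per_100k: float = 7.0
    age_distribution: tuple[float, ...] = tuple([1.0 / 15] * 15)  # ages 0..14
    sex_ratio: float = 0.51  # proportion male
    p_biopsy_if_cd: float = 0.90
    p_ohip_endoscopy_billed: float = 0.95
    p_sds_record_cd_coded: float = 0.80
    p_outpatient_cd_visit_post_dx: float = 0.85
    background_endoscopy_rate: float = 150.0  # per 100,000 person-years
    background_cd_code_noise: float = 0.0004
    p_sds_miscode_noncd: float = 0.10
    p_cd_hospitalization_post_dx: float = 0.05
    p_eligibility_gap: float = 0.03
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        for name in ("sex_ratio", "p_biopsy_if_cd", "p_ohip_endoscopy_billed",
                     "p_sds_record_cd_coded", "p_outpatient_cd_visit_post_dx",
                     "background_cd_code_noise", "p_sds_miscode_noncd",
                     "p_cd_hospitalization_post_dx", "p_eligibility_gap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        if self.annual_incidence_per_100k < 0 or self.background_endoscopy_rate < 0:
            raise ValueError("rates must be non-negative")
        if abs(sum(self.age_distribution) - 1.0) > 1e-9 or len(self.age_distribution) != 15:
            raise ValueError("age_distribution must be 15 weights summing to 1")


_PHYSICIANS = pd.DataFrame({
    "physician_id": ["MD-PGI-1", "MD-PGI-2", "MD-AGI-1", "MD-PED-1", "MD-FP-1", "MD-FP-2"],
    "specialty": ["gastroenterology_pediatric", "gastroenterology_pediatric",
                  "gastroenterology_adult", "pediatrics",
                  "family_medicine", "family_medicine"],
})

NONSPECIFIC_DX = "787"   # GI symptom code used when the diagnosis is not coded
SCREEN_FEE = "A001"
VISIT_FEE = "A005"


def _empty_tables() -> dict[str, pd.DataFrame]:
    return {
        "claims": pd.DataFrame(columns=["person_id", "service_date", "physician_id",
                                        "diagnostic_code", "fee_code"]),
        "procedures": pd.DataFrame(columns=["person_id", "procedure_date", "facility_id",
                                            "intervention_codes", "diagnostic_codes"]),
        "hospitalizations": pd.DataFrame(columns=["person_id", "admission_date",
                                                  "discharge_date", "diagnostic_codes"]),
    }


def simulate_population(
    params: SimulationParams,
    codes: CodeConfig | None = None,
) -> tuple[LinkedClaimsBundle, pd.DataFrame]:
    """Draw a cohort and its event streams; returns (bundle, truth table).

    The truth table has one row per child (person_id, is_cd, onset_date);
    the bundle's label table marks *biopsy-proven* cases as true positives —
    a true case that never reaches endoscopy is not biopsy-proven and sits
    in the negative reference, mirroring how a biopsy-based reference
    standard is actually assembled.
    """
    codes = codes or CodeConfig()
    rng = np.random.default_rng(params.seed)
    n = params.n_children
    win_start = pd.Timestamp(params.study_window[0])
    win_end = pd.Timestamp(params.study_window[1])
    window_days = (win_end - win_start).days
    years_at_risk = (window_days + 1) / 365.25

    person_id = np.array([f"P{i:07d}" for i in range(n)])
    # Open, roughly stationary cohort: each child is assigned an age drawn
    # from age_distribution at a uniformly chosen reference time inside the
    # window, so births spread across the preceding 15 years and the window
    # itself and every age stratum stays populated in every calendar year.
    age_years = rng.choice(15, size=n, p=np.asarray(params.age_distribution))
    ref_day = rng.uniform(0, window_days, n)
    birth_days_before_ref = age_years * 365.25 + rng.uniform(0, 365, n)
    birth = win_start + pd.to_timedelta(
        (ref_day - birth_days_before_ref).astype(int), unit="D")
    sex = np.where(rng.random(n) < params.sex_ratio, "male", "female")

    # Coverage: birth (or a pre-window grace date) to past the window end,
    # with occasional mid-window gaps.
    grace = win_start - pd.Timedelta(days=365)
    elig_start = pd.DatetimeIndex(np.where(birth > grace, birth, grace))
    elig_end = pd.DatetimeIndex([win_end + 180 * _DAY] * n)
    gap_at = win_start + pd.to_timedelta(rng.integers(100, window_days - 200, n), unit="D")
    gap_len = rng.integers(30, 181, n)
    has_gap = ((rng.random(n) < params.p_eligibility_gap)
               & (gap_at > elig_start + 30 * _DAY))

    registry_intervals = np.empty(n, dtype=object)
    starts = pd.DatetimeIndex(elig_start)
    for i in range(n):
        s, e = starts[i].date(), pd.Timestamp(elig_end[i]).date()
        if has_gap[i]:
            g0 = pd.Timestamp(gap_at[i]).date()
            g1 = g0 + dt.timedelta(days=int(gap_len[i]))
            registry_intervals[i] = format_intervals([(s, g0), (g1, e)])
        else:
            registry_intervals[i] = format_intervals([(s, e)])

    registry = pd.DataFrame({
        "person_id": person_id,
        "birth_date": pd.DatetimeIndex(birth),
        "sex": sex,
        "region_flag": True,
        "eligibility_intervals": registry_intervals,
    })

    # --- disease onset -----------------------------------------------------
    hazard = params.annual_incidence_per_100k / 1e5
    p_case = 1.0 - np.exp(-hazard * years_at_risk)
    is_cd = rng.random(n) < p_case
    # Onset inside the window while in the susceptible age range: at least
    # six months old (solid food introduced) and young enough that the
    # diagnostic work-up completes before the 15th birthday or window close.
    onset_lo = np.maximum((birth + pd.Timedelta(days=270) - win_start).days, 0)
    onset_hi = np.minimum(
        (birth + pd.DateOffset(years=15) - win_start).days - 200,
        window_days - 120)
    feasible = onset_hi - onset_lo > 30
    is_cd &= feasible
    span = np.maximum(onset_hi - onset_lo, 1)
    onset = win_start + pd.to_timedelta(
        onset_lo + (rng.random(n) * span).astype(int), unit="D")
    truth = pd.DataFrame({
        "person_id": person_id,
        "is_cd": is_cd,
        "onset_date": pd.DatetimeIndex(np.where(is_cd, onset, pd.NaT)),
    })

    claims_parts, proc_parts, hosp_parts = [], [], []

    def add_claims(pids, dates, physician, dx, fee):
        claims_parts.append(pd.DataFrame({
            "person_id": pids, "service_date": dates,
            "physician_id": physician, "diagnostic_code": dx, "fee_code": fee}))

    gi_pool = np.array(["MD-PGI-1", "MD-PGI-2", "MD-AGI-1"])
    fp_pool = np.array(["MD-FP-1", "MD-FP-2", "MD-PED-1"])
    celiac = codes.celiac_codes[0]
    endo_fee = codes.endoscopy_fee_codes[0]
    endo_proc = codes.endoscopy_intervention_codes[0]

    # --- true-case event stream: screen -> scope -> follow-up --------------
    case_idx = np.flatnonzero(is_cd)
    if len(case_idx):
        c_onset = pd.DatetimeIndex(onset[case_idx])
        add_claims(person_id[case_idx], c_onset,
                   rng.choice(fp_pool, len(case_idx)), celiac, SCREEN_FEE)

        biopsied = rng.random(len(case_idx)) < params.p_biopsy_if_cd
        b_idx = case_idx[biopsied]
        scope_date = pd.DatetimeIndex(onset[b_idx]) + pd.to_timedelta(
            rng.integers(14, 46, len(b_idx)), unit="D")

        billed = rng.random(len(b_idx)) < params.p_ohip_endoscopy_billed
        add_claims(person_id[b_idx][billed], scope_date[billed],
                   rng.choice(gi_pool, int(billed.sum())), NONSPECIFIC_DX, endo_fee)

        cd_coded = rng.random(len(b_idx)) < params.p_sds_record_cd_coded
        proc_dx = np.where(cd_coded, f"{celiac}.0;{NONSPECIFIC_DX}", NONSPECIFIC_DX)
        proc_parts.append(pd.DataFrame({
            "person_id": person_id[b_idx], "procedure_date": scope_date,
            "facility_id": "HOSP-1", "intervention_codes": endo_proc,
            "diagnostic_codes": proc_dx}))

        followed = rng.random(len(b_idx)) < params.p_outpatient_cd_visit_post_dx
        f_pid = person_id[b_idx][followed]
        f_dx_date = scope_date[followed]
        first_visit = f_dx_date + pd.to_timedelta(
            rng.integers(14, 61, len(f_pid)), unit="D")
        add_claims(f_pid, first_visit, rng.choice(gi_pool, len(f_pid)),
                   celiac, VISIT_FEE)
        remaining_years = np.maximum(
            (win_end - f_dx_date).days / 365.25 - 0.2, 0.0)
        extra = rng.poisson(0.5 * remaining_years)
        rep_pid = np.repeat(f_pid, extra)
        if len(rep_pid):
            rep_anchor = np.repeat(first_visit.values, extra)
            span_days = np.maximum(
                (win_end.value - rep_anchor.astype("datetime64[ns]").astype(np.int64))
                // 86_400_000_000_000, 1)
            offs = (rng.random(len(rep_pid)) * span_days).astype(int)
            rep_dates = pd.DatetimeIndex(rep_anchor) + pd.to_timedelta(offs, unit="D")
            add_claims(rep_pid, rep_dates, rng.choice(gi_pool, len(rep_pid)),
                       celiac, VISIT_FEE)

        hospitalized = rng.random(len(b_idx)) < params.p_cd_hospitalization_post_dx
        h_pid = person_id[b_idx][hospitalized]
        if len(h_pid):
            h_adm = scope_date[hospitalized] + pd.to_timedelta(
                rng.integers(30, 366, len(h_pid)), unit="D")
            hosp_parts.append(pd.DataFrame({
                "person_id": h_pid, "admission_date": h_adm,
                "discharge_date": h_adm + pd.to_timedelta(
                    rng.integers(1, 6, len(h_pid)), unit="D"),
                "diagnostic_codes": f"{celiac}.0"}))

        biopsy_label = np.zeros(n, bool)
        biopsy_label[b_idx] = True
        dx_dates = pd.Series(pd.NaT, index=range(n))
        dx_dates.iloc[b_idx] = scope_date
    else:
        biopsy_label = np.zeros(n, bool)
        dx_dates = pd.Series(pd.NaT, index=range(n))

    # --- background (non-case) channels ------------------------------------
    noncase = ~is_cd
    p_bg_endo = params.background_endoscopy_rate / 1e5 * years_at_risk
    bg_endo = noncase & (rng.random(n) < p_bg_endo)
    bg_idx = np.flatnonzero(bg_endo)
    if len(bg_idx):
        bg_date = win_start + pd.to_timedelta(
            rng.integers(0, window_days, len(bg_idx)), unit="D")
        bg_billed = rng.random(len(bg_idx)) < params.p_ohip_endoscopy_billed
        add_claims(person_id[bg_idx][bg_billed], bg_date[bg_billed],
                   rng.choice(gi_pool, int(bg_billed.sum())), NONSPECIFIC_DX, endo_fee)
        proc_parts.append(pd.DataFrame({
            "person_id": person_id[bg_idx], "procedure_date": bg_date,
            "facility_id": "HOSP-1", "intervention_codes": endo_proc,
            "diagnostic_codes": NONSPECIFIC_DX}))

    # Celiac-suspected non-cases (e.g. gluten sensitivity): celiac-coded GI
    # visits, frequently scoped with a negative biopsy; the same-day-surgery
    # record is only rarely mis-coded as celiac because the coder usually
    # sees the negative histology.
    noise = noncase & (rng.random(n) < params.background_cd_code_noise)
    nz_idx = np.flatnonzero(noise)
    if len(nz_idx):
        nz_date = win_start + pd.to_timedelta(
            rng.integers(30, max(window_days - 400, 31), len(nz_idx)), unit="D")
        n_visits = 1 + rng.poisson(0.5, len(nz_idx))
        rep_pid = np.repeat(person_id[nz_idx], n_visits)
        rep_base = np.repeat(nz_date.values, n_visits)
        rep_dates = pd.DatetimeIndex(rep_base) + pd.to_timedelta(
            rng.integers(0, 300, len(rep_pid)), unit="D")
        add_claims(rep_pid, rep_dates, rng.choice(gi_pool, len(rep_pid)),
                   celiac, VISIT_FEE)
        nz_scoped = rng.random(len(nz_idx)) < params.p_biopsy_if_cd
        s_idx = nz_idx[nz_scoped]
        if len(s_idx):
            s_date = pd.DatetimeIndex(nz_date[nz_scoped]) + pd.to_timedelta(
                rng.integers(14, 46, len(s_idx)), unit="D")
            s_billed = rng.random(len(s_idx)) < params.p_ohip_endoscopy_billed
            add_claims(person_id[s_idx][s_billed], s_date[s_billed],
                       rng.choice(gi_pool, int(s_billed.sum())),
                       NONSPECIFIC_DX, endo_fee)
            s_miscoded = rng.random(len(s_idx)) < params.p_sds_miscode_noncd
            s_dx = np.where(s_miscoded, f"{celiac}.0;{NONSPECIFIC_DX}", NONSPECIFIC_DX)
            proc_parts.append(pd.DataFrame({
                "person_id": person_id[s_idx], "procedure_date": s_date,
                "facility_id": "HOSP-1", "intervention_codes": endo_proc,
                "diagnostic_codes": s_dx}))

    empties = _empty_tables()
    claims = (pd.concat(claims_parts, ignore_index=True)
              if claims_parts else empties["claims"])
    procedures = (pd.concat(proc_parts, ignore_index=True)
                  if proc_parts else empties["procedures"])
    hospitalizations = (pd.concat(hosp_parts, ignore_index=True)
                        if hosp_parts else empties["hospitalizations"])

    marsh = np.full(n, "none", dtype=object)
    k = int(biopsy_label.sum())
    if k:
        marsh[biopsy_label] = np.random.default_rng(params.seed + 1).choice(
            list(MARSH_PROBS), size=k, p=np.array(list(MARSH_PROBS.values()))
            / sum(MARSH_PROBS.values()))
    labels = pd.DataFrame({
        "person_id": person_id,
        "status": np.where(biopsy_label, "true_positive", "true_negative"),
        "diagnosis_date": pd.DatetimeIndex(dx_dates),
        "marsh_class": marsh,
    })

    bundle = LinkedClaimsBundle(
        registry=registry, claims=claims, procedures=procedures,
        hospitalizations=hospitalizations, physicians=_PHYSICIANS.copy(),
        labels=labels, codes=codes,
    ).validate()
    return bundle, truth


def build_validation_fixture(
    tp: int, fp: int, fn: int, tn: int,
    algorithm: AlgorithmSpec,
    seed: int = DEFAULT_SEED,
    study_window: tuple[dt.date, dt.date] = (dt.date(2005, 1, 1), dt.date(2011, 12, 31)),
    codes: CodeConfig | None = None,
) -> tuple[LinkedClaimsBundle, pd.DataFrame]:
    """Construct a bundle on which ``algorithm`` attains exactly (tp, fp, fn, tn).

    True/false positives receive a constructed qualifying pattern (an
    endoscopy in the algorithm's source followed by the required
    gastroenterologist celiac-coded contacts within a year); false negatives
    are labeled positives with no administrative footprint; true negatives
    are event-free registry rows.  The construction qualifies under every
    rule variant of the standard grid, so the same counts hold for stricter
    and looser variants built from it.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    codes = codes or CodeConfig()
    rng = np.random.default_rng(seed)
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("fixture must contain at least one person")
    win_start = pd.Timestamp(study_window[0])
    win_end = pd.Timestamp(study_window[1])

    person_id = np.array([f"F{i:07d}" for i in range(n)])
    # young enough at window start that nobody reaches 15 before diagnosis
    age = rng.integers(1, 8, n)
    birth = win_start - pd.to_timedelta(age * 366 + rng.integers(0, 300, n), unit="D")
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    interval = format_intervals([
        ((win_start - pd.Timedelta(days=30)).date(),
         (win_end + pd.Timedelta(days=30)).date())])
    registry = pd.DataFrame({
        "person_id": person_id,
        "birth_date": pd.DatetimeIndex(birth),
        "sex": sex,
        "region_flag": True,
        "eligibility_intervals": interval,
    })

    # Role layout: [TP][FN][FP][TN]
    is_positive = np.zeros(n, bool)
    is_positive[:tp + fn] = True
    has_pattern = np.zeros(n, bool)
    has_pattern[:tp] = True
    has_pattern[tp + fn:tp + fn + fp] = True

    pat_idx = np.flatnonzero(has_pattern)
    scope_date = win_start + pd.to_timedelta(
        rng.integers(180, (win_end - win_start).days - 500, len(pat_idx)), unit="D")

    claims_parts, proc_parts = [], []
    celiac = codes.celiac_codes[0]
    if algorithm.endoscopy_source == "ohip_any_indication":
        claims_parts.append(pd.DataFrame({
            "person_id": person_id[pat_idx], "service_date": scope_date,
            "physician_id": "MD-PGI-1", "diagnostic_code": NONSPECIFIC_DX,
            "fee_code": codes.endoscopy_fee_codes[0]}))
    else:
        proc_parts.append(pd.DataFrame({
            "person_id": person_id[pat_idx], "procedure_date": scope_date,
            "facility_id": "HOSP-1",
            "intervention_codes": codes.endoscopy_intervention_codes[0],
            "diagnostic_codes": f"{celiac}.0;{NONSPECIFIC_DX}"}))

    # Contacts strictly after the scope, spaced monthly: satisfies ordering,
    # every 1..5-year window, and any min_contacts up to the count emitted.
    n_contacts = max(algorithm.min_contacts, 1)
    for j in range(n_contacts):
        claims_parts.append(pd.DataFrame({
            "person_id": person_id[pat_idx],
            "service_date": scope_date + pd.Timedelta(days=30 * (j + 1)),
            "physician_id": "MD-PGI-1" if j % 2 == 0 else "MD-AGI-1",
            "diagnostic_code": celiac,
            "fee_code": VISIT_FEE}))

    empties = _empty_tables()
    claims = (pd.concat(claims_parts, ignore_index=True)
              if claims_parts else empties["claims"])
    procedures = (pd.concat(proc_parts, ignore_index=True)
                  if proc_parts else empties["procedures"])

    dx_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    dx_date.iloc[:tp] = scope_date[:tp]
    # labeled positives without a record still carry a (chart) diagnosis date
    dx_date.iloc[tp:tp + fn] = win_start + pd.Timedelta(days=400)
    marsh = np.full(n, "none", dtype=object)
    if tp + fn:
        marsh[:tp + fn] = rng.choice(
            list(MARSH_PROBS), size=tp + fn,
            p=np.array(list(MARSH_PROBS.values())) / sum(MARSH_PROBS.values()))
    labels = pd.DataFrame({
        "person_id": person_id,
        "status": np.where(is_positive, "true_positive", "true_negative"),
        "diagnosis_date": pd.DatetimeIndex(dx_date),
        "marsh_class": marsh,
    })
    truth = pd.DataFrame({
        "person_id": person_id,
        "is_cd": is_positive,
        "onset_date": pd.DatetimeIndex(dx_date),
    })
    bundle = LinkedClaimsBundle(
        registry=registry, claims=claims, procedures=procedures,
        hospitalizations=empties["hospitalizations"],
        physicians=_PHYSICIANS.copy(), labels=labels, codes=codes,
    ).validate()
    return bundle, truth
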