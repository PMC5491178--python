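import datetime as dt

import numpy as np
import pandas as pd
import pytest

from celiaclaims.data_model import CodeConfig, LinkedClaimsBundle

WIN = (dt.date(2005, 1, 1), dt.date(2011, 12, 31))

PHYSICIANS = pd.DataFrame({
    "physician_id": ["GI1", "GI2", "FP1", "PED1"],
    "specialty": ["gastroenterology_pediatric", "gastroenterology_adult",
                  "family_medicine", "pediatrics"],
})


@pytest.fixture
def study_window():
    return WIN


def make_bundle(persons, claims=(), procedures=(), hospitalizations=(),
                labels=None, codes=None):
    """Hand-rolled toy bundle from terse event tuples.

    persons: list of (person_id, birth_date, sex)
    claims: (person_id, date, physician_id, dx, fee)
    procedures: (person_id, date, intervention_codes, diagnostic_codes)
    hospitalizations: (person_id, adm, dis, diagnostic_codes)
    labels: (person_id, status, diagnosis_date_or_None, marsh)
    """
    reg = pd.DataFrame(
        [(p, pd.Timestamp(b), s, True, f"{b}..2013-01-01")
         for p, b, s in persons],
        columns=["person_id", "birth_date", "sex", "region_flag",
                 "eligibility_intervals"])
    cl = pd.DataFrame(
        [(p, pd.Timestamp(d), md, dx, fee) for p, d, md, dx, fee in claims],
        columns=["person_id", "service_date", "physician_id",
                 "diagnostic_code", "fee_code"])
    pr = pd.DataFrame(
        [(p, pd.Timestamp(d), "H1", ic, dc) for p, d, ic, dc in procedures],
        columns=["person_id", "procedure_date", "facility_id",
                 "intervention_codes", "diagnostic_codes"])
    ho = pd.DataFrame(
        [(p, pd.Timestamp(a), pd.Timestamp(e), dc)
         for p, a, e, dc in hospitalizations],
        columns=["person_id", "admission_date", "discharge_date",
                 "diagnostic_codes"])
    lab = None
    if labels is not None:
        lab = pd.DataFrame(
            [(p, st, pd.Timestamp(d) if d else pd.NaT, m)
             for p, st, d, m in labels],
            columns=["person_id", "status", "diagnosis_date", "marsh_class"])
    return LinkedClaimsBundle(
        registry=reg, claims=cl, procedures=pr, hospitalizations=ho,
        physicians=PHYSICIANS.copy(), labels=lab,
        codes=codes or CodeConfig()).validate()


def random_toy_bundle(rng: np.random.Generator, n_persons: int = 25,
                      max_events: int = 6) -> LinkedClaimsBundle:
    """Random small bundle exercising both endoscopy sources and all
    contact types; every person has at most ``max_events`` of each kind."""
    persons, claims, procs, hosps = [], [], [], []
    day0 = pd.Timestamp("2005-06-01")
    for i in range(n_persons):
        pid = f"T{i:03d}"
        persons.append((pid, "2000-03-15", "female" if i % 2 else "male"))
        for _ in range(rng.integers(0, max_events)):
            d = day0 + pd.Timedelta(days=int(rng.integers(0, 2200)))
            kind = rng.integers(0, 5)
            if kind == 0:      # fee-code endoscopy, any dx
                claims.append((pid, d, "GI1", "787", "Z555"))
            elif kind == 1:    # procedure-record endoscopy, sometimes celiac-coded
                dx = "579.0;787" if rng.random() < 0.5 else "787"
                procs.append((pid, d, "1OD16", dx))
            elif kind == 2:    # GI celiac visit
                claims.append((pid, d, "GI1" if rng.random() < 0.5 else "GI2",
                               "579", "A005"))
            elif kind == 3:    # family-physician celiac visit (never qualifies)
                claims.append((pid, d, "FP1", "579", "A005"))
            else:              # hospitalization, sometimes celiac-coded
                dx = "579.0" if rng.random() < 0.5 else "486"
                hosps.append((pid, d, d + pd.Timedelta(days=2), dx))
    return make_bundle(persons, claims, procs, hosps)
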