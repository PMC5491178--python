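"""Standardized incidence and Poisson trend estimation.

Annual incidence is directly standardized to a fixed standard population
over age-band x sex strata, with confidence intervals by the Fay-Feuer
gamma method, which keeps valid coverage at the low event counts typical of
pediatric disease surveillance.  The time trend is a log-linear Poisson
model on stratum counts with a person-years offset, adjusting for age and
sex; the annual percent change is (exp(beta_year) - 1) x 100.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .algorithms import AscertainmentResult
from .data_model import LinkedClaimsBundle

__all__ = [
    "AGE_BANDS",
    "StandardPopulation",
    "StandardizedRate",
    "PoissonTrendFit",
    "person_years",
    "direct_standardize",
    "incidence_series",
    "fit_poisson_trend",
    "case_strata",
]

#: Default 5-year age bands covering the pediatric range.
AGE_BANDS: tuple[tuple[int, int], ...] = ((0, 4), (5, 9), (10, 14))
PER = 100_000.0


def _age_at_year_start(year: int, birth: pd.Timestamp) -> int:
    """Completed age on Jan 1 of ``year`` (0 for a birth during that year)."""
    if birth.year >= year:
        return 0
    return year - birth.year - (1 if (birth.month, birth.day) > (1, 1) else 0)


def band_of(age_years: float,
            bands: Sequence[tuple[int, int]] = AGE_BANDS) -> str:
    for lo, hi in bands:
        if lo <= age_years <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age_years} outside configured bands")


@dataclass(frozen=True)
class StandardPopulation:
    """Fixed age-band x sex weights (proportions summing to 1)."""

    strata: pd.DataFrame  # columns: age_band, sex, weight

    def __post_init__(self) -> None:
        total = float(self.strata["weight"].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"standard-population weights sum to {total}, not 1")

    @classmethod
    def uniform(cls, bands: Sequence[tuple[int, int]] = AGE_BANDS) -> "StandardPopulation":
        rows = [(f"{lo}-{hi}", sex, 1.0 / (2 * len(bands)))
                for lo, hi in bands for sex in ("female", "male")]
        return cls(pd.DataFrame(rows, columns=["age_band", "sex", "weight"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StandardPopulation":
        df = pd.read_csv(path)
        df["weight"] = df["weight"].astype(float)
        return cls(df[["age_band", "sex", "weight"]])

    def to_csv(self, path: str | Path) -> None:
        self.strata.to_csv(path, index=False)


@dataclass(frozen=True)
class StandardizedRate:
    year: int
    dsr: float          # per 100,000 person-years
    variance: float     # on the per-100,000 scale
    ci_lower: float
    ci_upper: float
    method: str = "gamma"


@dataclass
class PoissonTrendFit:
    """Fitted log-linear Poisson trend with person-years offset."""

    coefficients: pd.Series
    standard_errors: pd.Series
    rate_ratios: pd.DataFrame  # columns: rr, rr_lower, rr_upper
    p_values: pd.Series
    deviance: float
    converged: bool
    apc_percent: float
    apc_ci: tuple[float, float]

    def summary(self) -> pd.DataFrame:
        out = self.rate_ratios.copy()
        out.insert(0, "coef", self.coefficients)
        out.insert(1, "se", self.standard_errors)
        out["p"] = self.p_values
        return out


def person_years(registry: pd.DataFrame,
                 study_window: tuple[dt.date, dt.date],
                 bands: Sequence[tuple[int, int]] = AGE_BANDS) -> pd.DataFrame:
    """Exact person-years at risk per (year, age_band, sex) stratum.

    Each person contributes the eligible fraction of every calendar year,
    attributed to the age band of their age at the start of that year (or at
    birth for the birth year).  Returns columns year, age_band, sex, py.
    """
    from .data_model import parse_intervals

    win_start = pd.Timestamp(study_window[0])
    win_end = pd.Timestamp(study_window[1]) + pd.Timedelta(days=1)  # half-open
    years = range(win_start.year, pd.Timestamp(study_window[1]).year + 1)
    max_age = max(hi for _, hi in bands)
    acc: dict[tuple[int, str, str], float] = {}
    for pid, birth, sex, iv_spec in zip(
            registry["person_id"], pd.to_datetime(registry["birth_date"]),
            registry["sex"], registry["eligibility_intervals"]):
        intervals = parse_intervals(iv_spec)
        for year in years:
            y_start = max(pd.Timestamp(year, 1, 1), win_start)
            y_end = min(pd.Timestamp(year + 1, 1, 1), win_end)
            if y_start >= y_end:
                continue
            age = _age_at_year_start(year, birth)
            if age < 0 or age > max_age:
                continue
            band = band_of(age, bands)
            days = 0.0
            for s, e in intervals:
                s_t, e_t = pd.Timestamp(s), pd.Timestamp(e)
                lo = max(s_t, y_start, birth)
                hi = min(e_t, y_end)
                if hi > lo:
                    days += (hi - lo).days
            if days > 0:
                key = (year, band, sex)
                acc[key] = acc.get(key, 0.0) + days / 365.25
    rows = [(y, b, s, py) for (y, b, s), py in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["year", "age_band", "sex", "py"])


def direct_standardize(counts: pd.DataFrame, std: StandardPopulation,
                       alpha: float = 0.05,
                       year: int | None = None) -> StandardizedRate:
    """Directly standardized rate per 100,000 with a Fay-Feuer gamma CI.

    ``counts`` needs columns age_band, sex, d (events), n (person-years) for
    a single period; every standard stratum must be present.  The point
    estimate is sum_i w_i d_i/n_i x 100,000 with variance
    sum_i w_i^2 d_i/n_i^2.  The gamma lower bound matches a gamma
    distribution to (dsr, v); the upper bound augments both by the largest
    stratum weight-per-person-year w_M = max_i w_i x 100,000 / n_i:

        lower = qgamma(alpha/2;  shape=dsr^2/v,            scale=v/dsr)
        upper = qgamma(1-alpha/2; shape=(dsr+w_M)^2/(v+w_M^2),
                                  scale=(v+w_M^2)/(dsr+w_M))

    reducing to the exact Poisson chi-square interval when a single stratum
    carries all the weight.  lower = 0 when no events occurred.
    """
    merged = std.strata.merge(counts, on=["age_band", "sex"], how="left",
                              validate="one_to_one")
    missing = merged[merged["n"].isna()]
    if len(missing):
        miss = [f"{r.age_band}/{r.sex}" for r in missing.itertuples()]
        raise ValueError(f"missing count strata: {miss}")
    w = merged["weight"].to_numpy(float)
    d = merged["d"].to_numpy(float)
    n = merged["n"].to_numpy(float)
    if (n <= 0).any():
        raise ValueError("person-years must be positive in every stratum")
    dsr = float(np.sum(w * d / n)) * PER
    v = float(np.sum(w * w * d / n / n)) * PER * PER
    w_max = float(np.max(w / n)) * PER
    total_d = float(d.sum())
    if total_d == 0:
        lower = 0.0
    else:
        lower = float(gamma_dist.ppf(alpha / 2, a=dsr * dsr / v, scale=v / dsr))
    dsr_u, v_u = dsr + w_max, v + w_max * w_max
    upper = float(gamma_dist.ppf(1 - alpha / 2, a=dsr_u * dsr_u / v_u,
                                 scale=v_u / dsr_u))
    yr = int(year) if year is not None else int(counts["year"].iloc[0]) \
        if "year" in counts.columns and len(counts) else 0
    return StandardizedRate(year=yr, dsr=dsr, variance=v,
                            ci_lower=lower, ci_upper=upper)


def case_strata(result: AscertainmentResult, bundle: LinkedClaimsBundle,
                bands: Sequence[tuple[int, int]] = AGE_BANDS) -> pd.DataFrame:
    """Bucket flagged cases by (year of index date, age band at index, sex)."""
    reg = bundle.registry[["person_id", "birth_date", "sex"]]
    cases = result.cases.merge(reg, on="person_id", how="left", validate="one_to_one")
    if cases["birth_date"].isna().any():
        raise ValueError("case person missing from registry")
    idx = pd.to_datetime(cases["index_date"])
    birth = pd.to_datetime(cases["birth_date"])
    # age at start of the index year, matching the person-years attribution
    age = [_age_at_year_start(y, b) for y, b in zip(idx.dt.year, birth)]
    out = pd.DataFrame({
        "year": idx.dt.year,
        "age_band": [band_of(a, bands) for a in age],
        "sex": cases["sex"],
    })
    return (out.groupby(["year", "age_band", "sex"])
            .size().rename("d").reset_index())


def incidence_series(result: AscertainmentResult,
                     denominators: pd.DataFrame,
                     std: StandardPopulation,
                     bundle: LinkedClaimsBundle,
                     alpha: float = 0.05,
                     bands: Sequence[tuple[int, int]] = AGE_BANDS
                     ) -> list[StandardizedRate]:
    """Per-year standardized incidence from an ascertainment result.

    ``denominators`` is the output of :func:`person_years`.  A case falling
    in a (year, stratum) with no person-years is an error — it lies outside
    denominator coverage.
    """
    events = case_strata(result, bundle, bands)
    out: list[StandardizedRate] = []
    for year in sorted(denominators["year"].unique()):
        den = denominators[denominators["year"] == year]
        ev = events[events["year"] == year]
        merged = den.merge(ev[["age_band", "sex", "d"]], on=["age_band", "sex"],
                           how="outer", indicator=True)
        uncovered = merged[(merged["_merge"] == "right_only") & (merged["d"] > 0)]
        if len(uncovered):
            raise ValueError(
                f"cases outside denominator coverage in {year}: "
                f"{uncovered[['age_band', 'sex']].to_dict('records')}")
        counts = merged[merged["_merge"] != "right_only"][["age_band", "sex"]].copy()
        counts["d"] = merged.loc[merged["_merge"] != "right_only", "d"].fillna(0).to_numpy()
        counts["n"] = merged.loc[merged["_merge"] != "right_only", "py"].to_numpy()
        out.append(direct_standardize(counts, std, alpha, year=int(year)))
    return out


def _trend_frame(events: pd.DataFrame, denominators: pd.DataFrame,
                 center_year: int) -> pd.DataFrame:
    df = denominators.merge(events, on=["year", "age_band", "sex"], how="left")
    df["d"] = df["d"].fillna(0).astype(float)
    df["year_c"] = df["year"] - center_year
    df["sex_male"] = (df["sex"] == "male").astype(float)
    df["age_mid"] = df["age_band"].map(
        lambda b: (int(b.split("-")[0]) + int(b.split("-")[1])) / 2.0)
    return df


def fit_poisson_trend(result: AscertainmentResult | pd.DataFrame,
                      denominators: pd.DataFrame,
                      bundle: LinkedClaimsBundle | None = None,
                      interaction_year_age: bool = False,
                      quadratic_year: bool = False,
                      center_year: int | None = None,
                      alpha: float = 0.05) -> PoissonTrendFit:
    """Fit the annual-trend Poisson model on stratum counts.

    Events enter as counts per (year, age-band, sex) stratum with
    log(person-years) offset; covariates are calendar year (integer,
    centered at the first study year by default), a male indicator, and age
    (band midpoint, in years).  Optional terms: a year x age interaction and
    a quadratic year term (the linearity check).  Rate ratios exponentiate
    the unrounded coefficients with Wald intervals.
    """
    import statsmodels.api as sm

    if isinstance(result, AscertainmentResult):
        if bundle is None:
            raise ValueError("bundle is required to stratify case records")
        events = case_strata(result, bundle)
    else:
        events = result
    if denominators["py"].le(0).any():
        raise ValueError("person-years must be positive")
    if denominators["year"].nunique() < 2:
        raise ValueError("need at least two distinct years to fit a trend")
    if center_year is None:
        center_year = int(denominators["year"].min())
    df = _trend_frame(events, denominators, center_year)
    cols = ["year_c", "sex_male", "age_mid"]
    if interaction_year_age:
        df["year_x_age"] = df["year_c"] * df["age_mid"]
        cols.append("year_x_age")
    if quadratic_year:
        df["year_sq"] = df["year_c"] ** 2
        cols.append("year_sq")
    X = sm.add_constant(df[cols])
    model = sm.GLM(df["d"], X, family=sm.families.Poisson(),
                   offset=np.log(df["py"]))
    fit = model.fit()
    from scipy.stats import norm
    zq = float(norm.ppf(1 - alpha / 2))
    coefs = fit.params
    ses = fit.bse
    rr = pd.DataFrame({
        "rr": np.exp(coefs),
        "rr_lower": np.exp(coefs - zq * ses),
        "rr_upper": np.exp(coefs + zq * ses),
    })
    beta_y = float(coefs["year_c"])
    se_y = float(ses["year_c"])
    apc = (np.exp(beta_y) - 1.0) * 100.0
    apc_ci = ((np.exp(beta_y - zq * se_y) - 1.0) * 100.0,
              (np.exp(beta_y + zq * se_y) - 1.0) * 100.0)
    return PoissonTrendFit(
        coefficients=coefs,
        standard_errors=ses,
        rate_ratios=rr,
        p_values=fit.pvalues,
        deviance=float(fit.deviance),
        converged=bool(fit.converged),
        apc_percent=float(apc),
        apc_ci=apc_ci,
    )
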