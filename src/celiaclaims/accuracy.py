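"""Diagnostic-accuracy validation against the reference standard.

Operating characteristics (sensitivity, specificity, PPV, NPV) are binomial
proportions; their 95% intervals use the efficient-score (Wilson) method
with Newcombe's continuity correction, the standard choice for validation
studies with proportions near 0 or 1.  Predictive values are taken directly
from the population-based validation cohort — its prevalence reflects the
population, so no prevalence adjustment is applied.

Chart-review agreement on the ordinal Marsh biopsy grade is summarized by
the weighted kappa statistic.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .algorithms import AlgorithmSpec, AscertainmentResult, apply_algorithm
from .data_model import LinkedClaimsBundle

__all__ = [
    "ConfusionTable",
    "ProportionWithCI",
    "OperatingCharacteristics",
    "RatingPair",
    "confusion_table",
    "score_ci_cc",
    "operating_characteristics",
    "subgroup_validation",
    "weighted_kappa",
    "round_half_up",
]

Z_95 = 1.96  # conventional reporting value; differs from the exact quantile
             # (1.959964) only below the printed precision


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (report convention; Python's round is banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of an algorithm against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class ProportionWithCI:
    """A proportion with a continuity-corrected score confidence interval."""

    numerator: int
    denominator: int
    estimate: float
    ci_lower: float
    ci_upper: float
    alpha: float = 0.05
    method: str = "score_cc"

    def as_percent(self, ndigits: int = 2) -> tuple[float, float, float]:
        return tuple(round_half_up(100 * v, ndigits)
                     for v in (self.estimate, self.ci_lower, self.ci_upper))

    def format(self, ndigits: int = 2) -> str:
        est, lo, hi = self.as_percent(ndigits)
        f = f"{{:.{ndigits}f}}"
        return f"{f.format(est)} ({f.format(lo)}–{f.format(hi)})"


@dataclass(frozen=True)
class OperatingCharacteristics:
    algorithm_id: str
    sensitivity: ProportionWithCI
    specificity: ProportionWithCI
    ppv: ProportionWithCI | None
    npv: ProportionWithCI | None
    table: ConfusionTable


def confusion_table(result: AscertainmentResult,
                    labels: pd.DataFrame) -> ConfusionTable:
    """Cross-classify flagged persons against the reference-standard labels.

    Every flagged person must carry a label; a missing label is an error
    rather than silently counted either way.
    """
    status = dict(zip(labels["person_id"], labels["status"]))
    flagged = result.flagged_ids
    missing = [pid for pid in flagged if pid not in status]
    if missing:
        raise ValueError(f"flagged person(s) without reference label: "
                         f"{sorted(missing)[:5]}")
    n_pos = int((labels["status"] == "true_positive").sum())
    n_neg = int((labels["status"] == "true_negative").sum())
    tp = sum(1 for pid in flagged if status[pid] == "true_positive")
    fp = len(flagged) - tp
    return ConfusionTable(tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp)


def score_ci_cc(x: int, n: int, alpha: float = 0.05) -> ProportionWithCI:
    """Wilson score interval with continuity correction for x successes of n.

    With p = x/n and z the standard-normal upper alpha/2 quantile:

        lower = [2np + z^2 - 1 - z*sqrt(z^2 - 2 - 1/n + 4p(n(1-p)+1))] / [2(n+z^2)]
        upper = [2np + z^2 + 1 + z*sqrt(z^2 + 2 - 1/n + 4p(n(1-p)-1))] / [2(n+z^2)]

    clamped to [0, 1], with lower = 0 when x = 0 and upper = 1 when x = n.
    z is fixed at 1.96 for the 95% level (reporting convention); other levels
    use the exact normal quantile.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    from scipy.stats import norm

    z = Z_95 if math.isclose(alpha, 0.05) else float(norm.ppf(1 - alpha / 2))
    p = x / n
    denom = 2 * (n + z * z)
    lo_rad = z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)
    hi_rad = z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)
    lower = (2 * n * p + z * z - 1 - z * math.sqrt(max(lo_rad, 0.0))) / denom
    upper = (2 * n * p + z * z + 1 + z * math.sqrt(max(hi_rad, 0.0))) / denom
    if x == 0:
        lower = 0.0
    if x == n:
        upper = 1.0
    return ProportionWithCI(
        numerator=x, denominator=n, estimate=p,
        ci_lower=min(max(lower, 0.0), p),
        ci_upper=max(min(upper, 1.0), p),
        alpha=alpha,
    )


def operating_characteristics(ct: ConfusionTable, alpha: float = 0.05,
                              algorithm_id: str = "") -> OperatingCharacteristics:
    """The four operating characteristics with score-CC intervals.

    PPV is undefined (None, not zero) when the algorithm flags nobody;
    likewise NPV when it flags everybody.
    """
    if ct.n_positive == 0 or ct.n_negative == 0:
        raise ValueError("reference standard must contain positives and negatives")
    ppv = score_ci_cc(ct.tp, ct.tp + ct.fp, alpha) if ct.tp + ct.fp > 0 else None
    npv = score_ci_cc(ct.tn, ct.tn + ct.fn, alpha) if ct.tn + ct.fn > 0 else None
    return OperatingCharacteristics(
        algorithm_id=algorithm_id,
        sensitivity=score_ci_cc(ct.tp, ct.n_positive, alpha),
        specificity=score_ci_cc(ct.tn, ct.n_negative, alpha),
        ppv=ppv,
        npv=npv,
        table=ct,
    )


def subgroup_validation(
    bundle: LinkedClaimsBundle,
    labels: pd.DataFrame,
    grid: Sequence[AlgorithmSpec],
    age_cutoffs: Iterable[int],
    study_window: tuple[dt.date, dt.date] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-validate each algorithm with the reference restricted by age.

    Positives are restricted by age at diagnosis.  Negatives carry no
    diagnosis date, so their age is taken at the study-window midpoint (a
    documented convention; pass a different window to move it).  Returns one
    row per (algorithm, cutoff) with counts and the four characteristics;
    a subgroup with no positives yields NaN sensitivity (not estimable).
    """
    cutoffs = sorted(set(int(c) for c in age_cutoffs))
    if any(c <= 0 for c in cutoffs):
        raise ValueError("age cutoffs must be positive")
    reg = bundle.registry[["person_id", "birth_date"]]
    lab = labels.merge(reg, on="person_id", how="left")
    if study_window is None:
        dates = pd.to_datetime(lab["diagnosis_date"]).dropna()
        mid = dates.min() + (dates.max() - dates.min()) / 2 if len(dates) else None
    else:
        start, end = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
        mid = start + (end - start) / 2
    birth = pd.to_datetime(lab["birth_date"])
    dx = pd.to_datetime(lab["diagnosis_date"])
    ref_date = dx.fillna(mid)
    # Signed age in years: a negative born after the reference date has a
    # negative age and therefore falls below any positive cutoff.
    lab = lab.assign(_age=(ref_date - birth).dt.days / 365.25)
    rows = []
    results = {spec.algorithm_id: apply_algorithm(bundle, spec, study_window)
               for spec in grid}
    for cutoff in cutoffs:
        sub = lab[lab["_age"] < cutoff]
        sub_ids = set(sub["person_id"])
        for spec in grid:
            res = results[spec.algorithm_id]
            flagged = res.flagged_ids & sub_ids
            status = dict(zip(sub["person_id"], sub["status"]))
            n_pos = int((sub["status"] == "true_positive").sum())
            n_neg = int((sub["status"] == "true_negative").sum())
            tp = sum(1 for pid in flagged if status[pid] == "true_positive")
            fp = len(flagged) - tp
            row: dict = {"algorithm_id": spec.algorithm_id, "age_cutoff": cutoff,
                         "tp": tp, "fp": fp, "fn": n_pos - tp, "tn": n_neg - fp}
            if n_pos > 0 and n_neg > 0:
                oc = operating_characteristics(
                    ConfusionTable(tp, fp, n_pos - tp, n_neg - fp), alpha,
                    spec.algorithm_id)
                row.update(
                    sensitivity=oc.sensitivity.estimate,
                    specificity=oc.specificity.estimate,
                    ppv=oc.ppv.estimate if oc.ppv else np.nan,
                    npv=oc.npv.estimate if oc.npv else np.nan,
                )
            else:
                row.update(sensitivity=np.nan, specificity=np.nan,
                           ppv=np.nan, npv=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RatingPair:
    """One item rated independently by two raters on an ordinal scale."""

    item_id: str
    rating_a: str
    rating_b: str


def weighted_kappa(pairs: Sequence[RatingPair | tuple],
                   categories: Sequence[str],
                   weights: str = "quadratic") -> float:
    """Weighted kappa for two raters on ordered categories.

        kappa_w = 1 - sum(w_ij * o_ij) / sum(w_ij * e_ij)

    with disagreement weights w_ij = |i-j| (linear) or (i-j)^2 (quadratic),
    observed cell proportions o, and chance-expected proportions e from the
    marginals.  Raises when chance disagreement is zero (both raters use a
    single category), where kappa is undefined.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError(f"unknown weighting scheme {weights!r}")
    if len(pairs) < 2:
        raise ValueError("need at least two rated items")
    cat_index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    obs = np.zeros((k, k))
    for p in pairs:
        a, b = (p.rating_a, p.rating_b) if isinstance(p, RatingPair) else (p[-2], p[-1])
        try:
            obs[cat_index[a], cat_index[b]] += 1
        except KeyError as exc:
            raise ValueError(f"rating {exc.args[0]!r} not in declared categories") from exc
    obs /= obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    idx = np.arange(k)
    diff = idx[:, None] - idx[None, :]
    w = np.abs(diff) if weights == "linear" else diff.astype(float) ** 2
    chance = float((w * expected).sum())
    if chance == 0.0:
        raise ValueError("kappa undefined: no chance disagreement "
                         "(single category used by both raters)")
    return 1.0 - float((w * obs).sum()) / chance
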