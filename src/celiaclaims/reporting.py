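"""Pipeline orchestration, privacy-style cell suppression and report tables.

Reports follow the conventions of health-data custodians: displayed cell
counts between 1 and 5 are suppressed as "<6", and counts outside the union
of identified cases are rounded to the nearest 10.  Suppression applies to
*rendering only* — internal statistics always use raw counts.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import accuracy, algorithms, incidence, synthetic
from .accuracy import round_half_up
from .data_model import CodeConfig, LinkedClaimsBundle, load_bundle, write_bundle

__all__ = [
    "PipelineConfig",
    "SuppressedCell",
    "suppress",
    "render_table1",
    "render_venn",
    "run_pipeline",
]


@dataclass(frozen=True)
class SuppressedCell:
    raw: int
    display: str


def suppress(raw: int, context: str = "in_union") -> SuppressedCell:
    """Privacy suppression for a displayed count.

    Counts 1-5 render as "<6" regardless of context; counts outside the
    union of identified cases are additionally rounded to the nearest 10
    (half-up).  Zero and in-union counts of 6+ display as-is.
    """
    if raw < 0:
        raise ValueError("count must be non-negative")
    if context not in ("in_union", "outside_union"):
        raise ValueError(f"unknown suppression context {context!r}")
    if 1 <= raw <= 5:
        return SuppressedCell(raw, "<6")
    if context == "outside_union" and raw > 5:
        return SuppressedCell(raw, str(int(round_half_up(raw / 10, 0) * 10)))
    return SuppressedCell(raw, str(raw))


def render_table1(characteristics: Sequence[accuracy.OperatingCharacteristics],
                  ndigits: int = 2) -> str:
    """CSV text with one row per algorithm and `est (lo–hi)` cells."""
    if not characteristics:
        raise ValueError("no characteristics to render")
    rows = []
    for oc in characteristics:
        rows.append({
            "algorithm": oc.algorithm_id,
            "sensitivity": oc.sensitivity.format(ndigits),
            "specificity": oc.specificity.format(ndigits),
            "ppv": oc.ppv.format(ndigits) if oc.ppv is not None else "NA",
            "npv": oc.npv.format(ndigits) if oc.npv is not None else "NA",
        })
    return pd.DataFrame(rows).to_csv(index=False)


def render_venn(result_a: algorithms.AscertainmentResult,
                result_b: algorithms.AscertainmentResult,
                n_total: int | None = None,
                suppressed: bool = True) -> pd.DataFrame:
    """Overlap of two algorithms' flagged sets, with suppression applied."""
    only_a, both, only_b = algorithms.overlap(result_a, result_b)
    rows = [
        (f"only_{result_a.algorithm_id}", only_a, "in_union"),
        ("both", both, "in_union"),
        (f"only_{result_b.algorithm_id}", only_b, "in_union"),
    ]
    if n_total is not None:
        rows.append(("neither", n_total - (only_a + both + only_b), "outside_union"))
    out = pd.DataFrame(rows, columns=["region", "raw", "context"])
    out["display"] = [suppress(r, c).display if suppressed else str(r)
                      for r, c in zip(out["raw"], out["context"])]
    return out[["region", "display"]] if suppressed else out[["region", "raw"]]


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate -> ascertain -> validate ->
    incidence -> trends -> report)."""

    out_dir: Path = Path("pipeline_out")
    bundle_dir: Path | None = None          # load instead of simulate
    seed: int = synthetic.DEFAULT_SEED
    simulation: dict = field(default_factory=dict)
    algorithm_ids: tuple[str, ...] = ("13-OHIP", "1-SDS")
    study_window: tuple[dt.date, dt.date] = (dt.date(2005, 1, 1), dt.date(2011, 12, 31))
    alpha: float = 0.05
    report_digits: int = 2
    suppression: bool = True
    codes: CodeConfig = field(default_factory=CodeConfig)
    write_tables: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        if "bundle_dir" in raw:
            kwargs["bundle_dir"] = Path(raw["bundle_dir"])
        for key in ("seed", "simulation", "alpha", "report_digits",
                    "suppression", "write_tables"):
            if key in raw:
                kwargs[key] = raw[key]
        if "algorithm_ids" in raw:
            kwargs["algorithm_ids"] = tuple(raw["algorithm_ids"])
        if "study_window" in raw:
            a, b = raw["study_window"]
            kwargs["study_window"] = (dt.date.fromisoformat(str(a)),
                                      dt.date.fromisoformat(str(b)))
        if "codes" in raw:
            c = raw["codes"]
            kwargs["codes"] = CodeConfig(
                celiac_codes=tuple(c.get("celiac_codes", ("579",))),
                endoscopy_fee_codes=tuple(c.get("endoscopy_fee_codes", ("Z555", "Z715"))),
                endoscopy_intervention_codes=tuple(
                    c.get("endoscopy_intervention_codes", ("1OD16", "2OD71"))),
                match=c.get("match", "prefix"),
            )
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps({
            "seed": self.seed, "simulation": self.simulation,
            "algorithm_ids": list(self.algorithm_ids),
            "study_window": [d.isoformat() for d in self.study_window],
            "alpha": self.alpha, "report_digits": self.report_digits,
            "suppression": self.suppression,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full pipeline; deterministic for a fixed seed.

    Writes table1.csv, rates.csv, fit.json, venn.csv and run.log into
    ``config.out_dir`` and returns the path map.  Any stage failure aborts
    with the stage named in the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]

    def stage(name: str):
        log_lines.append(f"stage={name}")
        return name

    try:
        stage("simulate" if config.bundle_dir is None else "load")
        if config.bundle_dir is None:
            params = synthetic.SimulationParams(
                seed=config.seed,
                study_window=config.study_window,
                **config.simulation)
            bundle, truth = synthetic.simulate_population(params, config.codes)
        else:
            bundle = load_bundle(config.bundle_dir, config.codes)
            truth = None
        log_lines.append(f"registry_rows={len(bundle.registry)}")
        log_lines.append(f"claims_rows={len(bundle.claims)}")
        log_lines.append(f"procedure_rows={len(bundle.procedures)}")
        if config.write_tables:
            write_bundle(bundle, out / "bundle")

        stage("ascertain")
        grid = algorithms.build_algorithm_grid()
        specs = [algorithms.get_algorithm(aid, grid) for aid in config.algorithm_ids]
        results = {s.algorithm_id: algorithms.apply_algorithm(
            bundle, s, config.study_window) for s in specs}
        for aid, res in results.items():
            log_lines.append(f"cases[{aid}]={res.n_cases}")

        stage("validate")
        if bundle.labels is None:
            raise ValueError("bundle has no reference labels")
        ocs = []
        for s in specs:
            ct = accuracy.confusion_table(results[s.algorithm_id], bundle.labels)
            ocs.append(accuracy.operating_characteristics(
                ct, config.alpha, s.algorithm_id))
        (out / "table1.csv").write_text(
            render_table1(ocs, config.report_digits))

        stage("incidence")
        denom = incidence.person_years(bundle.registry, config.study_window)
        std = incidence.StandardPopulation.uniform()
        rate_rows = []
        for s in specs:
            for r in incidence.incidence_series(
                    results[s.algorithm_id], denom, std, bundle, config.alpha):
                rate_rows.append({"algorithm": s.algorithm_id, "year": r.year,
                                  "dsr": r.dsr, "ci_lower": r.ci_lower,
                                  "ci_upper": r.ci_upper})
        pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)

        stage("trends")
        fits = {}
        for s in specs:
            fit = incidence.fit_poisson_trend(results[s.algorithm_id], denom, bundle)
            fits[s.algorithm_id] = {
                "apc_percent": fit.apc_percent,
                "apc_ci": list(fit.apc_ci),
                "converged": fit.converged,
                "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
                "rate_ratios": {k: float(v) for k, v in fit.rate_ratios["rr"].items()},
            }
        (out / "fit.json").write_text(json.dumps(fits, indent=2))

        stage("report")
        if len(specs) >= 2:
            venn = render_venn(results[specs[0].algorithm_id],
                               results[specs[1].algorithm_id],
                               n_total=len(bundle.registry),
                               suppressed=config.suppression)
            venn.to_csv(out / "venn.csv", index=False)
    except Exception as exc:
        log_lines.append(f"aborted: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(
            f"pipeline failed at stage {log_lines[-2] if len(log_lines) > 1 else '?'}: {exc}"
        ) from exc

    log_lines.append("status=ok")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    paths = {p.stem: p for p in
             (out / "table1.csv", out / "rates.csv", out / "fit.json",
              out / "venn.csv", out / "run.log") if p.exists()}
    return paths
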