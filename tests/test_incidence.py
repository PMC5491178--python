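import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from celiaclaims.algorithms import AscertainmentResult, apply_algorithm, get_algorithm
from celiaclaims.incidence import (
    StandardPopulation,
    direct_standardize,
    fit_poisson_trend,
    incidence_series,
    person_years,
)
from celiaclaims.synthetic import SimulationParams, simulate_population

from conftest import WIN, make_bundle


def _registry(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "birth_date", "sex", "region_flag",
                       "eligibility_intervals"])


def _counts(rows):
    return pd.DataFrame(rows, columns=["age_band", "sex", "d", "n"])


UNIFORM = StandardPopulation.uniform()


class TestPersonYears:
    def test_fully_eligible_year(self):
        reg = _registry([("A", pd.Timestamp("1998-06-01"), "male", True,
                          "2004-01-01..2012-01-01")])
        py = person_years(reg, (pd.Timestamp("2005-01-01").date(),
                                pd.Timestamp("2005-12-31").date()))
        row = py[(py.year == 2005)].iloc[0]
        assert row.age_band == "5-9" and row.sex == "male"
        assert row.py == pytest.approx(365 / 365.25)

    def test_half_year_eligibility(self):
        reg = _registry([("A", pd.Timestamp("1998-06-01"), "female", True,
                          "2005-01-01..2005-07-02")])
        py = person_years(reg, (pd.Timestamp("2005-01-01").date(),
                                pd.Timestamp("2005-12-31").date()))
        assert py.py.sum() == pytest.approx(182 / 365.25, abs=1e-6)

    def test_total_person_years_conserved(self):
        rows = [(f"P{i}", pd.Timestamp("2000-06-01"), "male", True,
                 "2005-01-01..2008-01-01") for i in range(1000)]
        py = person_years(_registry(rows), (pd.Timestamp("2005-01-01").date(),
                                            pd.Timestamp("2007-12-31").date()))
        assert py.py.sum() == pytest.approx(1000 * 3 * 365 / 365.25, rel=1e-3)

    def test_no_eligibility_contributes_zero(self):
        reg = _registry([("A", pd.Timestamp("2000-01-01"), "male", True, "")])
        py = person_years(reg, (pd.Timestamp("2005-01-01").date(),
                                pd.Timestamp("2005-12-31").date()))
        assert py.empty or py.py.sum() == 0


class TestDirectStandardization:
    def test_equal_rates_recover_common_rate(self):
        # every stratum has rate 20/100k: weights cannot matter
        counts = _counts([(b, s, 20, 100_000.0)
                          for b in ("0-4", "5-9", "10-14")
                          for s in ("female", "male")])
        r = direct_standardize(counts, UNIFORM)
        assert r.dsr == pytest.approx(20.0)

    def test_standard_population_invariance_at_equal_rates(self):
        counts = _counts([(b, s, 5, 25_000.0)
                          for b in ("0-4", "5-9", "10-14")
                          for s in ("female", "male")])
        skew = StandardPopulation(pd.DataFrame({
            "age_band": ["0-4", "0-4", "5-9", "5-9", "10-14", "10-14"],
            "sex": ["female", "male"] * 3,
            "weight": [0.4, 0.3, 0.1, 0.1, 0.05, 0.05]}))
        assert (direct_standardize(counts, UNIFORM).dsr
                == pytest.approx(direct_standardize(counts, skew).dsr))

    def test_zero_events(self):
        counts = _counts([(b, s, 0, 10_000.0)
                          for b in ("0-4", "5-9", "10-14")
                          for s in ("female", "male")])
        r = direct_standardize(counts, UNIFORM)
        assert r.dsr == 0.0 and r.ci_lower == 0.0 and r.ci_upper > 0.0

    def test_missing_stratum_is_error(self):
        counts = _counts([("0-4", "female", 1, 1000.0)])
        with pytest.raises(ValueError, match="missing count strata"):
            direct_standardize(counts, UNIFORM)

    @pytest.mark.parametrize("d", [1, 4, 17, 120])
    def test_single_stratum_equals_exact_poisson_ci(self, d):
        """With all weight on one stratum the gamma CI must coincide with
        the exact Poisson chi-square interval for d events."""
        n = 40_000.0
        single = StandardPopulation(pd.DataFrame(
            {"age_band": ["0-4"], "sex": ["female"], "weight": [1.0]}))
        counts = _counts([("0-4", "female", d, n)])
        r = direct_standardize(counts, single)
        lo = chi2.ppf(0.025, 2 * d) / 2 / n * 1e5
        hi = chi2.ppf(0.975, 2 * d + 2) / 2 / n * 1e5
        assert r.ci_lower == pytest.approx(lo, rel=1e-9)
        assert r.ci_upper == pytest.approx(hi, rel=1e-9)

    def test_gamma_coverage_over_replicates(self):
        """95% gamma intervals are conservative: coverage in [93%, 99%]."""
        rng = np.random.default_rng(314)
        bands = ("0-4", "5-9", "10-14")
        n_py = {b: py for b, py in zip(bands, (30_000.0, 50_000.0, 40_000.0))}
        rate = {b: r for b, r in zip(bands, (4.0, 8.0, 12.0))}  # per 100k
        w = UNIFORM.strata.set_index(["age_band", "sex"])["weight"]
        true_dsr = sum(w[(b, s)] * rate[b] for b in bands
                       for s in ("female", "male"))
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            rows = []
            for b in bands:
                for s in ("female", "male"):
                    d = rng.poisson(rate[b] / 1e5 * n_py[b])
                    rows.append((b, s, d, n_py[b]))
            r = direct_standardize(_counts(rows), UNIFORM)
            hits += r.ci_lower <= true_dsr <= r.ci_upper
        assert 0.93 <= hits / n_rep <= 0.99


def _sim_trend_frame(rng, beta_year, n_years=17, base_rate_per100k=8.0,
                     py_per_stratum=150_000.0, beta_male=-0.3, beta_age=-0.05):
    """Stratum counts drawn from the log-linear model itself."""
    rows_ev, rows_py = [], []
    for year in range(1995, 1995 + n_years):
        t = year - 1995
        for band, age_mid in (("0-4", 2.0), ("5-9", 7.0), ("10-14", 12.0)):
            for sex, male in (("female", 0.0), ("male", 1.0)):
                mu = (base_rate_per100k / 1e5 * py_per_stratum
                      * np.exp(beta_year * t + beta_male * male + beta_age * age_mid))
                d = rng.poisson(mu)
                rows_ev.append((year, band, sex, d))
                rows_py.append((year, band, sex, py_per_stratum))
    ev = pd.DataFrame(rows_ev, columns=["year", "age_band", "sex", "d"])
    py = pd.DataFrame(rows_py, columns=["year", "age_band", "sex", "py"])
    return ev, py


class TestPoissonTrend:
    def test_constant_rate_null_recovery(self):
        ev, py = _sim_trend_frame(np.random.default_rng(1), beta_year=0.0)
        fit = fit_poisson_trend(ev, py)
        assert fit.converged
        assert abs(fit.coefficients["year_c"]) < 3 * fit.standard_errors["year_c"]
        assert fit.rate_ratios.loc["year_c", "rr"] == pytest.approx(1.0, abs=0.02)

    def test_nine_percent_apc_recovery(self):
        """Simulated 9%/year growth (beta = log 1.09) is recovered."""
        beta = float(np.log(1.09))
        ev, py = _sim_trend_frame(np.random.default_rng(2), beta_year=beta)
        fit = fit_poisson_trend(ev, py)
        se = fit.standard_errors["year_c"]
        assert abs(fit.coefficients["year_c"] - beta) < 3 * se
        assert fit.apc_percent == pytest.approx(9.0, abs=1.0)

    def test_rate_ratio_is_exponentiated_coefficient(self):
        ev, py = _sim_trend_frame(np.random.default_rng(3), beta_year=0.05)
        fit = fit_poisson_trend(ev, py)
        for term in fit.coefficients.index:
            assert fit.rate_ratios.loc[term, "rr"] == pytest.approx(
                np.exp(fit.coefficients[term]), rel=1e-12)
        # e.g. a -0.33 male coefficient prints RR 0.72 at 2 dp
        assert round(float(np.exp(-0.33)), 2) == 0.72

    def test_quadratic_and_interaction_terms_estimable(self):
        ev, py = _sim_trend_frame(np.random.default_rng(4), beta_year=0.05)
        fit = fit_poisson_trend(ev, py, quadratic_year=True,
                                interaction_year_age=True)
        assert fit.converged
        assert {"year_sq", "year_x_age"} <= set(fit.coefficients.index)

    def test_matches_independent_optimizer(self):
        """Poisson ML via the GLM path equals a generic optimizer on the
        same likelihood to 1e-6."""
        from scipy.optimize import minimize

        ev, py = _sim_trend_frame(np.random.default_rng(5), beta_year=0.05,
                                  n_years=6, py_per_stratum=50_000.0)
        fit = fit_poisson_trend(ev, py)
        df = py.merge(ev, on=["year", "age_band", "sex"])
        X = np.column_stack([
            np.ones(len(df)),
            df.year - df.year.min(),
            (df.sex == "male").astype(float),
            df.age_band.map({"0-4": 2.0, "5-9": 7.0, "10-14": 12.0}),
        ])
        d = df.d.to_numpy(float)
        off = np.log(df.py.to_numpy(float))

        def nll(beta):
            eta = X @ beta + off
            return float(np.sum(np.exp(eta) - d * eta))

        res = minimize(nll, np.zeros(4), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(res.x, fit.coefficients.to_numpy(),
                                   atol=1e-6)

    def test_single_year_rejected(self):
        ev, py = _sim_trend_frame(np.random.default_rng(6), 0.0, n_years=1)
        with pytest.raises(ValueError, match="two distinct years"):
            fit_poisson_trend(ev, py)


@pytest.fixture(scope="module")
def sim():
    params = SimulationParams(n_children=40_000, seed=55,
                              annual_incidence_per_100k=60.0)
    bundle, truth = simulate_population(params)
    denom = person_years(bundle.registry, WIN)
    return bundle, truth, denom


class TestIncidenceSeries:

    def test_zero_cases_zero_series(self, sim):
        bundle, _, denom = sim
        empty = AscertainmentResult("none")
        series = incidence_series(empty, denom, UNIFORM, bundle)
        assert all(r.dsr == 0.0 for r in series)

    def test_doubling_events_doubles_rates(self, sim):
        bundle, _, denom = sim
        res = apply_algorithm(bundle, get_algorithm("1-SDS"), WIN)
        doubled = AscertainmentResult("x2", pd.concat(
            [res.cases, res.cases.assign(person_id=res.cases.person_id + "_b")],
            ignore_index=True))
        reg2 = pd.concat([bundle.registry,
                          bundle.registry.assign(
                              person_id=bundle.registry.person_id + "_b")],
                         ignore_index=True)
        import dataclasses
        bundle2 = dataclasses.replace(bundle, registry=reg2)
        s1 = incidence_series(res, denom, UNIFORM, bundle)
        s2 = incidence_series(doubled, denom, UNIFORM, bundle2)
        for a, b in zip(s1, s2):
            assert b.dsr == pytest.approx(2 * a.dsr)

    def test_noiseless_series_tracks_generative_incidence(self):
        """Gamma CIs cover the generative rate in most simulated years."""
        hits = total = 0
        for seed in range(300, 325):
            params = SimulationParams(
                n_children=25_000, annual_incidence_per_100k=60.0, seed=seed,
                p_biopsy_if_cd=1.0, p_sds_record_cd_coded=1.0,
                p_outpatient_cd_visit_post_dx=1.0,
                background_endoscopy_rate=0.0, background_cd_code_noise=0.0)
            bundle, _ = simulate_population(params)
            res = apply_algorithm(bundle, get_algorithm("1-SDS"), WIN)
            denom = person_years(bundle.registry, WIN)
            # onset feasibility trims the very edges of the window; compare
            # interior years only
            for r in incidence_series(res, denom, UNIFORM, bundle)[1:-1]:
                total += 1
                hits += r.ci_lower <= 60.0 <= r.ci_upper
        assert hits / total >= 0.90
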