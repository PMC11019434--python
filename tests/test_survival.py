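"""Survival estimators and competing-risks tests."""

from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from kirpipe.survival import (
    aalen_johansen,
    coxph_cause_specific,
    gray_test,
    km_estimate,
    logrank_test,
)


def simulate_competing(rng, n, lam1=0.3, lam2=0.2, cens=0.15, hr1=None, group=None):
    scale1 = 1.0 / (lam1 if hr1 is None else lam1 * np.where(group == 1, hr1, 1.0))
    t1 = rng.exponential(scale1, n) if np.ndim(scale1) == 0 else rng.exponential(scale1)
    t2 = rng.exponential(1 / lam2, n)
    tc = rng.exponential(1 / cens, n) if cens > 0 else np.full(n, np.inf)
    t = np.minimum.reduce([t1, t2, tc])
    cause = np.where(t == t1, 1, np.where(t == t2, 2, 0))
    return t, cause


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_hand_product_limit(self):
        km = km_estimate([5.0, 10.0], [1, 0])
        assert km.at(5.0) == pytest.approx(0.5)
        assert km.at(10.0) == pytest.approx(0.5)

    def test_tied_failures_simultaneous(self):
        km = km_estimate([2.0, 2.0, 4.0, 5.0], [1, 1, 1, 0])
        assert km.at(2.0) == pytest.approx(0.5)
        assert km.at(4.0) == pytest.approx(0.25)

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(0)
        t, cause = simulate_competing(rng, 300)
        km = km_estimate(t, cause > 0)
        kmf = KaplanMeierFitter().fit(t, cause > 0)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.allclose(km.survival, theirs, atol=1e-12)
        # Greenwood variance too
        ci_var = kmf.survival_function_.iloc[:, 0]
        assert km.variance.shape == km.survival.shape

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(1)
        lam, n = 0.25, 100_000
        t = rng.exponential(1 / lam, n)
        km = km_estimate(t, np.ones(n))
        for tt in (1.0, 2.0, 4.0):
            truth = np.exp(-lam * tt)
            mc_se = np.sqrt(truth * (1 - truth) / n)
            assert abs(km.at(tt) - truth) < 3 * mc_se


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        e = np.array([1, 0, 1, 1, 0] * 2)
        g = np.repeat([0, 1], 5)
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_cox_score_direction(self):
        """The log-rank p agrees closely with a one-covariate Cox Wald p."""
        rng = np.random.default_rng(4)
        n = 400
        g = rng.integers(0, 2, n)
        t, cause = simulate_competing(rng, n, hr1=1.6, group=g)
        lr = logrank_test(t, cause > 0, g)
        df = pd.DataFrame({"time_months": t, "cause": (cause > 0).astype(int), "g": g})
        cox = coxph_cause_specific(df, ["g"], cause=1)
        assert lr.p_value == pytest.approx(cox.row("g[1]")["p"], abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestAalenJohansen:
    def test_single_cause_reduces_to_km(self):
        rng = np.random.default_rng(5)
        n = 200
        t = rng.exponential(2.0, n)
        e = (rng.random(n) < 0.7).astype(int)
        cif = aalen_johansen(t, e, 1)
        km = km_estimate(t, e)
        assert np.allclose(cif.cif, 1.0 - km.survival, atol=1e-12)

    def test_conservation_exact(self):
        rng = np.random.default_rng(6)
        t, cause = simulate_competing(rng, 500)
        km = km_estimate(t, cause > 0)
        c1 = aalen_johansen(t, cause, 1)
        c2 = aalen_johansen(t, cause, 2)
        assert np.abs(km.survival + c1.cif + c2.cif - 1.0).max() < 1e-12

    def test_constant_hazard_closed_form(self):
        rng = np.random.default_rng(7)
        lam1, lam2, n = 0.3, 0.2, 100_000
        t, cause = simulate_competing(rng, n, lam1, lam2, cens=0)
        cif = aalen_johansen(t, cause, 1)
        for tt in (1.0, 2.0, 5.0):
            truth = lam1 / (lam1 + lam2) * (1 - np.exp(-(lam1 + lam2) * tt))
            mc_se = np.sqrt(truth * (1 - truth) / n)
            assert abs(cif.at(tt) - truth) < 3 * mc_se

    def test_unknown_cause_is_error(self):
        with pytest.raises(ValueError):
            aalen_johansen([1.0, 2.0], [1, 2], 0)

    def test_variance_matches_r_cmprsk(self, competing_risks_sample, tmp_path):
        """Estimates and variances agree with the cmprsk reference."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript unavailable")
        t, cause, _ = competing_risks_sample
        cif = aalen_johansen(t, cause, 1)
        data = tmp_path / "d.txt"
        data.write_text(
            "time cause\n"
            + "\n".join(f"{ti:.10f} {ci}" for ti, ci in zip(t, cause))
        )
        script = (
            f'd <- read.table("{data}", header=TRUE);'
            "suppressMessages(library(cmprsk));"
            "r <- cuminc(d$time, d$cause);"
            "tp <- timepoints(r, c(2, 4));"
            'cat(tp$est[1,], tp$var[1,], "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        e2, e4, v2, v4 = map(float, out.stdout.split())
        assert cif.at(2.0) == pytest.approx(e2, abs=1e-6)  # R prints 7 digits
        assert cif.at(4.0) == pytest.approx(e4, abs=1e-6)
        i2 = np.searchsorted(cif.times, 2.0, side="right") - 1
        i4 = np.searchsorted(cif.times, 4.0, side="right") - 1
        assert cif.variance[i2] == pytest.approx(v2, rel=0.10)
        assert cif.variance[i4] == pytest.approx(v4, rel=0.10)


class TestGray:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 2)
        c = np.array([1, 2, 0, 1, 2, 1] * 2)
        g = np.repeat([0, 1], 6)
        res = gray_test(t, c, g, 1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_of_cause_is_error(self):
        with pytest.raises(ValueError):
            gray_test([1.0, 2.0], [2, 0], [0, 1], 1)

    def test_against_r_cmprsk(self, competing_risks_sample, tmp_path):
        """Statistic and p agree with the cmprsk reference implementation."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript unavailable")
        t, cause, g = competing_risks_sample
        res = gray_test(t, cause, g, 1)
        data = tmp_path / "d.txt"
        data.write_text(
            "time cause group\n"
            + "\n".join(f"{ti:.10f} {ci} {gi}" for ti, ci, gi in zip(t, cause, g))
        )
        script = (
            f'd <- read.table("{data}", header=TRUE);'
            "suppressMessages(library(cmprsk));"
            "r <- cuminc(d$time, d$cause, d$group);"
            'cat(r$Tests[1,1], r$Tests[1,2], "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        stat, p = map(float, out.stdout.split())
        assert res.statistic == pytest.approx(stat, rel=0.15, abs=0.05)
        assert res.p_value == pytest.approx(p, abs=0.02)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        t, cause = simulate_competing(rng, 80)
        g = rng.integers(0, 2, 80)
        a = gray_test(t, cause, g, 1)
        b = gray_test(t, cause, 1 - g, 1)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(10)
        n = 500
        t, cause = simulate_competing(rng, n)
        df = pd.DataFrame(
            {"time_months": t, "cause": cause, "x": rng.integers(0, 2, n)}
        )
        fit = coxph_cause_specific(df, ["x"], cause=1)
        row = fit.row("x[1]")
        assert abs(row["coef"]) < 3 * row["se"]

    def test_brute_force_efron_oracle(self):
        """Estimate matches grid maximization of the Efron partial
        likelihood on a tied 12-record fixture to 1e-4."""
        tt = np.array([1, 1, 2, 3, 3, 3, 4, 5, 6, 7, 8, 9], float)
        ee = np.array([1, 0, 1, 1, 1, 0, 1, 0, 1, 1, 0, 1])
        xx = np.array([0.5, 1.2, -0.3, 0.8, 0.0, 1.0, -1.1, 0.4, 0.9, -0.5, 0.2, 1.5])

        def efron_loglik(beta):
            ll = 0.0
            theta = np.exp(beta * xx)
            for s in np.unique(tt[ee == 1]):
                D = (tt == s) & (ee == 1)
                R = tt >= s
                d = D.sum()
                sum_r, sum_d = theta[R].sum(), theta[D].sum()
                ll += beta * xx[D].sum()
                for k in range(d):
                    ll -= np.log(sum_r - k / d * sum_d)
            return ll

        oracle = minimize_scalar(
            lambda b: -efron_loglik(b), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        ).x
        df = pd.DataFrame({"time_months": tt, "cause": ee, "x": xx})
        fit = coxph_cause_specific(df, ["x"], cause=1)
        assert fit.summary["coef"].iloc[0] == pytest.approx(oracle, abs=1e-4)

    def test_shift_and_time_rescale_invariance(self):
        rng = np.random.default_rng(12)
        n = 300
        g = rng.integers(0, 2, n)
        t, cause = simulate_competing(rng, n, hr1=1.5, group=g)
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({"time_months": t, "cause": cause, "x": x, "g": g})
        base = coxph_cause_specific(df, ["x", "g"], cause=1)
        shifted = df.assign(x=df.x + 100.0)
        rescaled = df.assign(time_months=df.time_months * 7.3)
        fit_s = coxph_cause_specific(shifted, ["x", "g"], cause=1)
        fit_r = coxph_cause_specific(rescaled, ["x", "g"], cause=1)
        assert fit_s.row("x")["coef"] == pytest.approx(base.row("x")["coef"], abs=1e-6)
        assert fit_r.row("x")["coef"] == pytest.approx(base.row("x")["coef"], abs=1e-8)

    def test_constant_stratum_equals_no_strata(self):
        rng = np.random.default_rng(13)
        n = 200
        t, cause = simulate_competing(rng, n)
        df = pd.DataFrame(
            {
                "time_months": t,
                "cause": cause,
                "x": rng.normal(0, 1, n),
                "s": "only",
            }
        )
        plain = coxph_cause_specific(df, ["x"], cause=1)
        strat = coxph_cause_specific(df, ["x"], cause=1, strata=["s"])
        assert strat.row("x")["coef"] == pytest.approx(
            plain.row("x")["coef"], abs=1e-8
        )

    def test_competing_cause_censored(self):
        """Cause-specific convention: competing events enter as censorings."""
        rng = np.random.default_rng(14)
        n = 400
        t, cause = simulate_competing(rng, n)
        df = pd.DataFrame({"time_months": t, "cause": cause, "x": rng.normal(size=n)})
        fit1 = coxph_cause_specific(df, ["x"], cause=1)
        df_manual = df.assign(cause=(df.cause == 1).astype(int))
        fit2 = coxph_cause_specific(df_manual, ["x"], cause=1)
        assert fit1.row("x")["coef"] == pytest.approx(fit2.row("x")["coef"], abs=1e-12)
        assert fit1.n_events == (cause == 1).sum()

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(15)
        n = 100
        t, cause = simulate_competing(rng, n)
        x = rng.normal(size=n)
        df = pd.DataFrame(
            {"time_months": t, "cause": cause, "x": x, "y": 2.0 * x}
        )
        with pytest.raises(ValueError, match="collinear"):
            coxph_cause_specific(df, ["x", "y"], cause=1)

    def test_missing_categorical_becomes_level(self):
        rng = np.random.default_rng(16)
        n = 300
        t, cause = simulate_competing(rng, n)
        grp = pd.Series(rng.choice(["a", "b"], n)).where(rng.random(n) > 0.1)
        df = pd.DataFrame({"time_months": t, "cause": cause, "g": grp})
        fit = coxph_cause_specific(df, ["g"], cause=1)
        names = set(fit.summary["covariate"])
        assert any("missing" in c for c in names)
        assert fit.n == n  # nothing dropped
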