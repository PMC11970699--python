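"""Robust two-rate regression: exactness, oracles, invariances."""

import math

import numpy as np
import pytest

import campmort as cm
from campmort.estimator import DegenerateDesignError
from campmort.exposure import DesignRow


def _row(x_b, x_m, deaths, name="r"):
    pt = max(x_b, x_m)
    frac = 0.0 if x_m == 0 else min(x_m / pt, 1.0)
    return DesignRow(
        camp_name=name, person_time=pt, monsoon_fraction=frac,
        x_b=float(x_b), x_m=float(x_m), deaths=int(deaths),
    )


def _noiseless(b, m, xs):
    return [_row(xb, xm, b * xb + m * xm, f"r{i}") for i, (xb, xm) in enumerate(xs)]


XS = [(2, 0), (0, 1), (1, 1), (3, 0.5), (0, 4), (5, 2)]


class TestFitRates:
    def test_noiseless_rows_recovered_exactly(self, config):
        rows = _noiseless(100, 300, XS)
        est = cm.fit_rates(rows, config)
        assert est.b == pytest.approx(100, abs=1e-9)
        assert est.m == pytest.approx(300, abs=1e-9)
        assert est.converged
        assert np.all(est.weights == 1.0)

    def test_infinite_tuning_constant_equals_ols(self, design, config):
        """At c = inf the M-estimate reduces to the normal-equations solution."""
        cfg = config.replace(huber_c=math.inf)
        est = cm.fit_rates(design, cfg)
        X = np.array([[r.x_b, r.x_m] for r in design])
        y = np.array([r.deaths for r in design], float)
        ols = np.linalg.solve(X.T @ X, X.T @ y)  # independent closed form
        assert est.b == pytest.approx(ols[0], rel=1e-9)
        assert est.m == pytest.approx(ols[1], rel=1e-9)

    def test_matches_independent_robust_fit(self, design, config):
        """Cross-check against statsmodels' Huber RLM with MAD scale."""
        sm = pytest.importorskip("statsmodels.api")
        X = np.array([[r.x_b, r.x_m] for r in design])
        y = np.array([r.deaths for r in design], float)
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=config.huber_c)).fit(
            scale_est="mad"
        )
        est = cm.fit_rates(design, config)
        assert est.b == pytest.approx(ref.params[0], rel=1e-4)
        assert est.m == pytest.approx(ref.params[1], rel=1e-4)

    def test_weighted_normal_equations_hold_at_solution(self, design, rates):
        X = np.array([[r.x_b, r.x_m] for r in design])
        y = np.array([r.deaths for r in design], float)
        resid = y - X @ np.array([rates.b, rates.m])
        grad = X.T @ (rates.weights * resid)
        scale = np.abs(X.T @ (np.abs(resid))).max()
        assert np.abs(grad).max() / scale < 1e-6

    def test_weights_in_unit_interval(self, rates, config):
        assert np.all(rates.weights > 0)
        assert np.all(rates.weights <= 1.0)

    def test_row_order_irrelevant(self, design, config, rates):
        shuffled = design[::-1]
        est = cm.fit_rates(shuffled, config)
        assert est.b == pytest.approx(rates.b, rel=1e-9)
        assert est.m == pytest.approx(rates.m, rel=1e-9)

    def test_joint_scaling_invariance(self, design, config, rates):
        """Scaling deaths and both covariates by the same factor keeps (b, m)."""
        scaled = [
            DesignRow(
                camp_name=r.camp_name,
                person_time=2 * r.person_time,
                monsoon_fraction=r.monsoon_fraction,
                x_b=2 * r.x_b, x_m=2 * r.x_m, deaths=2 * r.deaths,
            )
            for r in design
        ]
        est = cm.fit_rates(scaled, config)
        assert est.b == pytest.approx(rates.b, rel=1e-6)
        assert est.m == pytest.approx(rates.m, rel=1e-6)

    def test_positive_rates_on_bundled_data(self, rates):
        assert rates.b > 0
        assert rates.m > 0
        assert rates.converged

    @pytest.mark.parametrize(
        "xs",
        [
            [(1, 0)],  # too few rows
            [(1, 0), (2, 0), (3, 0)],  # monsoon column empty
            [(1, 1), (2, 2), (3, 3)],  # collinear
        ],
    )
    def test_degenerate_designs_rejected(self, xs, config):
        rows = [_row(xb, xm, 10, f"r{i}") for i, (xb, xm) in enumerate(xs)]
        with pytest.raises(DegenerateDesignError):
            cm.fit_rates(rows, config)

    def test_negative_rate_warns(self, config):
        # deaths decreasing in monsoon exposure force a negative m
        rows = [_row(1, 0, 500), _row(0, 1, 1), _row(1, 1, 400), _row(0, 2, 2)]
        with pytest.warns(UserWarning, match="negative fitted rate"):
            cm.fit_rates(rows, config)

    def test_parameter_recovery_on_resimulated_design(self, records, config):
        """Count resimulation at the bundled design recovers the truth.

        Deaths redrawn at known (b*, m*) should re-estimate without material
        bias, spread tightly around the truth, and the jackknife SE should
        be conservative on average (a 17-point jackknife of a robust fit is
        too variable for per-replicate 3-SE intervals to be exact).
        """
        true_b, true_m = 174.0, 370.0
        rng = np.random.default_rng(20260920)
        design = cm.build_design(records, config)
        n_rep = 200
        bs, ms, se_bs, se_ms = [], [], [], []
        for _ in range(n_rep):
            sim_rows = []
            for r in design:
                lam = true_b * r.x_b + true_m * r.x_m
                deaths = rng.poisson(lam)  # binomial small-p limit
                sim_rows.append(
                    DesignRow(
                        camp_name=r.camp_name, person_time=r.person_time,
                        monsoon_fraction=r.monsoon_fraction,
                        x_b=r.x_b, x_m=r.x_m, deaths=int(deaths),
                    )
                )
            est = cm.fit_rates(sim_rows, config)
            se_b, se_m = cm.jackknife_se_rates(sim_rows, config)
            bs.append(est.b)
            ms.append(est.m)
            se_bs.append(se_b)
            se_ms.append(se_m)
        bs, ms = np.array(bs), np.array(ms)
        sd_b, sd_m = bs.std(), ms.std()
        # unbiased within Monte-Carlo error, and truth inside 3 empirical SDs
        assert abs(bs.mean() - true_b) < 4 * sd_b / math.sqrt(n_rep)
        assert abs(ms.mean() - true_m) < 4 * sd_m / math.sqrt(n_rep)
        assert np.mean(np.abs(bs - true_b) <= 3 * sd_b) >= 0.95
        assert np.mean(np.abs(ms - true_m) <= 3 * sd_m) >= 0.95
        # jackknife SEs conservative in the mean
        assert np.mean(se_bs) >= sd_b
        assert np.mean(se_ms) >= sd_m


class TestCampRate:
    def test_salt_lake_general(self, records):
        rate = cm.camp_rate(records[0])
        assert rate == pytest.approx(3671 / 26.01)
        assert rate == pytest.approx(141.14, abs=5e-3)

    def test_karimpur_cholera(self, records):
        karimpur = records[3]  # 15,000 people, 17 days, 700 deaths
        assert cm.camp_rate(karimpur) == pytest.approx(700 / 0.255, rel=1e-9)
        assert cm.camp_rate(karimpur) == pytest.approx(2745.1, abs=0.05)

    def test_zero_deaths(self, records):
        rec = records[0].replace(deaths=0)
        assert cm.camp_rate(rec) == 0.0
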