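"""Likelihood engine: quadrature oracles, limits, invariances, cross-checks."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import flywaytrend as ft
from flywaytrend.gridding import assign_sites, build_grid
from flywaytrend.models import ModelData, laplace_marginal_loglik, residual_diagnostics
from flywaytrend.survey_io import SurveyTable, center_years, project_coordinates

from _oracles import agh_1d


def _single_site_data(y, t, overdispersion, hierarchical=False, L=50.0):
    return ModelData(
        y=np.asarray(y, float), t=np.asarray(t, float),
        site_idx=np.zeros(len(y), int), site_ids=["A"],
        cell_of_site=np.array([0]) if hierarchical else None,
        cell_ids=["C"] if hierarchical else None,
        L_cell=np.array([L]) if hierarchical else None,
        overdispersion=overdispersion,
    )


class TestMarginalLikelihoodOracle:
    """laplace_marginal_loglik vs brute-force quadrature on tiny designs."""

    def test_one_random_slope(self):
        """Single site, three observations, one random slope."""
        y, t = [22.0, 17.0, 30.0], [-1.0, 0.0, 1.0]
        alpha, mu, ss = 3.0, 0.05, 0.08

        def nli(s):
            eta = alpha + (mu + s) * np.asarray(t)
            return -(np.sum(np.asarray(y) * eta - np.exp(eta) - gammaln(np.asarray(y) + 1))
                     - 0.5 * s ** 2 / ss ** 2 - np.log(ss * np.sqrt(2 * np.pi)))

        oracle = agh_1d(nli, half_width=1.0)
        data = _single_site_data(y, t, overdispersion=False)
        mine = laplace_marginal_loglik(data, {"alpha": [alpha], "mu": mu, "sigma_s": ss})
        assert mine == pytest.approx(oracle, abs=1e-3)

    def test_three_random_effects_with_overdispersion(self):
        """Slope plus two observation-level effects: nested 50-node oracle."""
        y, t = np.array([25.0, 14.0]), np.array([-0.5, 0.5])
        alpha, mu, ss, se = 3.0, 0.05, 0.08, 0.6

        def pln(yk, etak):
            def nlik(e):
                ll = yk * (etak + e) - np.exp(etak + e) - gammaln(yk + 1)
                return -(ll - 0.5 * e ** 2 / se ** 2 - np.log(se * np.sqrt(2 * np.pi)))
            return agh_1d(nlik, half_width=10.0)

        def nlv(v):
            eta = alpha + (mu + v) * t
            return -(sum(pln(y[k], eta[k]) for k in range(2))
                     - 0.5 * v ** 2 / ss ** 2 - np.log(ss * np.sqrt(2 * np.pi)))

        oracle = agh_1d(nlv, half_width=1.0)
        data = _single_site_data(y, t, overdispersion=True)
        mine = laplace_marginal_loglik(
            data, {"alpha": [alpha], "mu": mu, "sigma_s": ss, "sigma_e": se})
        assert mine == pytest.approx(oracle, abs=1e-3)

    def test_hierarchical_cell_and_site_effect(self):
        """One cell, one site: nested u and v integrals."""
        y, t = np.array([22.0, 17.0, 30.0]), np.array([-1.0, 0.0, 1.0])
        alpha, beta0, gamma, L = 3.0, 0.4, -0.008, 50.0
        sb, sd = 0.04, 0.08
        base = beta0 + gamma * L

        def nluv(u):
            def nlv(v):
                eta = alpha + (base + u + v) * t
                return -(np.sum(y * eta - np.exp(eta) - gammaln(y + 1))
                         - 0.5 * v ** 2 / sd ** 2 - np.log(sd * np.sqrt(2 * np.pi)))
            return -(agh_1d(nlv, half_width=1.0)
                     - 0.5 * u ** 2 / sb ** 2 - np.log(sb * np.sqrt(2 * np.pi)))

        oracle = agh_1d(nluv, half_width=1.0)
        data = _single_site_data(y, t, overdispersion=False, hierarchical=True, L=L)
        mine = laplace_marginal_loglik(
            data, {"alpha": [alpha], "beta0": beta0, "gamma": gamma,
                   "sigma_b": sb, "sigma_d": sd})
        assert mine == pytest.approx(oracle, abs=1e-3)

    def test_vanishing_variance_recovers_fixed_poisson(self):
        """As sigma -> 0 the marginal tends to the plain Poisson likelihood."""
        y, t = np.array([22.0, 17.0, 30.0]), np.array([-1.0, 0.0, 1.0])
        alpha, mu = 3.0, 0.05
        eta = alpha + mu * t
        poisson_ll = float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))
        data = _single_site_data(y, t, overdispersion=False)
        mine = laplace_marginal_loglik(
            data, {"alpha": [alpha], "mu": mu, "sigma_s": 1e-7})
        assert mine == pytest.approx(poisson_ll, abs=1e-6)

    def test_invalid_sigma_rejected(self):
        data = _single_site_data([1.0], [0.0], overdispersion=False)
        with pytest.raises(ValueError):
            laplace_marginal_loglik(data, {"alpha": [0.0], "mu": 0.0, "sigma_s": 0.0})


def test_zero_variance_limit_matches_glm():
    """With variances pinned near zero the fit equals a fixed-effects GLM.

    statsmodels Poisson regression with per-site intercepts and a common
    slope is the independent oracle.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    t = np.tile(np.arange(-2.0, 3.0), 4)
    site = np.repeat(np.arange(4), 5)
    alpha_true = np.array([2.0, 2.5, 3.0, 1.5])
    y = rng.poisson(np.exp(alpha_true[site] - 0.06 * t)).astype(float)

    X = np.column_stack([np.eye(4)[site], t])
    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()

    data = ModelData(y=y, t=t, site_idx=site, site_ids=list("abcd"),
                     cell_of_site=None, cell_ids=None, L_cell=None,
                     overdispersion=False)
    mine = laplace_marginal_loglik(
        data, {"alpha": glm.params[:4], "mu": glm.params[4], "sigma_s": 1e-7})
    assert mine == pytest.approx(glm.llf, abs=1e-5)


def _simulate(n_cells, sites_per_cell, seed, truth=None, **kwargs):
    land = ft.generate_landscape(n_cells=n_cells, sites_per_cell=sites_per_cell,
                                 seed=seed)
    truth = truth or ft.truth_params_default()
    sim = ft.generate_counts(land, truth, seed=seed + 1000, **kwargs)
    sim.table = project_coordinates(sim.table)
    grid = build_grid(sim.table)
    return sim, assign_sites(sim.table, grid)


class TestFitBehaviour:
    def test_record_order_invariance(self):
        """Shuffling record order leaves the fitted parameters unchanged."""
        sim, asg = _simulate(10, 2, seed=21)
        fit1 = ft.fit_hierarchical(sim.table, asg, compute_cov=False)
        shuffled = sim.table.records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        table2 = SurveyTable(records=shuffled, sites=sim.table.sites,
                             center=sim.table.center, crs=sim.table.crs)
        fit2 = ft.fit_hierarchical(table2, asg, compute_cov=False)
        for k in fit1.params:
            assert fit1.params[k] == pytest.approx(fit2.params[k], abs=1e-5)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-5)

    def test_latitude_shift_reparameterization(self):
        """Shifting all latitudes by +c moves beta0 by -gamma*c only."""
        sim, asg = _simulate(15, 2, seed=31)
        fit1 = ft.fit_hierarchical(sim.table, asg, compute_cov=False)
        shifted = ft.CellAssignment(
            site_cells=asg.site_cells,
            cells=asg.cells.assign(lat=asg.cells["lat"] + 5.0),
        )
        fit2 = ft.fit_hierarchical(sim.table, shifted, compute_cov=False)
        assert fit2.params["gamma"] == pytest.approx(fit1.params["gamma"], abs=1e-4)
        assert fit2.params["beta0"] == pytest.approx(
            fit1.params["beta0"] - 5.0 * fit1.params["gamma"], abs=1e-3)
        for k in ("sigma_b", "sigma_d", "sigma_e"):
            assert fit2.params[k] == pytest.approx(fit1.params[k], rel=0.02, abs=1e-4)
        # fitted cell trends are unchanged
        np.testing.assert_allclose(
            fit1.params["beta0"] + fit1.b.to_numpy(),
            fit2.params["beta0"] + fit2.b.to_numpy(), atol=1e-3)

    def test_site_slope_shrinkage(self, small_sim, small_assignment, hier_fit):
        """Predicted site deviations are shrunk relative to per-site OLS."""
        rec = small_sim.table.records
        logy = np.log(rec["count"] + 0.5)
        ols = {}
        for sid, grp in rec.groupby("site_id"):
            tt = grp["t"].to_numpy()
            yy = np.log(grp["count"].to_numpy() + 0.5)
            ols[sid] = np.polyfit(tt, yy, 1)[0]
        ols = pd.Series(ols)
        raw_dev = ols - ols.mean()
        assert hier_fit.v.abs().mean() < raw_dev.abs().mean()
        assert hier_fit.v.std() < raw_dev.std()

    def test_cell_effect_centering(self, hier_fit):
        """Stationarity centers the latitude-detrended cell effects near 0."""
        u = hier_fit.u.to_numpy()
        assert abs(u.sum()) < 0.10 * np.abs(u).sum() + 1e-9

    def test_prediction_interfaces(self, hier_fit):
        b, d, e, b_se, d_se = ft.predict_random_effects(hier_fit)
        assert len(b) == hier_fit.assignment.n_cells
        assert len(d) == len(hier_fit.alpha)
        assert (b_se > 0).all() and (d_se > 0).all()
        # d decomposes as cell effect plus site deviation
        cmap = hier_fit.assignment.cell_of_site()
        np.testing.assert_allclose(
            d.to_numpy(),
            b[cmap[d.index]].to_numpy() + hier_fit.v.to_numpy(), atol=1e-10)

    def test_preliminary_recovers_mean_slope(self, small_sim, prelim_fit):
        """The preliminary mean slope matches the generative site-slope mean."""
        truth = small_sim.truth
        lat = small_sim.landscape.sites["lat"].to_numpy()
        expected = truth.beta0 + truth.gamma * lat.mean()
        z = (prelim_fit.params["mu"] - expected) / prelim_fit.se["mu"]
        assert abs(z) < 3.0

    def test_preliminary_requires_repeat_visits(self):
        table = SurveyTable(
            records=pd.DataFrame({"site_id": ["A", "B"], "year": [2007, 2007],
                                  "count": [1, 2]}),
            sites=pd.DataFrame({"site_id": ["A", "B"], "lon": [4.0, 5.0],
                                "lat": [52.0, 52.0]}),
        )
        with pytest.raises(ValueError, match=">= 2"):
            ft.fit_preliminary(center_years(table))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_hierarchical_matches_glmmtmb(tmp_path):
    """Independent cross-check: glmmTMB fits the same model on shared data.

    Fixed slopes and the structured variance components must agree closely;
    sigma_e may differ slightly because the reference uses a Laplace step
    for the observation-level effect where this package integrates it by
    quadrature.  The truth makes every variance component well identified
    so neither optimizer sits on a flat boundary region.
    """
    truth = ft.TruthParams(beta0=0.38, gamma=-0.008, sigma_b=0.08,
                           sigma_d=0.06, sigma_e=0.8)
    sim, asg = _simulate(50, 4, seed=11, truth=truth)
    fit = ft.fit_hierarchical(sim.table, asg, reml=False, compute_cov=False)

    cmap = asg.cell_of_site()
    lat = asg.cells.set_index("cell_id")["lat"]
    rec = sim.table.records.copy()
    rec["cell"] = rec["site_id"].map(cmap)
    rec["L"] = rec["cell"].map(lat)
    rec.to_csv(tmp_path / "d.csv", index=False)
    script = textwrap.dedent("""
        suppressMessages(library(glmmTMB))
        d <- read.csv("d.csv")
        d$site <- factor(d$site_id); d$cell <- factor(d$cell)
        d$obs <- factor(seq_len(nrow(d))); d$tL <- d$t * d$L
        m <- glmmTMB(count ~ 0 + site + t + tL + (0+t|cell) + (0+t|site) + (1|obs),
                     family=poisson, data=d, REML=FALSE)
        fe <- fixef(m)$cond; vc <- VarCorr(m)$cond
        cat(sprintf("%.6f %.6f %.6f %.6f %.6f\\n", fe["t"], fe["tL"],
            sqrt(vc$cell[1]), sqrt(vc$site[1]), sqrt(vc$obs[1])))
    """)
    (tmp_path / "m.R").write_text(script)
    out = subprocess.run(["Rscript", "m.R"], cwd=tmp_path,
                         capture_output=True, text=True, timeout=500)
    assert out.returncode == 0, out.stderr
    beta0, gamma, sb, sd, se = map(float, out.stdout.split()[-5:])
    assert fit.params["beta0"] == pytest.approx(beta0, abs=0.02)
    assert fit.params["gamma"] == pytest.approx(gamma, abs=5e-4)
    assert fit.params["sigma_b"] == pytest.approx(sb, abs=0.01)
    assert fit.params["sigma_d"] == pytest.approx(sd, abs=0.01)
    assert fit.params["sigma_e"] == pytest.approx(se, abs=0.03)


class TestResidualDiagnostics:
    def test_well_specified_model_is_clean(self, hier_fit, small_sim):
        diag = residual_diagnostics(hier_fit, small_sim.table)
        assert diag["normality"]["site"]["p_value"] > 0.05
        assert diag["normality"]["cell"]["p_value"] > 0.05
        assert diag["per_year"] is not None
        assert len(diag["per_year"]) == 11

    def test_quadratic_trend_is_flagged(self):
        """A quadratic true trend leaves a U-pattern in per-year residuals."""
        land = ft.generate_landscape(n_cells=20, sites_per_cell=3, seed=55)
        rng = np.random.default_rng(56)
        years = np.arange(2002, 2013)
        t = years - 2007.0
        alpha = 3.0 + 0.8 * rng.standard_normal(len(land.sites))
        rows = []
        for i, sid in enumerate(land.sites["site_id"]):
            log_lam = alpha[i] - 0.04 * t + 0.035 * t ** 2 \
                + 0.4 * rng.standard_normal(len(t))
            counts = rng.poisson(np.exp(log_lam))
            rows += [(sid, y, c) for y, c in zip(years, counts)]
        table = SurveyTable(
            records=pd.DataFrame(rows, columns=["site_id", "year", "count"]),
            sites=land.sites[["site_id", "lon", "lat"]].copy(),
        )
        table = project_coordinates(center_years(table))
        asg = assign_sites(table, build_grid(table))
        fit = ft.fit_hierarchical(table, asg)
        diag = residual_diagnostics(fit, table)
        assert diag["year_pattern_flag"]
        means = diag["per_year"]["mean"]
        assert means.iloc[0] > means.iloc[5] and means.iloc[-1] > means.iloc[5]

    def test_low_overdispersion_truth(self):
        """Near-zero true sigma_e yields a small estimate and tiny residuals."""
        truth = ft.TruthParams(beta0=0.0, gamma=0.0, sigma_b=0.02,
                               sigma_d=0.05, sigma_e=0.01,
                               alpha_mean=3.0, alpha_sd=1.0)
        sim, asg = _simulate(15, 3, seed=77, truth=truth)
        fit = ft.fit_hierarchical(sim.table, asg, compute_cov=False)
        assert fit.params["sigma_e"] < 0.05
        assert np.abs(fit.e_resid).mean() < 0.05
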