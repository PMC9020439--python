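"""Poisson trend models fitted by Laplace-approximated maximum likelihood.

Two model kinds share one engine:

* **preliminary** — the diagnostic fit run before any gridding:
  ``log lambda_it = alpha_i + (mu + s_i) t + e_it`` with a free intercept
  per site, a Gaussian random site slope ``s_i ~ N(0, sigma_s)`` and an
  observation-level Gaussian residual ``e_it ~ N(0, sigma_e)`` absorbing
  extra-Poisson dispersion (Poisson-lognormal counts).

* **hierarchical** — the main model with grid-cell structure:
  ``log lambda_it = alpha_i + (beta0 + d_i) t + e_it`` where the site slope
  decomposes over cells, ``d_i = gamma L_q(i) + u_q(i) + v_i`` with
  ``u_q ~ N(0, sigma_b)`` and ``v_i ~ N(0, sigma_d)`` — algebraically
  identical to drawing ``d_i ~ N(b_q, sigma_d)``, ``b_q ~ N(gamma L_q,
  sigma_b)``, but better conditioned for optimization.  Latitude is left
  uncentered in the reported parameterization; the year covariate ``t``
  must be centered upstream.

Estimation maximizes an approximate marginal likelihood over the fixed
slope parameters and the log-scale variance parameters:

* the observation-level effect is integrated out **exactly** (to quadrature
  precision) — conditional on the structured effects the e_it integrals
  factorize per observation, so each one is a one-dimensional
  Poisson-lognormal integral evaluated by adaptive Gauss-Hermite
  quadrature, vectorized over all observations.  A plain Laplace step here
  is known to bias sigma_e downward; the quadrature removes that bias.
* the cell and site slope effects (u, v) are integrated by the Laplace
  approximation: a damped Newton mode search on the sparse penalized
  profile log-likelihood — jointly over the unpenalized site intercepts,
  which are profiled — plus the half log-determinant of the random-effect
  block of the curvature.

Standard errors come from a finite-difference observed information of the
profile objective; the optimizer works internally with latitude centered
at the occupied-cell mean and maps back afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import gammaln, logsumexp
from scipy.stats import normaltest, kurtosis, skew

from .gridding import CellAssignment
from .survey_io import SurveyTable

logger = logging.getLogger(__name__)

_ETA_MAX = 30.0          # cap on the linear predictor, lambda <= ~1e13
_ALPHA_RIDGE = 1e-8      # negligible ridge keeping intercepts of all-zero sites finite

# Gauss-Hermite rule for the observation-level integrals; 20 adaptive nodes
# put the Poisson-lognormal pmf at ~1e-9 relative accuracy.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(20)
_GH_LOGW = np.log(_GH_WEIGHTS) + _GH_NODES ** 2


class ConvergenceError(RuntimeError):
    """Raised when the inner or outer optimization fails to converge."""


# ---------------------------------------------------------------------------
# model arrays
# ---------------------------------------------------------------------------

@dataclass
class ModelData:
    """Dense/sparse arrays the likelihood engine works on."""

    y: np.ndarray                    # (N,) counts
    t: np.ndarray                    # (N,) centered years
    site_idx: np.ndarray             # (N,) 0..S-1
    site_ids: list
    cell_of_site: np.ndarray | None  # (S,) 0..Q-1, hierarchical only
    cell_ids: list | None
    L_cell: np.ndarray | None        # (Q,) centroid latitudes
    overdispersion: bool = True

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_cells(self) -> int:
        return 0 if self.cell_ids is None else len(self.cell_ids)

    @property
    def hierarchical(self) -> bool:
        return self.cell_of_site is not None


def build_model_data(table: SurveyTable, assignment: CellAssignment | None = None,
                     overdispersion: bool = True) -> ModelData:
    """Assemble model arrays from a centered survey table.

    With an ``assignment`` the data describe the hierarchical model; without
    it, the preliminary site-slope model.
    """
    if "t" not in table.records.columns:
        raise ValueError("year covariate not centered; run center_years first")
    rec = table.records
    site_ids = sorted(rec["site_id"].unique())
    site_pos = {s: k for k, s in enumerate(site_ids)}
    site_idx = rec["site_id"].map(site_pos).to_numpy()

    cell_of_site = cell_ids = L_cell = None
    if assignment is not None:
        cmap = assignment.cell_of_site()
        missing = [s for s in site_ids if s not in cmap.index]
        if missing:
            raise ValueError(f"sites without cell assignment: {missing[:10]}")
        cell_ids = sorted(assignment.cells["cell_id"])
        cell_pos = {c: k for k, c in enumerate(cell_ids)}
        cell_of_site = np.array([cell_pos[cmap[s]] for s in site_ids])
        lat = assignment.cells.set_index("cell_id")["lat"]
        L_cell = np.array([lat[c] for c in cell_ids], dtype=float)

    return ModelData(
        y=rec["count"].to_numpy(dtype=float),
        t=rec["t"].to_numpy(dtype=float),
        site_idx=site_idx,
        site_ids=site_ids,
        cell_of_site=cell_of_site,
        cell_ids=cell_ids,
        L_cell=L_cell,
        overdispersion=overdispersion,
    )


# ---------------------------------------------------------------------------
# per-observation log-likelihood terms
# ---------------------------------------------------------------------------

def _pln_terms(eta: np.ndarray, y: np.ndarray, sigma_e: float):
    """Poisson-lognormal log-pmf and its first two eta-derivatives.

    For each observation, ``l(eta) = log Integral Poisson(y | exp(eta+e))
    N(e; 0, sigma_e^2) de`` by adaptive Gauss-Hermite quadrature centered at
    the conditional mode of e (a strictly concave one-dimensional problem
    solved by vectorized Newton).  Also returns the conditional modes, which
    double as overdispersion residuals.
    """
    prec = 1.0 / sigma_e ** 2
    # conditional mode of e given eta: y - exp(eta+e) - e/sigma^2 = 0
    ehat = np.where(y > 0, np.log(y + 0.5) - eta, 0.0)
    ehat = np.clip(ehat, -10 * sigma_e, None)
    for _ in range(30):
        lam = np.exp(np.clip(eta + ehat, -_ETA_MAX, _ETA_MAX))
        g = y - lam - ehat * prec
        step = g / (lam + prec)
        ehat = ehat + np.clip(step, -3.0, 3.0)
        if np.max(np.abs(g) / (1.0 + y)) < 1e-11:
            break
    lam_hat = np.exp(np.clip(eta + ehat, -_ETA_MAX, _ETA_MAX))
    s_hat = 1.0 / np.sqrt(lam_hat + prec)          # conditional SD scale

    # nodes e_jk = ehat_k + sqrt(2) s_k z_j
    nodes = ehat[None, :] + np.sqrt(2.0) * s_hat[None, :] * _GH_NODES[:, None]
    eta_n = np.clip(eta[None, :] + nodes, -_ETA_MAX, _ETA_MAX)
    lam_n = np.exp(eta_n)
    log_integrand = (
        y[None, :] * eta_n - lam_n
        - 0.5 * nodes ** 2 * prec
    )
    logmix = _GH_LOGW[:, None] + log_integrand
    lmax = logmix.max(axis=0)
    wpost = np.exp(logmix - lmax)
    norm = wpost.sum(axis=0)
    ll = (
        lmax + np.log(norm) + np.log(np.sqrt(2.0) * s_hat)
        - 0.5 * np.log(2 * np.pi) - np.log(sigma_e)
        - gammaln(y + 1)
    )
    p = wpost / norm
    mean_lam = (p * lam_n).sum(axis=0)
    d1 = y - mean_lam
    mean_sq = (p * ((y[None, :] - lam_n) ** 2 - lam_n)).sum(axis=0)
    d2 = mean_sq - d1 ** 2
    return ll, d1, d2, ehat


def _poisson_terms(eta: np.ndarray, y: np.ndarray):
    """Plain Poisson log-pmf and derivatives (no overdispersion)."""
    lam = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    ll = y * eta - lam - gammaln(y + 1)
    return ll, y - lam, -lam, np.zeros_like(eta)


def _obs_terms(eta, y, sigma_e):
    if sigma_e is None:
        return _poisson_terms(eta, y)
    return _pln_terms(eta, y, sigma_e)


# ---------------------------------------------------------------------------
# inner problem: penalized profile log-likelihood over structured effects
# ---------------------------------------------------------------------------

def _design(data: ModelData, include_alpha: bool) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse design for the structured effects and the block sizes.

    Columns: [alpha (S)] + [u (Q)] + [v (S)], with alpha omitted when the
    intercepts are held fixed.
    """
    N, S, Q = data.n_obs, data.n_sites, data.n_cells
    rows, cols, vals = [], [], []
    off = 0
    if include_alpha:
        rows.append(np.arange(N)); cols.append(data.site_idx); vals.append(np.ones(N))
        off = S
    if data.hierarchical:
        rows.append(np.arange(N))
        cols.append(off + data.cell_of_site[data.site_idx])
        vals.append(data.t)
        off += Q
    rows.append(np.arange(N)); cols.append(off + data.site_idx); vals.append(data.t)
    m = off + S
    X = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, m),
    )
    return X, np.array([S if include_alpha else 0, Q, S])


def _penalties(data: ModelData, sigmas: dict, include_alpha: bool) -> np.ndarray:
    """Per-column prior precisions for the structured effect vector."""
    parts = []
    if include_alpha:
        parts.append(np.full(data.n_sites, _ALPHA_RIDGE))
    if data.hierarchical:
        parts.append(np.full(data.n_cells, 1.0 / sigmas["sigma_b"] ** 2))
    key = "sigma_d" if data.hierarchical else "sigma_s"
    parts.append(np.full(data.n_sites, 1.0 / sigmas[key] ** 2))
    return np.concatenate(parts)


def _inner_newton(X: sp.csr_matrix, pen: np.ndarray, offset: np.ndarray,
                  y: np.ndarray, sigma_e: float | None, a0=None,
                  tol: float = 1e-12, max_iter: int = 100):
    """Damped Newton minimization of

        F(a) = -sum_k l_k(offset_k + (X a)_k) + 0.5 a' diag(pen) a

    where l_k is the per-observation (Poisson or Poisson-lognormal)
    log-likelihood.  Returns (a, weights, F, grad_norm, e_modes) with
    ``weights = -l''`` at the optimum for the curvature matrix.
    """
    N, m = X.shape
    a = np.zeros(m) if a0 is None else a0.copy()

    def evaluate(a):
        eta = offset + X @ a
        ll, d1, d2, ehat = _obs_terms(eta, y, sigma_e)
        F = float(-ll.sum() + 0.5 * (pen * a * a).sum())
        return F, d1, d2, ehat

    F, d1, d2, ehat = evaluate(a)
    scale = max(1.0, float(y.sum()))
    gtol = max(1e-9, tol * scale)
    grad_norm = np.inf
    for _ in range(max_iter):
        grad = -(X.T @ d1) + pen * a
        grad_norm = float(np.abs(grad).max())
        if grad_norm < gtol:
            break
        w = np.maximum(-d2, 1e-10)
        H = (X.T @ X.multiply(w[:, None]) + sp.diags(pen)).tocsc()
        try:
            da = splu(H).solve(-grad)
        except RuntimeError as err:  # singular factor
            raise ConvergenceError(f"inner Newton: singular system ({err})") from err
        dirderiv = float(grad @ da)
        # Armijo with an absolute slack at the quadrature precision of the
        # objective, so steps toward the gradient fixed point are not
        # rejected once F-differences fall below that precision
        slack = 1e-10 * (1.0 + abs(F))
        step = 1.0
        for _ in range(40):
            Fa, d1a, d2a, ehata = evaluate(a + step * da)
            if Fa <= F + 1e-4 * step * dirderiv + slack:
                break
            step *= 0.5
        else:
            break  # no decrease possible along the Newton direction
        a = a + step * da
        F, d1, d2, ehat = Fa, d1a, d2a, ehata
        if step * np.abs(da).max() < 1e-10:
            # recompute the gradient once more, then stop: the step has
            # collapsed to the gradient fixed point
            grad = -(X.T @ d1) + pen * a
            grad_norm = float(np.abs(grad).max())
            break
    # accept stalls only within the numerical noise floor of the data scale;
    # anything larger means this start diverged (callers retry cold)
    if not np.isfinite(F) or grad_norm > max(1e-2, 1e-7 * scale):
        raise ConvergenceError(f"inner Newton did not converge (grad {grad_norm:.2e})")
    return a, np.maximum(-d2, 1e-10), F, grad_norm, ehat


def _logdet_random_block(X: sp.csr_matrix, pen: np.ndarray, n_alpha: int,
                         w: np.ndarray) -> float:
    """log-determinant of the (u, v) block of the curvature at the mode."""
    Xr = X[:, n_alpha:]
    pen_r = pen[n_alpha:]
    Hr = (Xr.T @ Xr.multiply(w[:, None]) + sp.diags(pen_r)).tocsc()
    lu = splu(Hr)
    return float(np.log(np.abs(lu.U.diagonal())).sum())


def _prior_constant(data: ModelData, sigmas: dict) -> float:
    """Gaussian normalizers of the structured random-effect priors."""
    c = 0.0
    if data.hierarchical:
        c += data.n_cells * (np.log(sigmas["sigma_b"]) + 0.5 * np.log(2 * np.pi))
    key = "sigma_d" if data.hierarchical else "sigma_s"
    c += data.n_sites * (np.log(sigmas[key]) + 0.5 * np.log(2 * np.pi))
    return c


def _n_random(data: ModelData) -> int:
    """Number of random effects handled by the Laplace step (u and v)."""
    return data.n_sites + (data.n_cells if data.hierarchical else 0)


def _fixed_offset(data: ModelData, params: dict) -> np.ndarray:
    """Per-observation contribution of the fixed slope structure."""
    if data.hierarchical:
        base = params["beta0"] + params["gamma"] * data.L_cell[data.cell_of_site]
        return base[data.site_idx] * data.t
    return params["mu"] * data.t


def _needed_sigmas(data: ModelData) -> tuple[str, ...]:
    keys = ("sigma_b", "sigma_d") if data.hierarchical else ("sigma_s",)
    return keys + (("sigma_e",) if data.overdispersion else ())


def laplace_marginal_loglik(data: ModelData, params: dict) -> float:
    """Approximate log marginal likelihood at fixed parameters.

    ``params`` holds the fixed parameters — site intercepts ``alpha`` (array
    over sites in ``data.site_ids`` order) and ``beta0``/``gamma`` (or
    ``mu``) — plus the variance parameters on the natural scale.  The
    observation-level effect is integrated per observation by adaptive
    Gauss-Hermite quadrature; the slope effects (u, v) by Laplace (inner
    Newton mode plus half-log-determinant).  Deterministic given its inputs.
    """
    for k in _needed_sigmas(data):
        if params[k] <= 0:
            raise ValueError(f"{k} must be > 0")
    alpha = np.asarray(params["alpha"], dtype=float)
    offset = alpha[data.site_idx] + _fixed_offset(data, params)
    X, _ = _design(data, include_alpha=False)
    pen = _penalties(data, params, include_alpha=False)
    sigma_e = params["sigma_e"] if data.overdispersion else None
    a, w, F, _, _ = _inner_newton(X, pen, offset, data.y, sigma_e)
    F += _prior_constant(data, params)
    logdet = _logdet_random_block(X, pen, 0, w)
    return -F + 0.5 * _n_random(data) * np.log(2 * np.pi) - 0.5 * logdet


# ---------------------------------------------------------------------------
# outer problem: profile likelihood over (slope params, log sigmas)
# ---------------------------------------------------------------------------

class _Engine:
    """Profile objective with warm-started inner solves.

    The optimizer works in an internal parameterization with latitude
    centered at the occupied-cell mean, which removes the near-collinearity
    of the global slope and the latitude effect; estimates and covariance
    are mapped back to the raw-latitude parameterization afterwards
    (``beta0 = beta0_centered - gamma * Lbar``).
    """

    def __init__(self, data: ModelData, reml: bool = True):
        self.data = data
        self.X, self.blocks = _design(data, include_alpha=True)
        self.reml = reml
        self._warm = None
        if data.hierarchical:
            self.Lbar = float(np.mean(data.L_cell))
            self.theta_names = ["beta0", "gamma"] + [f"log_{k}" for k in _needed_sigmas(data)]
        else:
            self.Lbar = 0.0
            self.theta_names = ["mu"] + [f"log_{k}" for k in _needed_sigmas(data)]

    def unpack(self, theta: np.ndarray) -> dict:
        """Natural-scale parameters from an internal theta vector."""
        d = {}
        for name, val in zip(self.theta_names, theta):
            if name.startswith("log_"):
                d[name[4:]] = float(np.exp(val))
            else:
                d[name] = float(val)
        if self.data.hierarchical:
            d["beta0"] = d["beta0"] - d["gamma"] * self.Lbar
        return d

    def to_natural_theta(self, theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        if self.data.hierarchical:
            out[0] = theta[0] - theta[1] * self.Lbar
        return out

    def natural_cov(self, cov_internal: np.ndarray) -> np.ndarray:
        """Map the internal-theta covariance to the raw parameterization."""
        J = np.eye(len(self.theta_names))
        if self.data.hierarchical:
            J[0, 1] = -self.Lbar
        return J @ cov_internal @ J.T

    def profile_negloglik(self, theta: np.ndarray, want_state=False):
        data = self.data
        params = self.unpack(theta)
        offset = _fixed_offset(data, params)
        pen = _penalties(data, params, include_alpha=True)
        sigma_e = params["sigma_e"] if data.overdispersion else None
        a0 = self._warm
        try:
            a, w, F, _, ehat = _inner_newton(self.X, pen, offset, data.y, sigma_e, a0)
        except ConvergenceError:
            if a0 is None:
                raise
            a, w, F, _, ehat = _inner_newton(self.X, pen, offset, data.y, sigma_e)
        self._warm = a
        F += _prior_constant(data, params)
        # REML-style criterion: the unpenalized site intercepts are
        # integrated under a flat prior (their block enters the
        # log-determinant), removing the incidental-parameter bias that
        # plain profile ML inflicts on the variance parameters when each of
        # hundreds of intercepts is informed by only ~10 observations.
        n_alpha = 0 if self.reml else self.blocks[0]
        n_int = _n_random(data) + (self.blocks[0] if self.reml else 0)
        logdet = _logdet_random_block(self.X, pen, n_alpha, w)
        nll = F - 0.5 * n_int * np.log(2 * np.pi) + 0.5 * logdet
        if want_state:
            return nll, (a, w, pen, ehat)
        return nll

    def initial_theta(self) -> np.ndarray:
        """Per-site OLS slopes of log counts seed the fixed parameters."""
        data = self.data
        logy = np.log(data.y + 0.5)
        S = data.n_sites
        sums = np.zeros((S, 5))
        np.add.at(sums, data.site_idx,
                  np.column_stack([np.ones_like(logy), data.t, data.t ** 2,
                                   logy, data.t * logy]))
        n, st, stt, sy, sty = sums.T
        denom = n * stt - st * st
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(denom > 0, (n * sty - st * sy) / np.where(denom > 0, denom, 1.0), 0.0)
        if data.hierarchical:
            L = data.L_cell[data.cell_of_site] - self.Lbar
            A = np.column_stack([np.ones(S), L])
            coef, *_ = np.linalg.lstsq(A, slope, rcond=None)
            head = [coef[0], coef[1]]
        else:
            head = [float(np.mean(slope))]
        tail = []
        for k in _needed_sigmas(data):
            tail.append(np.log(1.0 if k == "sigma_e" else 0.1))
        return np.array(head + tail)


def _fd_hessian(fun, x: np.ndarray, h: float = 2e-3) -> np.ndarray:
    """Central finite-difference Hessian (symmetrized)."""
    p = len(x)
    H = np.zeros((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h
        fpp = fun(x + 2 * ei); fmm = fun(x - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h * h)
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h * h)
    return H


@dataclass
class FitResult:
    """Maximum-likelihood fit of a Poisson trend model."""

    kind: str                         # "preliminary" | "hierarchical"
    params: dict                      # natural-scale point estimates
    se: dict                          # delta-method SEs on the natural scale
    theta: np.ndarray                 # natural parameter vector
    theta_names: list
    cov_theta: np.ndarray             # covariance of theta (log-scale sigmas)
    loglik: float
    converged: bool
    grad_norm: float
    n_obs: int
    alpha: pd.Series                  # site intercepts
    site_slopes: pd.Series            # total fitted slope per site
    e_resid: np.ndarray | None = None  # overdispersion residual modes
    data: ModelData | None = field(repr=False, default=None)
    # hierarchical extras
    b: pd.Series | None = None        # cell slope effect b_q = gamma L_q + u_q
    d: pd.Series | None = None        # site slope deviation d_i = b_q + v_i
    u: pd.Series | None = None        # latitude-detrended cell effect
    v: pd.Series | None = None        # within-cell site deviation
    b_se: pd.Series | None = None
    d_se: pd.Series | None = None
    s: pd.Series | None = None        # preliminary site slope effect
    assignment: CellAssignment | None = field(repr=False, default=None)

    def cov_fixed(self) -> np.ndarray:
        """Covariance of (beta0, gamma) for delta-method summaries."""
        if self.kind != "hierarchical":
            raise ValueError("fixed-parameter covariance is a hierarchical-fit quantity")
        return self.cov_theta[:2, :2]


def _fit(data: ModelData, assignment=None, compute_cov=True, reml=True,
         gtol: float = 1e-4, maxiter: int = 300) -> FitResult:
    eng = _Engine(data, reml=reml)
    theta0 = eng.initial_theta()
    nsig = len(_needed_sigmas(data))
    bounds = [(None, None)] * (len(theta0) - nsig) + [(-6.0, 3.0)] * nsig
    res = minimize(
        eng.profile_negloglik, theta0, method="L-BFGS-B", jac="3-point",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol, "eps": 1e-5},
    )
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 10 * gtol)
    if not converged:
        logger.warning("outer optimizer: %s (grad %.3g after %d iterations)",
                       res.message, grad_norm, res.nit)

    nll, (a, w, pen, ehat) = eng.profile_negloglik(theta, want_state=True)
    params = eng.unpack(theta)

    if compute_cov:
        H = _fd_hessian(eng.profile_negloglik, theta)
        # guard against tiny negative eigenvalues from FD noise
        ew, V = np.linalg.eigh(H)
        ew = np.maximum(ew, 1e-8)
        cov = eng.natural_cov((V / ew) @ V.T)
    else:
        cov = np.full((len(theta), len(theta)), np.nan)
    theta = eng.to_natural_theta(theta)

    se = {}
    for k, name in enumerate(eng.theta_names):
        s_ = float(np.sqrt(cov[k, k]))
        if name.startswith("log_"):
            nat = name[4:]
            se[nat] = s_ * params[nat]  # delta method for sigma = exp(log sigma)
        else:
            se[name] = s_

    S, Q, N = data.n_sites, data.n_cells, data.n_obs
    alpha_hat = a[:S]
    site_ids = data.site_ids
    if data.hierarchical:
        u_hat = a[S:S + Q]
        v_hat = a[S + Q:]
        b_hat = params["gamma"] * data.L_cell + u_hat
        d_hat = b_hat[data.cell_of_site] + v_hat
        slope = params["beta0"] + d_hat
    else:
        v_hat = a[S:]
        slope = params["mu"] + v_hat

    # conditional prediction covariance of the structured effects
    b_se = d_se = None
    m = eng.X.shape[1]
    if compute_cov and data.hierarchical and m <= 6000:
        Hs = (eng.X.T @ eng.X.multiply(w[:, None]) + sp.diags(pen)).toarray()
        C = np.linalg.inv(Hs)
        var_u = np.diag(C)[S:S + Q]
        var_v = np.diag(C)[S + Q:]
        cov_uv = C[S + Q:, S:S + Q][np.arange(S), data.cell_of_site]
        b_se = pd.Series(np.sqrt(np.maximum(var_u, 0)), index=data.cell_ids, name="b_se")
        d_se = pd.Series(np.sqrt(np.maximum(var_u[data.cell_of_site] + var_v + 2 * cov_uv, 0)),
                         index=site_ids, name="d_se")

    kwargs = {}
    if data.hierarchical:
        kwargs.update(
            b=pd.Series(b_hat, index=data.cell_ids, name="b"),
            d=pd.Series(d_hat, index=site_ids, name="d"),
            u=pd.Series(u_hat, index=data.cell_ids, name="u"),
            v=pd.Series(v_hat, index=site_ids, name="v"),
            b_se=b_se, d_se=d_se, assignment=assignment,
        )
    else:
        kwargs.update(s=pd.Series(v_hat, index=site_ids, name="s"))

    return FitResult(
        kind="hierarchical" if data.hierarchical else "preliminary",
        params=params, se=se, theta=theta, theta_names=eng.theta_names,
        cov_theta=cov, loglik=-nll, converged=converged, grad_norm=grad_norm,
        n_obs=N,
        alpha=pd.Series(alpha_hat, index=site_ids, name="alpha"),
        site_slopes=pd.Series(slope, index=site_ids, name="slope"),
        e_resid=ehat if data.overdispersion else None,
        data=data, **kwargs,
    )


def fit_preliminary(table: SurveyTable, overdispersion: bool = True,
                    compute_cov: bool = True, reml: bool = True) -> FitResult:
    """Fit the preliminary site-slope model (no gridding).

    Requires at least two sites, each surveyed in at least two years.
    ``reml`` integrates the site intercepts under a flat prior when
    estimating the variance parameters (recommended; see module notes).
    """
    ny = table.site_years()
    if len(ny) < 2 or (ny < 2).any():
        raise ValueError("preliminary model needs >= 2 sites with >= 2 surveyed years each")
    data = build_model_data(table, None, overdispersion=overdispersion)
    return _fit(data, compute_cov=compute_cov, reml=reml)


def fit_hierarchical(table: SurveyTable, assignment: CellAssignment,
                     overdispersion: bool = True, compute_cov: bool = True,
                     reml: bool = True) -> FitResult:
    """Fit the grid-cell hierarchical trend model."""
    data = build_model_data(table, assignment, overdispersion=overdispersion)
    return _fit(data, assignment=assignment, compute_cov=compute_cov, reml=reml)


def predict_random_effects(fit: FitResult):
    """Posterior-mode random effects of a converged hierarchical fit.

    Returns (b, d, e_resid, b_se, d_se): cell slope effects b_q, site slope
    deviations d_i, observation-level residual modes, and the conditional
    prediction SEs (None if they were not computed).
    """
    if fit.kind != "hierarchical":
        raise ValueError("random-effect prediction is for hierarchical fits")
    if not fit.converged:
        raise ConvergenceError("fit did not converge; predictions unreliable")
    return fit.b, fit.d, fit.e_resid, fit.b_se, fit.d_se


def residual_diagnostics(fit: FitResult, table: SurveyTable) -> dict:
    """Normality checks of the slope random effects and a trend-vs-year probe.

    Returns a dict with per-level normality summaries (skewness, excess
    kurtosis, D'Agostino-Pearson p) for the standardized b and d
    predictions, plus per-year means of the observation-level residuals
    with a flag when any year mean exceeds two standard errors.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    out = {"normality": {}, "per_year": None, "year_pattern_flag": False}

    def _norm_summary(values: np.ndarray) -> dict:
        z = (values - values.mean()) / values.std(ddof=1)
        stat_p = float(normaltest(z).pvalue) if len(z) >= 8 else float("nan")
        return {"skewness": float(skew(z)), "kurtosis": float(kurtosis(z)),
                "p_value": stat_p, "n": int(len(z))}

    if fit.kind == "hierarchical":
        b_dev = fit.u.to_numpy()
        d_dev = fit.v.to_numpy()
        if fit.b_se is not None:
            b_dev = b_dev / np.where(fit.b_se.to_numpy() > 0, fit.b_se.to_numpy(), 1.0)
        if fit.d_se is not None:
            d_dev = d_dev / np.where(fit.d_se.to_numpy() > 0, fit.d_se.to_numpy(), 1.0)
        out["normality"]["cell"] = _norm_summary(b_dev)
        out["normality"]["site"] = _norm_summary(d_dev)
    else:
        out["normality"]["site"] = _norm_summary(fit.s.to_numpy())

    rec = table.records
    if fit.e_resid is not None and fit.data is not None \
            and fit.data.overdispersion and len(fit.e_resid) == len(rec):
        df = pd.DataFrame({"year": rec["year"].to_numpy(), "e": fit.e_resid})
        g = df.groupby("year")["e"]
        per_year = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
        per_year["se"] = per_year["sd"] / np.sqrt(per_year["n"])
        per_year["flag"] = per_year["mean"].abs() > 2 * per_year["se"]
        out["per_year"] = per_year
        out["year_pattern_flag"] = bool(per_year["flag"].any())
    return out
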