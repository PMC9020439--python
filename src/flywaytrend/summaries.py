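"""Headline trend quantities derived from a fitted hierarchical model.

All percentage declines come from the transform

    r(L, D) = 100 * (1 - exp(D * (beta0 + gamma * L)))

for a cell at latitude L degrees over a window of D years; positive r is a
decline.  Standard errors propagate the covariance of (beta0, gamma) by the
delta method.  Typical-range summaries move the cell log-trend by one
between-cell (sigma_b) or between-site (sigma_d) standard deviation, and
trajectory bands widen the mean-trend Wald interval by the corresponding
prediction spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .gridding import CellAssignment
from .models import FitResult


def percent_change(beta0: float, gamma: float, L: float, D: float) -> float:
    """Median percentage decline over D years at latitude L (Eq. r(L, D))."""
    return 100.0 * (1.0 - np.exp(D * (beta0 + gamma * L)))


def log_trend_se(fit: FitResult, L: float) -> float:
    """Delta-method SE of the cell mean log-trend m = beta0 + gamma * L."""
    cov = fit.cov_fixed()
    return float(np.sqrt(cov[0, 0] + L * L * cov[1, 1] + 2 * L * cov[0, 1]))


def percent_change_se(fit: FitResult, L: float, D: float) -> float:
    """Delta-method SE of the percentage decline r(L, D).

    SE(r) = |100 * D * exp(D m)| * SE(m) with m = beta0 + gamma L.
    """
    if fit.cov_theta is None or not np.all(np.isfinite(fit.cov_fixed())):
        raise ValueError("fit carries no covariance for (beta0, gamma)")
    m = fit.params["beta0"] + fit.params["gamma"] * L
    return float(abs(100.0 * D * np.exp(D * m)) * log_trend_se(fit, L))


def percent_change_with_se(fit: FitResult, L: float, D: float) -> tuple[float, float]:
    r = percent_change(fit.params["beta0"], fit.params["gamma"], L, D)
    return float(r), percent_change_se(fit, L, D)


def typical_decline_range(log_trend: float, sigma: float) -> tuple[float, float]:
    """Annual declines one slope-SD either side of a cell log-trend.

    Returns (smaller, larger) decline:
    ``(100*(1-exp(m+sigma)), 100*(1-exp(m-sigma)))``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    lo = 100.0 * (1.0 - np.exp(log_trend + sigma))
    hi = 100.0 * (1.0 - np.exp(log_trend - sigma))
    return float(lo), float(hi)


def typical_range(fit: FitResult, L: float, level: str = "cell") -> tuple[float, float]:
    """Typical annual decline range at a latitude, at cell or site scale.

    ``cell`` spreads the mean log-trend by sigma_b (between-cell variation);
    ``site`` by sigma_d (between-site variation within a typical cell).
    """
    if level not in ("cell", "site"):
        raise ValueError("level must be 'cell' or 'site'")
    m = fit.params["beta0"] + fit.params["gamma"] * L
    sigma = fit.params["sigma_b"] if level == "cell" else fit.params["sigma_d"]
    return typical_decline_range(m, sigma)


@dataclass
class FlywayTrend:
    """Equal-cell-weight average trend over the surveyed flyway."""

    mean_log_trend: float
    se_log_trend: float
    annual_percent: float
    annual_percent_se: float
    total_percent: float
    total_percent_se: float
    window_years: float
    n_cells: int


def flyway_mean_trend(fit: FitResult, assignment: CellAssignment | None = None,
                      window_years: float = 11.0) -> FlywayTrend:
    """Average population trend over all occupied grid cells.

    The mean log-trend is the equal-weight average of beta0 + gamma * L_q
    over occupied cells — every standardized sampling unit counts the same
    regardless of how many sites or birds it holds.  Percentages follow from
    the decline transform at D = 1 and D = ``window_years``.
    """
    if assignment is None:
        assignment = fit.assignment
    if assignment is None:
        raise ValueError("flyway trend needs the cell assignment")
    L = assignment.cells["lat"].to_numpy()
    beta0, gamma = fit.params["beta0"], fit.params["gamma"]
    m = float(np.mean(beta0 + gamma * L))
    cov = fit.cov_fixed()
    Lbar = float(L.mean())
    se_m = float(np.sqrt(cov[0, 0] + Lbar * Lbar * cov[1, 1] + 2 * Lbar * cov[0, 1]))
    annual = 100.0 * (1.0 - np.exp(m))
    annual_se = abs(100.0 * np.exp(m)) * se_m
    total = 100.0 * (1.0 - np.exp(window_years * m))
    total_se = abs(100.0 * window_years * np.exp(window_years * m)) * se_m
    return FlywayTrend(
        mean_log_trend=m, se_log_trend=se_m,
        annual_percent=float(annual), annual_percent_se=float(annual_se),
        total_percent=float(total), total_percent_se=float(total_se),
        window_years=window_years, n_cells=len(L),
    )


def intercept_slope_correlation(fit: FitResult) -> tuple[float, bool]:
    """Pearson correlation between site intercepts and fitted site slopes.

    Probes whether the decline depends on how many birds a site holds.
    Returns (R, degenerate_flag); with only two sites |R| = 1 by
    construction and the flag is set.
    """
    alpha = fit.alpha.to_numpy()
    slope = fit.site_slopes.to_numpy()
    if len(alpha) < 3:
        if len(alpha) < 2 or np.std(alpha) == 0 or np.std(slope) == 0:
            raise ValueError("correlation undefined for < 2 sites or zero variance")
        return float(np.sign(np.corrcoef(alpha, slope)[0, 1])), True
    if np.std(alpha) == 0 or np.std(slope) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, _ = pearsonr(alpha, slope)
    return float(r), False


def expected_trajectory(fit: FitResult, L: float, years, center: int | None = None) -> pd.DataFrame:
    """Log-scale expected trajectory at latitude L with three nested bands.

    For each year the point estimate is m * t (t the centered year) and the
    95% bands are, from narrowest to widest:

    * ``mean``: Wald interval on the mean trend, +/- 1.96 SE(m) |t|;
    * ``cell``: additionally +/- 1.96 sigma_b |t| of between-cell spread;
    * ``site``: additionally +/- 1.96 sqrt(sigma_b^2 + sigma_d^2) |t|.

    All bands have zero width at t = 0 because the year covariate is
    centered there.
    """
    if center is None:
        center = 2007
    years = np.asarray(list(years), dtype=float)
    t = years - center
    m = fit.params["beta0"] + fit.params["gamma"] * L
    se_m = log_trend_se(fit, L)
    sb, sd = fit.params["sigma_b"], fit.params["sigma_d"]
    point = m * t
    half_mean = 1.96 * se_m * np.abs(t)
    half_cell = 1.96 * np.sqrt(se_m ** 2 + sb ** 2) * np.abs(t)
    half_site = 1.96 * np.sqrt(se_m ** 2 + sb ** 2 + sd ** 2) * np.abs(t)
    return pd.DataFrame({
        "year": years.astype(int), "t": t, "log_index": point,
        "mean_lo": point - half_mean, "mean_hi": point + half_mean,
        "cell_lo": point - half_cell, "cell_hi": point + half_cell,
        "site_lo": point - half_site, "site_hi": point + half_site,
    })


def check_latitude_in_hull(fit: FitResult, L: float) -> None:
    """Warn when a summary latitude falls outside the fitted cells' range."""
    if fit.assignment is None:
        return
    lats = fit.assignment.cells["lat"]
    if not (lats.min() <= L <= lats.max()):
        warnings.warn(
            f"latitude {L} is outside the fitted range "
            f"[{lats.min():.2f}, {lats.max():.2f}]; extrapolating",
            stacklevel=2,
        )


def cell_trend_geojson(fit: FitResult, grid, path) -> None:
    """Export the per-cell trend surface beta0 + b_q as GeoJSON polygons."""
    import json

    from .projection import get_projection

    proj = get_projection(grid.crs)
    s = grid.cell_size
    cells = fit.assignment.cells
    features = []
    for rec in cells.itertuples(index=False):
        xlo, ylo = grid.x0 + rec.col * s, grid.y0 + rec.row * s
        xs = np.array([xlo, xlo + s, xlo + s, xlo, xlo])
        ys = np.array([ylo, ylo, ylo + s, ylo + s, ylo])
        lon, lat = proj.inverse(xs, ys)
        trend = fit.params["beta0"] + float(fit.b[rec.cell_id])
        features.append({
            "type": "Feature",
            "properties": {"cell_id": rec.cell_id, "log_trend": trend,
                           "annual_percent_change": float(100 * (np.exp(trend) - 1))},
            "geometry": {"type": "Polygon",
                         "coordinates": [[[float(a), float(b)] for a, b in zip(lon, lat)]]},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
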