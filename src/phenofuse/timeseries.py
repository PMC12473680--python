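"""NDVI series construction and harmonic gap filling.

A cloud-gapped seasonal NDVI series is reconstructed by fitting the
first two terms of a Fourier series,

    f(x) = a0 + a1*cos(w*x) + b1*sin(w*x) + a2*cos(2*w*x) + b2*sin(2*w*x),

to the valid observations of a pixel (x = day of year), evaluating the
fitted curve at every day of the season (DOY 121-296, 176 days) and
averaging the daily values over 7-day sliding windows anchored at
DOY 121, 128, ..., 296 (26 weekly anchors).

The model is linear in (a0, a1, b1, a2, b2) once the angular frequency
``w`` is fixed, so the solver profiles ``w``: coefficients come from an
exact linear least-squares solve, and ``w`` is found by a bounded scalar
search of the profiled residual sum of squares.  This is the same
objective as a joint nonlinear fit, but it is deterministic, has no
convergence failures, and vectorises over hundreds of thousands of
pixels (see :func:`fit_fourier_stack`).

Meteor-M scenes arrive as daily NDVI composites with no quality layer;
they bypass the harmonic fit and are composited directly
(:func:`meteor_weekly`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

SEASON_START = 121
SEASON_END = 296
SEASON_DAYS = np.arange(SEASON_START, SEASON_END + 1)  # 176 daily points
N_DAILY = SEASON_DAYS.size

WEEKLY_ANCHORS = np.arange(SEASON_START, SEASON_END + 1, 7)  # 26 anchors
N_WEEKS = WEEKLY_ANCHORS.size

# Meteor composite availability window (delivered product).
METEOR_START = 122
METEOR_END = 269

W_DEFAULT = 2 * np.pi / 368.0  # one cycle over ~ twice the season
W_MIN = 2 * np.pi / 800.0
W_MAX = 2 * np.pi / 120.0

DEFAULT_MIN_OBS = 8  # 6 parameters + 2


class DataShapeError(ValueError):
    pass


class InsufficientDataError(ValueError):
    """Too few valid observations to fit or composite a series."""

    def __init__(self, message, pixel=None):
        self.pixel = pixel
        super().__init__(message)


def compute_ndvi(nir, red):
    """Normalized difference vegetation index (NIR-RED)/(NIR+RED).

    Reflectances must be non-negative and co-registered; pixels where
    NIR+RED == 0 become NaN.  The result lies in [-1, 1].
    """
    nir = np.asarray(nir, float)
    red = np.asarray(red, float)
    if nir.shape != red.shape:
        raise DataShapeError(f"NIR shape {nir.shape} != RED shape {red.shape}")
    if (np.nanmin(nir, initial=0) < 0) or (np.nanmin(red, initial=0) < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def fourier_design(doy, w):
    """Design matrix [1, cos(wx), sin(wx), cos(2wx), sin(2wx)]."""
    x = np.asarray(doy, float) * w
    return np.column_stack(
        [np.ones_like(x), np.cos(x), np.sin(x), np.cos(2 * x), np.sin(2 * x)]
    )


def evaluate_fourier(doy, w, coef):
    """Evaluate the harmonic model at ``doy`` (coef = a0,a1,b1,a2,b2)."""
    return fourier_design(doy, w) @ np.asarray(coef, float)


@dataclass
class FourierFitResults:
    """Fitted harmonic parameters plus diagnostics for one pixel series."""

    w: float
    a0: float
    a1: float
    b1: float
    a2: float
    b2: float
    n_obs: int
    rmse: float

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.b1, self.a2, self.b2])

    def predict(self, doy) -> np.ndarray:
        """Raw (unclipped) model value at arbitrary days of year."""
        return evaluate_fourier(doy, self.w, self.coef)

    def summary(self) -> str:
        lines = [
            "Harmonic NDVI fit",
            f"  w      {self.w:.6e}  (period {2 * np.pi / self.w:.1f} d)",
        ]
        for name, v in zip(("a0", "a1", "b1", "a2", "b2"), self.coef):
            lines.append(f"  {name:<6} {v:+.4f}")
        lines.append(f"  n_obs  {self.n_obs}")
        lines.append(f"  rmse   {self.rmse:.5f}")
        return "\n".join(lines)


def _profile_solve(X, y):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


class FourierSeasonalModel:
    """Harmonic seasonal model for one gapped NDVI series.

    Parameters
    ----------
    doy : array-like of int
        Observation days of year, strictly increasing.
    ndvi : array-like of float
        NDVI values; NaN marks masked observations.
    """

    N_W_GRID = 25

    def __init__(self, doy, ndvi, pixel=None):
        doy = np.asarray(doy, float)
        ndvi = np.asarray(ndvi, float)
        if doy.shape != ndvi.shape or doy.ndim != 1:
            raise DataShapeError("doy and ndvi must be equal-length 1-d arrays")
        if np.any(np.diff(doy) <= 0):
            raise DataShapeError("observation days must be strictly increasing")
        keep = np.isfinite(ndvi)
        self.doy = doy[keep]
        self.ndvi = ndvi[keep]
        self.pixel = pixel

    def fit(self, min_obs: int = DEFAULT_MIN_OBS) -> FourierFitResults:
        """Profiled least-squares fit of the two-term harmonic model.

        ``w`` is searched over [2*pi/800, 2*pi/120] (grid including the
        canonical seasonal start 2*pi/368, then Brent refinement); the
        five linear coefficients are solved exactly at each candidate.
        Deterministic for a given series.
        """
        n = self.doy.size
        if n < min_obs:
            raise InsufficientDataError(
                f"{n} valid observations < min_obs={min_obs}"
                + (f" at pixel {self.pixel}" if self.pixel is not None else ""),
                pixel=self.pixel,
            )

        def rss(w):
            return _profile_solve(fourier_design(self.doy, w), self.ndvi)[1]

        # Candidate grid; the default frequency goes first so exact ties
        # (e.g. constant series) resolve to the canonical initialisation.
        grid = np.concatenate(
            [[W_DEFAULT], np.geomspace(W_MIN, W_MAX, self.N_W_GRID)]
        )
        vals = np.array([rss(w) for w in grid])
        scale = max(float(self.ndvi @ self.ndvi), 1.0)
        # first candidate among near-ties: the canonical frequency wins
        best = int(np.flatnonzero(vals <= vals.min() + 1e-14 * scale)[0])
        w_best, rss_best = float(grid[best]), float(vals[best])

        # Local refinement around the best candidate.
        lo = max(W_MIN, w_best / 1.6)
        hi = min(W_MAX, w_best * 1.6)
        res = minimize_scalar(
            rss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        if np.isfinite(res.fun) and res.fun < rss_best - 1e-14 * scale:
            w_best, rss_best = float(res.x), float(res.fun)

        coef, rss_best = _profile_solve(fourier_design(self.doy, w_best), self.ndvi)
        if not np.all(np.isfinite(coef)):
            raise InsufficientDataError(
                "degenerate design (non-finite coefficients)", pixel=self.pixel
            )
        return FourierFitResults(
            w=w_best,
            a0=float(coef[0]),
            a1=float(coef[1]),
            b1=float(coef[2]),
            a2=float(coef[3]),
            b2=float(coef[4]),
            n_obs=int(n),
            rmse=float(np.sqrt(max(rss_best, 0.0) / n)),
        )


def fit_fourier(doy, ndvi, min_obs: int = DEFAULT_MIN_OBS, pixel=None) -> FourierFitResults:
    """Functional wrapper around :class:`FourierSeasonalModel`."""
    return FourierSeasonalModel(doy, ndvi, pixel=pixel).fit(min_obs=min_obs)


def reconstruct_daily(fit: FourierFitResults, doy_range=None) -> np.ndarray:
    """Daily NDVI reconstruction over the season, clipped to [-1, 1]."""
    days = SEASON_DAYS if doy_range is None else np.asarray(doy_range)
    return np.clip(fit.predict(days), -1.0, 1.0)


def weekly_composites(daily, stat: str = "mean") -> np.ndarray:
    """Sliding-window weekly composites of a daily season series.

    ``daily`` holds one value per day of DOY 121-296 (leading axis of
    length 176; trailing axes are carried through).  Each of the 26
    anchors a = 121 + 7k takes the ``stat`` ("mean" or "max") of days
    [a, a+6], truncated at the season end.
    """
    daily = np.asarray(daily, float)
    if daily.shape[0] != N_DAILY:
        raise DataShapeError(f"expected {N_DAILY} daily values, got {daily.shape[0]}")
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    fn = np.mean if stat == "mean" else np.max
    out = np.empty((N_WEEKS,) + daily.shape[1:], float)
    for k, anchor in enumerate(WEEKLY_ANCHORS):
        i0 = anchor - SEASON_START
        i1 = min(i0 + 7, N_DAILY)
        out[k] = fn(daily[i0:i1], axis=0)
    return out


def meteor_weekly(doy, ndvi) -> np.ndarray:
    """Weekly composites straight from daily Meteor NDVI composites.

    ``doy`` (n,) are the composite days (within DOY 122-269); ``ndvi``
    is (n,) or (n, ...) with NaN for missing days.  Each anchor takes
    the mean of valid days in its 7-day window; anchors whose window is
    empty are filled by linear interpolation between neighbouring valid
    anchors, and leading/trailing empty anchors take the nearest valid
    anchor value (the delivered product only spans part of the season).

    Raises :class:`InsufficientDataError` when a series has no valid
    day at all (for array input such pixels become all-NaN columns).
    """
    doy = np.asarray(doy, float)
    ndvi = np.asarray(ndvi, float)
    if doy.ndim != 1 or ndvi.shape[0] != doy.size:
        raise DataShapeError("doy must be 1-d and match ndvi's leading axis")
    scalar_series = ndvi.ndim == 1
    flat = ndvi.reshape(doy.size, -1)

    weekly = np.full((N_WEEKS, flat.shape[1]), np.nan)
    for k, anchor in enumerate(WEEKLY_ANCHORS):
        sel = (doy >= anchor) & (doy <= min(anchor + 6, SEASON_END))
        if sel.any():
            block = flat[sel]
            good = np.isfinite(block)
            count = good.sum(axis=0)
            total = np.where(good, block, 0.0).sum(axis=0)
            weekly[k] = np.where(count > 0, total / np.maximum(count, 1), np.nan)

    idx = np.arange(N_WEEKS, dtype=float)
    for j in range(weekly.shape[1]):
        col = weekly[:, j]
        good = np.isfinite(col)
        if not good.any():
            if scalar_series:
                raise InsufficientDataError("series has no valid observation")
            continue
        if not good.all():
            # np.interp clamps beyond the ends: nearest-anchor extension.
            weekly[:, j] = np.interp(idx, idx[good], col[good])

    return weekly[:, 0] if scalar_series else weekly.reshape((N_WEEKS,) + ndvi.shape[1:])


def fit_fourier_stack(doy, values, min_obs: int = DEFAULT_MIN_OBS, refine: bool = True):
    """Vectorised harmonic fit of many pixel series sharing a scene schedule.

    Parameters
    ----------
    doy : (n_scenes,) array
        Scene days of year.
    values : (n_scenes, n_pix) array
        NDVI observations, NaN where masked.
    refine : bool
        Apply a per-pixel parabolic refinement of ``w`` around the best
        grid candidate.

    Returns
    -------
    w : (n_pix,) fitted frequencies (NaN where unfittable)
    coef : (n_pix, 5) coefficients a0,a1,b1,a2,b2
    rmse : (n_pix,)
    n_obs : (n_pix,) valid-observation counts

    Same objective as :class:`FourierSeasonalModel` (profiled linear
    least squares over a frequency grid); pixels with fewer than
    ``min_obs`` valid observations are returned as NaN rather than
    raising, so raster stacks degrade gracefully.
    """
    doy = np.asarray(doy, float)
    Y = np.asarray(values, float)
    if Y.ndim != 2 or Y.shape[0] != doy.size:
        raise DataShapeError("values must be (n_scenes, n_pix)")
    n_pix = Y.shape[1]
    M = np.isfinite(Y)
    n_obs = M.sum(axis=0)
    fittable = n_obs >= min_obs
    Mf = M.astype(float)
    Y0 = np.where(M, Y, 0.0)

    grid = np.concatenate([[W_DEFAULT], np.geomspace(W_MIN, W_MAX, 21)])
    order = np.argsort(np.abs(grid - W_DEFAULT), kind="stable")
    grid = grid[order]  # default first: argmin ties resolve to it

    MfT = np.ascontiguousarray(Mf.T)  # (p, s)
    Y0T = np.ascontiguousarray(Y0.T)
    yy = np.einsum("ps,ps->p", MfT, Y0T**2)  # masked sum of squares
    iu, ju = np.triu_indices(5)

    def batch_rss(w):
        # Normal equations assembled with two GEMMs per candidate:
        # A_p = X' diag(m_p) X via the 15 unique column products,
        # b_p = X' (m_p * y_p); RSS by the quadratic-form identity.
        X = fourier_design(doy, w)  # (s, 5)
        G = MfT @ (X[:, iu] * X[:, ju])  # (p, 15)
        A = np.empty((n_pix, 5, 5))
        A[:, iu, ju] = G
        A[:, ju, iu] = G
        b = Y0T @ X  # (p, 5)
        with np.errstate(all="ignore"):
            try:
                coef = np.linalg.solve(A, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                coef = np.full((n_pix, 5), np.nan)
                for p in range(n_pix):
                    try:
                        coef[p] = np.linalg.solve(A[p], b[p])
                    except np.linalg.LinAlgError:
                        pass
        quad = np.einsum("pi,pij,pj->p", coef, A, coef)
        rss = np.maximum(yy - 2 * np.einsum("pi,pi->p", b, coef) + quad, 0.0)
        bad = ~np.all(np.isfinite(coef), axis=1)
        rss[bad] = np.inf
        return coef, rss

    all_rss = np.empty((grid.size, n_pix))
    all_coef = np.empty((grid.size, n_pix, 5))
    for k, w in enumerate(grid):
        all_coef[k], all_rss[k] = batch_rss(w)

    best = np.argmin(all_rss, axis=0)
    w_best = grid[best]
    coef = all_coef[best, np.arange(n_pix)]
    rss = all_rss[best, np.arange(n_pix)]

    if refine:
        # One parabolic step through the three grid points bracketing the
        # minimum (in sorted-frequency order), evaluated per pixel.
        sidx = np.argsort(grid)
        pos_of = np.empty_like(sidx)
        pos_of[sidx] = np.arange(grid.size)
        pos = pos_of[best]
        interior = fittable & (pos > 0) & (pos < grid.size - 1) & np.isfinite(rss)
        if interior.any():
            gs = grid[sidx]
            rs = all_rss[:, interior][sidx]
            p = pos[interior]
            cols = np.arange(p.size)
            w0, w1, w2 = gs[p - 1], gs[p], gs[p + 1]
            f0, f1, f2 = rs[p - 1, cols], rs[p, cols], rs[p + 1, cols]
            denom = (w1 - w0) * (f1 - f2) - (w1 - w2) * (f1 - f0)
            with np.errstate(all="ignore"):
                w_star = w1 - 0.5 * (
                    (w1 - w0) ** 2 * (f1 - f2) - (w1 - w2) ** 2 * (f1 - f0)
                ) / denom
            ok = np.isfinite(w_star) & (w_star > w0) & (w_star < w2)
            if ok.any():
                pix_idx = np.flatnonzero(interior)[ok]
                w_try = w_star[ok]
                c_try, r_try = _per_pixel_rss(doy, Y0, Mf, M, w_try, pix_idx)
                better = r_try < rss[pix_idx]
                upd = pix_idx[better]
                w_best[upd] = w_try[better]
                coef[upd] = c_try[better]
                rss[upd] = r_try[better]

    w_best = np.where(fittable, w_best, np.nan)
    coef[~fittable] = np.nan
    rmse = np.sqrt(np.maximum(rss, 0.0) / np.maximum(n_obs, 1))
    rmse[~fittable] = np.nan
    return w_best, coef, rmse, n_obs


def _per_pixel_rss(doy, Y0, Mf, M, w_pix, pix_idx, chunk=20000):
    """Linear solve + RSS for per-pixel frequencies (chunked)."""
    out_coef = np.empty((pix_idx.size, 5))
    out_rss = np.empty(pix_idx.size)
    for s0 in range(0, pix_idx.size, chunk):
        sl = slice(s0, min(s0 + chunk, pix_idx.size))
        idx = pix_idx[sl]
        w = w_pix[sl]
        x = doy[:, None] * w[None, :]  # (s, q)
        B = np.stack(
            [np.ones_like(x), np.cos(x), np.sin(x), np.cos(2 * x), np.sin(2 * x)],
            axis=2,
        )  # (s, q, 5)
        m = Mf[:, idx]
        y = Y0[:, idx]
        A = np.einsum("sq,sqi,sqj->qij", m, B, B)
        b = np.einsum("sq,sqi->qi", y, B)
        with np.errstate(all="ignore"):
            try:
                c = np.linalg.solve(A, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                c = np.full((idx.size, 5), np.nan)
        fitted = np.einsum("sqi,qi->sq", B, c)
        resid = np.where(M[:, idx], y - fitted, 0.0)
        r = np.einsum("sq,sq->q", resid, resid)
        bad = ~np.all(np.isfinite(c), axis=1)
        r[bad] = np.inf
        out_coef[sl] = c
        out_rss[sl] = r
    return out_coef, out_rss


def reconstruct_daily_stack(w, coef, doy_range=None) -> np.ndarray:
    """Daily reconstruction for batched fits: (n_days, n_pix), clipped."""
    days = SEASON_DAYS if doy_range is None else np.asarray(doy_range)
    w = np.asarray(w, float)
    coef = np.asarray(coef, float)
    x = days[:, None] * w[None, :]
    with np.errstate(invalid="ignore"):
        out = (
            coef[:, 0]
            + coef[:, 1] * np.cos(x)
            + coef[:, 2] * np.sin(x)
            + coef[:, 3] * np.cos(2 * x)
            + coef[:, 4] * np.sin(2 * x)
        )
    return np.clip(out, -1.0, 1.0)
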