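"""Circular-arc fitting of cryosection contours and Rq surface roughness.

A smooth, high-tension aggregate has a cryosection contour close to a
circular arc; drug treatments that round up surface cells roughen it. The
roughness metric is the root-mean-squared radial deviation from the
best-fit circle:

    Rq = sqrt( (1/N) * sum_i z_i^2 ),   z_i = |p_i - center| - r,

with signed residuals ``z_i`` kept for diagnostics. The circle is fitted by
algebraic (Kasa) initialization refined with geometric least squares
(Levenberg-Marquardt on center and radius), which is exact on noiseless
data and standard for noisy arcs. Residuals are only ever evaluated at the
provided points — the fit never extrapolates beyond the sampled arc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .exceptions import DegenerateFitError

__all__ = ["RoughnessResult", "CircleFitter", "fit_circle", "roughness_rq"]


@dataclass(frozen=True)
class RoughnessResult:
    """Rq roughness of a contour against a circular arc (micrometres)."""

    Rq: float
    center: tuple[float, float]
    radius: float
    residuals: np.ndarray  #: signed point-to-arc distances, um
    n: int

    def to_dict(self) -> dict:
        return {
            "Rq_um": self.Rq,
            "r_um": self.radius,
            "cx_um": self.center[0],
            "cz_um": self.center[1],
            "n": self.n,
        }


def _as_points(contour) -> np.ndarray:
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array of (x, z) points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("contour contains non-finite coordinates")
    return pts


def _kasa(pts: np.ndarray):
    """Algebraic circle fit: linear least squares on x^2+y^2 + D x + E y + F."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if not r2 > 0:
        raise DegenerateFitError("algebraic circle fit collapsed (r^2 <= 0)")
    return cx, cy, float(np.sqrt(r2))


class CircleFitter(BaseEstimator):
    """Geometric least-squares circle fit of planar points.

    ``fit(X)`` with X of shape (N, 2) minimizes sum_i (|p_i - c| - r)^2 over
    center c and radius r, starting from the Kasa algebraic solution.

    Attributes
    ----------
    center_ : ndarray (2,)
        Fitted center (same units as the input).
    radius_ : float
        Fitted radius.
    residuals_ : ndarray (N,)
        Signed distances point-to-arc.
    rq_ : float
        Root-mean-squared residual.
    """

    def __init__(self, max_iter: int = 200):
        self.max_iter = max_iter

    def fit(self, X, y=None):
        pts = _as_points(X)
        if len(pts) < 3:
            raise DegenerateFitError(f"need >= 3 points for a circle, got {len(pts)}")
        # collinearity guard: area of the bounding triangle of extreme points
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        span = float(np.max(np.abs(centered)))
        if sv[-1] <= 1e-10 * max(sv[0], 1.0) or span == 0.0:
            raise DegenerateFitError("points are collinear: no unique circle")
        cx0, cy0, r0 = _kasa(pts)

        def resid(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        sol = least_squares(
            resid, x0=[cx0, cy0, r0], method="lm", max_nfev=self.max_iter * 4
        )
        self.center_ = sol.x[:2].copy()
        self.radius_ = float(sol.x[2])
        self.residuals_ = resid(sol.x)
        self.rq_ = float(np.sqrt(np.mean(self.residuals_**2)))
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        """Signed point-to-arc distances for new points."""
        pts = _as_points(X)
        return (
            np.hypot(pts[:, 0] - self.center_[0], pts[:, 1] - self.center_[1])
            - self.radius_
        )


def fit_circle(contour) -> tuple[tuple[float, float], float]:
    """Best-fit circle (center, radius) of a contour, geometric least squares."""
    est = CircleFitter().fit(contour)
    return (float(est.center_[0]), float(est.center_[1])), est.radius_


def roughness_rq(contour, arc=None) -> RoughnessResult:
    """Rq roughness of a contour relative to a circular arc.

    Parameters
    ----------
    contour : (N, 2) array-like
        Ordered (x, z) points, micrometres.
    arc : ((cx, cz), r), optional
        Fixed reference arc. When omitted the best-fit circle is used.
    """
    pts = _as_points(contour)
    if arc is None:
        est = CircleFitter().fit(pts)
        center, radius = est.center_, est.radius_
        residuals = est.residuals_
    else:
        (cx, cz), radius = arc
        center = np.array([cx, cz], dtype=float)
        residuals = np.hypot(pts[:, 0] - cx, pts[:, 1] - cz) - radius
    rq = float(np.sqrt(np.mean(residuals**2)))
    return RoughnessResult(
        Rq=rq,
        center=(float(center[0]), float(center[1])),
        radius=float(radius),
        residuals=residuals,
        n=len(pts),
    )
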