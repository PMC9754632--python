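"""Four-parameter Hill (logistic) dose-response fitting and IC50 extraction.

Inhibition of surface tension or Young's modulus by a drug is summarized by
the four-parameter Hill model

    Y(X) = Bottom + (Top - Bottom) / (1 + (IC50/X)^HillSlope)

with no bounds imposed on the four parameters. At X = IC50 the response is
the mid-point (Top+Bottom)/2 for any non-zero slope. The printed formula is
undefined at X = 0; the analytic limit is used instead (Top for negative
slope, Bottom for positive slope), so zero-dose controls participate in the
fit. The (Top, Bottom, HillSlope) <-> (Bottom, Top, -HillSlope) relabelling
is gauge freedom — both describe the same curve — and fitted results are
canonicalized to Top >= Bottom.

For a racemic drug only a fraction of which is the active enantiomer, the
active-compound IC50 is the racemic IC50 scaled by that fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DegenerateModelError, FitConvergenceError, UnidentifiableError

__all__ = [
    "DoseResponseFit",
    "HillCurveFitter",
    "hill_eval",
    "fit_hill",
    "active_ic50",
]


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted (or specified) Hill parameters."""

    Top: float
    Bottom: float
    IC50: float  #: uM
    HillSlope: float
    covariance: np.ndarray | None = field(default=None, repr=False)
    se_IC50: float | None = None

    def __post_init__(self):
        if not self.IC50 > 0:
            raise ValueError(f"IC50 must be > 0, got {self.IC50}")
        if self.HillSlope == 0:
            raise DegenerateModelError("HillSlope = 0 gives a constant model")

    def to_dict(self) -> dict:
        return {
            "Top": self.Top,
            "Bottom": self.Bottom,
            "IC50_uM": self.IC50,
            "HillSlope": self.HillSlope,
            "se_IC50_uM": self.se_IC50,
        }


def hill_eval(X, params: DoseResponseFit):
    """Evaluate the Hill curve at dose(s) X (uM), with the X=0 limit.

    Scalar in, scalar out; array in, array out.
    """
    if params.HillSlope == 0:
        raise DegenerateModelError("HillSlope = 0 gives a constant model")
    x = np.asarray(X, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("doses must be >= 0")
    out = np.empty_like(x)
    zero = x == 0.0
    limit0 = params.Top if params.HillSlope < 0 else params.Bottom
    out[zero] = limit0
    nz = ~zero
    out[nz] = params.Bottom + (params.Top - params.Bottom) / (
        1.0 + (params.IC50 / x[nz]) ** params.HillSlope
    )
    return float(out[0]) if scalar else out


def active_ic50(ic50_racemic: float, active_fraction: float) -> float:
    """IC50 of the active enantiomer from the racemic-mixture IC50.

    The racemic compound contains ``active_fraction`` (in (0, 1]) of the
    active form; at the racemic IC50 the active dose is the product.
    """
    if not ic50_racemic > 0:
        raise ValueError(f"IC50 must be > 0, got {ic50_racemic}")
    if not 0.0 < active_fraction <= 1.0:
        raise ValueError(f"active fraction must be in (0, 1], got {active_fraction}")
    return ic50_racemic * active_fraction


def _hill_raw(x, top, bottom, log_ic50, slope):
    """Vectorized model with log-IC50 internal parameterization."""
    ic50 = np.exp(log_ic50)
    out = np.empty_like(x)
    zero = x == 0.0
    out[zero] = top if slope < 0 else bottom
    nz = ~zero
    out[nz] = bottom + (top - bottom) / (1.0 + (ic50 / x[nz]) ** slope)
    return out


class HillCurveFitter(RegressorMixin, BaseEstimator):
    """Unconstrained four-parameter Hill regression.

    ``fit(X, y)`` takes doses X (uM, shape (n,) or (n, 1)) and responses y.
    No bounds are placed on Top, Bottom or HillSlope; IC50 is handled on a
    log scale internally purely so the power term stays defined along the
    optimizer's path, and its uncertainty is mapped back by the delta
    method.

    Attributes
    ----------
    top_, bottom_, ic50_, hill_slope_ : float
        Canonicalized parameters (top_ >= bottom_).
    covariance_ : ndarray (4, 4)
        Covariance of (Top, Bottom, IC50, HillSlope) from the Jacobian.
    se_ic50_ : float
        Standard error of IC50, uM.
    result_ : DoseResponseFit
    """

    def __init__(self, max_iter: int = 2000, xtol: float = 1e-12):
        self.max_iter = max_iter
        self.xtol = xtol

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        yy = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != yy.shape:
            raise ValueError("X and y must have the same length")
        if np.any(x < 0) or not np.all(np.isfinite(x)):
            raise ValueError("doses must be finite and >= 0")
        if not np.all(np.isfinite(yy)):
            raise ValueError("responses must be finite")
        if len(np.unique(x)) < 4:
            raise UnidentifiableError(
                "at least 4 distinct doses are needed for 4 free parameters"
            )
        spread = np.std(yy)
        if spread < 1e-12 * max(1.0, abs(np.mean(yy))):
            raise UnidentifiableError(
                "responses are constant: IC50 is unidentifiable"
            )

        # initialization from the data: plateaus from extreme-dose means,
        # IC50 from the dose nearest the half response, slope sign from trend
        order = np.argsort(x)
        xs, ys = x[order], yy[order]
        lo_mask = xs <= np.quantile(xs, 0.25)
        hi_mask = xs >= np.quantile(xs, 0.75)
        y_lo, y_hi = ys[lo_mask].mean(), ys[hi_mask].mean()
        top0, bottom0 = (y_lo, y_hi) if y_lo >= y_hi else (y_hi, y_lo)
        half = 0.5 * (top0 + bottom0)
        pos = xs[xs > 0]
        if pos.size == 0:
            raise UnidentifiableError("all doses are zero")
        i_half = int(np.argmin(np.abs(ys[xs > 0] - half)))
        ic50_0 = float(pos[i_half]) if pos[i_half] > 0 else float(np.median(pos))
        slope0 = -1.0 if y_hi < y_lo else 1.0

        def resid(p):
            return _hill_raw(x, p[0], p[1], p[2], p[3]) - yy

        best = None
        for s0 in (slope0, -slope0):
            sol = least_squares(
                resid,
                x0=[top0, bottom0, math.log(ic50_0), s0],
                method="lm",
                xtol=self.xtol,
                max_nfev=self.max_iter,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if not best.success and best.cost > 1e-6 * max(spread, 1.0) ** 2 * len(yy):
            raise FitConvergenceError(
                f"Hill fit did not converge (residual {best.cost:.3e})",
                residual=float(best.cost),
            )

        top, bottom, log_ic50, slope = best.x
        ic50 = math.exp(log_ic50)
        # covariance in (Top, Bottom, logIC50, slope) then delta method
        dof = max(len(yy) - 4, 1)
        s2 = 2.0 * best.cost / dof
        JtJ = best.jac.T @ best.jac
        try:
            cov_log = s2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov_log = np.full((4, 4), np.nan)
        scale = np.diag([1.0, 1.0, ic50, 1.0])  # d(IC50)/d(logIC50) = IC50
        cov = scale @ cov_log @ scale

        # canonicalize the (Top, Bottom, slope) gauge to Top >= Bottom
        if top < bottom:
            top, bottom, slope = bottom, top, -slope
            P = np.eye(4)[[1, 0, 2, 3]]
            P[3, 3] = 1.0
            cov = P @ cov @ P.T
            cov[3, :] *= -1
            cov[:, 3] *= -1
            cov[3, 3] = abs(cov[3, 3])

        self.top_, self.bottom_ = float(top), float(bottom)
        self.ic50_, self.hill_slope_ = float(ic50), float(slope)
        self.covariance_ = cov
        self.se_ic50_ = float(np.sqrt(abs(cov[2, 2])))
        self.result_ = DoseResponseFit(
            Top=self.top_,
            Bottom=self.bottom_,
            IC50=self.ic50_,
            HillSlope=self.hill_slope_,
            covariance=cov,
            se_IC50=self.se_ic50_,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return hill_eval(x, self.result_)


def fit_hill(doses, responses) -> DoseResponseFit:
    """Fit the four-parameter Hill model; thin wrapper over HillCurveFitter.

    Raises
    ------
    UnidentifiableError
        Fewer than 4 distinct doses, or flat responses.
    FitConvergenceError
        Optimizer terminated far from a minimum (carries the residual).
    """
    return HillCurveFitter().fit(doses, responses).result_
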