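"""Inverse problem: surface tension from flattened-spheroid landmarks.

The measured quantities are the landmarks a user points on the side-profile
image: height ``h``, width ``w`` and the initial (undeformed) radius ``R`` of
the spheroid, which fixes the conserved volume ``V = (4/3) pi R^3``. Fitting
the forward Young-Laplace model to (h, w, V) by minimizing the summed squared
*relative* errors over the apex curvature ``b`` and the capillary parameter
``c`` recovers ``c``, and hence the tissue surface tension

    gamma = f / c,   f = Mv * grad(B).

Relative errors are used because h, w and V carry different dimensions; equal
weights are applied. The optimizer is Nelder-Mead over (log b, log c) —
the log parameterization enforces positivity without constraints — seeded
from the initial-guess tension and refined from a one-dimensional pre-scan
over the flattening parameter beta = c/b^2 (shapes are self-similar in beta,
so each pre-scan point costs a single dimensionless integration).

High-tension spheroids barely deform, so gamma is unbounded as h -> 2R: an
exactly undeformed landmark set raises ``OutOfMeasurableRangeError`` and a
flattening below twice the pointing noise triggers an identifiability
warning in the diagnostics.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .context import MagneticContext
from .exceptions import FitConvergenceError, OutOfMeasurableRangeError
from .laplace import ShapeParams, _integrate_core, integrate_profile, profile_metrics

__all__ = [
    "LandmarkSet",
    "TensionResult",
    "LaplaceTensionFitter",
    "fit_capillary",
    "gamma_from_c",
]

_UNIT_TO_UM = {"um": 1.0, "m": 1e6, "mm": 1e3}


@dataclass(frozen=True)
class LandmarkSet:
    """Pointed landmarks of one spheroid profile (micrometres by default).

    Either the initial radius ``R`` (volume conservation, ``V=(4/3)pi R^3``)
    or the volume ``V`` directly must be given. ``L`` is the contact-zone
    radius, consumed by the Hertz analysis, not by the tension fit.
    """

    h: float
    w: float
    R: float | None = None
    V: float | None = None
    L: float | None = None
    unit: str = "um"

    def __post_init__(self):
        if self.unit not in _UNIT_TO_UM:
            raise ValueError(f"unknown length unit {self.unit!r}")
        k = _UNIT_TO_UM[self.unit]
        for name in ("h", "w", "R", "L"):
            v = getattr(self, name)
            if v is not None:
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(f"landmark {name} must be positive, got {v}")
                object.__setattr__(self, name, v * k)
        if self.V is not None:
            if self.V <= 0:
                raise ValueError(f"volume must be positive, got {self.V}")
            object.__setattr__(self, "V", self.V * k**3)
        object.__setattr__(self, "unit", "um")
        if self.V is None and self.R is None:
            raise ValueError("either R or V is required to fix the volume")
        if self.h > self.w * (1.0 + 1e-9):
            raise ValueError(
                f"h={self.h} um > w={self.w} um: not a flattened sessile profile"
            )

    @property
    def volume_um3(self) -> float:
        return self.V if self.V is not None else (4.0 / 3.0) * math.pi * self.R**3

    @property
    def radius_um(self) -> float:
        """Equivalent-sphere radius from the conserved volume, um."""
        if self.R is not None:
            return self.R
        return (3.0 * self.V / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class TensionResult:
    """Fitted capillary parameter and surface tension with diagnostics."""

    c: float  #: capillary parameter, 1/m^2
    gamma: float  #: surface tension, mN/m (= f/c, exactly)
    residual: float  #: final objective (sum of squared relative errors)
    b: float  #: fitted apex curvature, 1/m
    converged: bool
    n_iter: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def gamma_from_c(c: float, ctx: MagneticContext) -> float:
    """Surface tension gamma = f/c in mN/m from the capillary parameter.

    ``c`` is in 1/m^2; the force density ``f = Mv*grad(B)`` in N/m^3; the SI
    ratio f/c (N/m) is scaled by 1000 to the conventional mN/m.
    """
    if not c > 0:
        raise ValueError(f"capillary parameter must be > 0, got {c}")
    return ctx.force_density / c * 1e3


def _dimensionless_metrics(beta: float, step: float):
    """(H, W, Vd) of the unit-apex-curvature profile at flattening beta."""
    status, s, x, z, phi, V, _ = _integrate_core(1.0, beta, step)
    if status != 0:
        raise FitConvergenceError(f"forward model failed at beta={beta:g}")
    i = int(np.argmax(x))
    if 0 < i < len(x) - 1:
        x0, x1, x2 = x[i - 1], x[i], x[i + 1]
        denom = x0 - 2.0 * x1 + x2
        xmax = x1 - 0.25 * (x0 - x2) * ((x0 - x2) / denom * 0.5) if denom < 0 else x1
    else:
        xmax = x[i]
    return float(z[-1]), 2.0 * float(xmax), float(V)


def _fit_landmarks_si(
    h_m: float,
    w_m: float,
    V_m3: float,
    f: float,
    gamma_init_mN: float,
    step: float,
    pointing_noise_um: float,
    max_iter: int,
    prescan: bool,
):
    """Core fit in SI units. Returns (c, b, residual, converged, n_iter, warns)."""
    warns = []
    R0 = (3.0 * V_m3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    flattening_m = 2.0 * R0 - h_m
    if flattening_m <= 1e-9 * R0:
        raise OutOfMeasurableRangeError(
            f"h={h_m*1e6:.1f} um >= 2R={2*R0*1e6:.1f} um: the spheroid is not "
            "measurably deformed, surface tension is out of measurable range"
        )
    if flattening_m < 2.0 * pointing_noise_um * 1e-6:
        warns.append(
            f"flattening 2R-h = {flattening_m*1e6:.1f} um is below twice the "
            f"pointing noise ({pointing_noise_um:g} um): gamma is weakly "
            "identifiable"
        )

    def objective(p):
        b = math.exp(p[0])
        c = math.exp(p[1])
        status, s, x, z, phi, V, _ = _integrate_core(b, c, step)
        if status != 0:
            return 1e6
        i = int(np.argmax(x))
        if 0 < i < len(x) - 1:
            x0, x1, x2 = x[i - 1], x[i], x[i + 1]
            denom = x0 - 2.0 * x1 + x2
            xmax = (
                x1 - 0.25 * (x0 - x2) * ((x0 - x2) / denom * 0.5) if denom < 0 else x1
            )
        else:
            xmax = x[i]
        h_mod, w_mod = z[-1], 2.0 * xmax
        return (
            (h_mod / h_m - 1.0) ** 2
            + (w_mod / w_m - 1.0) ** 2
            + (V / V_m3 - 1.0) ** 2
        )

    # --- seed from gamma_init
    c_seed = f / (gamma_init_mN * 1e-3)
    b_seed = 1.0 / R0

    # --- 1D pre-scan over beta = c/b^2 (self-similar shapes), volume-matched
    if prescan:
        best = (np.inf, b_seed, c_seed)
        gammas = np.geomspace(0.5, 500.0, 25)  # mN/m
        for gam in gammas:
            c_try = f / (gam * 1e-3)
            beta = c_try * R0 * R0
            try:
                H, W, Vd = _dimensionless_metrics(beta, max(step, 2e-3))
            except FitConvergenceError:
                continue
            b_try = (Vd / V_m3) ** (1.0 / 3.0)  # exact volume match
            err = (H / (b_try * h_m) - 1.0) ** 2 + (W / (b_try * w_m) - 1.0) ** 2
            if err < best[0]:
                # recover c consistent with this (beta, b)
                best = (err, b_try, beta * b_try * b_try)
        _, b_seed, c_seed = best

    res = minimize(
        objective,
        x0=[math.log(b_seed), math.log(c_seed)],
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "xatol": 1e-9,
            "fatol": 1e-16,
        },
    )
    converged = bool(res.success) or res.fun < 1e-12
    if not converged:
        warns.append(f"optimizer did not converge: final residual {res.fun:.3e}")
    b_fit, c_fit = math.exp(res.x[0]), math.exp(res.x[1])
    return c_fit, b_fit, float(res.fun), converged, int(res.nit), warns


def fit_capillary(
    landmarks: LandmarkSet,
    ctx: MagneticContext,
    gamma_init: float = 20.0,
    step: float = 1e-3,
    pointing_noise_um: float = 5.0,
    max_iter: int = 500,
    prescan: bool = True,
) -> TensionResult:
    """Fit (b, c) to the landmarks and return the surface tension.

    Parameters
    ----------
    landmarks : LandmarkSet
        Measured h, w and R (or V).
    ctx : MagneticContext
        Magnetization context providing the force density f = Mv*grad(B).
    gamma_init : float
        Initial surface-tension guess, mN/m (the value a user enters in the
        analysis front-end).

    Raises
    ------
    OutOfMeasurableRangeError
        If ``h >= 2R`` (no measurable deformation, gamma unbounded).
    FitConvergenceError
        If the optimizer terminates far from a minimum.
    """
    if not gamma_init > 0:
        raise ValueError(f"gamma_init must be > 0, got {gamma_init}")
    V_m3 = landmarks.volume_um3 * 1e-18
    c, b, resid, converged, nit, warns = _fit_landmarks_si(
        landmarks.h * 1e-6,
        landmarks.w * 1e-6,
        V_m3,
        ctx.force_density,
        gamma_init,
        step,
        pointing_noise_um,
        max_iter,
        prescan,
    )
    if not converged and resid > 1e-2:
        raise FitConvergenceError(
            f"tension fit did not converge (residual {resid:.3e})", residual=resid
        )
    return TensionResult(
        c=c,
        gamma=gamma_from_c(c, ctx),
        residual=resid,
        b=b,
        converged=converged,
        n_iter=nit,
        warnings=tuple(warns),
    )


class LaplaceTensionFitter(BaseEstimator):
    """Estimator recovering surface tension from landmark rows.

    Scikit-learn-style wrapper over the Young-Laplace landmark fit: ``fit``
    takes an array of shape (n_spheroids, 3) with columns ``h_um``, ``w_um``,
    ``V_um3`` (or a DataFrame with those columns, where ``R_um`` may replace
    ``V_um3``), and exposes per-spheroid fitted attributes.

    Parameters
    ----------
    Mv : float
        Magnetic moment per unit volume, A/m.
    grad_B : float
        Field gradient, T/m.
    gamma_init : float
        Initial tension guess, mN/m.
    step : float
        Dimensionless integrator step.
    pointing_noise_um : float
        Landmark pointing error bound used by the identifiability guard, um.
    prescan : bool
        Run the 1D self-similar pre-scan before Nelder-Mead.

    Attributes
    ----------
    gamma_ : ndarray of shape (n_spheroids,)
        Fitted surface tensions, mN/m.
    c_ : ndarray of shape (n_spheroids,)
        Fitted capillary parameters, 1/m^2.
    residual_ : ndarray of shape (n_spheroids,)
        Final objective values.
    results_ : list of TensionResult
        Full per-spheroid diagnostics.
    """

    def __init__(
        self,
        Mv: float = 250.0,
        grad_B: float = 170.0,
        gamma_init: float = 20.0,
        step: float = 1e-3,
        pointing_noise_um: float = 5.0,
        max_iter: int = 500,
        prescan: bool = True,
    ):
        self.Mv = Mv
        self.grad_B = grad_B
        self.gamma_init = gamma_init
        self.step = step
        self.pointing_noise_um = pointing_noise_um
        self.max_iter = max_iter
        self.prescan = prescan

    def _rows_to_landmarks(self, X) -> list[LandmarkSet]:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            out = []
            for _, row in X.iterrows():
                out.append(
                    LandmarkSet(
                        h=row["h_um"],
                        w=row["w_um"],
                        R=row.get("R_um"),
                        V=row.get("V_um3"),
                        L=row.get("L_um"),
                    )
                )
            return out
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "X must be (n_spheroids, 3) with columns h_um, w_um, V_um3"
            )
        return [LandmarkSet(h=r[0], w=r[1], V=r[2]) for r in X]

    def fit(self, X, y=None):
        """Fit each landmark row; per-row failures become NaN with a warning."""
        ctx = MagneticContext(Mv=self.Mv, grad_B=self.grad_B)
        sets = self._rows_to_landmarks(X)
        self.results_ = []
        gam, cs, res = [], [], []
        for i, lm in enumerate(sets):
            try:
                r = fit_capillary(
                    lm,
                    ctx,
                    gamma_init=self.gamma_init,
                    step=self.step,
                    pointing_noise_um=self.pointing_noise_um,
                    max_iter=self.max_iter,
                    prescan=self.prescan,
                )
            except (OutOfMeasurableRangeError, FitConvergenceError) as exc:
                _warnings.warn(f"spheroid {i}: {exc}", stacklevel=2)
                self.results_.append(None)
                gam.append(np.nan)
                cs.append(np.nan)
                res.append(np.nan)
                continue
            self.results_.append(r)
            gam.append(r.gamma)
            cs.append(r.c)
            res.append(r.residual)
        self.gamma_ = np.asarray(gam)
        self.c_ = np.asarray(cs)
        self.residual_ = np.asarray(res)
        self.n_features_in_ = 3
        return self

    def predict_profile(self, index: int = 0):
        """Return the fitted forward profile for one spheroid (diagnostics)."""
        r = self.results_[index]
        if r is None:
            raise FitConvergenceError(f"spheroid {index} did not fit")
        return integrate_profile(ShapeParams(c=r.c, b=r.b, step=self.step))
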