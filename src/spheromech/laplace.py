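"""Forward model: axisymmetric Young-Laplace profiles under a volumetric force.

A nanoparticle-labelled spheroid sitting on a non-adhesive substrate above a
magnet behaves like a heavy sessile drop: the magnetic body force density
``f = Mv * grad(B)`` plays the role of an enhanced gravity and competes with
tissue surface tension ``gamma`` to set the equilibrium shape. With pressure
increasing linearly with depth, the Laplace balance at every point of the
meridian reads

    kappa_mean(s) = 2*b + c*z(s)

where ``b`` is the apex mean curvature (shooting parameter, housing the apex
pressure jump ``2*gamma*b``), ``c = f/gamma`` the capillary parameter (1/m^2,
the inverse-square capillary length) and ``z`` the depth below the apex. In
arc-length (Bashforth-Adams) form, with ``x`` the distance from the symmetry
axis and ``phi`` the tangent angle:

    dx/ds   = cos(phi)
    dz/ds   = sin(phi)
    dphi/ds = 2*b + c*z - sin(phi)/x      (apex limit: dphi/ds -> b)

Integration starts at the apex (x=z=phi=0) and terminates when phi reaches pi,
the non-wetting (180 degree) contact condition at the substrate. The enclosed
volume is carried along as a quadrature state dV/ds = pi*x^2*sin(phi), which
closes the solid of revolution at the contact disc automatically because z is
non-decreasing along the whole meridian.

The integrator is a fixed-step classical Runge-Kutta scheme (numba-compiled)
with a series start at the apex; the termination point is located by bisection
inside the final step. A fixed step makes the 4th-order convergence of h, w
and V directly verifiable by step halving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import IntegrationError

__all__ = [
    "ShapeParams",
    "ShapeSolution",
    "ProfileMetrics",
    "integrate_profile",
    "profile_metrics",
    "solve_shape_for_volume",
]

#: dimensionless arc length (in units of the blended scale 1/sqrt(b^2+c))
#: after which a profile that has not reached phi=pi is declared non-terminating
_MAX_ARC = 40.0


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one forward profile.

    Parameters
    ----------
    c : float
        Capillary parameter f/gamma, 1/m^2. ``c = 0`` gives a sphere.
    b : float
        Apex mean curvature, 1/m (must be > 0). The apex pressure jump is
        ``2*gamma*b``.
    step : float
        Dimensionless arc-length step, in units of ``1/sqrt(b^2 + c)``
        (the smaller of the apex radius and the capillary length).
    """

    c: float
    b: float
    step: float = 1e-3

    def __post_init__(self):
        if not self.c >= 0:
            raise ValueError(f"capillary parameter c must be >= 0, got {self.c}")
        if not self.b > 0:
            raise ValueError(f"apex curvature b must be > 0, got {self.b}")
        if not self.step > 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.step > 0.05:
            raise IntegrationError(
                f"step={self.step} too large to resolve the apex region; "
                "use step <= 0.05"
            )


@njit(cache=True)
def _sin_over_x(phi, x, z, b, c, x_min):
    """sin(phi)/x with its regular pole limit (2b + c z)/2 when a trial
    substep lands on or past the symmetry axis (x <= x_min)."""
    if x > x_min:
        return math.sin(phi) / x
    return 0.5 * (2.0 * b + c * z)


@njit(cache=True)
def _rk4_step(x, z, phi, V, b, c, h, x_min):
    """One classical RK4 step of the Bashforth-Adams system."""
    # k1
    dx1 = math.cos(phi)
    dz1 = math.sin(phi)
    dp1 = 2.0 * b + c * z - _sin_over_x(phi, x, z, b, c, x_min)
    dV1 = math.pi * x * x * math.sin(phi)
    # k2
    x2 = x + 0.5 * h * dx1
    z2 = z + 0.5 * h * dz1
    p2 = phi + 0.5 * h * dp1
    dx2 = math.cos(p2)
    dz2 = math.sin(p2)
    dp2 = 2.0 * b + c * z2 - _sin_over_x(p2, x2, z2, b, c, x_min)
    dV2 = math.pi * x2 * x2 * math.sin(p2)
    # k3
    x3 = x + 0.5 * h * dx2
    z3 = z + 0.5 * h * dz2
    p3 = phi + 0.5 * h * dp2
    dx3 = math.cos(p3)
    dz3 = math.sin(p3)
    dp3 = 2.0 * b + c * z3 - _sin_over_x(p3, x3, z3, b, c, x_min)
    dV3 = math.pi * x3 * x3 * math.sin(p3)
    # k4
    x4 = x + h * dx3
    z4 = z + h * dz3
    p4 = phi + h * dp3
    dx4 = math.cos(p4)
    dz4 = math.sin(p4)
    dp4 = 2.0 * b + c * z4 - _sin_over_x(p4, x4, z4, b, c, x_min)
    dV4 = math.pi * x4 * x4 * math.sin(p4)

    xn = x + h / 6.0 * (dx1 + 2.0 * dx2 + 2.0 * dx3 + dx4)
    zn = z + h / 6.0 * (dz1 + 2.0 * dz2 + 2.0 * dz3 + dz4)
    pn = phi + h / 6.0 * (dp1 + 2.0 * dp2 + 2.0 * dp3 + dp4)
    Vn = V + h / 6.0 * (dV1 + 2.0 * dV2 + 2.0 * dV3 + dV4)
    return xn, zn, pn, Vn


@njit(cache=True)
def _integrate_core(b, c, step):
    """Integrate from the apex until phi = pi.

    Returns (status, s, x, z, phi, V_final, n) where status is 0 on success,
    1 if phi never reached pi within the arc-length budget. Arrays are sized
    n+1 with index 0 the apex point.
    """
    ell = 1.0 / math.sqrt(b * b + c)
    h = step * ell
    x_min = 1e-9 * ell
    max_steps = int(_MAX_ARC / step) + 2

    s_arr = np.empty(max_steps + 1)
    x_arr = np.empty(max_steps + 1)
    z_arr = np.empty(max_steps + 1)
    p_arr = np.empty(max_steps + 1)

    s_arr[0] = 0.0
    x_arr[0] = 0.0
    z_arr[0] = 0.0
    p_arr[0] = 0.0

    # series start one step from the apex (odd/even expansions about s=0):
    # phi = b s + (c b/8) s^3,  x = s - b^2 s^3/6,  z = b s^2/2,  V = pi b s^4/4
    s0 = h
    phi = b * s0 + (c * b / 8.0) * s0 ** 3
    x = s0 - (b * b / 6.0) * s0 ** 3
    z = 0.5 * b * s0 * s0 + (c * b / 8.0 - b ** 3 / 6.0) * s0 ** 4 / 4.0
    V = math.pi * b * s0 ** 4 / 4.0

    s_arr[1] = s0
    x_arr[1] = x
    z_arr[1] = z
    p_arr[1] = phi

    n = 1
    while n < max_steps:
        xn, zn, pn, Vn = _rk4_step(x, z, phi, V, b, c, h, x_min)
        if pn >= math.pi:
            # bisect the step fraction t so that phi(t*h) = pi
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                xm, zm, pm, Vm = _rk4_step(x, z, phi, V, b, c, mid * h, x_min)
                if pm >= math.pi:
                    hi = mid
                else:
                    lo = mid
            t = 0.5 * (lo + hi)
            xn, zn, pn, Vn = _rk4_step(x, z, phi, V, b, c, t * h, x_min)
            n += 1
            s_arr[n] = s_arr[n - 1] + t * h
            x_arr[n] = xn
            z_arr[n] = zn
            p_arr[n] = math.pi
            return 0, s_arr[: n + 1], x_arr[: n + 1], z_arr[: n + 1], p_arr[: n + 1], Vn, n
        x, z, phi, V = xn, zn, pn, Vn
        n += 1
        s_arr[n] = s_arr[n - 1] + h
        x_arr[n] = x
        z_arr[n] = z
        p_arr[n] = phi
    return 1, s_arr[: n + 1], x_arr[: n + 1], z_arr[: n + 1], p_arr[: n + 1], V, n


@dataclass(frozen=True)
class ShapeSolution:
    """Integrated meridian profile, apex at the origin, depth z increasing
    toward the substrate, terminated at tangent angle phi = pi."""

    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    params: ShapeParams
    volume: float = field(repr=False, default=float("nan"))

    def to_frame(self):
        """Profile as a DataFrame with SI columns s_m, x_m, z_m, phi_rad."""
        import pandas as pd

        return pd.DataFrame(
            {"s_m": self.s, "x_m": self.x, "z_m": self.z, "phi_rad": self.phi}
        )


@dataclass(frozen=True)
class ProfileMetrics:
    """Scalar shape descriptors of one equilibrium profile (SI units)."""

    h: float  #: height, m (apex-to-substrate)
    w: float  #: width = 2 * max x, m
    V: float  #: volume of revolution, m^3
    L_model: float  #: model contact radius (x at phi = pi), m

    def to_dict(self) -> dict:
        """Metrics keyed with explicit micrometre units (1 um = 1e-6 m)."""
        return {
            "h_um": self.h * 1e6,
            "w_um": self.w * 1e6,
            "V_um3": self.V * 1e18,
            "L_model_um": self.L_model * 1e6,
        }


def integrate_profile(params: ShapeParams) -> ShapeSolution:
    """Integrate the Bashforth-Adams system from the apex to phi = pi.

    Raises
    ------
    IntegrationError
        If the tangent angle never reaches pi within the arc-length budget
        (40 blended length units) — in practice only for pathological inputs.
    """
    status, s, x, z, phi, V, _ = _integrate_core(params.b, params.c, params.step)
    if status != 0:
        raise IntegrationError(
            f"profile did not reach phi=pi within the arc-length budget "
            f"(b={params.b:g} 1/m, c={params.c:g} 1/m^2); the parameters do "
            "not describe a terminated sessile profile"
        )
    return ShapeSolution(s=s, x=x, z=z, phi=phi, params=params, volume=V)


def profile_metrics(sol: ShapeSolution) -> ProfileMetrics:
    """Height, width, volume and model contact radius of a terminated profile.

    The width is refined by parabolic interpolation around the widest sample
    (the equator, phi = pi/2); height and contact radius come from the
    bisected terminal point; the volume is the RK quadrature of
    ``pi x^2 dz`` along the meridian, closed at the contact disc.
    """
    if sol.phi[-1] < math.pi - 1e-9:
        raise IntegrationError("solution is not terminated at phi=pi")
    i = int(np.argmax(sol.x))
    if 0 < i < len(sol.x) - 1:
        # parabola through the three widest samples
        x0, x1, x2 = sol.x[i - 1], sol.x[i], sol.x[i + 1]
        denom = x0 - 2.0 * x1 + x2
        if denom < 0.0:
            d = 0.5 * (x0 - x2) / denom
            xmax = x1 - 0.25 * (x0 - x2) * d
        else:  # flat to machine precision
            xmax = x1
    else:
        xmax = float(sol.x[i])
    return ProfileMetrics(
        h=float(sol.z[-1]),
        w=2.0 * float(xmax),
        V=float(sol.volume),
        L_model=float(sol.x[-1]),
    )


def _volume_of(b: float, c: float, step: float) -> float:
    status, *_rest, V, _n = _integrate_core(b, c, step)
    if status != 0:
        raise IntegrationError(f"no terminated profile for b={b:g}, c={c:g}")
    return V


def solve_shape_for_volume(
    c: float, V_target: float, step: float = 1e-3, rtol: float = 1e-9
) -> ShapeSolution:
    """Find the profile of capillary parameter ``c`` enclosing ``V_target``.

    Root-finds the apex curvature ``b`` (volume is strictly decreasing in
    ``b`` at fixed ``c``), so the shape family can be parameterized by ``c``
    at conserved spheroid volume.

    Parameters
    ----------
    c : float
        Capillary parameter, 1/m^2 (>= 0).
    V_target : float
        Target volume, m^3 (> 0). For a spheroid of initial radius R this is
        ``(4/3) pi R^3``.

    Raises
    ------
    IntegrationError
        If no bracket for ``b`` can be found (diagnostic carries c, V_target).
    """
    from scipy.optimize import brentq

    if V_target <= 0:
        raise ValueError(f"V_target must be > 0, got {V_target}")
    if c < 0:
        raise ValueError(f"c must be >= 0, got {c}")
    R0 = (3.0 * V_target / (4.0 * math.pi)) ** (1.0 / 3.0)
    if c == 0.0:
        return integrate_profile(ShapeParams(c=0.0, b=1.0 / R0, step=step))

    def resid(logb):
        return math.log(_volume_of(math.exp(logb), c, step) / V_target)

    lo = hi = math.log(1.0 / R0)
    flo = fhi = resid(lo)
    # volume decreases with b: expand until the residual changes sign
    for _ in range(80):
        if flo > 0 and fhi < 0:
            break
        if fhi >= 0:
            hi += math.log(2.0)
            fhi = resid(hi)
        if flo <= 0:
            lo -= math.log(2.0)
            flo = resid(lo)
    else:
        raise IntegrationError(
            f"could not bracket apex curvature for c={c:g} 1/m^2, "
            f"V_target={V_target:g} m^3"
        )
    logb = brentq(resid, lo, hi, xtol=1e-13, rtol=8.9e-16)
    sol = integrate_profile(ShapeParams(c=c, b=math.exp(logb), step=step))
    if abs(sol.volume - V_target) / V_target > max(rtol, 1e-6):
        raise IntegrationError(
            f"volume match failed for c={c:g}, V_target={V_target:g}: "
            f"got {sol.volume:g}"
        )
    return sol
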