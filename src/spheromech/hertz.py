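"""Young's modulus of a spheroid from its contact-zone radius (Hertz theory).

During magnetic flattening the initial elastic response presses the spheroid
against the substrate over a contact disc of radius ``L``. Treating the
aggregate as an incompressible Hertzian elastic sphere of initial radius
``R`` loaded by the total magnetic force ``(4/3) pi R^3 f``, the modulus is

    E = (1 - sigma^2) * pi * f * R^4 / L^3,

with ``sigma`` the Poisson ratio (1/2 for an incompressible tissue, in which
case the prefactor is (3/4) pi). ``L`` is a direct image measurement (half
the contact-zone chord); it is never derived from the Laplace fit — surface
tension and elasticity come from independent features of the same picture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .context import MagneticContext

__all__ = ["ElasticityResult", "young_modulus", "contact_radius_for_modulus"]


@dataclass(frozen=True)
class ElasticityResult:
    """Hertz modulus with the geometry and force density it came from."""

    E: float  #: Young's modulus, Pa
    sigma: float  #: Poisson ratio
    L: float  #: contact radius, um
    R: float  #: initial radius, um
    f: float  #: force density, N/m^3


def _check_sigma(sigma: float) -> None:
    if not 0.0 <= sigma < 1.0:
        raise ValueError(f"Poisson ratio must be in [0, 1), got {sigma}")


def young_modulus(
    R: float,
    L: float,
    ctx: MagneticContext,
    sigma: float = 0.5,
    w: float | None = None,
) -> ElasticityResult:
    """Young's modulus E = (1-sigma^2) pi f R^4 / L^3.

    Parameters
    ----------
    R : float
        Initial spheroid radius, um.
    L : float
        Contact-zone radius, um.
    ctx : MagneticContext
        Provides the force density f = Mv*grad(B).
    sigma : float
        Poisson ratio; 1/2 (incompressible) by default.
    w : float, optional
        Measured width, um. If given, ``L > w/2`` raises a geometry warning
        (the contact disc cannot be wider than the spheroid).
    """
    if not R > 0:
        raise ValueError(f"R must be > 0, got {R}")
    if not L > 0:
        raise ZeroDivisionError(f"contact radius L must be > 0, got {L}")
    _check_sigma(sigma)
    if w is not None and L > w / 2.0:
        warnings.warn(
            f"L={L:g} um exceeds half the measured width ({w/2:g} um): "
            "geometrically impossible contact radius",
            stacklevel=2,
        )
    f = ctx.force_density
    R_m, L_m = R * 1e-6, L * 1e-6
    E = (1.0 - sigma**2) * 3.141592653589793 * f * R_m**4 / L_m**3
    return ElasticityResult(E=E, sigma=sigma, L=L, R=R, f=f)


def contact_radius_for_modulus(
    E: float, R: float, ctx: MagneticContext, sigma: float = 0.5
) -> float:
    """Contact radius L (um) producing modulus ``E`` — the algebraic inverse.

    L = [(1-sigma^2) pi f R^4 / E]^(1/3); used to build synthetic fixtures
    and round-trip checks.
    """
    if not E > 0:
        raise ValueError(f"E must be > 0, got {E}")
    if not R > 0:
        raise ValueError(f"R must be > 0, got {R}")
    _check_sigma(sigma)
    f = ctx.force_density
    R_m = R * 1e-6
    L_m = ((1.0 - sigma**2) * 3.141592653589793 * f * R_m**4 / E) ** (1.0 / 3.0)
    return L_m * 1e6
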