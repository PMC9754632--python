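"""Magnetization context: the volumetric body force acting on a labelled spheroid.

Cells loaded with superparamagnetic nanoparticles and placed above a permanent
magnet experience a body force per unit volume f = Mv * grad(B), where Mv is the
magnetic moment per unit volume of the aggregate (A/m, measured by VSM for each
experiment) and grad(B) the field-gradient magnitude (T/m). This force plays the
role of an enhanced, tunable gravity: it is what flattens the spheroid against
the non-adhesive substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidContextError


@dataclass(frozen=True)
class MagneticContext:
    """Magnetization and field-gradient parameters defining the body force.

    Parameters
    ----------
    Mv : float
        Magnetic moment per unit volume of the aggregate, A/m. Typical
        experimental values range from 150 to 500 A/m.
    grad_B : float
        Field-gradient magnitude, T/m (170 T/m for a 6 mm cylindrical NdFeB
        magnet averaged over the working distance).
    B : float, optional
        Field magnitude in T. Informational only; the force depends on the
        gradient, not the field.
    """

    Mv: float
    grad_B: float
    B: float | None = None

    def __post_init__(self):
        if not (self.Mv > 0 and self.grad_B > 0):
            raise InvalidContextError(
                f"Mv and grad_B must be strictly positive, got Mv={self.Mv}, "
                f"grad_B={self.grad_B}"
            )

    @property
    def force_density(self) -> float:
        """Body-force density f = Mv * grad(B), N/m^3."""
        return self.Mv * self.grad_B


def force_density(ctx: MagneticContext) -> float:
    """Return the volumetric force density f = Mv * grad(B) in N/m^3.

    For the experimental range Mv in [150, 500] A/m at grad(B) = 170 T/m this
    spans 2.55e4 to 8.5e4 N/m^3.
    """
    if not isinstance(ctx, MagneticContext):
        ctx = MagneticContext(*ctx)
    return ctx.force_density
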