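"""Decomposing tissue surface tension into cell-scale interfacial tensions.

Under the differential interfacial tension picture, the tissue surface
tension ``gamma`` of an aggregate arises from the cortical tension ``T_CM``
of cells at the cell-medium interface and the effective tension of the
cell-cell contact, the combination ``2*T_CC - J_CC`` of doubled cell-cell
cortical tension and intercellular adhesion energy:

    gamma = T_CM - (2*T_CC - J_CC)/2                       (energy balance)
    2*T_CM*cos(alpha/2) = 2*T_CC - J_CC                    (contact-line
                                                            equilibrium)

where ``alpha`` is the contact angle between the free surfaces of two
neighbouring cells at the aggregate surface (180 degrees = fully spread,
flat cells). Solving the two relations gives

    T_CM        = gamma / (1 - cos(alpha/2))
    2T_CC-J_CC  = 2*gamma*cos(alpha/2) / (1 - cos(alpha/2)).

Only the combination ``2*T_CC - J_CC`` is identifiable from (gamma, alpha);
the adhesion energy and the cell-cell cortical tension are never separated.
For cohesive aggregates with no surface cell engulfing its neighbours, the
effective cell-cell tension is strictly smaller than ``2*T_CM``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateModelError

__all__ = [
    "InterfacialTensions",
    "AngleSummary",
    "decompose_tensions",
    "summarize_angles",
]


@dataclass(frozen=True)
class InterfacialTensions:
    gamma: float  #: tissue surface tension, mN/m
    alpha: float  #: cell-cell contact angle, degrees (180 = flat)
    T_CM: float  #: cortical tension at the cell-medium interface, mN/m
    T_CC_eff: float  #: effective cell-cell tension 2*T_CC - J_CC, mN/m

    def to_dict(self) -> dict:
        return {
            "T_CM_mN_per_m": self.T_CM,
            "T_CC_eff_mN_per_m": self.T_CC_eff,
            "gamma_mN_per_m": self.gamma,
            "alpha_deg": self.alpha,
        }


@dataclass(frozen=True)
class AngleSummary:
    mean_alpha: float  #: degrees
    sd_alpha: float  #: sample standard deviation, degrees
    n: int


def decompose_tensions(gamma: float, alpha: float) -> InterfacialTensions:
    """Cell-medium and effective cell-cell tensions from (gamma, alpha).

    Parameters
    ----------
    gamma : float
        Tissue surface tension, mN/m (> 0).
    alpha : float
        Contact angle between neighbouring surface cells, degrees, in
        (0, 180]. ``alpha -> 0`` makes both tensions diverge (cos(alpha/2)
        -> 1) and is rejected.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if not 0.0 < alpha <= 180.0:
        raise ValueError(f"contact angle must be in (0, 180] degrees, got {alpha}")
    half = math.radians(alpha) / 2.0
    cos_half = math.cos(half)
    denom = 1.0 - cos_half
    if denom < 1e-12:
        raise DegenerateModelError(
            f"alpha={alpha} deg too close to 0: tensions diverge as "
            "cos(alpha/2) -> 1"
        )
    T_CM = gamma / denom
    T_CC_eff = 2.0 * gamma * cos_half / denom
    return InterfacialTensions(gamma=gamma, alpha=alpha, T_CM=T_CM, T_CC_eff=T_CC_eff)


def summarize_angles(angles) -> AngleSummary:
    """Mean and sample standard deviation of measured junction angles.

    Each angle must lie in (0, 180] degrees; an out-of-range entry is
    rejected with its index.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size == 0:
        raise ValueError("empty angle list")
    bad = np.where(~((arr > 0.0) & (arr <= 180.0) & np.isfinite(arr)))[0]
    if bad.size:
        raise ValueError(
            f"angle at index {int(bad[0])} out of range (0, 180]: {arr[bad[0]]}"
        )
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return AngleSummary(mean_alpha=float(arr.mean()), sd_alpha=sd, n=int(arr.size))
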