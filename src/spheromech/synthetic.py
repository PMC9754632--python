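"""Seeded synthetic fixtures emulating the magnetic-tensiometry regime.

Every analysis stage of the package is testable without microscope data:
this module generates equilibrium Laplace profiles, pointed landmarks with
pointing noise, rough cryosection-like contours and dose-response tables,
all deterministically from an integer seed. The default generating values
mirror the experimental regime: spheroids of 530 um initial radius,
Mv = 250 A/m in a 170 T/m gradient (force density 4.25e4 N/m^3), surface
tension 21 mN/m and modulus 100 Pa for the reference condition, and a
pointing error on landmark coordinates of 2-5 um (modelled as uniform on
+/- the bound, independently per landmark, since only the error magnitude
is known).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .context import MagneticContext
from .doseresponse import DoseResponseFit, hill_eval
from .hertz import contact_radius_for_modulus
from .laplace import profile_metrics, solve_shape_for_volume
from .tension import LandmarkSet

__all__ = [
    "FixtureConfig",
    "ProfileFixture",
    "make_profile_dataset",
    "make_dose_dataset",
    "make_rough_contour",
    "write_fixture",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Generating parameters of one synthetic condition.

    Defaults reproduce the reference condition: gamma = 21 mN/m and
    E = 100 Pa at Mv = 250 A/m, grad(B) = 170 T/m, R = 530 um.
    """

    seed: int = 0
    gamma: float = 21.0  #: surface tension, mN/m
    E: float = 100.0  #: Young's modulus, Pa
    Mv: float = 250.0  #: A/m (experimental range 150-500)
    grad_B: float = 170.0  #: T/m
    R: float = 530.0  #: initial radius, um
    pointing_noise: float = 5.0  #: landmark noise bound, um (2-5 typical)
    noise_on_L: bool = True
    n_replicates: int = 8
    doses: tuple = (0.0, 1.0, 3.0, 10.0, 30.0, 80.0, 160.0)  #: uM
    response_cv: float = 0.1  #: relative response noise
    n_contour: int = 400
    step: float = 1e-3

    def __post_init__(self):
        if not (self.gamma > 0 and self.E > 0 and self.R > 0):
            raise ValueError("gamma, E and R must be positive")
        if self.pointing_noise < 0:
            raise ValueError("pointing_noise must be >= 0")

    @property
    def ctx(self) -> MagneticContext:
        return MagneticContext(Mv=self.Mv, grad_B=self.grad_B)

    def manifest(self) -> dict:
        d = asdict(self)
        d["doses"] = list(self.doses)
        d["noise_model"] = "uniform on +/- pointing_noise, independent per landmark"
        d["force_density_N_per_m3"] = self.ctx.force_density
        return d


@dataclass(frozen=True)
class ProfileFixture:
    """A generated profile with its noisy landmarks and embedded truth."""

    contour: np.ndarray  #: (N, 2) side-profile points (x_um, z_um)
    landmarks: LandmarkSet  #: noisy pointed landmarks, um
    truth: dict  #: generating gamma (mN/m), E (Pa), L (um), h/w/V (noise-free)
    manifest: dict = field(repr=False, default_factory=dict)


def make_profile_dataset(cfg: FixtureConfig) -> ProfileFixture:
    """Forward-generate one equilibrium profile and its pointed landmarks.

    The profile is the Laplace shape at c = f/gamma with the volume of the
    initial sphere of radius R; the contact radius L is placed from the
    configured modulus through the inverse Hertz relation; h, w (and L)
    are then perturbed by the pointing-noise model.
    """
    rng = np.random.default_rng(cfg.seed)
    ctx = cfg.ctx
    f = ctx.force_density
    c = f / (cfg.gamma * 1e-3)
    V = (4.0 / 3.0) * math.pi * (cfg.R * 1e-6) ** 3
    sol = solve_shape_for_volume(c, V, step=cfg.step)
    m = profile_metrics(sol)
    L_true = contact_radius_for_modulus(cfg.E, cfg.R, ctx)

    # side-profile contour in um, right half mirrored to the left,
    # image convention (z grows downward, apex at z=0)
    n_half = max(cfg.n_contour // 2, 8)
    idx = np.linspace(0, len(sol.s) - 1, n_half).round().astype(int)
    xr, zr = sol.x[idx] * 1e6, sol.z[idx] * 1e6
    contour = np.vstack(
        [np.c_[-xr[::-1], zr[::-1]], np.c_[xr[1:], zr[1:]]]
    )

    b = cfg.pointing_noise
    noise = rng.uniform(-b, b, size=3) if b > 0 else np.zeros(3)
    h_meas = m.h * 1e6 + noise[0]
    w_meas = m.w * 1e6 + noise[1]
    L_meas = L_true + (noise[2] if cfg.noise_on_L else 0.0)
    landmarks = LandmarkSet(h=h_meas, w=w_meas, R=cfg.R, L=max(L_meas, 1e-6))
    truth = {
        "gamma_mN_per_m": cfg.gamma,
        "E_Pa": cfg.E,
        "L_um": L_true,
        "c_per_m2": c,
        "h_um": m.h * 1e6,
        "w_um": m.w * 1e6,
        "V_um3": m.V * 1e18,
    }
    return ProfileFixture(
        contour=contour, landmarks=landmarks, truth=truth, manifest=cfg.manifest()
    )


def make_dose_dataset(cfg: FixtureConfig, params: DoseResponseFit) -> pd.DataFrame:
    """Simulated dose-response table with Gaussian relative noise.

    Returns a DataFrame with columns ``dose_uM``, ``response``,
    ``replicate`` (n_replicates rows per dose, seeded).
    """
    if len(cfg.doses) == 0:
        raise ValueError("empty dose set")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for dose in cfg.doses:
        mu = hill_eval(float(dose), params)
        eps = rng.standard_normal(cfg.n_replicates)
        for rep, e in enumerate(eps):
            rows.append(
                {
                    "dose_uM": float(dose),
                    "response": mu * (1.0 + cfg.response_cv * e),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def make_rough_contour(
    cfg: FixtureConfig,
    r: float,
    sigma_r: float,
    n: int = 500,
    arc_span_deg: float = 300.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Points on a circular arc with i.i.d. radial Gaussian offsets.

    Parameters
    ----------
    r : float
        Arc radius, um (> 0).
    sigma_r : float
        Radial offset standard deviation, um (>= 0); the expected Rq.
    n : int
        Number of points (>= 3).
    """
    if not r > 0:
        raise ValueError(f"radius must be > 0, got {r}")
    if sigma_r < 0:
        raise ValueError(f"sigma_r must be >= 0, got {sigma_r}")
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    rng = np.random.default_rng(cfg.seed)
    span = math.radians(arc_span_deg)
    theta = np.linspace(-span / 2.0, span / 2.0, n)
    radii = r + (sigma_r * rng.standard_normal(n) if sigma_r > 0 else 0.0)
    return np.c_[
        center[0] + radii * np.cos(theta), center[1] + radii * np.sin(theta)
    ]


def write_fixture(fix: ProfileFixture, directory) -> None:
    """Write a fixture as contour.csv, landmarks.json, truth.json, manifest.yaml."""
    import pathlib

    import yaml

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(fix.contour, columns=["x_um", "z_um"]).to_csv(
        d / "contour.csv", index=False
    )
    lm = fix.landmarks
    payload = {"h_um": lm.h, "w_um": lm.w, "R_um": lm.R, "L_um": lm.L}
    (d / "landmarks.json").write_text(json.dumps(payload, indent=1))
    (d / "truth.json").write_text(json.dumps(fix.truth, indent=1))
    (d / "manifest.yaml").write_text(yaml.safe_dump(fix.manifest, sort_keys=True))
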