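"""File formats, landmark extraction from contours, and the batch pipeline.

Coordinate convention for all contour files: x grows rightward, z grows
downward (image convention), units micrometres after applying any pixel
size; the substrate is at maximum z. File formats are plain text: contour
CSV (``x_um,z_um``), landmarks JSON (``h_um``, ``w_um``, ``R_um`` or
``V_um3``, optional ``L_um``), angle CSV (``alpha_deg``), dose CSV
(``dose_uM,response``), run configuration YAML, and versioned results JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import pathlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .context import MagneticContext
from .exceptions import SpheromechError
from .hertz import young_modulus
from .interfaces import decompose_tensions, summarize_angles
from .tension import LandmarkSet, fit_capillary

__all__ = [
    "RunConfig",
    "landmarks_from_contour",
    "run_pipeline",
    "read_contour_csv",
    "read_landmarks_json",
    "write_results_json",
    "contour_from_mask",
]

log = logging.getLogger("spheromech")

RESULTS_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Run configuration mirroring the tensiometer front-end inputs."""

    Mv_A_per_m: float = 250.0
    gradB_T_per_m: float = 170.0
    B_T: float | None = None
    pixel_size_um: float = 1.0
    sigma_poisson: float = 0.5
    gamma_init_mN_per_m: float = 20.0
    noise_bound_um: float = 5.0

    def __post_init__(self):
        for name in ("Mv_A_per_m", "gradB_T_per_m", "pixel_size_um",
                     "gamma_init_mN_per_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.sigma_poisson < 1.0:
            raise ValueError("sigma_poisson must be in [0, 1)")

    @property
    def ctx(self) -> MagneticContext:
        return MagneticContext(
            Mv=self.Mv_A_per_m, grad_B=self.gradB_T_per_m, B=self.B_T
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = pathlib.Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------- contours


def read_contour_csv(path, pixel_size_um: float = 1.0) -> np.ndarray:
    """Read an (N, 2) contour from a CSV with header ``x_um,z_um``."""
    df = pd.read_csv(path)
    if not {"x_um", "z_um"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns x_um,z_um")
    return df[["x_um", "z_um"]].to_numpy(dtype=float) * pixel_size_um


def _angular_coverage_deg(pts: np.ndarray) -> float:
    """Fraction of the full turn (degrees) covered around the centroid."""
    c = pts.mean(axis=0)
    ang = np.degrees(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
    bins = np.zeros(72, dtype=bool)  # 5-degree sectors
    bins[((ang + 180.0) / 5.0).astype(int) % 72] = True
    return float(bins.sum() * 5.0)


def landmarks_from_contour(
    contour, substrate_tol_um: float = 2.0
) -> LandmarkSet:
    """Automated landmark pointing on a side-profile contour.

    Height is the z extent, width the x extent, and the contact radius L is
    half the chord of the run of points lying within ``substrate_tol_um`` of
    the substrate line (the maximum-z row). The conserved volume is
    estimated from the solid of revolution of the profile about its
    vertical mid-axis.

    Raises
    ------
    ValueError
        Fewer than 10 points, or an open contour covering less than 180
        degrees around its centroid (insufficient coverage to place the
        landmarks).
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be (N, 2)")
    if len(pts) < 10:
        raise ValueError(f"insufficient coverage: only {len(pts)} contour points")
    cov = _angular_coverage_deg(pts)
    if cov < 180.0:
        raise ValueError(
            f"insufficient coverage: contour spans {cov:.0f} deg < 180 deg"
        )
    x, z = pts[:, 0], pts[:, 1]
    h = float(z.max() - z.min())
    w = float(x.max() - x.min())
    x0 = 0.5 * (x.max() + x.min())
    bottom = pts[z >= z.max() - substrate_tol_um]
    L = 0.5 * float(bottom[:, 0].max() - bottom[:, 0].min()) if len(bottom) else 0.0

    # volume of revolution about the mid-axis: average radius per depth
    r = np.abs(x - x0)
    order = np.argsort(z)
    zs, rs = z[order], r[order]
    zu, inv = np.unique(zs.round(9), return_inverse=True)
    r_mean = np.zeros_like(zu)
    counts = np.bincount(inv)
    np.add.at(r_mean, inv, rs)
    r_mean /= counts
    V = float(np.trapezoid(math.pi * r_mean**2, zu))
    return LandmarkSet(h=h, w=w, V=V, L=L if L > 0 else None)


def contour_from_mask(mask, pixel_size_um: float = 1.0) -> np.ndarray:
    """Boundary contour (um) of a binary mask — convenience plumbing for
    image inputs; threshold + largest-component extraction lives with the
    caller. Requires scikit-image."""
    from skimage import measure

    mask = np.asarray(mask).astype(bool)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found in mask")
    longest = max(contours, key=len)
    # rows are (row, col) = (z, x); flip to (x, z)
    return np.c_[longest[:, 1], longest[:, 0]] * pixel_size_um


# ---------------------------------------------------------------- pipeline


def read_landmarks_json(path) -> LandmarkSet:
    data = json.loads(pathlib.Path(path).read_text())
    return LandmarkSet(
        h=data["h_um"],
        w=data["w_um"],
        R=data.get("R_um"),
        V=data.get("V_um3"),
        L=data.get("L_um"),
    )


def _coerce_record(rec) -> tuple[LandmarkSet, dict]:
    """Accept a LandmarkSet, a mapping, or a fixture directory path."""
    extra: dict = {}
    if isinstance(rec, LandmarkSet):
        return rec, extra
    if isinstance(rec, (str, pathlib.Path)):
        d = pathlib.Path(rec)
        lm = read_landmarks_json(d / "landmarks.json" if d.is_dir() else d)
        return lm, extra
    if isinstance(rec, dict):
        extra = {k: rec[k] for k in ("alpha_deg", "name") if k in rec}
        lm = LandmarkSet(
            h=rec["h_um"],
            w=rec["w_um"],
            R=rec.get("R_um"),
            V=rec.get("V_um3"),
            L=rec.get("L_um"),
        )
        return lm, extra
    raise TypeError(f"cannot interpret input record of type {type(rec)!r}")


def run_pipeline(config: RunConfig, inputs) -> dict:
    """Run tension -> modulus -> decomposition over a batch of spheroids.

    Per-spheroid failures are recorded and skipped; the batch never aborts.
    Returns a versioned results document with one record per spheroid, a
    min/median/max summary, and provenance (config hash, package version).
    """
    inputs = list(inputs)
    if not inputs:
        raise ValueError("empty input set")
    from . import __version__

    ctx = config.ctx
    records = []
    for i, rec in enumerate(inputs):
        entry: dict = {"index": i}
        try:
            lm, extra = _coerce_record(rec)
            entry.update(extra)
            log.info("spheroid %d: fitting tension", i)
            t = fit_capillary(
                lm,
                ctx,
                gamma_init=config.gamma_init_mN_per_m,
                pointing_noise_um=config.noise_bound_um,
            )
            entry["gamma_mN_per_m"] = t.gamma
            entry["c_per_m2"] = t.c
            entry["residual"] = t.residual
            entry["warnings"] = list(t.warnings)
            if lm.L is not None:
                e = young_modulus(
                    lm.radius_um, lm.L, ctx, sigma=config.sigma_poisson, w=lm.w
                )
                entry["E_Pa"] = e.E
            if "alpha_deg" in extra:
                summ = summarize_angles(np.atleast_1d(extra["alpha_deg"]))
                dec = decompose_tensions(t.gamma, summ.mean_alpha)
                entry["T_CM_mN_per_m"] = dec.T_CM
                entry["T_CC_eff_mN_per_m"] = dec.T_CC_eff
                entry["mean_alpha_deg"] = summ.mean_alpha
            entry["ok"] = True
        except (SpheromechError, ValueError, KeyError) as exc:
            log.warning("spheroid %d failed: %s", i, exc)
            entry["ok"] = False
            entry["error"] = str(exc)
        records.append(entry)

    def _summary(key):
        vals = [r[key] for r in records if r.get("ok") and key in r]
        if not vals:
            return None
        return {
            "min": float(np.min(vals)),
            "median": float(np.median(vals)),
            "max": float(np.max(vals)),
            "n": len(vals),
        }

    return {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "results": records,
        "summary": {
            "gamma_mN_per_m": _summary("gamma_mN_per_m"),
            "E_Pa": _summary("E_Pa"),
        },
        "provenance": {
            "config_hash": config.content_hash(),
            "package_version": __version__,
        },
    }


def write_results_json(doc: dict, path) -> None:
    pathlib.Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
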