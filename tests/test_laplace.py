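"""Forward Young-Laplace shape model: limits, residuals, convergence order."""

import math

import numpy as np
import pytest

from spheromech import (
    MagneticContext,
    ShapeParams,
    force_density,
    integrate_profile,
    profile_metrics,
    solve_shape_for_volume,
)
from spheromech.exceptions import IntegrationError, InvalidContextError

from conftest import R_M, V_SPHERE


class TestForceDensity:
    @pytest.mark.parametrize(
        "Mv, gradB, expected",
        [
            (500.0, 170.0, 8.5e4),  # upper bound of the experimental range
            (250.0, 170.0, 4.25e4),
            (150.0, 170.0, 2.55e4),  # lower bound
        ],
    )
    def test_values(self, Mv, gradB, expected):
        assert force_density(MagneticContext(Mv=Mv, grad_B=gradB)) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("Mv, gradB", [(0.0, 170.0), (-5.0, 170.0), (250.0, 0.0)])
    def test_invalid_context_rejected(self, Mv, gradB):
        with pytest.raises(InvalidContextError):
            MagneticContext(Mv=Mv, grad_B=gradB)


class TestZeroForceSphere:
    def test_sphere_metrics(self, sphere_solution):
        m = profile_metrics(sphere_solution)
        assert m.h == pytest.approx(2 * R_M, rel=1e-6)
        assert m.w == pytest.approx(2 * R_M, rel=1e-6)
        assert m.V == pytest.approx(V_SPHERE, rel=1e-6)
        # c=0 implies h=w and V=(pi/6) h^3
        assert m.V == pytest.approx(math.pi / 6 * m.h**3, rel=1e-6)
        assert m.L_model == pytest.approx(0.0, abs=1e-9)

    def test_solution_boundary_conditions(self, sphere_solution):
        s = sphere_solution
        assert s.x[0] == 0.0 and s.z[0] == 0.0 and s.phi[0] == 0.0
        assert s.phi[-1] == pytest.approx(math.pi, abs=1e-12)
        assert np.all(np.diff(s.phi) > 0), "tangent angle must be strictly increasing"
        assert np.all(np.diff(s.z) >= 0), "depth must be non-decreasing"


class TestLaplaceResidual:
    @pytest.mark.parametrize(
        "c, b", [(0.0, 1 / R_M), (2.0e6, 2000.0), (1.0e7, 1500.0)]
    )
    def test_pointwise_curvature_balance(self, c, b):
        """Mean curvature dphi/ds + sin(phi)/x equals 2b + c z along the
        profile (central differences on the uniformly spaced samples; the
        bisected terminal step is excluded)."""
        sol = integrate_profile(ShapeParams(c=c, b=b))
        dphi = (sol.phi[2:-1] - sol.phi[:-3]) / (sol.s[2:-1] - sol.s[:-3])
        interior = slice(1, -2)
        kappa = dphi + np.sin(sol.phi[interior]) / sol.x[interior]
        target = 2 * b + c * sol.z[interior]
        assert np.max(np.abs(kappa - target)) / (2 * b) < 1e-5

    def test_residual_decreases_with_step(self):
        errs = []
        for step in (4e-3, 2e-3, 1e-3):
            sol = integrate_profile(ShapeParams(c=2.0e6, b=2000.0, step=step))
            dphi = (sol.phi[2:-1] - sol.phi[:-3]) / (sol.s[2:-1] - sol.s[:-3])
            kappa = dphi + np.sin(sol.phi[1:-2]) / sol.x[1:-2]
            errs.append(np.max(np.abs(kappa - (2 * 2000.0 + 2.0e6 * sol.z[1:-2]))))
        assert errs[0] > errs[1] > errs[2]
        # finite-difference residual is 2nd order in the step
        assert errs[0] / errs[1] > 3.0


class TestConvergenceOrder:
    def test_step_halving_richardson(self):
        """h, w, V converge at (at least) 4th order under step halving."""
        metrics = {}
        for step in (4e-3, 2e-3, 1e-3):
            m = profile_metrics(
                integrate_profile(ShapeParams(c=2.0e6, b=2000.0, step=step))
            )
            metrics[step] = np.array([m.h, m.w, m.V])
        d_coarse = np.abs(metrics[4e-3] - metrics[2e-3])
        d_fine = np.abs(metrics[2e-3] - metrics[1e-3])
        # 4th order: successive differences shrink by ~16; allow 8
        assert np.all(d_fine <= d_coarse / 8.0 + 1e-15)

    def test_against_independent_adaptive_integrator(self):
        """Cross-check the fixed-step scheme against scipy's adaptive RK
        on the same initial-value problem."""
        from scipy.integrate import solve_ivp

        b, c = 2000.0, 2.0e6

        def rhs(s, y):
            x, z, phi = y
            return [np.cos(phi), np.sin(phi), 2 * b + c * z - np.sin(phi) / x]

        s0 = 1e-9
        y0 = [s0, b * s0**2 / 2, b * s0]
        ev = lambda s, y: y[2] - np.pi
        ev.terminal = True
        ref = solve_ivp(rhs, [s0, 1.0], y0, rtol=1e-11, atol=1e-15, events=ev,
                        dense_output=True)
        m = profile_metrics(integrate_profile(ShapeParams(c=c, b=b)))
        assert m.h == pytest.approx(ref.y_events[0][0][1], rel=1e-7)
        assert m.L_model == pytest.approx(ref.y_events[0][0][0], rel=1e-6)


class TestShapeFamily:
    def test_monotonicity_at_fixed_volume(self):
        """At conserved volume, height decreases and width increases with c."""
        hs, ws = [], []
        for c in (0.0, 1e5, 1e6, 1e7):
            m = profile_metrics(solve_shape_for_volume(c, V_SPHERE))
            hs.append(m.h)
            ws.append(m.w)
        assert np.all(np.diff(hs) < 0)
        assert np.all(np.diff(ws) > 0)

    def test_flattened_below_sphere_height(self):
        sol = solve_shape_for_volume(2.024e6, V_SPHERE)
        assert sol.volume == pytest.approx(V_SPHERE, rel=1e-6)
        assert profile_metrics(sol).h < 2 * R_M

    def test_puddle_asymptote(self):
        """h -> 2/sqrt(c) (twice the capillary length) as V grows."""
        c = 1.0e6
        for scale, tol in ((1000.0, 0.05), (8000.0, 0.02)):
            m = profile_metrics(solve_shape_for_volume(c, V_SPHERE * scale))
            assert m.h == pytest.approx(2.0 / math.sqrt(c), rel=tol)

    def test_scale_invariance(self):
        """Rescaling lengths by lambda with c -> c/lambda^2 maps solutions
        onto each other in dimensionless form."""
        lam = 3.7
        m1 = profile_metrics(integrate_profile(ShapeParams(c=2.0e6, b=2000.0)))
        m2 = profile_metrics(
            integrate_profile(ShapeParams(c=2.0e6 / lam**2, b=2000.0 / lam))
        )
        assert m2.h == pytest.approx(lam * m1.h, rel=1e-10)
        assert m2.w == pytest.approx(lam * m1.w, rel=1e-10)
        assert m2.V == pytest.approx(lam**3 * m1.V, rel=1e-10)

    def test_width_dominates_contact_radius(self, flattened_solution):
        m = profile_metrics(flattened_solution)
        assert m.w >= 2 * m.L_model


class TestErrors:
    def test_step_too_large(self):
        with pytest.raises(IntegrationError):
            ShapeParams(c=0.0, b=1000.0, step=0.5)

    @pytest.mark.parametrize("c, b", [(-1.0, 1000.0), (1e6, 0.0), (1e6, -5.0)])
    def test_invalid_params(self, c, b):
        with pytest.raises(ValueError):
            ShapeParams(c=c, b=b)

    def test_volume_solver_rejects_bad_targets(self):
        with pytest.raises(ValueError):
            solve_shape_for_volume(1e6, -1.0)

    def test_export_roundtrip(self, flattened_solution, tmp_path):
        df = flattened_solution.to_frame()
        assert list(df.columns) == ["s_m", "x_m", "z_m", "phi_rad"]
        p = tmp_path / "profile.csv"
        df.to_csv(p, index=False)
        import pandas as pd

        back = pd.read_csv(p)
        assert np.allclose(back["z_m"], df["z_m"], rtol=1e-12)
        keys = profile_metrics(flattened_solution).to_dict()
        assert set(keys) == {"h_um", "w_um", "V_um3", "L_model_um"}
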