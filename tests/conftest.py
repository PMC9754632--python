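import math

import pytest

from spheromech import (
    MagneticContext,
    ShapeParams,
    integrate_profile,
    profile_metrics,
    solve_shape_for_volume,
)

R_UM = 530.0
R_M = R_UM * 1e-6
V_SPHERE = (4.0 / 3.0) * math.pi * R_M**3
F_REF = 4.25e4  # N/m^3: Mv=250 A/m, grad(B)=170 T/m


@pytest.fixture(scope="session")
def ctx_ref():
    """Reference magnetization context (Mv=250 A/m, grad(B)=170 T/m)."""
    return MagneticContext(Mv=250.0, grad_B=170.0)


@pytest.fixture(scope="session")
def sphere_solution():
    """Zero-force solution for a 530 um sphere."""
    return integrate_profile(ShapeParams(c=0.0, b=1.0 / R_M))


@pytest.fixture(scope="session")
def flattened_solution():
    """Moderately flattened reference shape (c=2e6 1/m^2, b=2000 1/m)."""
    return integrate_profile(ShapeParams(c=2.0e6, b=2000.0))


@pytest.fixture(scope="session")
def fig_shape_metrics(ctx_ref):
    """Noise-free landmarks of the gamma=21 mN/m reference condition."""
    c = ctx_ref.force_density / 21.0e-3
    sol = solve_shape_for_volume(c, V_SPHERE)
    return profile_metrics(sol)
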