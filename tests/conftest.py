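import numpy as np
import pytest

import fluxpolytope as fp


@pytest.fixture
def two_flux_model():
    return fp.synthetic_data.make_two_flux_model()


@pytest.fixture
def two_flux_poly(two_flux_model):
    return fp.build_polytope(two_flux_model)


@pytest.fixture
def unit_box_2d():
    poly, truth = fp.synthetic_data.make_box_polytope([1.0, 1.0])
    return poly, truth


@pytest.fixture
def random_model():
    model, v_star = fp.synthetic_data.make_random_network(5, 8, density=0.5, seed=42)
    return model, v_star


def rotated_box_polytope(sides, angle_deg=30.0):
    """Anisotropic box rotated in the plane: constraints |R v - c| <= s/2."""
    s = np.asarray(sides, float)
    t = np.deg2rad(angle_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    c_box = s / 2.0
    A = np.vstack([R, -R])
    b = np.concatenate([s, np.zeros(2)])
    anchor = R.T @ c_box
    poly = fp.FluxPolytope(
        G=np.eye(2), A_ineq=A, b_ineq=b, anchor=anchor, reaction_ids=["u0", "u1"]
    )
    return poly, R
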