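"""Shared fixtures: independent cell-equilibrium oracle and small meshes."""

import numpy as np
import pytest
from scipy.optimize import brentq

import cardioem as cm
from cardioem.ionic import GATE_NAMES, CellState, gate_rates


def state_at(v, ca):
    """Cell state with gates at their rate-equation steady state for v."""
    rates = gate_rates(v)
    gates = {name: np.float64(a / (a + b)) for name, (a, b) in rates.items()}
    return CellState(v=np.float64(v), ca_i=np.float64(ca), **gates)


@pytest.fixture(scope="session")
def br_equilibrium():
    """Full Beeler-Reuter equilibrium found by root-finding, independent of
    the forward-Euler integrator: gates at steady state, calcium balancing
    its ODE, and the voltage at which the total membrane current vanishes."""
    params = cm.IonicParams()

    def ca_balance(v):
        def g(ca):
            cur = cm.ionic_currents(state_at(v, ca), params)
            return -1e-7 * float(cur.i_ca) + 0.07 * (1e-7 - ca)
        return brentq(g, 1e-9, 1e-4, xtol=1e-18, rtol=1e-15)

    def total(v):
        return float(cm.ionic_currents(state_at(v, ca_balance(v)), params).i_total)

    v_eq = brentq(total, -95.0, -75.0, xtol=1e-12)
    return state_at(v_eq, ca_balance(v_eq))


@pytest.fixture
def small_slab():
    """0.4 cm slab at coarse resolution (10 x 10 x 1 elements)."""
    spec = cm.GeometrySpec(kind="slab", dimensions=(0.4, 0.4, 0.001),
                           mesh_size=0.04)
    return cm.make_slab(spec), spec


@pytest.fixture
def single_element_mesh():
    """One unit-ish hexahedron (0.1 cm cube), no constraints."""
    X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float) * 0.1
    hexes = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
    a0 = np.array([[1.0, 0.0, 0.0]])
    return cm.Mesh(X_ref=X, hexes=hexes, a0_field=a0)
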