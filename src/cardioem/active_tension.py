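"""Excitation-induced active fiber tension and the active Kirchhoff stress.

The active fiber tension T_a (MPa) follows the voltage-driven first-order
relaxation law of Nash-Panfilov type:

    dT_a/dt = eps(v) * [k_f * (v - v_r) - T_a]
    eps(v)  = eps0 + (eps_inf - eps0) * exp(-exp(-l * (v - v_bar)))

so that for frozen voltage T_a relaxes exponentially, at rate eps(v), toward
the steady tension k_f*(v - v_r).  The switch function eps is a smooth,
strictly increasing sigmoid between eps0 (diastolic voltages) and eps_inf
(systolic voltages): tension develops fast during the action-potential
plateau and decays slowly near rest.

The resulting active Kirchhoff stress is rank-one along the deformed fiber:
sigma_act = T_a * kappa with kappa = a (x) a the deformed structural tensor.

The printed unit of eps is 1/mV; dimensional consistency of the rate equation
requires a temporal rate, so the values are interpreted as 1/ms with the
published voltage-dependence shape (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ActiveTensionParams:
    k_f: float = 0.005     # maximum active fiber tension slope, MPa/mV
    v_r: float = -94.7     # resting potential reference of the tension law, mV
    eps0: float = 0.1      # low-voltage switch rate, 1/ms
    eps_inf: float = 1.0   # high-voltage switch rate, 1/ms
    l: float = 1.0         # switch steepness, 1/mV
    v_bar: float = 0.0     # switch midpoint, mV

    def validate(self):
        errs = []
        if self.k_f < 0:
            errs.append(f"tension.k_f must be >= 0, got {self.k_f}")
        if not self.eps0 > 0:
            errs.append(f"tension.eps0 must be > 0, got {self.eps0}")
        if not self.eps_inf > 0:
            errs.append(f"tension.eps_inf must be > 0, got {self.eps_inf}")
        return errs


def switch_epsilon(v, params: ActiveTensionParams):
    """Voltage-dependent rate eps(v); bounded in (eps0, eps_inf), strictly
    increasing, with eps(v_bar) = eps0 + (eps_inf - eps0)/e."""
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> exp(-inf) = 0, exact
        return params.eps0 + (params.eps_inf - params.eps0) \
            * np.exp(-np.exp(-params.l * (v - params.v_bar)))


def steady_tension(v, params: ActiveTensionParams):
    """Fixed point of the tension ODE at frozen voltage: k_f * (v - v_r)."""
    return params.k_f * (np.asarray(v, dtype=float) - params.v_r)


def step_tension(t_a, v, dt: float, params: ActiveTensionParams):
    """One forward-Euler substep of dT_a/dt = eps(v)[k_f (v - v_r) - T_a].

    Advanced in the same reaction (operator-splitting) stage and with the same
    substep as the ionic model.  T_a is not clamped: transient negative
    excursions when v dips below v_r are kept and recorded.
    """
    t_a = np.asarray(t_a, dtype=float)
    return t_a + dt * switch_epsilon(v, params) * (steady_tension(v, params) - t_a)


def active_stress(t_a, kappa):
    """Active Kirchhoff stress sigma_act = T_a * kappa (MPa).

    ``kappa`` must be a symmetric positive-semidefinite rank-<=1 structural
    tensor (batched shapes ``(..., 3, 3)`` are supported, with ``t_a``
    broadcasting over the leading axes).
    """
    kappa = np.asarray(kappa, dtype=float)
    if kappa.shape[-2:] != (3, 3):
        raise ValueError("kappa must have shape (..., 3, 3)")
    asym = np.abs(kappa - np.swapaxes(kappa, -1, -2)).max()
    if asym > 1e-12:
        raise ValueError(f"kappa must be symmetric; asymmetry {asym:.3e} > 1e-12")
    t_a = np.asarray(t_a, dtype=float)
    return t_a[..., None, None] * kappa if t_a.ndim else t_a * kappa
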