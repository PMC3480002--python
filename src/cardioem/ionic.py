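"""Beeler-Reuter (1977) ventricular cell electrophysiology with a stretch-activated current.

The membrane model is the standard eight-variable Beeler-Reuter formulation:
transmembrane potential ``v`` (mV), intracellular calcium ``ca_i`` (mol/L), and
six Hodgkin-Huxley gates (m, h, j for the fast sodium current; d, f for the
slow inward calcium current; x1 for the time-activated outward current).  The
total membrane current is

    I_ion = I_Na + I_K1 + I_x1 + I_Ca + I_sac - I_stim     [uA/uF]

where ``I_sac`` is a linear stretch-activated channel current, active only when
the local fiber stretch exceeds one:

    I_sac = delta * G_s * (|a| - 1) * (v - v_s),   delta = 1 iff |a| > 1.

The cell ODE dv/dt = -I_ion/C_m is advanced with explicit forward Euler
substeps (default dt = 0.005 ms); gates may optionally be advanced with the
exact exponential (Rush-Larsen) update.

All functions are vectorized: state fields may be scalars or arrays of any
common shape (one entry per mesh node in tissue simulations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BlowUpError, GateOvershootError, NonFiniteStateError

#: hard guard on the membrane potential magnitude (mV)
V_BLOWUP = 500.0

#: tolerance by which a gate may overshoot [0, 1] before the step is rejected
GATE_TOL = 1e-6

#: standard BR initial membrane potential (mV)
V_INITIAL = -84.5737

#: standard BR initial intracellular calcium (mol/L)
CA_INITIAL = 1.782e-7

GATE_NAMES = ("m", "h", "j", "d", "f_gate", "x1")
STATE_NAMES = ("v", "ca_i") + GATE_NAMES


@dataclass
class IonicParams:
    """Membrane, stimulus and stretch-channel parameters.

    Conductances of the BR currents themselves follow the original 1977
    coefficient set and are exposed for completeness (``g_na``, ``g_nac``,
    ``e_na``, ``g_si``).
    """

    c_m: float = 1.0              # membrane capacitance, uF/cm^2
    g_s: float = 10.0             # max stretch-channel conductance, mS/uF
    v_s: float = -20.0            # stretch-channel reversal potential, mV
    stim_amplitude: float = 80.0  # stimulus magnitude, uA/uF (depolarizing; see Notes)
    stim_duration: float = 1.0    # stimulus pulse length, ms
    g_na: float = 4.0             # mS/cm^2
    g_nac: float = 0.003          # background Na conductance, mS/cm^2
    e_na: float = 50.0            # Na reversal potential, mV
    g_si: float = 0.09            # slow inward (Ca) conductance, mS/cm^2
    gate_update: str = "euler"    # "euler" | "exponential" (Rush-Larsen)

    def validate(self):
        errs = []
        if not self.c_m > 0:
            errs.append(f"ionic.c_m must be > 0, got {self.c_m}")
        if self.stim_duration < 0:
            errs.append(f"ionic.stim_duration must be >= 0, got {self.stim_duration}")
        if self.gate_update not in ("euler", "exponential"):
            errs.append(f"ionic.gate_update must be 'euler' or 'exponential', got {self.gate_update!r}")
        return errs


@dataclass
class CellState:
    """Per-node electrophysiological state (arrays broadcast together)."""

    v: np.ndarray       # membrane potential, mV
    ca_i: np.ndarray    # intracellular calcium, mol/L
    m: np.ndarray
    h: np.ndarray
    j: np.ndarray
    d: np.ndarray
    f_gate: np.ndarray
    x1: np.ndarray

    def copy(self) -> "CellState":
        return CellState(*(np.array(getattr(self, n), dtype=float, copy=True)
                           for n in STATE_NAMES))

    def gates(self) -> np.ndarray:
        """The six gating variables stacked along a leading axis."""
        return np.stack([np.asarray(getattr(self, n), dtype=float)
                         for n in GATE_NAMES])

    def validate(self):
        """Raise on non-finite fields or violated invariants."""
        g = self.gates()
        v = np.asarray(self.v, dtype=float)
        ca = np.asarray(self.ca_i, dtype=float)
        if not (np.isfinite(g).all() and np.isfinite(v).all()
                and np.isfinite(ca).all()):
            for name in STATE_NAMES:
                if not np.all(np.isfinite(np.asarray(getattr(self, name)))):
                    raise NonFiniteStateError(
                        f"cell state field {name!r} is not finite")
        if g.min() < -GATE_TOL or g.max() > 1.0 + GATE_TOL:
            for i, name in enumerate(GATE_NAMES):
                if np.any(g[i] < -GATE_TOL) or np.any(g[i] > 1.0 + GATE_TOL):
                    raise GateOvershootError(f"gate {name!r} outside [0, 1]")
        if ca.min() <= 0:
            raise NonFiniteStateError("ca_i must stay positive")
        if np.abs(v).max() > V_BLOWUP:
            raise BlowUpError("membrane potential exceeded the 500 mV guard")


def _safe_div(num, den, limit):
    """num/den with a supplied limit where |den| underflows (removable singularity)."""
    den = np.asarray(den, dtype=float)
    tiny = np.abs(den) < 1e-12
    out = np.where(tiny, limit, num / np.where(tiny, 1.0, den))
    return out


def _stacked_rates(v):
    """BR alpha/beta rates stacked in GATE_NAMES order: two (6, ...) arrays."""
    dv47 = v + 47.0
    alpha_m = _safe_div(-dv47, np.expm1(-0.1 * dv47), 10.0)
    beta_m = 40.0 * np.exp(-0.056 * (v + 72.0))
    alpha_h = 0.126 * np.exp(-0.25 * (v + 77.0))
    beta_h = 1.7 / (np.exp(-0.082 * (v + 22.5)) + 1.0)
    alpha_j = 0.055 * np.exp(-0.25 * (v + 78.0)) / (np.exp(-0.2 * (v + 78.0)) + 1.0)
    beta_j = 0.3 / (np.exp(-0.1 * (v + 32.0)) + 1.0)
    alpha_d = 0.095 * np.exp(-0.01 * (v - 5.0)) / (np.exp(-0.072 * (v - 5.0)) + 1.0)
    beta_d = 0.07 * np.exp(-0.017 * (v + 44.0)) / (np.exp(0.05 * (v + 44.0)) + 1.0)
    alpha_f = 0.012 * np.exp(-0.008 * (v + 28.0)) / (np.exp(0.15 * (v + 28.0)) + 1.0)
    beta_f = 0.0065 * np.exp(-0.02 * (v + 30.0)) / (np.exp(-0.2 * (v + 30.0)) + 1.0)
    alpha_x1 = 0.0005 * np.exp(0.083 * (v + 50.0)) / (np.exp(0.057 * (v + 50.0)) + 1.0)
    beta_x1 = 0.0013 * np.exp(-0.06 * (v + 20.0)) / (np.exp(-0.04 * (v + 20.0)) + 1.0)
    alpha = np.stack([alpha_m, alpha_h, alpha_j, alpha_d, alpha_f, alpha_x1])
    beta = np.stack([beta_m, beta_h, beta_j, beta_d, beta_f, beta_x1])
    return alpha, beta


def gate_rates(v):
    """Standard BR 1977 alpha/beta rate coefficients (1/ms) for the six gates.

    Returns a dict ``{gate: (alpha, beta)}``.  The removable singularity of
    alpha_m at v = -47 mV is handled by its analytic limit.
    """
    alpha, beta = _stacked_rates(np.asarray(v, dtype=float))
    return {name: (alpha[i], beta[i]) for i, name in enumerate(GATE_NAMES)}


def resting_state(shape=()) -> CellState:
    """Standard BR initial conditions: v = -84.5737 mV, gates at their
    rate-equation steady state for that voltage, ca_i = 1.782e-7 mol/L."""
    v0 = np.full(shape, V_INITIAL, dtype=float)
    alpha, beta = _stacked_rates(np.float64(V_INITIAL))
    ss = alpha / (alpha + beta)
    gates = {name: np.full(shape, float(ss[i]), dtype=float)
             for i, name in enumerate(GATE_NAMES)}
    return CellState(v=v0, ca_i=np.full(shape, CA_INITIAL, dtype=float), **gates)


@dataclass
class Currents:
    """Signed membrane current components (uA/uF)."""

    i_na: np.ndarray
    i_k1: np.ndarray
    i_x1: np.ndarray
    i_ca: np.ndarray
    i_sac: np.ndarray
    i_stim: np.ndarray
    i_total: np.ndarray


def ionic_currents(state: CellState, params: IonicParams,
                   stretch=1.0, stim=0.0) -> Currents:
    """Evaluate all membrane current components at the given state.

    ``stretch`` is the local fiber stretch |a| (dimensionless, >= 0); the
    stretch-activated current engages only for stretch > 1.  ``stim`` is the
    external stimulus magnitude (uA/uF); it enters the total with a minus
    sign, so a positive stimulus depolarizes the cell.
    """
    state.validate()
    v = np.asarray(state.v, dtype=float)
    stretch = np.asarray(stretch, dtype=float)
    if np.any(stretch < 0):
        raise ValueError("stretch must be >= 0")

    i_na = (params.g_na * state.m ** 3 * state.h * state.j + params.g_nac) \
        * (v - params.e_na)
    # time-independent outward potassium current
    ik1_a = 4.0 * (np.exp(0.04 * (v + 85.0)) - 1.0) \
        / (np.exp(0.08 * (v + 53.0)) + np.exp(0.04 * (v + 53.0)))
    ik1_b = 0.2 * _safe_div(v + 23.0, -np.expm1(-0.04 * (v + 23.0)), 25.0)
    i_k1 = 0.35 * (ik1_a + ik1_b)
    i_x1 = state.x1 * 0.8 * (np.exp(0.04 * (v + 77.0)) - 1.0) \
        / np.exp(0.04 * (v + 35.0))
    e_s = -82.3 - 13.0287 * np.log(state.ca_i)
    i_ca = params.g_si * state.d * state.f_gate * (v - e_s)
    i_sac = np.where(stretch > 1.0,
                     params.g_s * (stretch - 1.0) * (v - params.v_s), 0.0)
    i_stim = np.broadcast_to(np.asarray(stim, dtype=float), v.shape).copy() \
        if v.shape else np.asarray(stim, dtype=float)
    i_total = i_na + i_k1 + i_x1 + i_ca + i_sac - i_stim
    return Currents(i_na=i_na, i_k1=i_k1, i_x1=i_x1, i_ca=i_ca,
                    i_sac=i_sac, i_stim=i_stim, i_total=i_total)


def _advance_gates(gates, alpha, beta, dt, mode):
    """Forward-Euler or exact-exponential gate update with clamping.

    ``gates``/``alpha``/``beta`` are stacked (6, ...) arrays.
    """
    if mode == "exponential":
        tau_inv = alpha + beta
        g_inf = alpha / tau_inv
        g_new = g_inf + (gates - g_inf) * np.exp(-dt * tau_inv)
    else:
        g_new = gates + dt * (alpha * (1.0 - gates) - beta * gates)
    if g_new.min() < -GATE_TOL or g_new.max() > 1.0 + GATE_TOL:
        for i, name in enumerate(GATE_NAMES):
            if np.any(g_new[i] < -GATE_TOL) or np.any(g_new[i] > 1.0 + GATE_TOL):
                raise GateOvershootError(
                    f"gate {name!r} left [0, 1] by more than {GATE_TOL}; "
                    "use a smaller dt_ode")
    return np.clip(g_new, 0.0, 1.0)


def step_cell(state: CellState, params: IonicParams,
              stretch=1.0, stim=0.0, dt: float = 0.005) -> CellState:
    """One forward-Euler substep of the full cell model.

    dt = 0 returns an unchanged copy.  Raises :class:`BlowUpError` if the
    updated potential leaves [-500, 500] mV and :class:`GateOvershootError`
    when a gate overshoots beyond the clamping tolerance.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return state.copy()
    cur = ionic_currents(state, params, stretch=stretch, stim=stim)
    v_old = np.asarray(state.v, dtype=float)
    v_new = v_old - dt * cur.i_total / params.c_m
    if np.abs(v_new).max() > V_BLOWUP:
        raise BlowUpError(
            "membrane potential exceeded 500 mV; simulation aborted")
    alpha, beta = _stacked_rates(v_old)
    g_new = _advance_gates(state.gates(), alpha, beta, dt, params.gate_update)
    ca_new = state.ca_i + dt * (-1e-7 * cur.i_ca
                                + 0.07 * (1e-7 - state.ca_i))
    return CellState(v=np.asarray(v_new, dtype=float),
                     ca_i=np.asarray(ca_new, dtype=float),
                     **{name: g_new[i] for i, name in enumerate(GATE_NAMES)})


def stimulus_waveform(t: float, onset: float, params: IonicParams) -> float:
    """Square stimulus pulse: the depolarizing amplitude for
    onset <= t < onset + stim_duration, else 0 (uA/uF)."""
    if onset <= t < onset + params.stim_duration:
        return params.stim_amplitude
    return 0.0


def integrate_cell(state: CellState, params: IonicParams, duration: float,
                   dt: float = 0.005, stim_onset=None, stretch=1.0,
                   record_every: int = 0):
    """Integrate a cell for ``duration`` ms.

    ``stim_onset`` (ms) schedules a single square pulse of the configured
    amplitude/duration; None disables stimulation.  When ``record_every`` is a
    positive integer k, the voltage is sampled every k-th substep and
    ``(state, times, v_trace)`` is returned; otherwise the trace arrays are
    empty.
    """
    n_steps = int(round(duration / dt))
    s = state.copy()
    times, trace = [], []
    if record_every:
        times.append(0.0)
        trace.append(float(np.asarray(s.v).reshape(-1)[0]))
    for k in range(n_steps):
        t = k * dt
        stim = stimulus_waveform(t, stim_onset, params) \
            if stim_onset is not None else 0.0
        s = step_cell(s, params, stretch=stretch, stim=stim, dt=dt)
        if record_every and (k + 1) % record_every == 0:
            times.append((k + 1) * dt)
            trace.append(float(np.asarray(s.v).reshape(-1)[0]))
    return s, np.asarray(times), np.asarray(trace)
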