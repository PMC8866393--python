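"""Single-neuron dynamics of the STN, GPe/GPi and thalamic relay models.

The pallido-subthalamic cells carry six state variables per neuron
(V, n, h, r, Ca, s); the thalamic relay cell three (V, h, r).  All right-hand
sides are vectorised: states may be scalars or 1-D arrays over a population.

Membrane equation (STN/GPe/GPi)::

    C dV/dt = -I_LEAK - I_K - I_Na - I_Ca - I_T - I_AHP - I_syn + I_app + I_DBS

with I_LEAK = g_L (V - E_L), I_K = g_K n^4 (V - E_K),
I_Na = g_Na m_inf^3 h (V - E_Na), I_Ca = g_Ca s_inf^2 (V - E_Ca),
I_AHP = g_AHP Ca/(Ca + k1) (V - E_K) and a low-threshold T-current that is
g_T a_inf^3 b_inf(r)^2 (V - E_Ca) for STN but g_T a_inf^3 r (V - E_K) for the
pallidal cells (the weaker, potassium-reversal form tempers pallidal
bursting relative to STN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import PopulationParams

__all__ = [
    "NeuronState",
    "steady_state",
    "b_inf",
    "tau_x",
    "smooth_heaviside",
    "membrane_rhs",
    "thalamic_rhs",
    "rest_state",
    "integrate_single",
    "single_neuron_rate",
]


@dataclass
class NeuronState:
    """State variables of one population (arrays) or one neuron (scalars).

    ``n``, ``ca`` and ``s`` are ``None`` for the thalamic relay model.
    """

    v: np.ndarray
    h: np.ndarray
    r: np.ndarray
    n: Optional[np.ndarray] = None
    ca: Optional[np.ndarray] = None
    s: Optional[np.ndarray] = None


def steady_state(v, theta, sigma):
    """Logistic equilibrium activation 1/(1 + exp(-(V - theta)/sigma)).

    Monotone increasing in ``v`` for ``sigma > 0``, decreasing for
    ``sigma < 0`` (inactivation gates).
    """
    if sigma == 0:
        raise ValueError("sigma must be non-zero")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    return 1.0 / (1.0 + np.exp(-(v - theta) / sigma))


def b_inf(r_gate, theta_b, sigma_b):
    """Equilibrium of the T-current inactivation helper gate b.

    Note the argument is the gating variable ``r``, not the voltage:
    b_inf(r) = 1/(1+exp((r-theta_b)/sigma_b)) - 1/(1+exp(-theta_b/sigma_b)),
    which vanishes at r = 0.
    """
    r_gate = np.asarray(r_gate, dtype=float)
    return (1.0 / (1.0 + np.exp((r_gate - theta_b) / sigma_b))
            - 1.0 / (1.0 + np.exp(-theta_b / sigma_b)))


def smooth_heaviside(v, theta, sigma):
    """Smooth (logistic) step used in the synaptic release kinetics."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - theta) / sigma))


def tau_x(v, p: PopulationParams, x: str):
    """Voltage-dependent relaxation time of gate ``x`` in ms.

    STN/GPe/GPi gates use tau_x(V) = [tau_x0 + tau_x1 L(V)]/phi_x with a
    logistic L; when the logistic's parameters are not defined for a gate
    (pallidal r), or when ``p.constant_tau`` is set, the constant
    tau_x0/phi_x is used.  The thalamic h and r gates use their own closed
    forms (see :func:`thalamic_rhs`).
    """
    if x not in ("h", "n", "r"):
        raise ValueError("gate must be one of h, n, r")
    if p.population_label == "THA":
        return _tha_tau(np.asarray(v, dtype=float), p, x)
    tau0 = getattr(p, f"tau_{x}0")
    tau1 = getattr(p, f"tau_{x}1")
    theta = getattr(p, f"theta_tau_{x}")
    sigma = getattr(p, f"sigma_tau_{x}")
    phi = getattr(p, f"phi_{x}")
    if phi is None or phi == 0:
        raise ValueError(f"phi_{x} must be non-zero")
    v = np.asarray(v, dtype=float)
    if p.constant_tau or theta is None or sigma is None:
        return np.full_like(v, tau0 / phi) if v.ndim else tau0 / phi
    return (tau0 + tau1 / (1.0 + np.exp(-(v - theta) / sigma))) / phi


def _tha_tau(v, p: PopulationParams, x: str):
    if x == "h":
        a_h = 0.128 * np.exp(-(v + 46.0) / 18.0)
        b_h = 4.0 / (1.0 + np.exp(-(v + 23.0) / 5.0))
        return 1.0 / (a_h + b_h)
    if x == "r":
        bump = np.exp(-(v + 25.0) / 10.5)
        if p.tha_tau_r_literal:
            return 28.0 + (1.0 + bump)
        return 28.0 + bump
    raise ValueError("thalamic model has only h and r gates")


def membrane_rhs(state: NeuronState, i_syn, i_app, i_dbs,
                 p: PopulationParams) -> NeuronState:
    """Time derivatives of an STN or pallidal population.

    ``i_syn`` is the total synaptic current (positive = hyperpolarising, as
    it enters the membrane equation with a minus sign); ``i_app`` the
    constant cortical/striatal drive; ``i_dbs`` the stimulation current.
    """
    if p.population_label not in ("STN", "GPe", "GPi"):
        raise ValueError("membrane_rhs applies to STN/GPe/GPi only")
    if state.n is None or state.ca is None or state.s is None:
        raise ValueError("STN/GP state requires n, Ca and s variables")
    v, n, h, r = state.v, state.n, state.h, state.r
    ca, s = state.ca, state.s

    m_inf = steady_state(v, p.theta_m, p.sigma_m)
    s_inf = steady_state(v, p.theta_s, p.sigma_s)
    a_inf = steady_state(v, p.theta_a, p.sigma_a)

    i_leak = p.g_leak * (v - p.e_leak)
    i_k = p.g_k * n ** 4 * (v - p.e_k)
    i_na = p.g_na * m_inf ** 3 * h * (v - p.e_na)
    i_ca = p.g_ca * s_inf ** 2 * (v - p.e_ca)
    if p.population_label == "STN":
        i_t = p.g_t * a_inf ** 3 * b_inf(r, p.theta_b, p.sigma_b) ** 2 * (v - p.e_ca)
    else:
        e_rev_t = p.e_ca if p.gp_it_uses_e_ca else p.e_k
        i_t = p.g_t * a_inf ** 3 * r * (v - e_rev_t)
    i_ahp = p.g_ahp * (ca / (ca + p.k1)) * (v - p.e_k)

    dv = (-i_leak - i_k - i_na - i_ca - i_t - i_ahp
          - i_syn + i_app + i_dbs) / p.capacitance
    dn = (steady_state(v, p.theta_n, p.sigma_n) - n) / tau_x(v, p, "n")
    dh = (steady_state(v, p.theta_h, p.sigma_h) - h) / tau_x(v, p, "h")
    dr = (steady_state(v, p.theta_r, p.sigma_r) - r) / tau_x(v, p, "r")
    dca = p.k2 * (-i_ca - i_t - p.k_ca * ca)
    ds = p.alpha * (1.0 - s) * smooth_heaviside(v, p.theta_syn, p.sigma_syn) - p.beta * s
    return NeuronState(v=dv, h=dh, r=dr, n=dn, ca=dca, s=ds)


def thalamic_rhs(state: NeuronState, i_gpth, i_sm,
                 p: PopulationParams) -> NeuronState:
    """Time derivatives of the thalamic relay population.

    ``i_gpth`` is the GABAergic input from GPi, ``i_sm`` the excitatory
    sensorimotor drive.  The potassium gate is slaved to sodium
    inactivation via n = 0.75 (1 - h).
    """
    if p.population_label != "THA":
        raise ValueError("thalamic_rhs applies to THA only")
    v, h, r = state.v, state.h, state.r
    m_inf = steady_state(v, p.theta_m, p.sigma_m)
    p_inf = steady_state(v, p.theta_p, p.sigma_p)

    i_leak = p.g_leak * (v - p.e_leak)
    i_k = p.g_k * (0.75 * (1.0 - h)) ** 4 * (v - p.e_k)
    i_na = p.g_na * m_inf ** 3 * h * (v - p.e_na)
    i_t = p.g_t * p_inf ** 2 * r * (v - p.e_t)

    dv = (-i_leak - i_k - i_na - i_t - i_gpth + i_sm) / p.capacitance
    dh = (steady_state(v, p.theta_h, p.sigma_h) - h) / _tha_tau(v, p, "h")
    dr = (steady_state(v, p.theta_r, p.sigma_r) - r) / _tha_tau(v, p, "r")
    return NeuronState(v=dv, h=dh, r=dr)


def rest_state(p: PopulationParams, v0: float = -60.0) -> NeuronState:
    """State with gates at their equilibrium for membrane potential v0."""
    v = np.asarray(float(v0))
    h = steady_state(v, p.theta_h, p.sigma_h)
    r = steady_state(v, p.theta_r, p.sigma_r)
    if p.population_label == "THA":
        return NeuronState(v=v, h=h, r=r)
    n = steady_state(v, p.theta_n, p.sigma_n)
    return NeuronState(v=v, h=h, r=r, n=n, ca=np.asarray(0.1), s=np.asarray(0.0))


def _pack(state: NeuronState, tha: bool) -> np.ndarray:
    if tha:
        return np.array([state.v, state.h, state.r], dtype=float).ravel()
    return np.array([state.v, state.n, state.h, state.r, state.ca, state.s],
                    dtype=float).ravel()


def integrate_single(p: PopulationParams, i_app=0.0, duration: float = 2000.0,
                     i_app_fn=None, i_dbs_fn=None, i_sm_fn=None, i_gpth_fn=None,
                     v0: float = -62.0, rtol: float = 1e-6, atol: float = 1e-6,
                     max_step: float = 1.0, dt_out: float = 0.05):
    """Integrate one uncoupled neuron; returns (t, V) on a uniform grid.

    Time-dependent drives can be supplied as callables of t (ms); constant
    ``i_app`` is used otherwise.
    """
    tha = p.population_label == "THA"
    y0 = _pack(rest_state(p, v0), tha)

    if tha:
        def rhs(t, y):
            st = NeuronState(v=y[0], h=y[1], r=y[2])
            sm = i_sm_fn(t) if i_sm_fn is not None else i_app
            gpth = i_gpth_fn(t) if i_gpth_fn is not None else 0.0
            d = thalamic_rhs(st, gpth, sm, p)
            return [d.v, d.h, d.r]
    else:
        def rhs(t, y):
            st = NeuronState(v=y[0], n=y[1], h=y[2], r=y[3], ca=y[4], s=y[5])
            app = i_app_fn(t) if i_app_fn is not None else i_app
            dbs = i_dbs_fn(t) if i_dbs_fn is not None else 0.0
            d = membrane_rhs(st, 0.0, app, dbs, p)
            return [d.v, d.n, d.h, d.r, d.ca, d.s]

    t_eval = np.arange(0.0, duration + dt_out / 2, dt_out)
    sol = solve_ivp(rhs, (0.0, duration), y0, method="RK23",
                    rtol=rtol, atol=atol, max_step=max_step, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, sol.y[0]


def spike_times_from_trace(t: np.ndarray, v: np.ndarray,
                           threshold: float = -15.0,
                           lockout: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with linear interpolation and a lockout."""
    v = np.asarray(v)
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= lockout:
            keep.append(i)
    return times[keep]


def single_neuron_rate(p: PopulationParams, i_app: float = 0.0,
                       duration: float = 2500.0, transient: float = 500.0,
                       **kwargs) -> float:
    """Mean firing rate (Hz) of one uncoupled neuron under constant drive.

    Spikes are upward crossings of -15 mV; the first ``transient`` ms are
    discarded before counting.
    """
    if duration < 1000.0:
        raise ValueError("duration must be at least 1000 ms")
    t, v = integrate_single(p, i_app=i_app, duration=duration, **kwargs)
    spikes = spike_times_from_trace(t, v)
    spikes = spikes[spikes >= transient]
    return 1000.0 * spikes.size / (duration - transient)
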