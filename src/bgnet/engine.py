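"""Network integration, spike detection and result containers.

The coupled 1700-neuron system is integrated with an adaptive embedded
Runge-Kutta 3(2) pair (relative/absolute tolerances 1e-6 by default, the
regime used for all published-figure-scale runs); a fixed-step RK4 fallback
is available.  States are recorded on a uniform output grid (0.1 ms) by
dense interpolation, independent of the internal adaptive steps.  The
maximum internal step is capped at a quarter of the narrowest active pulse
width so that 0.6 ms DBS pulses are never skipped.

Spikes are upward crossings of -15 mV (linearly interpolated between grid
samples) separated by at least 2 ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import _kernels as K
from .neurons import smooth_heaviside, steady_state, tau_x
from .params import PopulationParams, default_params
from .stimulation import StimulusProtocol
from .topology import NetworkTopology, PROJECTIONS

__all__ = ["SimulationResult", "integrate", "detect_spikes", "raster",
           "initial_state"]

SPIKE_THRESHOLD = -15.0  # mV
SPIKE_LOCKOUT = 2.0      # ms

_BG_POPS = ("STN", "GPe", "GPi")
_POPS = ("STN", "GPe", "GPi", "THA")


def _pack_bg(p: PopulationParams) -> np.ndarray:
    def f(x, default=np.nan):
        return default if x is None else float(x)
    out = np.empty(50)
    out[K.P_GL], out[K.P_GK], out[K.P_GNA] = p.g_leak, p.g_k, p.g_na
    out[K.P_GT], out[K.P_GCA], out[K.P_GAHP] = p.g_t, p.g_ca, p.g_ahp
    out[K.P_EL], out[K.P_EK], out[K.P_ENA], out[K.P_ECA] = \
        p.e_leak, p.e_k, p.e_na, f(p.e_ca)
    out[K.P_THM], out[K.P_SGM] = f(p.theta_m), f(p.sigma_m)
    out[K.P_THH], out[K.P_SGH] = f(p.theta_h), f(p.sigma_h)
    out[K.P_THN], out[K.P_SGN] = f(p.theta_n), f(p.sigma_n)
    out[K.P_THR], out[K.P_SGR] = f(p.theta_r), f(p.sigma_r)
    out[K.P_THA_], out[K.P_SGA] = f(p.theta_a), f(p.sigma_a)
    out[K.P_THB], out[K.P_SGB] = f(p.theta_b, 0.4), f(p.sigma_b, -0.1)
    out[K.P_THS], out[K.P_SGS] = f(p.theta_s), f(p.sigma_s)
    out[K.P_TH0], out[K.P_TH1] = f(p.tau_h0), f(p.tau_h1)
    out[K.P_THTH], out[K.P_SGTH], out[K.P_PHH] = \
        f(p.theta_tau_h, 0.0), f(p.sigma_tau_h, 0.0), f(p.phi_h, 1.0)
    out[K.P_TN0], out[K.P_TN1] = f(p.tau_n0), f(p.tau_n1)
    out[K.P_THTN], out[K.P_SGTN], out[K.P_PHN] = \
        f(p.theta_tau_n, 0.0), f(p.sigma_tau_n, 0.0), f(p.phi_n, 1.0)
    out[K.P_TR0], out[K.P_TR1] = f(p.tau_r0), f(p.tau_r1)
    out[K.P_THTR], out[K.P_SGTR], out[K.P_PHR] = \
        f(p.theta_tau_r, 0.0), f(p.sigma_tau_r, 0.0), f(p.phi_r, 1.0)
    out[K.P_K1], out[K.P_K2], out[K.P_KCA] = f(p.k1), f(p.k2), f(p.k_ca)
    out[K.P_ALPHA], out[K.P_BETA] = f(p.alpha), f(p.beta)
    out[K.P_THSYN], out[K.P_SGSYN] = f(p.theta_syn), f(p.sigma_syn)
    out[K.P_CAP] = p.capacitance
    out[K.P_ISSTN] = 1.0 if p.population_label == "STN" else 0.0
    out[K.P_ITECA] = 1.0 if p.gp_it_uses_e_ca else 0.0
    out[K.P_CONSTTAU] = 1.0 if p.constant_tau else 0.0
    return out


def _pack_tha(p: PopulationParams) -> np.ndarray:
    out = np.empty(18)
    out[K.T_GL], out[K.T_GK], out[K.T_GNA], out[K.T_GT] = \
        p.g_leak, p.g_k, p.g_na, p.g_t
    out[K.T_EL], out[K.T_EK], out[K.T_ENA], out[K.T_ET] = \
        p.e_leak, p.e_k, p.e_na, p.e_t
    out[K.T_THM], out[K.T_SGM] = p.theta_m, p.sigma_m
    out[K.T_THP], out[K.T_SGP] = p.theta_p, p.sigma_p
    out[K.T_THH], out[K.T_SGH] = p.theta_h, p.sigma_h
    out[K.T_THR], out[K.T_SGR] = p.theta_r, p.sigma_r
    out[K.T_CAP] = p.capacitance
    out[K.T_TAUR_LIT] = 1.0 if p.tha_tau_r_literal else 0.0
    return out


def _logistic(v, theta, sigma):
    return 1.0 / (1.0 + np.exp(-(v - theta) / sigma))


def gating_tables(params: dict[str, PopulationParams]):
    """Tabulate every voltage-dependent gating curve on a fine V grid.

    The compiled right-hand side interpolates these tables linearly; on the
    0.02 mV grid the interpolation error is below ~1e-6, i.e. below the
    integration tolerances.  The tables are generated from the same
    analytic functions exposed by :mod:`bgnet.neurons`, so the compiled and
    the reference right-hand sides share one definition of the kinetics.
    """
    v = np.arange(K.TABLE_V_LO, K.TABLE_V_HI + K.TABLE_DV / 2, K.TABLE_DV)
    tables = {}
    for pop in _BG_POPS:
        p = params[pop]
        tbl = np.empty((v.size, K.NCOL_BG))
        tbl[:, K.C_MINF] = steady_state(v, p.theta_m, p.sigma_m)
        tbl[:, K.C_SINF] = steady_state(v, p.theta_s, p.sigma_s)
        tbl[:, K.C_AINF] = steady_state(v, p.theta_a, p.sigma_a)
        tbl[:, K.C_NINF] = steady_state(v, p.theta_n, p.sigma_n)
        tbl[:, K.C_HINF] = steady_state(v, p.theta_h, p.sigma_h)
        tbl[:, K.C_RINF] = steady_state(v, p.theta_r, p.sigma_r)
        tbl[:, K.C_ITAUN] = 1.0 / tau_x(v, p, "n")
        tbl[:, K.C_ITAUH] = 1.0 / tau_x(v, p, "h")
        tbl[:, K.C_ITAUR] = 1.0 / tau_x(v, p, "r")
        tbl[:, K.C_HSYN] = smooth_heaviside(v, p.theta_syn, p.sigma_syn)
        tables[pop] = tbl
    p = params["THA"]
    tbl = np.empty((v.size, K.NCOL_TH))
    tbl[:, K.D_MINF] = steady_state(v, p.theta_m, p.sigma_m)
    tbl[:, K.D_PINF] = steady_state(v, p.theta_p, p.sigma_p)
    tbl[:, K.D_HINF] = steady_state(v, p.theta_h, p.sigma_h)
    tbl[:, K.D_RINF] = steady_state(v, p.theta_r, p.sigma_r)
    tbl[:, K.D_ITAUH] = 1.0 / tau_x(v, p, "h")
    tbl[:, K.D_ITAUR] = 1.0 / tau_x(v, p, "r")
    tables["THA"] = tbl
    return tables


def initial_state(params: dict[str, PopulationParams], seed: int) -> np.ndarray:
    """Desynchronised initial condition: V ~ U(-70, -50) mV per neuron,
    gates at their steady state for that voltage, Ca = 0.1, s = 0."""
    rng = np.random.default_rng(seed)
    y = np.zeros(K.NSTATE)
    for pop, base in zip(_BG_POPS, (K.S_STN, K.S_GPE, K.S_GPI)):
        p = params[pop]
        v0 = rng.uniform(-70.0, -50.0, K.N_BG)
        y[base + K.V_:base + K.V_ + K.N_BG] = v0
        y[base + K.N_:base + K.N_ + K.N_BG] = _logistic(v0, p.theta_n, p.sigma_n)
        y[base + K.H_:base + K.H_ + K.N_BG] = _logistic(v0, p.theta_h, p.sigma_h)
        y[base + K.R_:base + K.R_ + K.N_BG] = _logistic(v0, p.theta_r, p.sigma_r)
        y[base + K.CA_:base + K.CA_ + K.N_BG] = 0.1
    p = params["THA"]
    v0 = rng.uniform(-70.0, -50.0, K.N_TH)
    y[K.S_THA:K.S_THA + K.N_TH] = v0
    y[K.S_THA + K.N_TH:K.S_THA + 2 * K.N_TH] = _logistic(v0, p.theta_h, p.sigma_h)
    y[K.S_THA + 2 * K.N_TH:K.S_THA + 3 * K.N_TH] = _logistic(v0, p.theta_r, p.sigma_r)
    return y


@dataclass
class SimulationResult:
    """Recorded traces, spikes and run metadata of one network simulation."""

    t: np.ndarray
    v: dict[str, np.ndarray]          # population -> (n_times, n_neurons)
    s_gpi: np.ndarray                 # (n_times, 500) GPi release variables
    spikes: dict[str, list]           # population -> list of spike-time arrays
    protocol: StimulusProtocol
    seed: int
    solver: dict = field(default_factory=dict)
    topology_seed: int = 0
    stn_variant: str = "sparse"

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def mean_rate(self, population: str, t_start: float = 500.0,
                  t_stop: float | None = None) -> float:
        """Population-average firing rate (Hz) in [t_start, t_stop)."""
        t_stop = self.duration if t_stop is None else t_stop
        counts = [np.count_nonzero((s >= t_start) & (s < t_stop))
                  for s in self.spikes[population]]
        return 1000.0 * float(np.mean(counts)) / (t_stop - t_start)

    def save(self, path) -> None:
        """Write the result to an HDF5 container, one group per population."""
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=self.t)
            f.create_dataset("s_gpi", data=self.s_gpi)
            for pop in self.v:
                g = f.create_group(pop)
                g.create_dataset("v", data=self.v[pop])
                flat = np.concatenate(self.spikes[pop]) if self.spikes[pop] else np.empty(0)
                offs = np.cumsum([0] + [len(s) for s in self.spikes[pop]])
                g.create_dataset("spike_times", data=flat)
                g.create_dataset("spike_offsets", data=offs)
            f.attrs["manifest"] = json.dumps({
                "seed": self.seed,
                "topology_seed": self.topology_seed,
                "stn_variant": self.stn_variant,
                "condition": self.protocol.condition,
                "dbs_frequency": self.protocol.dbs_frequency,
                "i_app": self.protocol.i_app,
                "solver": self.solver,
            })

    @classmethod
    def load(cls, path) -> "SimulationResult":
        with h5py.File(path, "r") as f:
            man = json.loads(f.attrs["manifest"])
            v = {}
            spikes = {}
            for pop in _POPS:
                g = f[pop]
                v[pop] = g["v"][()]
                flat = g["spike_times"][()]
                offs = g["spike_offsets"][()]
                spikes[pop] = [flat[offs[i]:offs[i + 1]] for i in range(len(offs) - 1)]
            proto = StimulusProtocol(condition=man["condition"],
                                     dbs_frequency=man["dbs_frequency"])
            return cls(t=f["t"][()], v=v, s_gpi=f["s_gpi"][()], spikes=spikes,
                       protocol=proto, seed=man["seed"], solver=man["solver"],
                       topology_seed=man["topology_seed"],
                       stn_variant=man["stn_variant"])


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD,
                  lockout: float = SPIKE_LOCKOUT) -> list[np.ndarray]:
    """Spike times per neuron from a (n_times, n_neurons) voltage array.

    Spikes are upward crossings of ``threshold`` with sub-sample timing by
    linear interpolation; crossings closer than ``lockout`` ms to the
    previous accepted spike are discarded.
    """
    v = np.atleast_2d(np.asarray(v))
    if v.shape[0] != t.size:
        v = v.T
    out = []
    above = v >= threshold
    for j in range(v.shape[1]):
        col = v[:, j]
        idx = np.flatnonzero(~above[:-1, j] & above[1:, j])
        if idx.size == 0:
            out.append(np.empty(0))
            continue
        frac = (threshold - col[idx]) / (col[idx + 1] - col[idx])
        times = t[idx] + frac * (t[idx + 1] - t[idx])
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= lockout:
                keep.append(i)
        out.append(times[keep])
    return out


def _csr_arrays(topology: NetworkTopology, proj: str):
    a = topology.adjacency[proj]
    return a.indptr.astype(np.int64), a.indices.astype(np.int64)


def integrate(topology: NetworkTopology, protocol: StimulusProtocol,
              t_span: float = 1500.0, rtol: float = 1e-6, atol: float = 1e-6,
              seed: int = 0, dt_out: float = 0.1,
              params: dict[str, PopulationParams] | None = None,
              method: str = "rk23", dt_fixed: float = 0.025,
              max_step: float | None = None, y0: np.ndarray | None = None
              ) -> SimulationResult:
    """Integrate the full network and return recorded traces and spikes.

    Deterministic given (topology, protocol, seed, solver settings).  The
    initial state is drawn from ``seed``; ``y0`` overrides it.
    """
    if t_span < 100.0:
        raise ValueError("t_span must be at least 100 ms")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    params = params or default_params()
    pstn = _pack_bg(params["STN"])
    pgpe = _pack_bg(params["GPe"])
    pgpi = _pack_bg(params["GPi"])
    ptha = _pack_tha(params["THA"])

    csr = sum((_csr_arrays(topology, pr) for pr in PROJECTIONS), ())
    gsyn = np.array([topology.conductances[pr] for pr in PROJECTIONS])
    erev = np.array([topology.reversal(pr) for pr in PROJECTIONS])
    i_app = np.array([protocol.i_app[p] for p in _BG_POPS])
    sm = np.array([protocol.a_sm, protocol.delta_sm, protocol.t_sm])
    dbs = np.array([1.0 if protocol.dbs_active else 0.0, protocol.a_dbs,
                    protocol.delta_dbs,
                    protocol.t_dbs if protocol.dbs_active else 1.0])

    if max_step is None:
        max_step = protocol.delta_sm / 4.0
        if protocol.dbs_active:
            max_step = min(max_step, protocol.delta_dbs / 4.0)

    grid = np.arange(0.0, t_span + dt_out / 2.0, dt_out)
    rec_idx = np.concatenate([
        np.arange(K.S_STN + K.V_, K.S_STN + K.V_ + K.N_BG),
        np.arange(K.S_GPE + K.V_, K.S_GPE + K.V_ + K.N_BG),
        np.arange(K.S_GPI + K.V_, K.S_GPI + K.V_ + K.N_BG),
        np.arange(K.S_THA, K.S_THA + K.N_TH),
        np.arange(K.S_GPI + K.SS_, K.S_GPI + K.SS_ + K.N_BG),
    ]).astype(np.int64)

    if y0 is None:
        y0 = initial_state(params, seed)
    tables = gating_tables(params)
    inv_dv = 1.0 / K.TABLE_DV
    args = (pstn, pgpe, pgpi, ptha,
            tables["STN"], tables["GPe"], tables["GPi"], tables["THA"],
            inv_dv) + csr + (gsyn, erev, i_app, sm, dbs)

    if method == "rk23":
        rec, status, n_steps, n_rej, n_fev, t_fail, i_fail = K.integrate_rk23(
            y0, 0.0, float(t_span), rtol, atol, max_step, 0.01, grid, rec_idx,
            *args)
    elif method == "rk4":
        rec, status, n_steps, n_rej, n_fev, t_fail, i_fail = K.integrate_rk4(
            y0, 0.0, float(t_span), dt_fixed, grid, rec_idx, *args)
    else:
        raise ValueError("method must be 'rk23' or 'rk4'")
    if status != 0:
        raise RuntimeError(
            f"non-finite state during integration at t={t_fail:.3f} ms "
            f"(state index {i_fail})")

    v = {
        "STN": rec[:, 0:K.N_BG],
        "GPe": rec[:, K.N_BG:2 * K.N_BG],
        "GPi": rec[:, 2 * K.N_BG:3 * K.N_BG],
        "THA": rec[:, 3 * K.N_BG:3 * K.N_BG + K.N_TH],
    }
    s_gpi = rec[:, 3 * K.N_BG + K.N_TH:]
    spikes = {pop: detect_spikes(grid, v[pop]) for pop in _POPS}
    solver = {"method": method, "rtol": rtol, "atol": atol,
              "max_step": float(max_step), "n_steps": int(n_steps),
              "n_rejected": int(n_rej), "n_fevals": int(n_fev)}
    return SimulationResult(t=grid, v=v, s_gpi=s_gpi, spikes=spikes,
                            protocol=protocol, seed=seed, solver=solver,
                            topology_seed=topology.seed,
                            stn_variant=topology.stn_variant)


def raster(result: SimulationResult, population: str) -> pd.DataFrame:
    """Spike raster (neuron_index, time_ms) for one population."""
    if population not in result.spikes:
        raise ValueError(f"population {population!r} not simulated")
    idx, times = [], []
    for j, s in enumerate(result.spikes[population]):
        idx.extend([j] * len(s))
        times.extend(s)
    return pd.DataFrame({"neuron_index": np.array(idx, dtype=int),
                         "time_ms": np.array(times)})
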