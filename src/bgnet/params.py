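"""Population parameter sets for the basal ganglia-thalamus network.

Each simulated nucleus (STN, GPe, GPi, THA) is described by one
:class:`PopulationParams` record holding the ionic conductances, reversal
potentials, gating half-activations/slopes, time-constant parameters,
calcium kinetics, synaptic kinetics and stimulation defaults of its
conductance-based (Hodgkin-Huxley type) neuron model.  The STN/GPe/GPi
models follow the Terman-type pallido-subthalamic formulation; the thalamic
relay cell is a reduced three-variable model.

Units: voltages mV, times ms, conductances nS/um^2, currents pA/um^2
(capacitance C = 1 in this convention, so pA and mV/ms coincide).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml

POPULATIONS = ("STN", "GPe", "GPi", "THA")


@dataclass
class PopulationParams:
    """Full parameter set for one neuronal population.

    Fields that do not apply to a population (e.g. calcium kinetics for the
    thalamic relay model, DBS amplitudes for non-STN nuclei) are ``None``.
    """

    population_label: str

    # membrane
    capacitance: float = 1.0
    g_leak: float = 0.0
    g_k: float = 0.0
    g_na: float = 0.0
    g_t: float = 0.0
    g_ca: float = 0.0
    g_ahp: float = 0.0
    e_leak: float = 0.0
    e_k: float = 0.0
    e_na: float = 0.0
    e_ca: Optional[float] = None
    e_t: Optional[float] = None

    # gating half-activations (mV) and slopes
    theta_m: Optional[float] = None
    theta_h: Optional[float] = None
    theta_n: Optional[float] = None
    theta_r: Optional[float] = None
    theta_a: Optional[float] = None
    theta_b: Optional[float] = None
    theta_s: Optional[float] = None
    theta_p: Optional[float] = None
    sigma_m: Optional[float] = None
    sigma_h: Optional[float] = None
    sigma_n: Optional[float] = None
    sigma_r: Optional[float] = None
    sigma_a: Optional[float] = None
    sigma_b: Optional[float] = None
    sigma_s: Optional[float] = None
    sigma_p: Optional[float] = None

    # voltage-dependent time constants  tau_x(V) = [tau_x0 + tau_x1 * L(V)] / phi_x
    tau_h0: Optional[float] = None
    tau_h1: Optional[float] = None
    tau_n0: Optional[float] = None
    tau_n1: Optional[float] = None
    tau_r0: Optional[float] = None
    tau_r1: Optional[float] = None
    theta_tau_h: Optional[float] = None
    theta_tau_n: Optional[float] = None
    theta_tau_r: Optional[float] = None
    sigma_tau_h: Optional[float] = None
    sigma_tau_n: Optional[float] = None
    sigma_tau_r: Optional[float] = None
    phi_h: Optional[float] = None
    phi_n: Optional[float] = None
    phi_r: Optional[float] = None

    # calcium kinetics
    k1: Optional[float] = None
    k2: Optional[float] = None
    k_ca: Optional[float] = None

    # synaptic release kinetics (ds/dt = alpha (1-s) H(V - theta_syn) - beta s)
    alpha: Optional[float] = None
    beta: Optional[float] = None
    theta_syn: Optional[float] = None
    sigma_syn: Optional[float] = None

    # stimulation defaults
    a_dbs: Optional[float] = None
    delta_dbs: Optional[float] = None
    t_dbs: Optional[float] = None
    a_sm: Optional[float] = None
    delta_sm: Optional[float] = None
    t_sm: Optional[float] = None

    # behavioural switches
    constant_tau: bool = False      # force tau_x = tau_x0/phi_x (voltage independent)
    tha_tau_r_literal: bool = False  # use 28+(1+e^...) instead of 28+e^... for THA tau_r
    gp_it_uses_e_ca: bool = False   # pallidal I_T driving force (V - E_Ca) instead of (V - E_K)

    def __post_init__(self) -> None:
        if self.population_label not in POPULATIONS:
            raise ValueError(f"unknown population {self.population_label!r}")
        for name in ("g_leak", "g_k", "g_na", "g_t", "g_ca", "g_ahp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.sigma_syn is not None and self.sigma_syn <= 0:
            raise ValueError("sigma_syn must be positive")
        if self.population_label != "STN" and self.a_dbs not in (None, 0.0):
            raise ValueError("only STN neurons receive DBS")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        return cls(**d)


def stn_params() -> PopulationParams:
    """Subthalamic nucleus neuron parameters."""
    return PopulationParams(
        population_label="STN",
        g_leak=2.25, g_k=45.0, g_na=37.5, g_t=0.5, g_ca=0.5, g_ahp=9.0,
        e_leak=-60.0, e_k=-80.0, e_na=55.0, e_ca=140.0,
        theta_m=-30.0, theta_h=-39.0, theta_n=-32.0, theta_r=-67.0,
        theta_a=-63.0, theta_b=0.4, theta_s=-39.0,
        sigma_m=15.0, sigma_h=-3.1, sigma_n=8.0, sigma_r=-2.0,
        sigma_a=7.8, sigma_b=-0.1, sigma_s=8.0,
        tau_h0=1.0, tau_h1=500.0, tau_n0=1.0, tau_n1=100.0,
        tau_r0=40.0, tau_r1=17.5,
        theta_tau_h=-57.0, theta_tau_n=-80.0, theta_tau_r=68.0,
        sigma_tau_h=-3.0, sigma_tau_n=-26.0, sigma_tau_r=-2.2,
        phi_h=0.75, phi_n=0.75, phi_r=0.12,
        k1=15.0, k2=3.75e-5, k_ca=22.5,
        alpha=5.0, beta=1.0, theta_syn=-39.0, sigma_syn=1.0,
        a_dbs=200.0, delta_dbs=0.6, t_dbs=6.0,
    )


def gp_params(label: str = "GPe") -> PopulationParams:
    """Globus pallidus (externa or interna) neuron parameters.

    The GPe and GPi share one cell model; they differ only in their synaptic
    afferents and applied striatal currents.
    """
    return PopulationParams(
        population_label=label,
        g_leak=0.1, g_k=30.0, g_na=120.0, g_t=0.5, g_ca=0.15, g_ahp=30.0,
        e_leak=-55.0, e_k=-80.0, e_na=55.0, e_ca=120.0,
        theta_m=-37.0, theta_h=-58.0, theta_n=-50.0, theta_r=-70.0,
        theta_a=-57.0, theta_s=-35.0,
        sigma_m=10.0, sigma_h=-12.0, sigma_n=14.0, sigma_r=-2.0,
        sigma_a=2.0, sigma_s=2.0,
        tau_h0=0.05, tau_h1=0.27, tau_n0=1.0, tau_n1=0.27,
        tau_r0=30.0, tau_r1=0.05,
        theta_tau_h=-40.0, theta_tau_n=-40.0,
        sigma_tau_h=-37.0, sigma_tau_n=-37.0,
        phi_h=0.05, phi_n=0.05, phi_r=1.0,
        k1=30.0, k2=1e-4, k_ca=20.0,
        alpha=2.0, beta=0.08, theta_syn=-57.0, sigma_syn=0.5,
    )


def tha_params() -> PopulationParams:
    """Thalamocortical relay neuron parameters.

    The table of constants for this population also lists a calcium
    conductance and calcium rate constants; the three-variable relay model
    (V, h, r) does not use them, but they are stored for completeness.
    """
    return PopulationParams(
        population_label="THA",
        g_leak=0.05, g_k=5.0, g_na=3.0, g_t=5.0, g_ca=0.5,
        e_leak=-70.0, e_k=-90.0, e_na=50.0, e_ca=140.0, e_t=0.0,
        theta_m=-37.0, theta_h=-41.0, theta_r=-84.0, theta_p=-60.0,
        sigma_m=7.0, sigma_h=-4.0, sigma_r=-4.0, sigma_p=6.2,
        tau_h0=1.0, tau_h1=500.0, tau_r0=40.0, tau_r1=17.5,
        k1=15.0,
        a_sm=5.0, delta_sm=5.0, t_sm=25.0,
    )


def default_params() -> dict[str, PopulationParams]:
    """Default parameter sets for all four populations."""
    return {
        "STN": stn_params(),
        "GPe": gp_params("GPe"),
        "GPi": gp_params("GPi"),
        "THA": tha_params(),
    }


def save_params(params: dict[str, PopulationParams], path) -> None:
    """Serialise a population->parameters mapping to YAML."""
    doc = {label: p.to_dict() for label, p in params.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_params(path) -> dict[str, PopulationParams]:
    """Load a population->parameters mapping written by :func:`save_params`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {label: PopulationParams.from_dict(d) for label, d in doc.items()}
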