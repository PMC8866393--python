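"""Exogenous drives and synaptic current assembly.

Three kinds of input act on the network:

* constant cortical/striatal currents ``I_app`` per population, whose values
  define the functional condition (normal vs Parkinsonian);
* the sensorimotor pulse train ``I_SM`` to the thalamus (5 pA, 5 ms pulses
  at 40 Hz) representing movement-programme input;
* the DBS pulse train ``I_DBS`` injected into every STN neuron
  (200 pA, 0.6 ms pulses at the stimulation frequency).

Both trains share the rectangular form
``A H(sin(2 pi t/T)) (1 - H(sin(2 pi (t+delta)/T)))`` with the exact
(discontinuous) Heaviside ``H``, yielding width-``delta`` pulses at period
``T``.  The smooth logistic step is used only inside the synaptic release
kinetics (``synapse_rhs``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import smooth_heaviside

__all__ = ["StimulusProtocol", "pulse_train", "synaptic_drive", "synapse_rhs",
           "APPLIED_CURRENTS"]

#: Striatal/cortical constant drives (pA) per condition.  The STN always
#: receives 4 pA of cortical drive; the Parkinsonian state disinhibits GPi
#: (4 -> 8 pA) and inhibits GPe (5 -> 3 pA); DBS keeps the Parkinsonian drives.
APPLIED_CURRENTS = {
    "normal": {"STN": 4.0, "GPe": 5.0, "GPi": 4.0},
    "parkinsonian": {"STN": 4.0, "GPe": 3.0, "GPi": 8.0},
    "dbs": {"STN": 4.0, "GPe": 3.0, "GPi": 8.0},
}


def _heaviside(x):
    # H(0) = 1 so that the pulse is active on [0, delta) exactly
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


def pulse_train(t, amplitude: float, width: float, period: float):
    """Rectangular pulse train value at time(s) ``t`` (ms).

    The train A H(sin(2 pi t/T)) (1 - H(sin(2 pi (t+delta)/T))) produces
    width-``delta`` rectangles once per period; we anchor the phase so that
    each pulse occupies ``[k T, k T + delta)``, which makes pulse onsets
    coincide with multiples of the period (the convention used for the
    response-efficacy windows).
    """
    if not 0.0 < width < period:
        raise ValueError("pulse width must satisfy 0 < width < period")
    t = np.asarray(t, dtype=float)
    phase = np.mod(t, period)
    return amplitude * (phase < width)


def synapse_rhs(s, v_pre, alpha: float, beta: float,
                theta_0: float, sigma_h: float):
    """Release-variable kinetics ds/dt = alpha (1-s) H(V - theta_0) - beta s.

    ``H`` is the smooth logistic step of width ``sigma_h``.  Under sustained
    presynaptic depolarisation s approaches alpha/(alpha+beta); otherwise it
    decays exponentially at rate beta.  s stays in [0, 1] for any bounded
    presynaptic voltage trajectory.
    """
    s = np.asarray(s, dtype=float)
    return alpha * (1.0 - s) * smooth_heaviside(v_pre, theta_0, sigma_h) - beta * s


def synaptic_drive(s_pre, adjacency, g: float, e_rev: float, v_post):
    """Per-postsynaptic-neuron synaptic current g (V_i - E_rev) sum_j A_ij s_j.

    ``adjacency`` is (n_post, n_pre) with A[i, j] = 1 iff presynaptic j
    projects to postsynaptic i; it may be a dense array or a scipy sparse
    matrix.  Positive values hyperpolarise (the current enters the membrane
    equation with a minus sign).
    """
    s_pre = np.asarray(s_pre, dtype=float)
    v_post = np.asarray(v_post, dtype=float)
    if adjacency.shape[1] != s_pre.shape[0]:
        raise ValueError("adjacency and presynaptic state shapes differ")
    if v_post.ndim and adjacency.shape[0] != v_post.shape[0]:
        raise ValueError("adjacency and postsynaptic state shapes differ")
    summed = adjacency @ s_pre
    return g * (v_post - e_rev) * summed


@dataclass
class StimulusProtocol:
    """Complete stimulus description for one functional condition.

    ``condition`` is ``normal``, ``parkinsonian`` or ``dbs``; the DBS pulse
    train is active only for ``dbs``, where its period is derived from
    ``dbs_frequency`` (Hz).
    """

    condition: str = "normal"
    i_app: dict = field(default_factory=dict)
    a_sm: float = 5.0
    delta_sm: float = 5.0
    t_sm: float = 25.0
    a_dbs: float = 200.0
    delta_dbs: float = 0.6
    dbs_frequency: float = 184.0

    def __post_init__(self) -> None:
        if self.condition not in APPLIED_CURRENTS:
            raise ValueError(f"unknown condition {self.condition!r}")
        defaults = dict(APPLIED_CURRENTS[self.condition])
        defaults.update(self.i_app)
        self.i_app = defaults
        if not 0.0 < self.delta_sm < self.t_sm:
            raise ValueError("SM pulse width must be below the period")
        if self.dbs_active and not 0.0 < self.delta_dbs < self.t_dbs:
            raise ValueError("DBS pulse width must be below the period")

    @property
    def dbs_active(self) -> bool:
        return self.condition == "dbs"

    @property
    def t_dbs(self) -> float:
        """DBS period in ms, derived from the requested frequency."""
        return 1000.0 / self.dbs_frequency

    def i_sm(self, t):
        """Sensorimotor drive to every thalamic neuron at time t."""
        return pulse_train(t, self.a_sm, self.delta_sm, self.t_sm)

    def i_dbs(self, t):
        """DBS current injected into every STN neuron at time t."""
        if not self.dbs_active:
            return np.zeros_like(np.asarray(t, dtype=float))
        return pulse_train(t, self.a_dbs, self.delta_dbs, self.t_dbs)

    def sm_onsets(self, t_start: float, t_stop: float) -> np.ndarray:
        """Onset times of sensorimotor pulses with t_start <= t < t_stop."""
        first = int(np.ceil(t_start / self.t_sm))
        last = int(np.ceil(t_stop / self.t_sm))
        return np.arange(first, last) * self.t_sm
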