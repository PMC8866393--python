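"""Macroscopic observables of the network dynamics.

From microscopic spike trains and synaptic release variables this module
derives the order parameters used to classify the normal, Parkinsonian and
DBS regimes:

* ``r(t)`` -- Kuramoto synchronisation index, the modulus of the
  population-mean unit phasor of per-neuron phases (GPi by default).
  Phases are assigned either piecewise-linearly between consecutive spikes
  (2 pi per interspike interval) or from the analytic signal via the
  Hilbert transform of the release variables.
* ``l(t)`` -- mean GPi synaptic activity, the population average of the
  release variables s_i; a proxy for the inhibitory drive to thalamus and
  for the local field potential.
* ``R`` -- thalamic response efficacy: the mean, over sensorimotor pulses,
  of the fraction of thalamic neurons that spike within twice the pulse
  width of the pulse onset.
* Shannon entropy of r and l, estimated from a fixed 50-bin histogram on
  [0, 1].
* The power spectrum of l(t) with its dominant peaks and the log-log
  spectral slope, which separates the three regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert, welch

from .engine import SimulationResult
from .stimulation import StimulusProtocol

__all__ = ["MacroSeries", "linear_phase", "phase_matrix", "hilbert_phase",
           "sync_index", "mean_synaptic_activity", "response_efficacy",
           "shannon_entropy", "spectrum_and_slope", "dominant_peak",
           "compute_macro"]


def linear_phase(spike_times: np.ndarray, t) -> np.ndarray:
    """Piecewise-linear phase of one neuron: 2 pi per interspike interval.

    theta(t) = 2 pi (t - t_n)/(t_{n+1} - t_n) + 2 pi n for t in
    [t_n, t_{n+1}).  Outside [first spike, last spike) the phase is
    undefined and NaN is returned.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    t = np.asarray(t, dtype=float)
    if spike_times.size < 2:
        return np.full(t.shape, np.nan)
    n = np.searchsorted(spike_times, t, side="right") - 1
    valid = (n >= 0) & (n < spike_times.size - 1)
    nn = np.clip(n, 0, spike_times.size - 2)
    t0 = spike_times[nn]
    t1 = spike_times[nn + 1]
    theta = 2.0 * np.pi * ((t - t0) / (t1 - t0) + nn)
    return np.where(valid, theta, np.nan)


def phase_matrix(spikes: list, t_grid: np.ndarray) -> np.ndarray:
    """(n_times, n_neurons) matrix of linear phases; NaN where undefined."""
    return np.column_stack([linear_phase(s, t_grid) for s in spikes])


def hilbert_phase(signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, wrapped to [0, 2 pi)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 256:
        raise ValueError("need at least 256 samples for a stable transform")
    if np.ptp(signal) == 0:
        raise ValueError("phase of a constant signal is undefined")
    analytic = hilbert(signal - signal.mean())
    return np.mod(np.angle(analytic), 2.0 * np.pi)


def sync_index(phases: np.ndarray) -> np.ndarray:
    """Kuramoto order parameter r = |mean_k exp(i theta_k)|.

    ``phases`` is (n_neurons,) for one instant or (n_times, n_neurons);
    NaN phases (undefined, e.g. outside a neuron's spike span) are
    excluded, and N is the per-time count of defined phases.  Requires at
    least two defined phases.
    """
    phases = np.asarray(phases, dtype=float)
    one_d = phases.ndim == 1
    ph = np.atleast_2d(phases)
    defined = np.isfinite(ph)
    counts = defined.sum(axis=1)
    if np.any(counts < 2):
        raise ValueError("need at least 2 defined phases at every instant")
    z = np.where(defined, np.exp(1j * np.where(defined, ph, 0.0)), 0.0)
    r = np.abs(z.sum(axis=1)) / counts
    return float(r[0]) if one_d else r


def mean_synaptic_activity(s: np.ndarray) -> np.ndarray:
    """l(t): arithmetic mean of the release variables across neurons."""
    s = np.asarray(s, dtype=float)
    return s.mean(axis=-1)


def response_efficacy(tha_spikes: list, sm_onsets: np.ndarray,
                      delta: float = 5.0,
                      window: tuple[float, float] = (500.0, 1500.0)) -> float:
    """Thalamic response efficacy R in [0, 1].

    For each sensorimotor pulse onset t_i inside ``window``, a_i is the
    fraction of thalamic neurons with at least one spike in
    [t_i, t_i + 2 delta]; R is the mean of a_i over pulses.
    """
    onsets = np.asarray(sm_onsets, dtype=float)
    onsets = onsets[(onsets >= window[0]) & (onsets < window[1])]
    if onsets.size == 0:
        raise ValueError("no sensorimotor pulses inside the window")
    n_tha = len(tha_spikes)
    frac = np.zeros(onsets.size)
    for s in tha_spikes:
        if len(s) == 0:
            continue
        idx_lo = np.searchsorted(s, onsets, side="left")
        idx_hi = np.searchsorted(s, onsets + 2.0 * delta, side="right")
        frac += (idx_hi > idx_lo)
    return float(np.mean(frac / n_tha))


def shannon_entropy(x: np.ndarray, bins: int = 50,
                    support: tuple[float, float] = (0.0, 1.0)) -> float:
    """Histogram estimate of the Shannon entropy -sum p ln p (nats).

    The histogram uses ``bins`` equal bins on a fixed support so that
    entropies of different runs are comparable; 0 ln 0 := 0.  A constant
    series has entropy 0; a series uniform over the bins attains ln(bins).
    """
    x = np.asarray(x, dtype=float)
    if x.size < bins:
        raise ValueError("series shorter than the number of bins")
    counts, _ = np.histogram(x, bins=bins, range=support)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def spectrum_and_slope(t: np.ndarray, x: np.ndarray,
                       fit_band: tuple[float, float] = (1.0, 100.0),
                       peak_prominence_decades: float = 1.0,
                       peak_exclude_hz: float = 2.0):
    """Averaged power spectrum of a macroscopic series, peaks, log-log slope.

    The spectrum is a Welch estimate (Hann windows of half the series
    length, 50% overlap), whose segment averaging suppresses the large
    bin-to-bin variance of a raw periodogram; peaks are local maxima of
    log10 power with the given prominence (in decades) inside the fit
    band; the slope is the least-squares fit of log10 power against log10
    frequency over the fit band, excluding ``peak_exclude_hz`` around each
    detected peak (so that narrow rhythmic peaks do not dominate the
    broadband estimate).

    Returns (freq, power, peak_freqs, slope).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    dt = t[1] - t[0]
    fs = 1000.0 / dt  # ms -> Hz
    if fit_band[1] > fs / 2.0:
        raise ValueError("fit band exceeds the Nyquist frequency")
    nperseg = max(256, x.size // 2)
    freq, power = welch(x - x.mean(), fs=fs, nperseg=min(nperseg, x.size))

    in_band = (freq >= fit_band[0]) & (freq <= fit_band[1])
    fb, pb = freq[in_band], power[in_band]
    safe = pb > 0
    logp = np.full(pb.shape, -np.inf)
    logp[safe] = np.log10(pb[safe])
    pk, _ = find_peaks(logp, prominence=peak_prominence_decades)
    peak_freqs = fb[pk]

    keep = safe.copy()
    for f0 in peak_freqs:
        keep &= np.abs(fb - f0) > peak_exclude_hz
    if keep.sum() < 10:
        keep = safe
    slope = float(np.polyfit(np.log10(fb[keep]), logp[keep], 1)[0])
    return freq, power, peak_freqs, slope


def dominant_peak(freq: np.ndarray, power: np.ndarray,
                  fmax: float = 30.0, fmin: float = 1.0) -> float:
    """Frequency of the highest-power local maximum below ``fmax`` Hz."""
    band = (freq >= fmin) & (freq <= fmax)
    fb, pb = freq[band], power[band]
    pk, _ = find_peaks(pb)
    if pk.size == 0:
        return float(fb[np.argmax(pb)])
    return float(fb[pk[np.argmax(pb[pk])]])


@dataclass
class MacroSeries:
    """Macroscopic time series and scalars derived from one simulation."""

    t_r: np.ndarray              # 1 ms grid for r(t)
    r: np.ndarray                # synchronisation index, NaN before phases exist
    t_l: np.ndarray              # output grid for l(t)
    l: np.ndarray                # mean GPi synaptic activity
    response: float              # thalamic response efficacy R
    entropy_r: float
    entropy_l: float
    spectrum_freq: np.ndarray
    spectrum_power: np.ndarray
    peak_freqs: np.ndarray
    slope: float
    condition: str = ""
    dbs_frequency: float | None = None

    def summary(self) -> dict:
        return {
            "condition": self.condition,
            "dbs_frequency": self.dbs_frequency,
            "R": self.response,
            "entropy_r": self.entropy_r,
            "entropy_l": self.entropy_l,
            "slope": self.slope,
            "peak_freqs": [float(f) for f in np.round(self.peak_freqs, 3)],
            "mean_l": float(np.mean(self.l[self.t_l >= 500.0])),
            "mean_r": float(np.nanmean(self.r[self.t_r >= 500.0])),
        }

    def to_frame(self) -> pd.DataFrame:
        """(t, r, l) on the 1 ms grid, for CSV export."""
        l_on_r = np.interp(self.t_r, self.t_l, self.l)
        return pd.DataFrame({"t_ms": self.t_r, "r": self.r, "l": l_on_r})


def compute_macro(result: SimulationResult,
                  protocol: StimulusProtocol | None = None,
                  phase_method: str = "linear",
                  spectral_window: tuple[float, float] = (500.0, 1500.0),
                  entropy_window: tuple[float, float] = (0.0, 1500.0),
                  bins: int = 50) -> MacroSeries:
    """All macroscopic observables of one simulation.

    r(t) uses the GPi spike trains with linear interspike phases by default
    (``phase_method='hilbert'`` switches to analytic-signal phases of the
    GPi release variables).  Entropies use the full run including the
    transient; R and the spectrum use the post-transient window.
    """
    protocol = protocol or result.protocol
    t_end = result.duration
    t_r = np.arange(0.0, t_end + 0.5, 1.0)
    if phase_method == "linear":
        phases = phase_matrix(result.spikes["GPi"], t_r)
    elif phase_method == "hilbert":
        cols = []
        for j in range(result.s_gpi.shape[1]):
            sj = result.s_gpi[:, j]
            if np.ptp(sj) == 0:  # silent synapse: phase undefined
                cols.append(np.full(sj.shape, np.nan))
            else:
                cols.append(np.unwrap(hilbert_phase(sj)))
        phases = np.column_stack(cols)
        idx = np.searchsorted(result.t, t_r)
        phases = phases[np.clip(idx, 0, len(result.t) - 1)]
    else:
        raise ValueError("phase_method must be 'linear' or 'hilbert'")

    defined = np.isfinite(phases).sum(axis=1) >= 2
    r = np.full(t_r.shape, np.nan)
    if defined.any():
        r[defined] = sync_index(phases[defined])

    l = mean_synaptic_activity(result.s_gpi)

    upper = min(spectral_window[1], t_end)
    onsets = protocol.sm_onsets(0.0, t_end)
    response = response_efficacy(result.spikes["THA"], onsets,
                                 delta=protocol.delta_sm,
                                 window=(spectral_window[0], upper))

    ent_mask_r = (t_r >= entropy_window[0]) & (t_r <= min(entropy_window[1], t_end))
    r_ent = r[ent_mask_r]
    entropy_r = shannon_entropy(r_ent[np.isfinite(r_ent)], bins=bins)
    t_l_1ms = np.arange(entropy_window[0], min(entropy_window[1], t_end) + 0.5, 1.0)
    entropy_l = shannon_entropy(np.interp(t_l_1ms, result.t, l), bins=bins)

    spec_mask = (result.t >= spectral_window[0]) & (result.t <= upper)
    freq, power, peaks, slope = spectrum_and_slope(result.t[spec_mask], l[spec_mask])

    return MacroSeries(t_r=t_r, r=r, t_l=result.t, l=l, response=response,
                       entropy_r=entropy_r, entropy_l=entropy_l,
                       spectrum_freq=freq, spectrum_power=power,
                       peak_freqs=peaks, slope=slope,
                       condition=protocol.condition,
                       dbs_frequency=protocol.dbs_frequency
                       if protocol.dbs_active else None)
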