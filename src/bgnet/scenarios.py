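"""Scenario presets, frequency sweeps and reporting.

A scenario bundles everything one published-figure-scale run needs: the
functional condition (normal, parkinsonian, dbs), duration, topology and
initial-state seeds, solver settings and output options.  ``run_scenario``
builds the network, integrates it and derives all macroscopic observables;
``frequency_sweep`` repeats the DBS scenario over a frequency grid with
shared seeds and tabulates (f, R, entropies, slope).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, medfilt

from .engine import SimulationResult, integrate, raster
from .macro import MacroSeries, compute_macro
from .stimulation import StimulusProtocol
from .topology import build_full_network

__all__ = ["ScenarioConfig", "run_scenario", "frequency_sweep", "sweep_peaks",
           "thalamic_relay_rate"]


def thalamic_relay_rate(duration: float = 2000.0,
                        transient: float = 250.0) -> float:
    """Firing rate (Hz) of one isolated thalamic cell under the 40 Hz
    sensorimotor pulse train; 1:1 relay corresponds to 40 Hz."""
    from .neurons import integrate_single, spike_times_from_trace
    from .params import tha_params
    from .stimulation import pulse_train
    p = tha_params()
    t, v = integrate_single(
        p, i_sm_fn=lambda t: pulse_train(t, p.a_sm, p.delta_sm, p.t_sm),
        duration=duration, v0=-65.0, max_step=p.delta_sm / 4.0)
    spikes = spike_times_from_trace(t, v)
    spikes = spikes[spikes >= transient]
    return 1000.0 * spikes.size / (duration - transient)


@dataclass
class ScenarioConfig:
    """Declarative description of one simulation scenario."""

    condition: str = "normal"
    duration: float = 1500.0
    dbs_frequency: float = 184.0
    topology_seed: int = 0
    state_seed: int = 0
    stn_variant: str = "sparse"
    rtol: float = 1e-6
    atol: float = 1e-6
    method: str = "rk23"
    phase_method: str = "linear"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.duration < 1000.0:
            raise ValueError("duration must be >= 1000 ms (R needs the "
                             "500-1500 ms window)")
        if self.dbs_frequency <= 0:
            raise ValueError("DBS frequency must be positive")

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(condition=self.condition,
                                dbs_frequency=self.dbs_frequency)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _save_figures(result: SimulationResult, macro: MacroSeries, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(9, 8), sharex=True)
    for ax, pop in zip(axes[:2], ("STN", "GPi")):
        df = raster(result, pop)
        ax.plot(df["time_ms"], df["neuron_index"], ".k", markersize=1)
        ax.set_ylabel(f"{pop} neuron")
    axes[2].plot(macro.t_r, macro.r, label="r(t)")
    axes[2].plot(macro.t_l, macro.l, label="l(t)")
    axes[2].set_xlabel("time (ms)")
    axes[2].legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(out / "overview.png", dpi=120)
    plt.close(fig)


def run_scenario(config: ScenarioConfig,
                 save_traces: bool = False,
                 save_figures: bool = False
                 ) -> tuple[SimulationResult, MacroSeries]:
    """Build, integrate and analyse one scenario.

    If ``config.out_dir`` is set, writes the run manifest, the macro series
    CSV, the summary JSON, the GPi/STN rasters, an overview figure (rasters
    plus order parameters, with ``save_figures``) and optionally the full
    trace container there.
    """
    topo = build_full_network(seed=config.topology_seed,
                              stn_variant=config.stn_variant)
    proto = config.protocol()
    result = integrate(topo, proto, t_span=config.duration,
                       rtol=config.rtol, atol=config.atol,
                       seed=config.state_seed, method=config.method)
    macro = compute_macro(result, proto, phase_method=config.phase_method,
                          spectral_window=(500.0, min(1500.0, config.duration)))

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"config": asdict(config), "solver": result.solver,
                    "summary": macro.summary()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        macro.to_frame().to_csv(out / "macro_series.csv", index=False)
        for pop in ("STN", "GPi", "THA"):
            raster(result, pop).to_csv(out / f"raster_{pop.lower()}.csv",
                                       index=False)
        if save_figures:
            _save_figures(result, macro, out)
        if save_traces:
            result.save(out / "result.h5")
    return result, macro


def frequency_sweep(frequencies, topology_seed: int = 0, state_seed: int = 0,
                    duration: float = 1500.0, out_dir: str | None = None,
                    **scenario_kwargs) -> pd.DataFrame:
    """Run the DBS scenario at each frequency with shared seeds.

    Returns a table with one row per frequency: response efficacy R,
    entropies of r and l, spectral slope and mean l.  Rows are independent,
    so the result does not depend on execution order.
    """
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if frequencies.size < 2:
        raise ValueError("a sweep needs at least two frequencies")
    rows = []
    for f in frequencies:
        cfg = ScenarioConfig(condition="dbs", dbs_frequency=float(f),
                             topology_seed=topology_seed,
                             state_seed=state_seed, duration=duration,
                             **scenario_kwargs)
        _, macro = run_scenario(cfg)
        rows.append({"frequency": float(f), "R": macro.response,
                     "entropy_r": macro.entropy_r, "entropy_l": macro.entropy_l,
                     "slope": macro.slope,
                     "mean_l": float(np.mean(macro.l[macro.t_l >= 500.0]))})
    table = pd.DataFrame(rows).sort_values("frequency", ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "frequency_sweep.csv", index=False)
    return table


def sweep_peaks(table: pd.DataFrame, column: str = "R",
                prominence: float = 0.05) -> np.ndarray:
    """Local maxima of a sweep column after 3-point median smoothing."""
    x = medfilt(table[column].to_numpy(), kernel_size=3)
    pk, _ = find_peaks(x, prominence=prominence)
    return table["frequency"].to_numpy()[pk]
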