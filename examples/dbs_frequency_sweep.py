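"""Coarse DBS frequency sweep.

Sweeps the stimulation frequency over 60-250 Hz in 10 Hz steps (a coarse
version of the 2 Hz production sweep), tabulating the thalamic response
efficacy R and the entropies of the order parameters, then reports the
local maxima of R.  With the full 2 Hz sweep this is the frequency-
response curve used to identify therapeutic stimulation windows.

Expect roughly an hour at this resolution; pass --fast for a 3-point demo.
"""

import sys

import numpy as np

from bgnet.scenarios import frequency_sweep, sweep_peaks

freqs = np.array([150.0, 184.0, 210.0]) if "--fast" in sys.argv \
    else np.arange(60.0, 251.0, 10.0)
table = frequency_sweep(freqs, topology_seed=1, state_seed=1)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
peaks = sweep_peaks(table)
print("local maxima of R at:", ", ".join(f"{f:.0f} Hz" for f in peaks)
      if peaks.size else "none detected at this resolution")
print("Higher R = better thalamic relay under stimulation; entropy minima "
      "of r and l co-locate with effective frequencies.")
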