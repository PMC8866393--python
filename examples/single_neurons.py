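"""Current-frequency behaviour of the isolated cell models.

Integrates one uncoupled neuron of each type under constant current
injections and prints its firing rate (upward crossings of -15 mV after a
500 ms transient).  The subthalamic cell fires spontaneously at a few Hz
and speeds up roughly linearly with depolarising current; the pallidal
cell is a fast pacemaker (tens of Hz at rest) that switches to bursting
near 6-8 pA.
"""

from bgnet import single_neuron_rate
from bgnet.params import gp_params, stn_params

for label, p, currents in [("STN", stn_params(), (0.0, 4.0, 10.0)),
                           ("GP", gp_params(), (0.0, 3.0, 5.0, 8.0))]:
    for i_app in currents:
        rate = single_neuron_rate(p, i_app)
        print(f"{label:3s} I_app={i_app:5.1f} pA -> {rate:5.1f} Hz")
print("Each line: firing rate of one isolated neuron under constant drive;")
print("the 2.5 s integration discards the first 500 ms as transient.")
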