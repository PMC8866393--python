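# bgnet — a basal ganglia–thalamus network model with deep brain stimulation

`bgnet` simulates a large-scale conductance-based model of the motor loop
implicated in Parkinson's disease: 500 subthalamic (STN), 500 external and
500 internal pallidal (GPe/GPi) neurons wired in small-world topologies,
projecting onto 200 thalamocortical relay cells.  It is aimed at
computational neuroscientists studying how striatal drive shifts the
network between a healthy and a Parkinsonian regime, and how high-frequency
deep brain stimulation (DBS) of the STN reshapes the basal ganglia output
that gates thalamic relay of sensorimotor commands.

## Model

Each basal ganglia neuron follows a Hodgkin–Huxley current balance

```
C dV/dt = −I_LEAK − I_K − I_Na − I_Ca − I_T − I_AHP − I_syn + I_app + I_DBS
```

with gating variables x ∈ {n, h, r} relaxing as dx/dt = (x∞(V) − x)/τ_x(V),
an intracellular calcium pool driving the after-hyperpolarisation current,
and first-order synaptic release ds/dt = α(1−s)H(V−θ) − βs (Terman-type
pallido-subthalamic cell models).  The thalamic relay cell is a reduced
three-variable (V, h, r) Rubin–Terman-type neuron driven by GABAergic GPi
input and a 40 Hz sensorimotor pulse train (5 pA, 5 ms).  DBS is a
rectangular pulse train (200 pA, 0.6 ms) injected into every STN neuron at
a chosen frequency.

Functional states differ only in the constant striatal/cortical drives:
normal (STN 4, GPe 5, GPi 4 pA), Parkinsonian (GPe 3, GPi 8 pA —
disinhibited GPi, inhibited GPe) and DBS (Parkinsonian drives plus the
pulse train).  Macroscopic readouts: the Kuramoto synchronisation index
r(t) of GPi phases, the mean GPi synaptic activity l(t) (a local-field-
potential proxy), the thalamic response efficacy R (mean fraction of
thalamic cells answering each sensorimotor pulse), Shannon entropies of r
and l, and the log–log slope of the l(t) power spectrum.

## Worked example

```
$ python examples/single_neurons.py
STN I_app=  0.0 pA ->   2.5 Hz
STN I_app=  4.0 pA ->   5.5 Hz
STN I_app= 10.0 pA ->  12.5 Hz
GP  I_app=  0.0 pA ->  34.5 Hz
GP  I_app=  3.0 pA ->  54.5 Hz
GP  I_app=  5.0 pA ->  59.0 Hz
GP  I_app=  8.0 pA ->  39.0 Hz
```

The subthalamic cell fires spontaneously at ~2.5 Hz and accelerates with
depolarising current; the pallidal cell is a fast pacemaker whose rate
first grows with drive and then drops when it switches into burst firing
near 6–8 pA — the single-cell signature behind pathological pallidal
bursting.  `examples/thalamic_relay.py` shows the isolated relay cell
locking 1:1 (40 Hz) to the sensorimotor train;
`examples/network_conditions.py` runs the full 1700-neuron network through
the three functional states and prints R, l and the spectral slope; and
`examples/dbs_frequency_sweep.py` scans the DBS frequency.

A thin CLI wraps the same pipeline:

```
bgnet run --condition dbs --dbs-frequency 184 --seed 1 --out out/
bgnet sweep --fmin 50 --fmax 250 --step 2 --out sweep/
```

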