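# Methods

## Populations and cell models

Four populations are simulated: subthalamic nucleus (STN, 500 cells),
globus pallidus externa and interna (GPe/GPi, 500 each, sharing one cell
model) and thalamus (THA, 200 relay cells); 1700 neurons in total.

STN/GPe/GPi cells are single-compartment Hodgkin–Huxley models with leak,
potassium, sodium, high-threshold calcium, low-threshold T-type and
calcium-gated after-hyperpolarisation currents:

* I_LEAK = g_L (V − E_L), I_K = g_K n⁴ (V − E_K),
  I_Na = g_Na m∞³ h (V − E_Na), I_Ca = g_Ca s∞² (V − E_Ca),
  I_AHP = g_AHP [Ca]/([Ca]+k₁) (V − E_K).
* The T-current differs between nuclei: STN uses g_T a∞³ b∞(r)² (V − E_Ca)
  with the helper gate b∞(r) a function of the slow gate r; the pallidal
  cells use g_T a∞³ r (V − E_K).  The potassium-reversal driving force in
  the pallidal form tempers rebound bursting relative to STN; a config
  flag (`gp_it_uses_e_ca`) restores the calcium-reversal variant, which in
  our measurements slows the pallidal pacemaker to ~7 Hz and was therefore
  rejected as the default.
* Gates relax as dx/dt = (x∞(V) − x)/τ_x(V) with logistic x∞ and
  τ_x(V) = [τ_x0 + τ_x1/(1+e^{−(V−θ_τx)/σ_τx})]/φ_x; where no sigmoid
  parameters exist for a gate (pallidal r) the constant τ_x0/φ_x is used,
  and `constant_tau` forces that for all gates.
* Calcium: d[Ca]/dt = k₂(−I_Ca − I_T − k_Ca [Ca]).

The thalamic relay cell carries V, h, r with
I_K = g_K (0.75(1−h))⁴ (V−E_K), I_Na = g_Na m∞³ h (V−E_Na),
I_T = g_T p∞² r (V−E_T), closed-form τ_h(V) = 1/(a_h+b_h) and
τ_r(V) = 28 + e^{−(V+25)/10.5} (a literal variant 28 + (1+e^{−(V+25)/10.5})
is selectable).

### Parameter provenance

Parameter values follow the published tables for this model family.  A few
entries are internally inconsistent with the cell behaviour the same
source reports (sign or decimal point lost); the defaults resolve these in
favour of reproducing the single-cell behaviour: STN σ_h = −3.1, pallidal
θ_a = −57 mV and θ_s = −35 mV, thalamic σ_h = σ_r = −4 (inactivation gates
must close with depolarisation), σ_s = 8 (STN) / 2 (GP), pallidal φ_r = 1.
Membrane capacitance is C = 1 in the nS/µm², pA/µm², mV, ms unit
convention.  With these defaults the isolated cells fire at 2.5 Hz (STN,
0 pA), 12.5 Hz (STN, 10 pA), 34.5 Hz (GP, 0 pA) and 59 Hz (GP, 5 pA) under
the standard measurement protocol (2.5 s, 500 ms transient, spikes =
upward crossings of −15 mV with a 2 ms lockout).

The pallidal current–frequency curve is non-monotone: the cell switches
from tonic pacemaking to burst firing near 6–8 pA and the threshold-
crossing rate drops.  Monotonicity therefore holds for the STN cell over
0–20 pA and for the pallidal tonic branch (≲5 pA) only.

### Synaptic release step width

The release kinetics ds/dt = α(1−s)H(V−θ₀) − βs use a logistic smooth
step H of width σ_H, which is not constrained by the cell tables.  Wide
steps (σ_H of a few mV) leave the release variables half-activated at
subthreshold voltages; the resulting tonic mutual inhibition freezes the
whole network into a silent state in every condition.  The defaults are
therefore sharp widths — σ_H = 1.0 mV (STN, θ₀ = −39 mV) and 0.5 mV
(GP, θ₀ = −57 mV) — so that release tracks suprathreshold excursions, as
a smooth approximation of a step function should.  Both widths are
configurable.

## Connectivity

Boolean directed adjacencies per projection (A_ij = 1 iff presynaptic j
contacts postsynaptic i), built from a single integer seed:

* intra-GPe / intra-GPi: Watts–Strogatz rings, k = 20, p = 0.005, each
  undirected edge realised in both directions;
* intra-STN (default "sparse"): 20% of neurons are hubs; undirected
  hub–hub edges are drawn, with ring-distance band weights 30% (|Δ| ≤ 10),
  45% (10 < |Δ| ≤ 20) and 25% (|Δ| > 25), until the mean hub degree is 25;
  the remaining 400 neurons stay unconnected.  A "dense" variant uses a
  k = 20 small-world ring;
* GPe↔STN and STN→GPi: index-matched one-to-one projections;
* GPe→GPi: 18 ring-local targets (9 per side) plus 2 uniform remote
  targets per GPe cell (mean out-degree 20);
* GPi→THA: a 200-cell GPi pool is drawn uniformly; every thalamic cell
  samples 3 distinct afferents from it.

Synaptic conductances (g_STST, g_GPST, g_GPeGPe, g_STGPe, g_GPiGPi,
g_GPeGPi, g_STGPi, g_GPiTha) = (0.5, 4.5, 0.07, 0.56, 0.07, 0.01, 0.2,
0.1) nS/µm², E_Glu = −10 mV, E_GABA = −70 mV, identical across
conditions.  The default build contains 34 600 directed synapses.

## Stimulation

Constant drives per condition (pA): normal STN 4 / GPe 5 / GPi 4;
Parkinsonian and DBS: STN 4 / GPe 3 / GPi 8.  The sensorimotor train to
the thalamus is a 5 pA, 5 ms rectangular pulse every 25 ms; DBS injects
200 pA, 0.6 ms pulses into every STN neuron at period 1000/f ms.  Pulse
trains place each pulse at the start of its period, so onsets coincide
with multiples of the period (a pure phase choice; the response-efficacy
windows are anchored at these onsets).  The exact (discontinuous) step is
used for pulse trains; the smooth logistic step only inside the release
kinetics.

## Numerical integration

The coupled 9 600-dimensional system is integrated with an adaptive
embedded Bogacki–Shampine Runge–Kutta 3(2) pair (the ode23 family),
relative and absolute tolerances 10⁻⁶, RMS error norm over all states, and
a step-size ceiling of a quarter of the narrowest active pulse width
(0.15 ms under DBS) so pulses are never stepped over.  A fixed-step RK4
integrator is available as a fallback.  States are recorded on a uniform
0.1 ms grid through the cubic Hermite interpolant of each accepted step.

Two performance measures keep a 1.5 s run at a few minutes on one CPU
without touching the model definition: the hot loop is compiled with
numba, and all purely voltage-dependent gating curves are pre-tabulated on
a 0.02 mV grid and linearly interpolated (interpolation error below
~10⁻⁶, i.e. below the integration tolerances; the tables are generated
from the same analytic functions the reference right-hand side uses, and a
test asserts the two agree).

Initial conditions: V₀ ~ U(−70, −50) mV per neuron from the run seed,
gates at their steady state for V₀, [Ca]₀ = 0.1, s₀ = 0.  Runs are
bit-reproducible given (topology seed, state seed, solver settings).

## Macroscopic observables

* r(t): modulus of the mean unit phasor over GPi phases, evaluated on a
  1 ms grid.  Phases are piecewise-linear between consecutive spikes (2π
  per interspike interval) by default; an analytic-signal (Hilbert) phase
  of the release variables is available.  Neurons without a defined phase
  at t are excluded and N is the count of defined phases.
* l(t): population mean of the GPi release variables on the 0.1 ms output
  grid.
* R: for each sensorimotor pulse onset t_i in 500–1500 ms, the fraction of
  thalamic neurons with ≥1 spike in [t_i, t_i+2δ] (δ = 5 ms), averaged
  over pulses.
* Entropies: 50 equal bins on [0, 1], series sampled at 1 ms over the full
  0–1500 ms window including the transient (deliberately, to capture the
  onset response); natural logarithm, so the maximum is ln 50 ≈ 3.91.
* Spectrum and slope: Welch estimate (Hann windows of half the series,
  50% overlap) of the mean-removed l(t) on 500–1500 ms — segment averaging
  suppresses the χ² bin noise of a raw periodogram at the cost of 2 Hz
  resolution;
  peaks are local maxima of log₁₀ power with ≥1 decade prominence inside
  the 1–100 Hz fit band; the slope is the least-squares fit of log₁₀ power
  against log₁₀ frequency over that band excluding ±2 Hz around each
  detected peak, so narrow rhythmic peaks do not dominate the broadband
  exponent.

## Problem sizes used in tests and the acceptance script

Network-level checks use single 1500 ms runs per condition (one topology
seed, one initial-state seed); the acceptance script derives all seeds
from its `--seed` argument.  Engine unit tests use 300–1000 ms runs.
Single-cell rates use 2.5 s integrations.  The frequency-sweep example
defaults to a 10 Hz grid; production sweeps use 2 Hz.

## Known limitations

* The reconstruction reproduces the qualitative regime structure —
  pallidal output and mean synaptic activity l rise from normal to
  Parkinsonian drives, thalamic relay degrades, and 184 Hz DBS entrains
  STN and regularises GPi — but not all published-scale numbers: isolated
  STN rates run ~15–20% below the nominal 3/15 Hz points, the normal-state
  response efficacy comes out near 0.7 rather than ~0.5, the Parkinsonian
  response does not collapse to zero, and the l(t) spectral slopes are
  shallower than the nominal −3.6/−2.5/−3.1 because the simulated GPi
  population remains largely asynchronous (synchronisation index near the
  1/√N floor).  The DBS-vs-Parkinsonian ordering of R is consequently not
  reproduced.  Single-relay-cell experiments (conductance-based GPi input,
  both GABA reversal variants, both τ_r variants) show tonic inhibition at
  the published synaptic strength silences the relay, so the rescue must
  rely on synchronisation structure this reconstruction does not develop.
  The affected checks assert the published values and fail honestly.
* Gating-table interpolation adds a ≤10⁻⁶ relative error to the gating
  curves; tolerance-halving experiments show single-neuron spike times
  stable to <1 ms over 2 s.
* For weakly synchronised activity the two phase estimators disagree
  systematically: the spike-phase synchronisation index sits near the
  1/√N incoherence floor (~0.05 for 500 cells) while the analytic-signal
  index also reflects common slow modulation of the release traces
  (~0.2–0.3).  They converge only when the population actually locks.
* The network is chaotic: trajectory-level comparisons across solver
  settings diverge within a few hundred ms; population rates and the
  macroscopic observables are the stable quantities.
* No channel noise, no plasticity, no multi-compartment morphology, no
  charge-balanced biphasic DBS waveforms, no electrode field model.
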