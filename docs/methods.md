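# Methods

`dbsnet` simulates pathologically synchronized populations of bursting
neurons — a computational caricature of the parkinsonian subthalamic
nucleus (STN) — and the desynchronizing action of high-frequency deep brain
stimulation (DBS). This note documents the models, the measurement
pipeline, every parameter that is a package choice rather than a published
constant, and what the simulations do and do not show.

## Neuron models

### Morris-Lecar reference backend

Each neuron follows four delayed ODEs: membrane potential `v`, K⁺ gating
fraction `w`, a slow current `I_slow`, and a synaptic gate `s`:

    C dv/dt     = −g_Ca m∞(v)(v−v_Ca) − g_K w (v−v_K) − g_L (v−v_L)
                  + I_slow + I_syn + I_noise + s₁ X₁ I_stim
    dw/dt       = φ (w∞(v) − w) / τ_w(v)
    dI_slow/dt  = ε_j (v* − v(t−τ_j) − α I_slow) − s₂ X₁ |I_stim|
    ds/dt       = α_s H∞(v)(1−s) − β_s s

with the canonical hyperbolic activation curves m∞ = (1+tanh((v−v₁)/v₂))/2,
w∞ = (1+tanh((v−v₃)/v₄))/2, τ_w = 1/cosh((v−v₃)/(2v₄)) and the logistic
gate activation H∞(v) = 1/(1+exp(−(v−θ_s)/σ_s)). The model is
dimensionless; the package identifies one time unit with 1 ms, which puts
the resulting burst rhythm (~3.6 Hz in the coupled lattice, ~5.5 Hz
isolated) in the tremor band.

The slow current is the burst generator: it integrates the delayed
deviation of `v` from the set point `v* = −0.22` (delay τ_j = 10 ms, the
abstracted STN→GPe→STN inhibitory loop) and alternates the spike generator
between firing and quiescence. With the reference parameter set
(`MLParams` defaults) the isolated neuron emits bursts with a median of 8
spikes. Per-neuron rates ε_j are Gaussian (2·10⁻³ ± 2·10⁻⁵), dispersing
natural burst frequencies by ~1%.

Integration is classical RK4 at dt = 0.025 ms; the delayed potential reads
a ring-buffer history (constant initial history, linear interpolation at
the RK4 midpoint). `w` and `s` are clamped to [0,1] — both are fractions,
and the clamp also removes the numerical stiffness of τ_w → 0 at strongly
hyperpolarized potentials.

### Izhikevich reduced backend

The large-population backend is the quadratic adaptation model

    dv/dt = 0.04 v² + 5v + 140 − u + I,   du/dt = a(bv − u)

with after-spike reset (v←c, u←u+d at v ≥ 30 mV), a = 0.02, b = 0.2,
c = −50 mV, d = 0.7, integrated by forward Euler at dt = 0.1 ms with exact
spike-time logging. Two parameters are package choices:

- **Tonic drive (default 4.0).** The printed drive of 22 produces tonic
  spiking, not bursting, at any step size; the bursting regime of this
  parameter set lies near drive ≈ 4–5. The default 4.0 gives 8–9 spikes
  per burst at ~6.5 Hz, matching the Morris-Lecar reference bursts. It is
  exposed as `IzhParams.drive`.
- **Drive dispersion (`drive_sd`, default 0.05).** In a population the
  drive is drawn per neuron from N(drive, drive_sd), clipped to the
  bursting band [3.6, 5.5]. This is the reduced model's analog of the
  Morris-Lecar ε_j spread: without natural-frequency dispersion, identical
  oscillators lock to any common input, which trivializes synchrony (R ≡ 1)
  and makes desynchronization untransferable between populations.

## Coupling

Neurons sit on a square lattice (spacing dl = 0.1), coupled all-to-all
through a Gaussian spatial kernel w(d) = exp(−d²/2σ_g²), σ_g = 0.5, with

    I_syn,j = (ḡ_s / c_n) Σ_k w(D_jk) s_k (v_j − v_rev)

The reversal constant (−0.85 ML, −0.8 Izhikevich) lies *below* the entire
voltage range, so the driving force (v_j − v_rev) is strictly positive:
the coupling is excitatory (glutamatergic), stronger the more depolarized
the target. This driving-force orientation is essential — with the
opposite sign the same constants make the coupling hyperpolarizing and the
lattice never synchronizes. c_n is a fixed normalization constant (2.0584
for N=100, 2.1765 for N=225); `auto_c_n` offers a size-consistent
alternative for other lattices.

For the Izhikevich backend the synaptic expression is inherited unchanged
from the dimensionless formulation: the driving force is evaluated on
v/100 (`v_scale = 0.01`, mapping mV into the dimensionless range) and the
resulting current is scaled into the model's current units by
`i_scale = 5`, calibrated once so that the full coupling synchronizes a
random-state population within ~1 s while a quarter of it (the driven
population's "weak" coupling) does not synchronize at all.

The "random network" variant adds Gaussian jitter (sd 0.1) to the pairwise
*distances* (not positions), drawn once per ordered pair and clamped at
zero, so the jittered distance matrix is deliberately asymmetric.

### Two populations

The pacemaker→driven experiment connects two 225-neuron lattices strictly
feedforward: driven neuron i receives Σ_k W_ik s_k^(pac) in the same
synaptic form, with W_ik Gaussian, mean pinned exactly to the mean
intra-pacemaker kernel weight (the stated strong-driving condition) and
coefficient of variation 0.2 (unpublished; clipped at zero and rescaled so
the mean is exact for every seed). The driven population models a cortical
area: weak intra-coupling (¼ of the pacemaker's) and broader drive
dispersion (drive_sd = 0.1), so it synchronizes only *because of* coherent
pacemaker input — the mechanism by which stimulating one nucleus
desynchronizes a downstream area.

## Noise

Each neuron receives an independent Ornstein-Uhlenbeck current with
amplitude D_noise = 10⁻⁵ and correlation time τ_noise = 5 ms, generated by
the exact exponential update (stationary variance D·τ/2, autocorrelation
e^(−Δ/τ), step-size independent). Traces are pre-generated on a 1 ms grid
and held constant between grid points — τ_noise = 5 ms makes the hold
error negligible — which gives both backends one identical, separately
tested noise path.

## Stimulation

The DBS waveform is a 130 Hz train of biphasic pulses: +amp_pos for
0.2 ms, then the negative phase for 3.0 ms with amplitude derived from
exact charge balance (amp_neg = −amp_pos/15). Delivery is through one
central electrode or four quadrant-centroid electrodes; the per-neuron
current decays as exp(−d/decay_len) from each electrode, and the layout
normalization c_n_stim rescales the four-electrode layout so that the
summed delivered stimulation over the lattice equals the one-electrode
protocol exactly.

Three stimulation constants are unpublished and set by calibration against
the study's reported synchronization levels (once, before freezing the
packaged scenarios):

- **Pulse amplitude** amp_pos: 9 (ML; pulse peak ≈ 0.9 at the electrode,
  the scale at which single pulses trigger spikes) and 256 (Izhikevich,
  together with the published somatic weight s = 50).
- **Spatial decay** decay_len: 0.35 (ML) and 0.15 (Izhikevich) lattice
  units. The decay length controls the *contrast* between the layouts:
  with a long reach both layouts drive the lattice almost uniformly and
  four electrodes lose their advantage; with a short reach the central
  electrode overdrives its neighborhood and leaves the periphery
  untouched, while four distributed electrodes cover the sheet — which is
  what makes four electrodes desynchronize more than one, as reported.
- **Afferent-inhibition weight** s₂ = 0.008 (ML only). DBS acts both by
  somatic excitation and by activating inhibitory afferents; the package
  models the latter by feeding |I_stim| into the slow-current equation
  (third equation above, switched by the same window X₁). For the ML
  lattice this pathway is what produces deep desynchronization: it slows
  and, near electrodes, suppresses bursting with a spatial gradient, so
  burst rates disperse across the lattice. Somatic excitation alone
  saturates near mean R ≈ 0.65 and inverts the electrode-count ordering.
  The pathway is off (`slow_weight = 0`) unless a scenario enables it.

## Synchronization measure

Burst onsets anchor the phases. For Morris-Lecar, onsets are upward
crossings of v = −0.05 preceded by ≥ 100 ms below threshold (the coupled
lattice's burst tails stutter with pauses up to ~80 ms, which a tighter
gap would misread as new bursts); spike counting within bursts uses a
40 ms gap (noise can shorten genuine inter-burst pauses of the isolated
neuron to ~60 ms). For Izhikevich, onsets come from the exactly logged
spike times grouped with a 30 ms gap. A standalone detector with the
automatic gap rule (3× the median inter-crossing interval) is available
for generic traces.

The phase grows linearly by 2π between consecutive onsets; the population
order parameter is R e^{iΘ} = ⟨e^{iφ_j}⟩. Engine-level analysis
*extrapolates* each neuron's phase beyond its covered onset interval at
the nearest observed inter-onset rate. This choice matters under strong
stimulation: neurons whose bursting is suppressed would otherwise leave
the statistic entirely (leaving R undefined, or biased toward the
still-synchronized survivors); extrapolation keeps them in R, advancing at
their last (stimulation-graded) rate, so suppression reads as
desynchronization. The strict-exclusion variant remains the default of
the low-level API. R(t) is evaluated on the 1 ms record grid.

A subtlety verified by the synthetic-fixture tests: for Gaussian onset
jitter of sd σ_t at rate f, R equals the characteristic function
exp(−(2πfσ_t)²/2) exactly when sampled at the nominal grid instants;
time-averaged R is slightly higher because linear interpolation between
independently jittered onsets smooths the jitter by ((1−f)²+f²).

## LFP and spectra

The simulated local field potential is the point-source sum
LFP(t) = R_e Σ_j I_j(t)/r_j at the lattice centroid, R_e = 1, with r_j
floored at dl/2 and I_j the total non-stimulation current (for ML, the
full membrane equation right-hand side times C minus the stimulation term;
for Izhikevich, which has no explicit ionic currents, the summed synaptic,
noise and tonic input — a documented extension). Spectrograms use a 1 s
Hann window with 75% overlap (mean removed), resolving the 5–20 Hz band
where the synchronized network concentrates its power; `band_power_ratio`
reduces the stimulated-vs-unstimulated comparison to a scalar fraction.

## Synthetic fixtures

`dbsnet.synthetic` generates burst populations with controlled Gaussian
onset jitter (analytic expected R as above) and voltage traces with a
stereotyped clipped-sinusoid burst template injected at known onsets, so
the detection/phase/order-parameter stack is tested without the simulator.
The fixtures emulate onset statistics only — no subthreshold dynamics, no
spike-shape realism — so passing metrics tests demonstrates correctness of
the measurement pipeline, not biological fidelity of the traces.

## Problem sizes and reproducibility

The packaged scenarios are the study conditions: 100 Morris-Lecar neurons
(10×10, 9 s, stimulation window 4.5–9 s) and 225 Izhikevich neurons
(15×15, jittered, 6.5 s, window 3–6.5 s); statistical claims average five
independent seeds. One master seed expands deterministically into the
four component seeds (lattice jitter, noise, initial conditions,
inter-population weights); identical configuration and seeds reproduce
traces bit-for-bit. Halving either integrator step changes mean R by less
than 0.05.

## Known limitations

- The lattice abstractions (all-to-all Gaussian kernel, open boundaries,
  point electrodes with exponential reach) are caricatures; none of the
  spatial constants is anatomically derived.
- The excitatory driving force (v − v_rev) grows with depolarization, so
  sufficiently strong somatic stimulation can push the ML lattice into
  runaway excitation; the engine aborts with a diagnostic rather than
  integrating through it. The packaged amplitudes sit well below this
  regime.
- Burst-phase R depends on detector conventions under strong stimulation;
  the conventions above are fixed and documented, and the qualitative
  conclusions (desynchronization under stimulation, more electrodes →
  stronger effect, transfer to a driven population) are robust to them.
- The Izhikevich LFP uses input currents as a proxy for transmembrane
  ionic currents; its absolute scale is not comparable across backends.
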