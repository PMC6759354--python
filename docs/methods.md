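# Methods

## Model

The package simulates spiking networks derived from a single
normative principle: a population of N leaky integrate-and-fire
neurons should represent an M-dimensional stimulus φ(t) through a
fixed linear decoder φ̂ = Wᵀr while greedily minimizing

    E(t) = ‖φ(t) − φ̂(t)‖² + μ Σᵢ fᵢ(t)²,

where rᵢ filters the spike train at the decoder/membrane time
constant τ and fᵢ (the firing history) filters it at the slower
adaptation time constant τₐ.  Both filters are unit-height decaying
exponentials.  The squared-history cost charges *sustained* firing of
individual neurons, so the optimal population response redistributes
spiking from fatigued neurons to fresh ones; because the decoder is
fixed, the redistribution must happen along the iso-coding manifold
{r : Wᵀr = φ}, and the derived recurrent weights Ω = WWᵀ + μI
implement exactly that coordination.  All derived quantities (gains
gᵢ = 1/(‖wᵢ‖² + μ), adaptation coefficients κᵢ = μgᵢ(1 − τ/τₐ),
normalized thresholds 1/2 + ηgᵢ, reset −1/2) are computed in
`ebnet.core` from (W, μ, τ, τₐ, η) alone.

Assumptions worth keeping in mind: delta synapses (recurrent effects
are instantaneous), no conduction delays, no intrinsic noise anywhere,
a decoder that never adapts, and a single quadratic cost.  Scalar
stimuli are the M = 1 special case of the same code path.

## Spike generation: two voltages, one rule

The greedy condition "spike iff E decreases" reduces algebraically to
Vᵢ > 1/2 with Vᵢ = gᵢ(wᵢ·(φ − φ̂) − μfᵢ).  The simulator evaluates
this *closed form* from the filtered state at every step, so the
greedy-descent property (ΔE < 0 at every emitted spike) holds exactly
and is asserted by the test suite along entire trajectories.

Alongside it, the simulator integrates the equivalent membrane ODE

    τ V̇ᵢ = −Vᵢ + gᵢ wᵢ·(τφ̇ + φ) − κᵢfᵢ − [jumps −gᵢΩᵢⱼ per spike in j]

by forward Euler.  The two agree up to integration error: the test
suite verifies first-order convergence (the max deviation halves when
dt is halved).  We deliberately do *not* gate spikes on the
Euler-integrated voltage: with dt = 0.1 ms and the drive scales of the
bundled experiments, Euler overshoot (~(dt/2τ)·drive) is comparable
to typical threshold margins, and a large fraction of voltage-gated
spikes would violate the greedy condition they are meant to realize.
The integrated voltage exists for inspection, for the convergence
check, and as the *only* meaningful gate for control variants whose
recurrence has been modified (`spike_rule="voltage"`), e.g. the
recurrence-removed network of the manifold experiment, where no
closed-form voltage exists.

Spike resolution: at most one spike per time step across the
population; among neurons above threshold, the largest margin
Vᵢ − thresholdᵢ wins, ties to the lowest index.  Sequential
resolution preserves the one-spike-at-a-time greedy derivation and
avoids double-counting the instantaneous recurrent effects.  We
verified that relaxing this (all-above-threshold spiking on the
integrated voltage) is numerically unstable for the ring networks at
η = 0 — runaway volleys sustained by the mutual excitation of
oppositely tuned neurons — which is also the reason the threshold
offset η exists in the orientation networks.  dt must be small enough
that the estimate error, not the step, limits firing; the default
dt = 0.1 ms warns above τ/10.

Other numerical choices: exponential decay factors for r and f are
applied exactly (exp(−dt/τ)); the stimulus derivative is the backward
finite difference, which for piecewise-constant stimuli concentrates
the onset kick g wᵢΔφ at step edges (the trace is treated as zero
before t = 0, so a stimulus that starts high kicks at the first
step); the reset is implemented through the self term of the
recurrent update, which equals −1 in normalized units exactly;
initial conditions are V = r = f = 0; spiking uses strict inequality;
non-finite states abort with a diagnostic.

## Parameters

| parameter | meaning | unit | typical values |
|---|---|---|---|
| W (N×M) | decoding weights; ‖wᵢ‖ sets precision vs cost | stimulus units/spike | 1–10 (scalar nets), γ∈{3,9} (rings) |
| μ | cost weight | — | 0.02–0.2 |
| τ | decoder = membrane time constant | ms | 5–25 |
| τₐ | adaptation (history) time constant | ms | 1000–2000 |
| η | gain-proportional threshold offset | — | 0–10 |
| dt | integration step | ms | 0.1 |

η deserves a note: it raises thresholds by ηgᵢ, i.e. much more for
high-gain neurons.  In the orientation rings it prevents neurons from
being driven by the recurrent excitation of oppositely tuned neurons
and enables the high→low-gain handoff during adaptation (with η = 0
and the greedy gate, low-gain neurons are recruited only once the
residual error exceeds ~threshold/(gᵢ‖wᵢ‖), which strong high-gain
activity keeps small).  It defaults to 0 everywhere except the ring
builders, whose defaults follow the tuning-curve protocols (η = 10
for the dual ring, η = 1 for the random-gain ring).

## Synthetic stimuli

All inputs are generated in-package (`ebnet.stimuli`): seven-segment
digit patterns (standard A–G table, segment order top bar, upper
right, lower right, bottom, lower left, upper left, middle) presented
200 ms each with 100 ms gaps between consecutive digits; random
constant 7-dimensional training patterns uniform on [0, 4] (100
examples × 300 ms); constant scalar pulses; and oriented drives
φ = C·[cos 2θ, sin 2θ].  The doubled angle maps the orientation
half-circle (−π/2, π/2] bijectively onto the full circle, making
‖φ‖ = C, giving the ring weights γᵢ[cos 2Θᵢ, sin 2Θᵢ] their stated
meaning ("opposing preferences excite", since orientations 90° apart
are antipodal in weight space), and making the decoder
θ̂ = ½·atan2(φ̂₂, φ̂₁) the exact inverse of the stimulus map.  The
test-digit amplitude is not dictated by anything in the model; the
default 2 is the midpoint of the training range and is exposed as a
parameter.

These generators emulate idealized laboratory protocols: noiseless,
piecewise-constant, perfectly timed.  They contain no stimulus noise,
no naturalistic statistics, no contrast dynamics; passing tests
therefore demonstrate properties of the model under clean drive, not
robustness of any conclusion to realistic sensory input.

## Decoders

Derived networks are decoded by their own weights (D = Wᵀ), which
reproduces the estimate used internally, exactly.  The generic
baseline network gets a least-squares decoder trained on its
responses to the random constant patterns: all time samples are
stacked after discarding the first 50 ms of each trace (so the
decoder reflects steady responses; exposed as a parameter), and the
normal equations are solved with a small ridge term (1e-6 of the mean
Gram diagonal; 0 recovers the pure pseudoinverse).  Rank deficiency —
expected, since ~12% of baseline neurons never fire — is warned
about and handled by the ridge.  Angle statistics are computed on the
doubled angle and halved at the end.

## The generic baseline network

The digit experiment needs a conventional point of comparison: a
400-neuron LIF network with random feedforward weights (uniform on
[−1, 1]), random Gaussian recurrent weights (std 0.87) plus a
negative autapse −Σₘ F²ᵢₘ, threshold 1, and optionally a
spike-triggered adaptive threshold 1 + μfᵢ.  Several of its details
are modelling choices documented here: membrane time constant equal
to the decoder τ (5 ms); hard reset to 0 (which supersedes the
autapse for the spiking neuron); simultaneous spikes allowed; and a
postsynaptic amplitude of `psp_scale`·Rᵢⱼ per spike with
psp_scale = 0.02, i.e. the recurrent weights act as current
amplitudes delivered over one 0.1 ms step of the 5 ms membrane.  The
last choice is load-bearing: with unit-amplitude kicks (std 0.87
against threshold 1) the network falls into a chaotic multi-kilohertz
regime whose responses no linear decoder can reconstruct, which would
make it useless as the "accurate, history-independent" reference the
experiment requires.  At the default weak coupling the network is
stable, decodes digits accurately and position-independently
(MSE ≈ 0.01–0.05), and degrades exactly as intended when the
adaptive threshold is enabled (MSE ≈ 1–2, growing along the
sequence).  Conclusions drawn from this network are qualitative.

## Experiment protocols and problem sizes

* **Digits** — baseline (plain and adaptive-threshold) vs balanced
  network (400 neurons, random U[−1, 1] decoding weights, μ = 0.02,
  τ = 5 ms, τₐ = 2000 ms) on an 8-digit, 2300 ms sequence;
  reconstruction error is the per-presentation MSE over the
  on-window after a 20 ms onset allowance (parameterized).
* **Manifold** — two neurons (w = [1, 2], μ = 0.02, τ = 25 ms,
  τₐ = 1000 ms), 2 s constant drive φ = 10; deviation
  |w·r − φ|/‖w‖ for the intact and recurrence-removed variants.
* **Population traces** — w = 1..10, μ = 0.2, τ = 5 ms, τₐ = 1000 ms,
  2 s pulse φ = 10; recruitment order, objective decomposition,
  smoothed estimate (100 ms causal window, a display choice).
* **Tuning curves** — dual ring (μ = 0.1, τ = 5 ms, τₐ = 2000 ms,
  η = 10, C = 50): each test orientation 250 ms from a reinitialized
  state; adapted curves follow a 1.5 s adaptor immediately (no gap);
  the response statistic is the mean filtered rate over the test
  window.  With a fixed adaptor on an even ring, rows of the
  (neuron × test) response matrix indexed by preference-relative-to-
  adaptor sweep the full adaptation surface, so one adaptor position
  suffices.  Default grid: 24 orientations; the acceptance test uses
  12 to keep the run under a minute.
* **Tilt bias** — dual ring with η = 0, adaptor C = 25 for 2 s, test
  C = 5 for 250 ms, orientation decoded from the mean estimate over
  the test window; bias is signed positive for repulsion (estimate
  pushed away from the adaptor).  The bias curve sweeps the
  adaptor–test difference on a 5° grid and finds the sign change by
  linear interpolation between neighbouring grid points; with no
  sign change the crossover is reported as undefined.

All protocols are deterministic given their seeds; reruns are
bit-identical.  The problem sizes above were chosen so the complete
test suite and the acceptance script each run in minutes on one CPU.

## Known limitations

* The tilt-bias curve has the right structure — repulsion peaking
  near 20° at ~12° amplitude, weak attraction for oblique adaptors,
  repulsion much stronger than attraction — but the
  repulsion-to-attraction crossover lands near 60°, not at the ~45°
  characteristic of psychophysical tilt aftereffects.  Under the
  exact greedy rule with η = 0, adaptation at C = 25 engages only
  high-gain neurons within ±60° of the adaptor; near-orthogonal
  neurons (whose fatigue would generate the attraction lobe that
  pulls the crossover down) receive recurrent excitation but spiking
  them would not lower the objective, so they stay silent.  The
  result is robust to dt, to gating on the integrated voltage, and to
  exchanging which of adaptor/test is varied.
* The generic baseline network is qualitative by construction (see
  above); its absolute error levels should not be interpreted.
* The greedy rule is locally optimal one spike at a time; no claim of
  global optimality is made, and at μ = 0 it degenerates to strict
  winner-take-all (only the smallest-weight neuron ever fires).
* Decoder weights never adapt, by design; scenarios where the readout
  itself is plastic are out of scope, as are Dale's-law sign
  constraints, conductance synapses, delays, and stochastic spiking.
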