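"""Simulation of the balanced spiking network.

The network performs a greedy descent on the cost-accuracy objective

    E(t) = ||phi(t) - phi_hat(t)||^2 + mu * sum_i f_i(t)^2

where phi_hat = W^T r is the linearly decoded estimate, r_i the spike
train filtered at the decoder time constant tau, and f_i the firing
history filtered at the slower adaptation time constant tau_a.  A spike
in neuron i instantaneously adds w_i to phi_hat and 1 to f_i, and is
justified exactly when it lowers E; algebraically the condition
"E(spike in i) < E(no spike)" reduces to

    V_i = g_i (w_i . (phi - phi_hat) - mu f_i)  >  1/2

so the greedy rule is a leaky integrate-and-fire network with membrane
potential V_i, threshold 1/2 (+ eta g_i) and reset -1/2.

Two representations of the voltage coexist here and their agreement is
a consistency check of the simulator:

* the *closed form* above, computed each step from (phi, r, f) — this
  is what gates spikes, so every emitted spike provably decreases E;
* the *integrated* membrane ODE

    tau dV_i/dt = -V_i + g_i w_i.(tau dphi/dt + phi) - kappa_i f_i
                  - [instantaneous jumps -g_i Omega_ij per spike in j]

  advanced by forward Euler, which is the mechanistic account of the
  same dynamics (feedforward drive, adaptation current, recurrent
  delta-synapses whose self term implements the reset).

For control variants whose recurrence has been modified (e.g. the
off-diagonal of Omega zeroed), the closed form no longer describes the
network, so spiking is gated on the integrated voltage instead
(``spike_rule="voltage"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core import NetworkSpec
from .stimuli import StimulusTrace

__all__ = [
    "NetworkState",
    "SpikeRaster",
    "SimulationResult",
    "initial_state",
    "filter_spike_train",
    "voltage_direct",
    "objective_value",
    "spike_delta_objective",
    "step",
    "run_simulation",
    "instantaneous_rate",
]


@dataclass
class NetworkState:
    """Time-varying state: integrated voltages V, filtered rates r,
    firing histories f, and the index of the neuron that spiked on the
    current step (or None)."""

    t: float
    V: np.ndarray
    r: np.ndarray
    f: np.ndarray
    o_now: int | None = None

    def copy(self) -> "NetworkState":
        return NetworkState(self.t, self.V.copy(), self.r.copy(), self.f.copy(), self.o_now)


@dataclass
class SpikeRaster:
    """Ordered spike events (neuron index, time in ms)."""

    neurons: np.ndarray
    times: np.ndarray
    n_neurons: int

    def __post_init__(self):
        self.neurons = np.asarray(self.neurons, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.neurons.shape != self.times.shape:
            raise ValueError("neurons and times must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        if self.neurons.size and (self.neurons.min() < 0 or self.neurons.max() >= self.n_neurons):
            raise ValueError("neuron index out of range")

    @property
    def n_spikes(self) -> int:
        return self.neurons.size

    def for_neuron(self, i: int) -> np.ndarray:
        return self.times[self.neurons == i]


@dataclass
class SimulationResult:
    """Raster plus per-step trajectories and objective bookkeeping.

    ``estimate_trace`` is phi_hat(t) (M x T), ``error_trace`` the squared
    estimation error, ``cost_trace`` the metabolic term mu sum f^2; their
    sum is the objective E(t).  ``V_trace``/``r_trace``/``f_trace`` are
    stored when the run was made with ``record_state=True``.  The
    ``spike_*`` arrays capture, for each emitted spike, the pre-spike
    quantities needed to audit the greedy rule (stimulus, estimate,
    firing history of the spiker, and the objective change dE).
    """

    raster: SpikeRaster
    dt: float
    time: np.ndarray
    estimate_trace: np.ndarray
    error_trace: np.ndarray
    cost_trace: np.ndarray
    V_trace: np.ndarray | None = None
    r_trace: np.ndarray | None = None
    f_trace: np.ndarray | None = None
    spike_phi: np.ndarray | None = None
    spike_phihat: np.ndarray | None = None
    spike_f: np.ndarray | None = None
    spike_delta_E: np.ndarray | None = None

    @property
    def objective_trace(self) -> np.ndarray:
        return self.error_trace + self.cost_trace


def initial_state(spec: NetworkSpec) -> NetworkState:
    """Quiescent state: V = r = f = 0."""
    N = spec.N
    return NetworkState(t=0.0, V=np.zeros(N), r=np.zeros(N), f=np.zeros(N))


def filter_spike_train(raster: SpikeRaster, time_constant: float, n_samples: int, dt: float) -> np.ndarray:
    """Leaky integration of a spike raster on a uniform grid.

    Returns an (N, T) array: each spike contributes a unit-height
    decaying exponential exp(-u / time_constant); decay factors are
    applied exactly per step, so the result is linear in the spike
    train.
    """
    if time_constant <= 0:
        raise ValueError("time_constant must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    counts = np.zeros((raster.n_neurons, n_samples))
    if raster.n_spikes:
        idx = np.round(raster.times / dt).astype(int)
        if idx.max() >= n_samples:
            raise ValueError("raster extends past the grid")
        np.add.at(counts, (raster.neurons, idx), 1.0)
    a = np.exp(-dt / time_constant)
    return lfilter([1.0], [1.0, -a], counts, axis=1)


def voltage_direct(spec: NetworkSpec, phi, phihat, f) -> np.ndarray:
    """Closed-form membrane potential ``g_i (w_i.(phi - phihat) - mu f_i)``.

    The voltage is the projection of the coding error onto the neuron's
    decoding direction, penalized by its own firing history and scaled
    by the gain.  Serves as the oracle for the Euler-integrated ODE.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    phihat = np.atleast_1d(np.asarray(phihat, dtype=float))
    return spec.g * (spec.W @ (phi - phihat) - spec.mu * np.asarray(f))


def objective_value(spec: NetworkSpec, phi, phihat, f):
    """Objective E = ||phi - phihat||^2 + mu sum f^2 and its two terms.

    Returns ``(total, error_term, cost_term)``.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    phihat = np.atleast_1d(np.asarray(phihat, dtype=float))
    err = phi - phihat
    error_term = float(err @ err)
    f = np.asarray(f, dtype=float)
    cost_term = float(spec.mu * (f @ f))
    return error_term + cost_term, error_term, cost_term


def spike_delta_objective(spec: NetworkSpec, phi, phihat, f_i: float, i: int) -> float:
    """Objective change dE if neuron i spiked now.

    Computed from the definition: a spike adds w_i to the estimate and
    1 to f_i (unit kernel heights at the spike instant), so

        dE = ||phi - phihat - w_i||^2 - ||phi - phihat||^2
             + mu ((f_i + 1)^2 - f_i^2)

    which reduces to (||w_i||^2 + mu)(1 - 2 V_i); a spike lowers the
    objective exactly when V_i > 1/2.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    phihat = np.atleast_1d(np.asarray(phihat, dtype=float))
    err = phi - phihat
    w = spec.W[i]
    after = err - w
    return float(after @ after - err @ err + spec.mu * (2.0 * f_i + 1.0))


def step(
    spec: NetworkSpec,
    state: NetworkState,
    phi: np.ndarray,
    dphi: np.ndarray,
    dt: float,
    spike_rule: str = "objective",
) -> int | None:
    """Advance the network by one step of length dt (in place).

    Order of operations: forward-Euler update of the integrated voltage
    with the continuous currents; exact exponential decay of r and f;
    spike resolution.  At most one neuron spikes per step — among those
    above threshold the largest margin wins (ties to the lowest index)
    — and the spike applies its instantaneous effects to everything:
    recurrent/self jumps -g_i Omega_ij on V (the self term lands the
    spiker at reset), +1 on the spiker's r and f.

    ``spike_rule="objective"`` gates spikes on the closed-form voltage
    (exact greedy descent); ``"voltage"`` gates on the integrated V,
    which is the meaningful rule when Omega has been modified.

    Returns the index of the spiking neuron, or None.
    """
    g, W, kappa, mu = spec.g, spec.W, spec.kappa, spec.mu
    # continuous currents (spike jumps are applied separately below)
    drive = g * (W @ (spec.tau * dphi + phi))
    state.V += (dt / spec.tau) * (-state.V + drive - kappa * state.f)
    state.r *= np.exp(-dt / spec.tau)
    state.f *= np.exp(-dt / spec.tau_a)
    state.t += dt

    if spike_rule == "objective":
        phihat = W.T @ state.r
        V_gate = g * (W @ (phi - phihat) - mu * state.f)
    elif spike_rule == "voltage":
        V_gate = state.V
    else:
        raise ValueError(f"unknown spike_rule {spike_rule!r}")

    if not np.all(np.isfinite(state.V)):
        raise FloatingPointError(f"non-finite voltage at t={state.t:.3f} ms")

    margins = V_gate - spec.threshold
    j = int(np.argmax(margins))
    if margins[j] > 0:  # strict inequality: spiking must strictly lower E
        state.V -= g * spec.Omega[:, j]
        state.r[j] += 1.0
        state.f[j] += 1.0
        state.o_now = j
        return j
    state.o_now = None
    return None


def run_simulation(
    spec: NetworkSpec,
    stimulus: StimulusTrace,
    dt: float | None = None,
    state: NetworkState | None = None,
    record_state: bool = False,
    spike_rule: str = "objective",
    audit_spikes: bool = True,
) -> SimulationResult:
    """Simulate the network over a stimulus trace.

    Deterministic: identical spec, stimulus, dt and initial state give
    bit-identical results.  ``dt`` defaults to the stimulus sampling
    step; the stimulus must be sampled on the simulation grid.  The
    time derivative of the stimulus is taken as a backward finite
    difference, which concentrates onset/offset kicks at step edges.
    """
    if dt is None:
        dt = stimulus.dt
    if abs(dt - stimulus.dt) > 1e-12:
        raise ValueError("stimulus must be sampled at the simulation dt")
    if dt > spec.tau / 10 + 1e-12:
        warnings.warn(
            f"dt = {dt} ms is coarse relative to tau = {spec.tau} ms; "
            "use dt <= tau/10", stacklevel=2,
        )
    if state is None:
        state = initial_state(spec)
    else:
        state = state.copy()
    if spike_rule not in ("objective", "voltage"):
        raise ValueError(f"unknown spike_rule {spike_rule!r}")

    phis = stimulus.values  # (M, T)
    T = phis.shape[1]
    N, M = spec.N, spec.M
    W = spec.W
    WT = np.ascontiguousarray(W.T)
    g, kappa, mu = spec.g, spec.kappa, spec.mu
    G = g[:, None] * W  # rows g_i w_i
    g_Omega = g[:, None] * spec.Omega  # per-spike voltage jumps
    threshold = spec.threshold
    decay_r = np.exp(-dt / spec.tau)
    decay_f = np.exp(-dt / spec.tau_a)

    # feedforward drive for every step in one pass; the stimulus is
    # taken to be zero before t = 0, so a trace that starts nonzero
    # delivers its onset kick on the first step
    dphis = np.diff(phis, axis=1, prepend=np.zeros((M, 1))) / dt
    drive_all = G @ (spec.tau * dphis + phis)  # (N, T)

    est = np.empty((M, T))
    err_tr = np.empty(T)
    cost_tr = np.empty(T)
    if record_state:
        V_tr = np.empty((N, T))
        r_tr = np.empty((N, T))
        f_tr = np.empty((N, T))
    sp_n, sp_t = [], []
    a_phi, a_phihat, a_f, a_dE = [], [], [], []

    V, r, f = state.V, state.r, state.f
    gate_on_V = spike_rule == "voltage"
    check_every = max(1, int(round(1.0 / dt)))  # NaN guard ~once per ms
    for k in range(T):
        phi = phis[:, k]
        V += (dt / spec.tau) * (-V + drive_all[:, k] - kappa * f)
        r *= decay_r
        f *= decay_f
        phihat = WT @ r
        if gate_on_V:
            V_gate = V
        else:
            V_gate = G @ (phi - phihat) - mu * (g * f)
        j = int(np.argmax(V_gate - threshold))
        if V_gate[j] > threshold[j]:  # strict: the spike strictly lowers E
            if audit_spikes:
                a_phi.append(phi.copy())
                a_phihat.append(phihat.copy())
                a_f.append(f[j])
                a_dE.append(spike_delta_objective(spec, phi, phihat, f[j], j))
            V -= g_Omega[:, j]
            r[j] += 1.0
            f[j] += 1.0
            phihat = phihat + W[j]
            sp_n.append(j)
            sp_t.append((k + 1) * dt)
        est[:, k] = phihat
        d = phi - phihat
        err_tr[k] = d @ d
        cost_tr[k] = mu * (f @ f)
        if record_state:
            V_tr[:, k] = V
            r_tr[:, k] = r
            f_tr[:, k] = f
        if k % check_every == 0 and not np.isfinite(err_tr[k]):
            raise FloatingPointError(f"non-finite state at t={(k + 1) * dt:.3f} ms")
    state.t += T * dt

    raster = SpikeRaster(np.array(sp_n, dtype=int), np.array(sp_t), n_neurons=N)
    return SimulationResult(
        raster=raster,
        dt=dt,
        time=(np.arange(T) + 1) * dt,
        estimate_trace=est,
        error_trace=err_tr,
        cost_trace=cost_tr,
        V_trace=V_tr if record_state else None,
        r_trace=r_tr if record_state else None,
        f_trace=f_tr if record_state else None,
        spike_phi=np.array(a_phi) if audit_spikes else None,
        spike_phihat=np.array(a_phihat) if audit_spikes else None,
        spike_f=np.array(a_f) if audit_spikes else None,
        spike_delta_E=np.array(a_dE) if audit_spikes else None,
    )


def instantaneous_rate(raster: SpikeRaster, n_samples: int, dt: float, window_ms: float = 50.0) -> np.ndarray:
    """Display-oriented firing-rate trace (spikes/s).

    Exponential filtering of the spike train with a display time
    constant (default 50 ms), normalized to a rate.  A plotting
    utility, not a model quantity.
    """
    tr = filter_spike_train(raster, window_ms, n_samples, dt)
    return tr / (window_ms / 1000.0)
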