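"""Concrete network builders.

Three networks are used by the experiments:

* a generic random recurrent LIF population (the *baseline*) for the
  digit-encoding comparison — random feedforward and recurrent weights,
  decoded by a trained least-squares readout;
* the *dual ring*: an orientation-coding population in which every
  preferred orientation is represented by one high-gain (small decoding
  weight, gamma = 3) and one low-gain (gamma = 9) neuron, preferences
  evenly spaced on the half-circle;
* the *random-gain ring*: same layout, but each neuron's decoding
  magnitude gamma is drawn uniformly from [3, 9].

Naming note: a *small* decoding-weight magnitude means a *high* gain
(g = 1/(gamma^2 + mu)), i.e. an excitable, precise, costly neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NetworkSpec, build_network
from .dynamics import SpikeRaster, filter_spike_train
from .stimuli import StimulusTrace

__all__ = [
    "BaselineNetwork",
    "BaselineResult",
    "RingSpec",
    "build_random_baseline",
    "simulate_baseline",
    "build_dual_ring",
    "build_random_gain_ring",
]


@dataclass
class BaselineNetwork:
    """Generic random recurrent LIF network.

    ``F`` is the (N, M) feedforward weight matrix (entries uniform on
    [-1, 1]); ``R`` the (N, N) recurrent matrix with i.i.d. Gaussian
    off-diagonal entries and an autapse R_ii = -sum_m F_im^2.  The
    spiking threshold is 1 (optionally raised by adaptation to
    1 + mu f_i), the reset is 0, and the membrane time constant equals
    the decoder time constant tau.

    ``psp_scale`` sets the postsynaptic potential caused by one
    presynaptic spike: psp_scale * R_ij.  The default (0.02)
    corresponds to reading R as current amplitudes delivered over one
    0.1 ms integration step of a 5 ms membrane.  Near unit scale the
    recurrent kicks rival the threshold and the network falls into a
    chaotic multi-kHz regime whose responses no linear decoder can
    reconstruct; at the default weak coupling the network is stable
    and linearly decodable, which is the regime the digit experiment
    requires of its non-adapting reference.
    """

    F: np.ndarray
    R: np.ndarray
    tau: float
    threshold: float
    seed: int
    psp_scale: float = 0.02

    @property
    def N(self) -> int:
        return self.F.shape[0]

    @property
    def M(self) -> int:
        return self.F.shape[1]


@dataclass
class BaselineResult:
    """Raster and decoder-filtered rates from a baseline simulation."""

    raster: SpikeRaster
    dt: float
    r_trace: np.ndarray  # (N, T), spikes filtered at tau
    f_trace: np.ndarray | None = None


def build_random_baseline(
    N: int = 400,
    M: int = 7,
    recurrent_std: float = 0.87,
    tau: float = 5.0,
    seed: int = 0,
    psp_scale: float = 0.02,
) -> BaselineNetwork:
    """Draw a random baseline network (reproducible from the seed)."""
    rng = np.random.default_rng(seed)
    F = rng.uniform(-1.0, 1.0, size=(N, M))
    R = rng.normal(0.0, recurrent_std, size=(N, N))
    R[np.diag_indices(N)] = -np.einsum("ij,ij->i", F, F)
    return BaselineNetwork(F=F, R=R, tau=tau, threshold=1.0, seed=seed,
                           psp_scale=psp_scale)


def simulate_baseline(
    net: BaselineNetwork,
    stimulus: StimulusTrace,
    adaptive: bool = False,
    mu: float = 0.02,
    tau_a: float = 2000.0,
    dt: float | None = None,
) -> BaselineResult:
    """Simulate the baseline LIF network over a stimulus.

    Dynamics: tau dV/dt = -V + F phi, with each presynaptic spike in j
    kicking the voltages by psp_scale * R[:, j] and a hard reset to 0
    for the spiker (which supersedes its autapse).  With
    ``adaptive=True`` the threshold is dynamically raised to
    1 + mu f_i(t), where f_i filters the neuron's own spikes at tau_a
    — spike-triggered threshold fatigue.  Unlike the derived balanced
    networks, any number of neurons may spike in the same step.
    """
    if dt is None:
        dt = stimulus.dt
    if abs(dt - stimulus.dt) > 1e-12:
        raise ValueError("stimulus must be sampled at the simulation dt")
    if stimulus.M != net.M:
        raise ValueError(f"network expects M={net.M}, stimulus has M={stimulus.M}")
    N = net.N
    T = stimulus.n_samples
    phis = stimulus.values
    V = np.zeros(N)
    f = np.zeros(N)
    r = np.zeros(N)
    decay_r = np.exp(-dt / net.tau)
    decay_f = np.exp(-dt / tau_a)
    r_trace = np.empty((N, T))
    f_trace = np.empty((N, T)) if adaptive else None
    sp_n, sp_t = [], []
    for k in range(T):
        V += (dt / net.tau) * (-V + net.F @ phis[:, k])
        r *= decay_r
        f *= decay_f
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(f"non-finite voltage at step {k}")
        thr = net.threshold + mu * f if adaptive else net.threshold
        spikers = np.flatnonzero(V > thr)
        if spikers.size:
            V += net.psp_scale * net.R[:, spikers].sum(axis=1)
            V[spikers] = 0.0  # hard reset supersedes the autapse for the spiker
            r[spikers] += 1.0
            f[spikers] += 1.0
            t_now = (k + 1) * dt
            sp_n.extend(spikers.tolist())
            sp_t.extend([t_now] * spikers.size)
        r_trace[:, k] = r
        if adaptive:
            f_trace[:, k] = f
    raster = SpikeRaster(np.array(sp_n, dtype=int), np.array(sp_t), n_neurons=N)
    return BaselineResult(raster=raster, dt=dt, r_trace=r_trace, f_trace=f_trace)


@dataclass
class RingSpec:
    """Orientation ring: preferred orientations, decoding magnitudes,
    and the derived :class:`~ebnet.core.NetworkSpec`.

    Decoding weights follow the doubled-angle convention:
    w_i = gamma_i [cos(2 Theta_i), sin(2 Theta_i)], Theta_i in
    (-pi/2, pi/2], so ||w_i|| = gamma_i.
    """

    theta: np.ndarray  # (N,) preferred orientations, radians
    gamma: np.ndarray  # (N,) decoding magnitudes
    spec: NetworkSpec
    high_gain: np.ndarray  # (N,) bool mask; True = small gamma


def _ring_orientations(n_orient: int) -> np.ndarray:
    """``n_orient`` evenly spaced orientations spanning (-pi/2, pi/2]."""
    return -np.pi / 2 + np.pi * (np.arange(1, n_orient + 1)) / n_orient


def _ring_weights(theta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    return np.column_stack([gamma * np.cos(2 * theta), gamma * np.sin(2 * theta)])


def build_dual_ring(
    N: int = 200,
    gamma_high: float = 3.0,
    gamma_low: float = 9.0,
    mu: float = 0.1,
    tau: float = 5.0,
    tau_a: float = 2000.0,
    eta: float = 10.0,
) -> RingSpec:
    """Dual-ring orientation network.

    N/2 preferred orientations evenly span the half-circle; each is
    carried by a pair of neurons, one high gain (gamma_high, small
    weight) and one low gain (gamma_low).  The recurrence maximally
    inhibits same-preference neighbours and excites orthogonal
    preferences.
    """
    if N % 2:
        raise ValueError("dual ring needs an even number of neurons")
    n_or = N // 2
    base = _ring_orientations(n_or)
    theta = np.concatenate([base, base])
    gamma = np.concatenate([np.full(n_or, gamma_high), np.full(n_or, gamma_low)])
    spec = build_network(_ring_weights(theta, gamma), mu, tau, tau_a, eta)
    high = np.concatenate([np.ones(n_or, bool), np.zeros(n_or, bool)])
    return RingSpec(theta=theta, gamma=gamma, spec=spec, high_gain=high)


def build_random_gain_ring(
    N: int = 200,
    gamma_low: float = 3.0,
    gamma_high: float = 9.0,
    seed: int = 0,
    mu: float = 0.2,
    tau: float = 5.0,
    tau_a: float = 1000.0,
    eta: float = 1.0,
) -> RingSpec:
    """Ring with evenly spaced preferences but random decoding
    magnitudes gamma_i ~ U[gamma_low, gamma_high]."""
    rng = np.random.default_rng(seed)
    theta = _ring_orientations(N)
    gamma = rng.uniform(gamma_low, gamma_high, size=N)
    spec = build_network(_ring_weights(theta, gamma), mu, tau, tau_a, eta)
    high = gamma < 0.5 * (gamma_low + gamma_high)
    return RingSpec(theta=theta, gamma=gamma, spec=spec, high_gain=high)
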