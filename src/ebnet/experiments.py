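"""Scripted experiment protocols.

Each protocol builds its networks and stimuli, runs the simulator, and
reduces the result to the quantities of interest:

* ``digit_experiment`` — digit-sequence encoding compared across a
  random LIF baseline, the same baseline with an adaptive threshold,
  and the derived balanced network with adaptation;
* ``manifold_deviation`` — two-neuron network: distance of the
  population rate vector from the iso-coding line, with and without
  recurrent connections;
* ``population_trace_experiment`` — ten-neuron population adaptation:
  recruitment order, error/cost accumulation, estimate stability;
* ``tuning_curve_protocol`` — orientation tuning curves before and
  after adaptation on a ring network;
* ``tilt_bias_protocol`` / ``bias_curve`` — tilt-aftereffect bias of
  the decoded orientation as a function of adaptor-test angle.

All protocols are deterministic given their seeds.  Angles are radians
internally; user-facing tables use degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import readout, stimuli
from .core import NetworkSpec, build_network, without_recurrence
from .dynamics import SimulationResult, run_simulation
from .networks import (
    BaselineNetwork,
    RingSpec,
    build_random_baseline,
    simulate_baseline,
)

__all__ = [
    "DigitExperimentResult",
    "ManifoldResult",
    "PopulationTraceResult",
    "TuningCurveSet",
    "BiasCurve",
    "digit_experiment",
    "manifold_deviation",
    "population_trace_experiment",
    "tuning_curve_protocol",
    "tilt_bias_protocol",
    "bias_curve",
    "wrap_orientation",
]


def wrap_orientation(angle):
    """Wrap an angular difference to the orientation half-period
    [-pi/2, pi/2)."""
    return (np.asarray(angle) + np.pi / 2) % np.pi - np.pi / 2


# ---------------------------------------------------------------------------
# digit encoding (three-condition comparison)
# ---------------------------------------------------------------------------


@dataclass
class DigitExperimentResult:
    """Per-presentation reconstruction errors for the three conditions.

    ``table`` has columns position, digit, condition, mse.
    ``late_error_ratio`` compares mean late-sequence (last 3 digits)
    MSE of the adaptive-threshold baseline against the balanced
    network with adaptation.
    """

    table: pd.DataFrame
    decoder: np.ndarray
    late_error_ratio: float
    params: dict = field(default_factory=dict)

    def condition_mse(self, condition: str, positions=None) -> float:
        t = self.table[self.table.condition == condition]
        if positions is not None:
            t = t[t.position.isin(positions)]
        return float(t.mse.mean())


def _digit_mse(estimate, stim: stimuli.StimulusTrace, onset_allowance_ms: float):
    """Mean squared reconstruction error per labelled digit window."""
    rows = []
    skip = int(round(onset_allowance_ms / stim.dt))
    for pos, (start, end, digit) in enumerate(stim.labels):
        k0 = int(round(start / stim.dt)) + skip
        k1 = int(round(end / stim.dt))
        target = stim.values[:, k0:k1]
        err = estimate[:, k0:k1] - target
        rows.append((pos, digit, float(np.mean(err**2))))
    return rows


def digit_experiment(
    seed: int = 0,
    digits=(0, 1, 2, 3, 4, 5, 6, 7),
    amplitude: float = 2.0,
    dt: float = 0.1,
    N: int = 400,
    mu: float = 0.02,
    tau: float = 5.0,
    tau_a: float = 2000.0,
    n_train: int = 100,
    onset_allowance_ms: float = 20.0,
    baseline: BaselineNetwork | None = None,
) -> DigitExperimentResult:
    """Digit-sequence encoding under three conditions.

    A random recurrent LIF baseline is trained with an optimal linear
    decoder on random constant patterns, then presented with the digit
    sequence (i) as is and (ii) with a spike-triggered adaptive
    threshold 1 + mu f_i.  A balanced network with adaptation (random
    uniform decoding weights, same N) encodes the identical sequence
    and is decoded by its own weights.  Reconstruction error is the
    MSE between decoded trace and true pattern over each digit's
    on-window, after a short onset allowance.
    """
    if baseline is None:
        baseline = build_random_baseline(N=N, M=7, tau=tau, seed=seed)
    train = stimuli.random_pattern_stimuli(n=n_train, M=7, dt=dt, seed=seed + 1)
    responses = [simulate_baseline(baseline, s, adaptive=False, dt=dt).r_trace for s in train]
    decoder = readout.train_optimal_decoder(
        responses, [s.values for s in train], dt=dt
    )

    seq = stimuli.digit_sequence(digits, amplitude=amplitude, dt=dt)

    base = simulate_baseline(baseline, seq, adaptive=False, dt=dt)
    adapt = simulate_baseline(baseline, seq, adaptive=True, mu=mu, tau_a=tau_a, dt=dt)

    rng = np.random.default_rng(seed + 2)
    W = rng.uniform(-1.0, 1.0, size=(N, 7))
    balanced_spec = build_network(W, mu, tau, tau_a, eta=0.0)
    balanced = run_simulation(balanced_spec, seq, dt=dt, audit_spikes=False)

    rows = []
    for cond, est in (
        ("baseline", readout.linear_decode(base.r_trace, decoder)),
        ("baseline_adaptive", readout.linear_decode(adapt.r_trace, decoder)),
        ("balanced_adaptation", balanced.estimate_trace),
    ):
        for pos, digit, mse in _digit_mse(est, seq, onset_allowance_ms):
            rows.append({"position": pos, "digit": digit, "condition": cond, "mse": mse})
    table = pd.DataFrame(rows)

    late = range(len(list(digits)) - 3, len(list(digits)))
    result = DigitExperimentResult(
        table=table,
        decoder=decoder,
        late_error_ratio=float(
            table[(table.condition == "baseline_adaptive") & table.position.isin(late)].mse.mean()
            / table[(table.condition == "balanced_adaptation") & table.position.isin(late)].mse.mean()
        ),
        params=dict(seed=seed, digits=tuple(digits), amplitude=amplitude, dt=dt, N=N,
                    mu=mu, tau=tau, tau_a=tau_a, n_train=n_train,
                    onset_allowance_ms=onset_allowance_ms),
    )
    return result


# ---------------------------------------------------------------------------
# two-neuron iso-coding manifold
# ---------------------------------------------------------------------------


@dataclass
class ManifoldResult:
    """Distance from the iso-coding line for the intact and
    recurrence-free two-neuron networks, plus the (r1, r2) paths."""

    time: np.ndarray
    deviation_intact: np.ndarray
    deviation_no_recurrence: np.ndarray
    r_path_intact: np.ndarray  # (2, T)
    r_path_no_recurrence: np.ndarray
    params: dict = field(default_factory=dict)


def _line_deviation(r_trace: np.ndarray, w: np.ndarray, phi: float) -> np.ndarray:
    """Per-sample distance |w.r - phi| / ||w|| from the iso-coding line."""
    return np.abs(w @ r_trace - phi) / np.linalg.norm(w)


def manifold_deviation(
    w=(1.0, 2.0),
    mu: float = 0.02,
    tau: float = 25.0,
    tau_a: float = 1000.0,
    phi: float = 10.0,
    duration_ms: float = 2000.0,
    dt: float = 0.1,
) -> ManifoldResult:
    """Two-neuron network driven by a constant stimulus.

    The intact network keeps its rate vector on the iso-coding line
    w1 r1 + w2 r2 = phi; removing the cross-neuron recurrence (while
    keeping adaptation and the self-reset) lets the rates drift off
    the line, so the activity can no longer be linearly decoded.
    """
    w = np.asarray(w, dtype=float)
    spec = build_network(w, mu, tau, tau_a, eta=0.0)
    pulse = stimuli.constant_pulse(phi, duration_ms, dt=dt)
    intact = run_simulation(spec, pulse, record_state=True, audit_spikes=False)
    uncoupled = run_simulation(
        without_recurrence(spec), pulse, record_state=True,
        spike_rule="voltage", audit_spikes=False,
    )
    return ManifoldResult(
        time=intact.time,
        deviation_intact=_line_deviation(intact.r_trace, w, phi),
        deviation_no_recurrence=_line_deviation(uncoupled.r_trace, w, phi),
        r_path_intact=intact.r_trace,
        r_path_no_recurrence=uncoupled.r_trace,
        params=dict(w=tuple(w), mu=mu, tau=tau, tau_a=tau_a, phi=phi,
                    duration_ms=duration_ms, dt=dt),
    )


# ---------------------------------------------------------------------------
# ten-neuron population adaptation
# ---------------------------------------------------------------------------


@dataclass
class PopulationTraceResult:
    """Population adaptation to a pulse: full simulation, recruitment
    order (neuron indices sorted by first-spike time), and the
    smoothed estimate with running dispersion."""

    result: SimulationResult
    recruitment_order: np.ndarray
    first_spike_times: np.ndarray  # NaN for neurons that never fired
    estimate_mean: np.ndarray
    estimate_std: np.ndarray
    params: dict = field(default_factory=dict)


def population_trace_experiment(
    w=tuple(range(1, 11)),
    mu: float = 0.2,
    tau: float = 5.0,
    tau_a: float = 1000.0,
    phi: float = 10.0,
    duration_ms: float = 2000.0,
    dt: float = 0.1,
    smooth_window_ms: float = 100.0,
) -> PopulationTraceResult:
    """Heterogeneous population (w = 1..10) driven by a constant pulse.

    Strongly excitable neurons (small w) respond first and adapt;
    weaker ones are disinhibited and recruited in order of decreasing
    excitability, while the decoded estimate keeps tracking the
    stimulus with slowly growing bias and dispersion.
    """
    spec = build_network(np.asarray(w, dtype=float), mu, tau, tau_a, eta=0.0)
    pulse = stimuli.constant_pulse(phi, duration_ms, dt=dt)
    res = run_simulation(spec, pulse, record_state=True)
    first = np.full(spec.N, np.nan)
    for i in range(spec.N):
        t_i = res.raster.for_neuron(i)
        if t_i.size:
            first[i] = t_i[0]
    fired = np.flatnonzero(~np.isnan(first))
    order = fired[np.argsort(first[fired])]
    mean, std = readout.smooth_estimate(res.estimate_trace[0], smooth_window_ms, dt)
    return PopulationTraceResult(
        result=res,
        recruitment_order=order,
        first_spike_times=first,
        estimate_mean=mean,
        estimate_std=std,
        params=dict(w=tuple(w), mu=mu, tau=tau, tau_a=tau_a, phi=phi,
                    duration_ms=duration_ms, dt=dt,
                    smooth_window_ms=smooth_window_ms),
    )


# ---------------------------------------------------------------------------
# orientation tuning curves
# ---------------------------------------------------------------------------


@dataclass
class TuningCurveSet:
    """Mean responses on an orientation grid, before and after
    adaptation to a fixed adaptor orientation.

    ``pre`` and ``post`` are (N, K): mean decoder-filtered rate of each
    neuron over the test window for each of the K test orientations.
    With a fixed adaptor, a neuron's row is its tuning curve given an
    adaptor sitting at ``adapt_orient - theta_i`` relative to its own
    preference, so rows indexed by relative preference sweep out the
    full two-argument adaptation surface of a symmetric ring.
    """

    test_orients: np.ndarray  # (K,) radians
    pre: np.ndarray
    post: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray
    high_gain: np.ndarray
    adapt_orient: float
    params: dict = field(default_factory=dict)

    def neurons_near(self, orientation: float, tol_deg: float, high_gain: bool | None = None):
        """Indices of neurons whose preference is within tol of an
        orientation, optionally restricted to one gain class."""
        d = np.abs(np.degrees(wrap_orientation(self.theta - orientation)))
        mask = d <= tol_deg
        if high_gain is not None:
            mask &= self.high_gain == high_gain
        return np.flatnonzero(mask)

    def centered_average(self, adapted: bool = False, high_gain: bool = True):
        """Subpopulation tuning curve centered on preferred orientation.

        Each selected neuron's curve is shifted so its preference maps
        to relative angle 0 (periodic linear interpolation), then the
        curves are averaged; returns (relative grid, mean, std across
        neurons).  For ``adapted=True`` remember the adaptor is fixed
        in absolute orientation, so neurons at different relative
        positions to the adaptor are being mixed.
        """
        resp = self.post if adapted else self.pre
        sel = np.flatnonzero(self.high_gain == high_gain)
        grid = np.sort(wrap_orientation(self.test_orients))
        shifted = np.empty((sel.size, grid.size))
        for row, i in enumerate(sel):
            rel = wrap_orientation(self.test_orients - self.theta[i])
            order = np.argsort(rel)
            x, y = rel[order], resp[i, order]
            xp = np.concatenate([x - np.pi, x, x + np.pi])
            yp = np.tile(y, 3)
            shifted[row] = np.interp(grid, xp, yp)
        return grid, shifted.mean(axis=0), shifted.std(axis=0)


def _mean_test_response(spec: NetworkSpec, trace, n_test: int) -> np.ndarray:
    res = run_simulation(spec, trace, record_state=True, audit_spikes=False)
    return res.r_trace[:, -n_test:].mean(axis=1)


def tuning_curve_protocol(
    ring: RingSpec,
    test_orients=None,
    test_ms: float = 250.0,
    adapt_orient: float = 0.0,
    adapt_ms: float = 1500.0,
    C_test: float = 50.0,
    C_adapt: float = 50.0,
    dt: float = 0.1,
) -> TuningCurveSet:
    """Tuning curves before and after adaptation.

    Pre-adaptation: each test orientation is presented for ``test_ms``
    to a reinitialized network.  Post-adaptation: the adaptor is
    presented for ``adapt_ms`` and immediately followed by the test.
    The response statistic is the mean decoder-filtered rate over the
    test window.
    """
    if test_orients is None:
        test_orients = np.linspace(-np.pi / 2, np.pi / 2, 25)[1:]  # (-90, 90] open at -90
    test_orients = np.asarray(test_orients, dtype=float)
    n_test = int(round(test_ms / dt))
    pre = np.empty((ring.spec.N, test_orients.size))
    post = np.empty_like(pre)
    adaptor = stimuli.orientation_stimulus(adapt_orient, C_adapt, adapt_ms, dt)
    for k, th in enumerate(test_orients):
        test = stimuli.orientation_stimulus(th, C_test, test_ms, dt)
        pre[:, k] = _mean_test_response(ring.spec, test, n_test)
        post[:, k] = _mean_test_response(ring.spec, stimuli.concatenate([adaptor, test]), n_test)
    return TuningCurveSet(
        test_orients=test_orients, pre=pre, post=post,
        theta=ring.theta, gamma=ring.gamma, high_gain=ring.high_gain,
        adapt_orient=float(adapt_orient),
        params=dict(test_ms=test_ms, adapt_orient=adapt_orient, adapt_ms=adapt_ms,
                    C_test=C_test, C_adapt=C_adapt, dt=dt),
    )


# ---------------------------------------------------------------------------
# tilt illusion
# ---------------------------------------------------------------------------


def tilt_bias_protocol(
    ring: RingSpec,
    adaptor: float,
    test: float,
    adapt_ms: float = 2000.0,
    test_ms: float = 250.0,
    C_adapt: float = 25.0,
    C_test: float = 5.0,
    dt: float = 0.1,
) -> float:
    """Signed decoded bias (degrees) of a test orientation after an
    adaptor.

    The adaptor is presented for ``adapt_ms`` immediately followed by
    the test for ``test_ms``; the perceived angle is decoded from the
    mean network estimate over the test window.  Sign convention:
    positive = repulsion (estimate pushed away from the adaptor),
    negative = attraction.  With a zero-contrast adaptor the bias is
    the raw decoding error.
    """
    seq = stimuli.concatenate([
        stimuli.orientation_stimulus(adaptor, C_adapt, adapt_ms, dt),
        stimuli.orientation_stimulus(test, C_test, test_ms, dt),
    ])
    res = run_simulation(ring.spec, seq, audit_spikes=False)
    n_test = int(round(test_ms / dt))
    mean_est = res.estimate_trace[:, -n_test:].mean(axis=1)
    if np.allclose(mean_est, 0.0):
        raise ValueError("zero mean estimate over the test window: orientation undefined")
    theta_hat = readout.decode_orientation(mean_est)
    raw = wrap_orientation(theta_hat - test)
    d = wrap_orientation(test - adaptor)
    sign = np.sign(d) if d != 0 else 1.0
    return float(np.degrees(sign * raw))


@dataclass
class BiasCurve:
    """Tilt bias vs adaptor-test angular difference.

    ``bias_deg`` is signed, positive = repulsion.  ``crossover_deg``
    is the first repulsion-to-attraction zero crossing (linear
    interpolation between grid points; None if the sign never
    changes).
    """

    delta_deg: np.ndarray
    bias_deg: np.ndarray
    crossover_deg: float | None
    max_repulsion: float
    max_attraction: float
    params: dict = field(default_factory=dict)


def bias_curve(
    ring: RingSpec,
    delta_deg=None,
    adaptor: float = 0.0,
    adapt_ms: float = 2000.0,
    test_ms: float = 250.0,
    C_adapt: float = 25.0,
    C_test: float = 5.0,
    dt: float = 0.1,
) -> BiasCurve:
    """Sweep the adaptor-test difference and locate the bias crossover.

    For each difference on the grid (default 5..85 degrees in 5-degree
    steps) the tilt protocol is run with the test rotated by that
    amount from the adaptor.  Small differences give repulsion,
    oblique ones attraction; the crossover angle is found by the sign
    change of the bias between neighbouring grid points.
    """
    if delta_deg is None:
        delta_deg = np.arange(5.0, 90.0, 5.0)
    delta_deg = np.asarray(delta_deg, dtype=float)
    bias = np.array([
        tilt_bias_protocol(
            ring, adaptor, wrap_orientation(adaptor + np.radians(d)),
            adapt_ms=adapt_ms, test_ms=test_ms,
            C_adapt=C_adapt, C_test=C_test, dt=dt,
        )
        for d in delta_deg
    ])
    crossover = None
    for i in range(len(bias) - 1):
        if bias[i] > 0 >= bias[i + 1]:
            x0, x1, b0, b1 = delta_deg[i], delta_deg[i + 1], bias[i], bias[i + 1]
            crossover = float(x0 + b0 * (x1 - x0) / (b0 - b1))
            break
    return BiasCurve(
        delta_deg=delta_deg,
        bias_deg=bias,
        crossover_deg=crossover,
        max_repulsion=float(bias.max(initial=0.0)),
        max_attraction=float(-bias.min(initial=0.0)),
        params=dict(adaptor=adaptor, adapt_ms=adapt_ms, test_ms=test_ms,
                    C_adapt=C_adapt, C_test=C_test, dt=dt),
    )
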