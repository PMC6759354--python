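"""Synthetic stimulus generators.

All experiments run on stimuli built here: seven-segment digit patterns
presented as a timed sequence, constant scalar pulses, random constant
training patterns, and two-dimensional oriented drives.

Orientation convention: an orientation theta lives on a half-circle,
theta in (-pi/2, pi/2].  Stimuli (and the ring networks' decoding
weights) use the doubled angle so that the half-circle of orientations
maps bijectively onto the full unit circle:

    phi(t) = C(t) * [cos(2 theta(t)), sin(2 theta(t))]

Under this convention ``||phi|| = C`` always, and decoding an
orientation from an estimate is ``theta_hat = atan2(phi2, phi1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusTrace",
    "SEGMENT_TABLE",
    "digit_pattern",
    "digit_sequence",
    "random_pattern_stimuli",
    "constant_pulse",
    "orientation_stimulus",
    "concatenate",
]


@dataclass
class StimulusTrace:
    """An M-dimensional stimulus sampled on a uniform time grid.

    ``values`` has shape (M, T); ``labels`` optionally annotates
    intervals as ``(start_ms, end_ms, label)`` tuples (which digit or
    orientation is on when).
    """

    dt: float
    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.shape[1] < 1:
            raise ValueError("stimulus must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stimulus contains non-finite values")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


# Standard seven-segment display, segments ordered A, B, C, D, E, F, G
# (A top bar, B upper right, C lower right, D bottom, E lower left,
#  F upper left, G middle).
SEGMENT_TABLE = {
    0: (1, 1, 1, 1, 1, 1, 0),
    1: (0, 1, 1, 0, 0, 0, 0),
    2: (1, 1, 0, 1, 1, 0, 1),
    3: (1, 1, 1, 1, 0, 0, 1),
    4: (0, 1, 1, 0, 0, 1, 1),
    5: (1, 0, 1, 1, 0, 1, 1),
    6: (1, 0, 1, 1, 1, 1, 1),
    7: (1, 1, 1, 0, 0, 0, 0),
    8: (1, 1, 1, 1, 1, 1, 1),
    9: (1, 1, 1, 1, 0, 1, 1),
}


def digit_pattern(digit: int, amplitude: float = 2.0) -> np.ndarray:
    """Seven-segment encoding of a digit as a 7-vector.

    Active segments take the value ``amplitude``, inactive ones 0.
    """
    if digit not in SEGMENT_TABLE:
        raise ValueError(f"digit must be in 0..9, got {digit!r}")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    return amplitude * np.array(SEGMENT_TABLE[digit], dtype=float)


def digit_sequence(
    digits,
    on_ms: float = 200.0,
    off_ms: float = 100.0,
    amplitude: float = 2.0,
    dt: float = 0.1,
) -> StimulusTrace:
    """Piecewise-constant 7-dimensional trace of a digit sequence.

    Each digit is shown for ``on_ms`` ms; consecutive digits are
    separated by an ``off_ms`` blank (no gap after the last digit, so
    eight digits at 200/100 ms span 2300 ms).  Labels record the
    on-interval of every digit.
    """
    digits = list(digits)
    if not digits:
        raise ValueError("digit sequence must be nonempty")
    n_on = int(round(on_ms / dt))
    n_off = int(round(off_ms / dt))
    blocks, labels = [], []
    t = 0.0
    for k, d in enumerate(digits):
        blocks.append(np.tile(digit_pattern(d, amplitude)[:, None], (1, n_on)))
        labels.append((t, t + n_on * dt, d))
        t += n_on * dt
        if k < len(digits) - 1 and n_off:
            blocks.append(np.zeros((7, n_off)))
            t += n_off * dt
    return StimulusTrace(dt=dt, values=np.concatenate(blocks, axis=1), labels=labels)


def random_pattern_stimuli(
    n: int = 100,
    duration_ms: float = 300.0,
    low: float = 0.0,
    high: float = 4.0,
    M: int = 7,
    dt: float = 0.1,
    seed: int = 0,
) -> list[StimulusTrace]:
    """Random constant training patterns, i.i.d. uniform on [low, high].

    The defaults match the decoder-training set of the digit
    experiment: 100 examples, 300 ms each, 7 dimensions, values 0-4.
    """
    rng = np.random.default_rng(seed)
    T = int(round(duration_ms / dt))
    traces = []
    for _ in range(n):
        pattern = rng.uniform(low, high, size=M)
        traces.append(StimulusTrace(dt=dt, values=np.tile(pattern[:, None], (1, T))))
    return traces


def constant_pulse(
    value: float = 10.0,
    duration_ms: float = 2000.0,
    onset_ms: float = 0.0,
    dt: float = 0.1,
    M: int = 1,
    tail_ms: float = 0.0,
) -> StimulusTrace:
    """Scalar (or M-dim, all channels equal) rectangular pulse.

    The trace is ``value`` on [onset, onset + duration) and zero
    outside; ``tail_ms`` appends silence after the pulse.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    n_on = int(round(duration_ms / dt))
    n_pre = int(round(onset_ms / dt))
    n_post = int(round(tail_ms / dt))
    values = np.zeros((M, n_pre + n_on + n_post))
    values[:, n_pre:n_pre + n_on] = value
    return StimulusTrace(dt=dt, values=values)


def orientation_stimulus(theta, C, duration_ms: float = None, dt: float = 0.1) -> StimulusTrace:
    """Two-dimensional oriented drive ``C * [cos(2 theta), sin(2 theta)]``.

    ``theta`` (radians, in (-pi/2, pi/2]) and ``C`` (>= 0) may be
    scalars — in which case ``duration_ms`` sets the length of a
    constant presentation — or per-sample arrays of equal length.
    """
    theta = np.asarray(theta, dtype=float)
    C = np.asarray(C, dtype=float)
    if theta.ndim == 0 and C.ndim == 0:
        if duration_ms is None:
            raise ValueError("duration_ms required for scalar theta and C")
        T = int(round(duration_ms / dt))
        theta = np.full(T, float(theta))
        C = np.full(T, float(C))
    else:
        theta, C = np.broadcast_arrays(np.atleast_1d(theta), np.atleast_1d(C))
    if np.any(C < 0):
        raise ValueError("stimulus magnitude C must be >= 0")
    values = np.stack([C * np.cos(2 * theta), C * np.sin(2 * theta)])
    return StimulusTrace(dt=dt, values=values)


def concatenate(traces) -> StimulusTrace:
    """Concatenate traces in time (equal dt and dimension required)."""
    traces = list(traces)
    dt = traces[0].dt
    M = traces[0].M
    for tr in traces:
        if tr.dt != dt or tr.M != M:
            raise ValueError("all traces must share dt and dimension")
    labels, offset = [], 0.0
    for tr in traces:
        labels.extend((a + offset, b + offset, lab) for a, b, lab in tr.labels)
        offset += tr.duration
    return StimulusTrace(
        dt=dt, values=np.concatenate([tr.values for tr in traces], axis=1), labels=labels
    )
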