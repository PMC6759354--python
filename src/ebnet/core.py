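"""Network construction from decoding weights and cost parameters.

A network of N leaky integrate-and-fire neurons encodes an M-dimensional
stimulus through a fixed linear decoder.  Every derived quantity of the
model — per-neuron gain, recurrent (lateral) weights, adaptation
coefficients, normalized thresholds — is a deterministic function of the
decoding-weight matrix ``W`` (one row w_i per neuron), the cost weight
``mu``, and the two time constants ``tau`` (decoder/membrane, ms) and
``tau_a`` (adaptation, ms):

* gain            g_i   = 1 / (||w_i||^2 + mu)
* recurrence      Omega = W W^T + mu I          (mutual inhibition)
* adaptation      kappa_i = mu g_i (1 - tau/tau_a)
* threshold       1/2 + eta g_i ;  reset  -1/2   (normalized units)

The ``eta`` term raises thresholds in proportion to the gain; it is used
by the orientation networks to keep neurons with opposing preferences
from spiking off each other's recurrent excitation, and defaults to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkSpec",
    "compute_gains",
    "compute_recurrent_weights",
    "compute_adaptation_coefficients",
    "build_network",
    "without_recurrence",
    "save_spec",
    "load_spec",
]

RESET = -0.5


@dataclass(frozen=True)
class NetworkSpec:
    """Immutable definition of a balanced network with adaptation.

    Attributes
    ----------
    W : (N, M) ndarray
        Decoding weights, one row per neuron (stimulus units per spike).
    mu : float
        Cost weight, >= 0; trades metabolic cost against accuracy.
    tau : float
        Decoder / membrane time constant in ms.
    tau_a : float
        Adaptation time constant in ms (usually >> tau).
    eta : float
        Threshold-offset coefficient (threshold_i = 1/2 + eta * g_i).
    g, Omega, kappa, threshold
        Derived quantities (see module docstring).
    reset : float
        Post-spike normalized voltage, always -1/2.
    """

    W: np.ndarray
    mu: float
    tau: float
    tau_a: float
    eta: float = 0.0
    g: np.ndarray = field(default=None, repr=False)
    Omega: np.ndarray = field(default=None, repr=False)
    kappa: np.ndarray = field(default=None, repr=False)
    threshold: np.ndarray = field(default=None, repr=False)
    reset: float = RESET

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]


def _as_weight_matrix(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:  # a vector of scalar-stimulus weights
        W = W[:, None]
    if W.ndim != 2 or W.shape[0] < 1:
        raise ValueError(f"W must be an (N, M) matrix with N >= 1, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("W contains non-finite entries")
    return W


def compute_gains(W, mu: float) -> np.ndarray:
    """Per-neuron gain ``g_i = 1 / (||w_i||^2 + mu)``.

    Strictly positive and decreasing in the decoding-weight norm: neurons
    with small ||w_i|| are 'high gain' (excitable, precise, costly).
    """
    W = _as_weight_matrix(W)
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    norms2 = np.einsum("ij,ij->i", W, W)
    if mu == 0 and np.any(norms2 == 0):
        raise ValueError("mu = 0 with an all-zero weight row gives an infinite gain")
    return 1.0 / (norms2 + mu)


def compute_recurrent_weights(W, mu: float) -> np.ndarray:
    """Lateral connectivity ``Omega = W W^T + mu I``.

    Omega_ij measures how correlated the feedforward selectivities of
    neurons i and j are; the network subtracts exactly this redundancy
    after each spike.  Symmetric, and positive definite for mu > 0.
    """
    W = _as_weight_matrix(W)
    Omega = W @ W.T
    Omega[np.diag_indices_from(Omega)] += mu
    return Omega


def compute_adaptation_coefficients(g, mu: float, tau: float, tau_a: float) -> np.ndarray:
    """Adaptation current coefficient ``kappa_i = mu g_i (1 - tau/tau_a)``.

    Vanishes when spiking is free (mu = 0) or when the adaptation and
    decoding time scales coincide (tau_a = tau).
    """
    if tau <= 0 or tau_a <= 0:
        raise ValueError(f"time constants must be positive, got tau={tau}, tau_a={tau_a}")
    g = np.asarray(g, dtype=float)
    return mu * g * (1.0 - tau / tau_a)


def build_network(W, mu: float, tau: float, tau_a: float, eta: float = 0.0) -> NetworkSpec:
    """Assemble a :class:`NetworkSpec` with all derived quantities.

    Parameters are validated; ``tau_a < tau`` is allowed but warned
    about, since the model assumes the metabolic cost recovers more
    slowly than the representation decays.
    """
    W = _as_weight_matrix(W)
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta}")
    g = compute_gains(W, mu)
    if tau <= 0 or tau_a <= 0:
        raise ValueError(f"time constants must be positive, got tau={tau}, tau_a={tau_a}")
    if tau_a < tau:
        warnings.warn(
            f"tau_a ({tau_a} ms) < tau ({tau} ms): adaptation is faster than "
            "the decoder; the model expects tau_a >> tau",
            stacklevel=2,
        )
    Omega = compute_recurrent_weights(W, mu)
    kappa = compute_adaptation_coefficients(g, mu, tau, tau_a)
    threshold = 0.5 + eta * g
    spec = NetworkSpec(
        W=W, mu=float(mu), tau=float(tau), tau_a=float(tau_a), eta=float(eta),
        g=g, Omega=Omega, kappa=kappa, threshold=threshold,
    )
    return spec


def without_recurrence(spec: NetworkSpec) -> NetworkSpec:
    """Control variant with all cross-neuron recurrent weights removed.

    Only the diagonal of Omega (the self term implementing reset and the
    spike cost) is kept, so each neuron keeps its intrinsic adaptation
    but no longer coordinates with the rest of the population.
    """
    return replace(spec, Omega=np.diag(np.diag(spec.Omega)))


def save_spec(spec: NetworkSpec, path) -> None:
    """Serialize a spec to an .npz container (arrays + scalar parameters)."""
    np.savez(
        path,
        W=spec.W, mu=spec.mu, tau=spec.tau, tau_a=spec.tau_a, eta=spec.eta,
        Omega=spec.Omega,
    )


def load_spec(path) -> NetworkSpec:
    """Load a spec saved by :func:`save_spec`, rebuilding derived fields."""
    with np.load(path) as data:
        spec = build_network(
            data["W"], float(data["mu"]), float(data["tau"]),
            float(data["tau_a"]), float(data["eta"]),
        )
        if not np.allclose(data["Omega"], spec.Omega):
            spec = replace(spec, Omega=data["Omega"])
    return spec
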