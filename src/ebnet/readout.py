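"""Linear decoding of population activity.

Derived balanced networks are decoded with their own weights
(phi_hat = W^T r); generic networks get a least-squares decoder trained
on example responses.  Orientation networks decode an angle from the
two-dimensional estimate under the doubled-angle convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "linear_decode",
    "train_optimal_decoder",
    "decode_orientation",
    "smooth_estimate",
]


def linear_decode(r: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Apply a decoder: phi_hat(t) = D r(t).

    ``r`` is (N,) or (N, T); ``D`` is (M, N).  Returns (M,) or (M, T).
    """
    D = np.asarray(D, dtype=float)
    r = np.asarray(r, dtype=float)
    if D.shape[1] != r.shape[0]:
        raise ValueError(f"decoder expects {D.shape[1]} neurons, got {r.shape[0]}")
    return D @ r


def train_optimal_decoder(
    responses,
    stimuli,
    dt: float,
    discard_ms: float = 50.0,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Least-squares decoder from response/stimulus training pairs.

    Stacks all time samples of all trials (discarding the first
    ``discard_ms`` of each so the decoder reflects steady responses,
    not onset transients) and solves min_D sum_t ||phi(t) - D r(t)||^2
    via the normal equations, with a small ridge term (relative to the
    mean Gram diagonal) guarding rank deficiency; ridge=0 recovers the
    pure pseudoinverse solution.

    Parameters
    ----------
    responses : list of (N, T) arrays (or a single array)
    stimuli : matching list of (M, T) arrays
    dt : sampling step of the traces, ms

    Returns
    -------
    D : (M, N) decoder matrix
    """
    if isinstance(responses, np.ndarray):
        responses, stimuli = [responses], [stimuli]
    skip = int(round(discard_ms / dt))
    R_parts, P_parts = [], []
    for r, p in zip(responses, stimuli, strict=True):
        r = np.atleast_2d(np.asarray(r, dtype=float))
        p = np.atleast_2d(np.asarray(p, dtype=float))
        if r.shape[1] != p.shape[1]:
            raise ValueError("response and stimulus traces differ in length")
        R_parts.append(r[:, skip:])
        P_parts.append(p[:, skip:])
    R = np.concatenate(R_parts, axis=1)  # (N, samples)
    P = np.concatenate(P_parts, axis=1)  # (M, samples)
    N = R.shape[0]
    if R.shape[1] < N:
        warnings.warn(
            f"only {R.shape[1]} samples for {N} neurons; decoder is underdetermined",
            stacklevel=2,
        )
    gram = R @ R.T
    rank = np.linalg.matrix_rank(gram)
    if rank < N:
        warnings.warn(f"response Gram matrix is rank deficient ({rank} < {N})", stacklevel=2)
    if ridge:
        gram = gram + ridge * np.mean(np.diag(gram)) * np.eye(N)
        D = np.linalg.solve(gram, R @ P.T).T
    else:
        D = (np.linalg.pinv(gram) @ (R @ P.T)).T
    return D


def decode_orientation(phihat) -> np.ndarray | float:
    """Orientation from a 2-d estimate: theta_hat = atan2(phi2, phi1) / 2.

    Accepts a single 2-vector or a (2, T) trace; the halving undoes the
    doubled-angle stimulus convention, so the result lies in
    (-pi/2, pi/2].  A zero estimate carries no orientation and raises.
    """
    phihat = np.asarray(phihat, dtype=float)
    squeeze = phihat.ndim == 1
    ph = phihat[:, None] if squeeze else phihat
    if ph.shape[0] != 2:
        raise ValueError("orientation decoding needs a 2-dimensional estimate")
    if np.any((ph[0] == 0) & (ph[1] == 0)):
        raise ValueError("zero estimate: orientation undefined")
    theta = 0.5 * np.arctan2(ph[1], ph[0])
    # map the branch point -pi/2 onto +pi/2 so results lie in (-pi/2, pi/2]
    theta = np.where(theta <= -np.pi / 2 + 1e-15, theta + np.pi, theta)
    return float(theta[0]) if squeeze else theta


def smooth_estimate(trace: np.ndarray, window_ms: float, dt: float, circular: bool = False):
    """Causal moving average and running standard deviation of a trace.

    ``trace`` is 1-d (T,).  With ``circular=True`` the trace is treated
    as an orientation (period pi): statistics are computed on the
    doubled-angle unit vectors, the mean is halved back, and the
    dispersion is the circular standard deviation (also halved).
    """
    if window_ms < dt:
        raise ValueError("window must be at least one sample")
    k = max(int(round(window_ms / dt)), 1)
    s = pd.Series(np.asarray(trace, dtype=float))
    if not circular:
        mean = s.rolling(k, min_periods=1).mean().to_numpy()
        std = s.rolling(k, min_periods=1).std(ddof=0).to_numpy()
        return mean, std
    c = pd.Series(np.cos(2 * s)).rolling(k, min_periods=1).mean().to_numpy()
    sn = pd.Series(np.sin(2 * s)).rolling(k, min_periods=1).mean().to_numpy()
    mean = 0.5 * np.arctan2(sn, c)
    Rlen = np.minimum(np.hypot(c, sn), 1.0)
    with np.errstate(divide="ignore"):
        std = 0.5 * np.sqrt(np.maximum(-2.0 * np.log(Rlen), 0.0))
    return mean, std
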