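"""Constant-velocity Kalman smoothing of fused keypoint trajectories.

Each joint is filtered independently with a 6-state (position, velocity)
model.  Per frame the filter predicts

    x_k^- = A x_{k-1},            P_k^- = A P_{k-1} A^T + Q,

with A the constant-velocity transition (position += dt * velocity) and
Q = q I6, then corrects against the measured fused position z_k:

    K = P^- H^T (H P^- H^T + R)^{-1},   H = [I3 | 0],   R = r I3,
    x_k = x^- + K (z_k - H x^-),        P_k = (I - K H) P^-.

Defaults follow the noise scales q = 0.08 and r = 0.2 applied to the full
identity of each matrix's natural dimension; units follow the data unit
(pixels for 2-D runs, metres for 3-D) and are config-overridable.  The
initial velocity is the mean finite difference over the first
``init_window`` frames (default 30, i.e. one second at 30 fps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .keypoints import KeypointSequence


@dataclass
class KalmanConfig:
    dt: float = 1.0 / 30.0
    q: float = 0.08
    r: float = 0.2
    init_window: int = 30

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.q <= 0 or self.r <= 0 or self.init_window < 2:
            raise ValueError("dt, q, r must be positive and init_window >= 2")

    @property
    def A(self) -> np.ndarray:
        A = np.eye(6)
        A[:3, 3:] = self.dt * np.eye(3)
        return A

    @property
    def Q(self) -> np.ndarray:
        return self.q * np.eye(6)

    @property
    def R(self) -> np.ndarray:
        return self.r * np.eye(3)


_H = np.hstack([np.eye(3), np.zeros((3, 3))])


@dataclass
class KalmanState:
    """Per-joint state: 6-vector (position, velocity) and 6x6 covariance."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).reshape(6)
        self.P = np.asarray(self.P, dtype=np.float64).reshape(6, 6)
        if not np.allclose(self.P, self.P.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.P)) < -1e-9:
            raise ValueError("covariance must be positive semi-definite")


def kalman_predict(state: KalmanState, cfg: KalmanConfig) -> KalmanState:
    """Time update: propagate mean through A, inflate covariance by Q."""
    A = cfg.A
    x = A @ state.x
    P = A @ state.P @ A.T + cfg.Q
    return KalmanState(x=x, P=0.5 * (P + P.T))


def kalman_update(prior: KalmanState, z, cfg: KalmanConfig) -> KalmanState:
    """Measurement update against an observed 3-D position."""
    z = np.asarray(z, dtype=np.float64).reshape(3)
    P = prior.P
    S = _H @ P @ _H.T + cfg.R  # innovation covariance; r > 0 keeps it invertible
    K = P @ _H.T @ np.linalg.inv(S)
    x = prior.x + K @ (z - _H @ prior.x)
    Pn = (np.eye(6) - K @ _H) @ P
    return KalmanState(x=x, P=0.5 * (Pn + Pn.T))


def kalman_forecast(state: KalmanState, cfg: KalmanConfig, steps: int) -> KalmanState:
    """Multi-step-ahead prediction (predict-only), e.g. 30 steps = 1 s at 30 fps."""
    for _ in range(steps):
        state = kalman_predict(state, cfg)
    return state


def _init_state(coords: np.ndarray, valid: np.ndarray, cfg: KalmanConfig) -> KalmanState | None:
    """Initial state from the first valid frame and the early-window velocity."""
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return None
    first = idx[0]
    pos = coords[first]
    w = idx[idx < first + cfg.init_window]
    vel = np.zeros(3)
    if w.size >= 2:
        diffs = np.diff(coords[w], axis=0) / (np.diff(w)[:, None] * cfg.dt)
        vel = diffs.mean(axis=0)
    return KalmanState(x=np.concatenate([pos, vel]), P=np.eye(6))


def smooth_sequence(seq: KeypointSequence, cfg: KalmanConfig | None = None) -> KeypointSequence:
    """Filter every joint trajectory; output positions are posterior means.

    Invalid measurements skip the correction (predict-only), so gaps are
    bridged by the constant-velocity prior.  Joints with no valid frame at
    all stay invalid.  Filtering is causal: the output at frame k depends
    only on frames up to k.
    """
    cfg = cfg or KalmanConfig()
    if len(seq) < cfg.init_window:
        raise ValueError(
            f"sequence has {len(seq)} frames; init_window={cfg.init_window} required"
        )
    out = np.full_like(seq.coords, np.nan)
    out_valid = np.zeros_like(seq.valid)
    for j in range(seq.n_joints):
        coords = seq.coords[:, j, :]
        valid = seq.valid[:, j]
        state = _init_state(coords, valid, cfg)
        if state is None:
            continue
        first = int(np.nonzero(valid)[0][0])
        out[first, j] = state.x[:3]
        out_valid[first, j] = True
        for k in range(first + 1, len(seq)):
            state = kalman_predict(state, cfg)
            if valid[k]:
                state = kalman_update(state, coords[k], cfg)
            out[k, j] = state.x[:3]
            out_valid[k, j] = True
    return seq.copy(coords=out, valid=out_valid)
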