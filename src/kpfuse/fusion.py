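"""Multi-source keypoint fusion and light adaptation.

For one lighting condition the fused stream is the convex blend
``L = h U' + (1 - h) V'`` of the RGB-detector stream U' and the aligned
depth stream V'.  The optimal blend weight ``h_best`` minimises the mean
squared error against reference (motion-capture) data D,

    Mse(h) = (1/n) sum_i || h U'_i + (1 - h) V'_i - D_i ||^2 ,

found with the limited-memory BFGS engine (the objective is a scalar
quadratic, so the closed-form minimiser doubles as an independent check).
Across lighting conditions the (brightness, weight) pairs are fitted with
the logistic curve

    h_est(x_bar) = 1 / (1 + exp(-a x_bar + b)) ,

which predicts the blend weight for unseen brightness: dark scenes push
weight onto the depth stream, bright scenes onto the RGB detector.

:class:`LightAdaptiveFusion` wraps the calibration as a model object whose
``fit()`` returns :class:`LightAdaptiveFusionResults` carrying estimates,
the calibration table, diagnostics and a ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .keypoints import KeypointSequence
from .optim import lbfgs_minimize


@dataclass
class LBFGSConfig:
    """Settings for the quasi-Newton weight solver.

    h0 is the initial weight, epsilon the gradient threshold, num the
    number of stored vector pairs, max_iter the iteration cap.
    """

    h0: float = 0.5
    epsilon: float = 1e-5
    num: int = 10
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.num < 1 or self.max_iter < 1:
            raise ValueError("epsilon > 0, num >= 1, max_iter >= 1 required")


class FusionDataset:
    """Jointly valid (U', V', D) samples for one lighting condition.

    Built either directly from ``(n, 3)`` arrays or from three keypoint
    sequences sharing the same frame grid and joint set; a sample enters
    only where all three sources mark the joint valid.
    """

    def __init__(self, u: np.ndarray, v: np.ndarray, d: np.ndarray):
        self.u = np.asarray(u, dtype=np.float64)
        self.v = np.asarray(v, dtype=np.float64)
        self.d = np.asarray(d, dtype=np.float64)
        if not (self.u.shape == self.v.shape == self.d.shape):
            raise ValueError("U', V', D must have identical shapes")
        if self.u.ndim != 2 or self.u.shape[1] != 3:
            raise ValueError("samples must be (n, 3) arrays")
        if self.n < 1:
            raise ValueError("dataset needs at least one jointly valid sample")
        if not np.all(np.isfinite(self.u)) or not np.all(np.isfinite(self.v)) or not np.all(
            np.isfinite(self.d)
        ):
            raise ValueError("dataset samples must be finite")

    @property
    def n(self) -> int:
        return self.u.shape[0]

    @classmethod
    def from_sequences(
        cls,
        u_seq: KeypointSequence,
        v_seq: KeypointSequence,
        d_seq: KeypointSequence,
    ) -> "FusionDataset":
        if not (u_seq.same_grid(v_seq) and u_seq.same_grid(d_seq)):
            raise ValueError("sequences must share frame grid and joint set")
        mask = u_seq.valid & v_seq.valid & d_seq.valid
        return cls(u_seq.coords[mask], v_seq.coords[mask], d_seq.coords[mask])


@dataclass(frozen=True)
class SigmoidWeightModel:
    """Fitted logistic brightness -> weight map, h = 1/(1 + e^(-a x_bar + b))."""

    a_est: float
    b_est: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a_est) and math.isfinite(self.b_est)):
            raise ValueError("model parameters must be finite")


@dataclass
class FusionResult:
    """Optimal weight for one condition, with the achieved objective."""

    h: float
    objective: float
    iterations: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.h <= 1.0) or self.objective < 0:
            raise ValueError("h must lie in [0, 1] and objective be non-negative")


def fusion_mse(h: float, data: FusionDataset) -> float:
    """Mean squared Euclidean error of the h-blend against the reference."""
    resid = h * data.u + (1.0 - h) * data.v - data.d
    return float(np.sum(resid * resid) / data.n)


def _fusion_mse_grad(h: float, data: FusionDataset) -> float:
    diff = data.u - data.v
    resid = h * data.u + (1.0 - h) * data.v - data.d
    return float(2.0 * np.sum(diff * resid) / data.n)


def closed_form_weight(data: FusionDataset) -> float:
    """Exact minimiser of the quadratic weight objective, clamped to [0, 1].

    h* = sum <U'-V', D-V'> / sum ||U'-V'||^2.  Serves as the independent
    oracle for the iterative solver.  If U' = V' everywhere the objective
    is constant in h; returns 0.5 with a warning.
    """
    diff = data.u - data.v
    denom = float(np.sum(diff * diff))
    if denom <= 1e-300:
        warnings.warn("U' and V' coincide; objective is constant in h, returning 0.5")
        return 0.5
    h = float(np.sum(diff * (data.d - data.v))) / denom
    return min(1.0, max(0.0, h))


def optimize_weight(data: FusionDataset, cfg: LBFGSConfig | None = None) -> FusionResult:
    """Solve for the optimal blend weight by limited-memory BFGS.

    Starts at cfg.h0, descends along the two-loop-recursion direction with
    an Armijo backtracking search, and stops when the gradient magnitude
    falls below cfg.epsilon.  The returned weight is clamped to [0, 1].
    """
    cfg = cfg or LBFGSConfig()
    res = lbfgs_minimize(
        lambda x: fusion_mse(float(x[0]), data),
        lambda x: np.array([_fusion_mse_grad(float(x[0]), data)]),
        np.array([cfg.h0]),
        eps=cfg.epsilon,
        memory=cfg.num,
        max_iter=cfg.max_iter,
    )
    h = min(1.0, max(0.0, float(res.x[0])))
    return FusionResult(
        h=h, objective=fusion_mse(h, data), iterations=res.iterations, converged=res.converged
    )


# ---------------------------------------------------------------------------
# Logistic brightness -> weight fit
# ---------------------------------------------------------------------------

_MULTISTART_A = (-20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0)
_MULTISTART_B = (-10.0, -5.0, 0.0, 5.0, 10.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_weight(x_bar: float, model: SigmoidWeightModel) -> float:
    """Adaptive blend weight h = 1/(1 + e^(-a x_bar + b)), always in (0, 1)."""
    return float(_sigmoid(np.array([model.a_est * x_bar - model.b_est]))[0])


def fit_sigmoid(
    samples,
    cfg: LBFGSConfig | None = None,
) -> SigmoidWeightModel:
    """Least-squares logistic fit of (brightness, optimal-weight) pairs.

    Minimises sum_i (sigma(a x_i - b) - h_i)^2 with the same quasi-Newton
    engine in two dimensions.  The problem is non-convex, so a fixed grid
    of (a, b) starts is tried and the best final objective kept.
    """
    cfg = cfg or LBFGSConfig()
    pts = [(float(x), float(h)) for x, h in samples]
    if len(pts) < 3:
        raise ValueError("need at least 3 (brightness, weight) samples")
    x = np.array([p[0] for p in pts])
    h = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("brightness values must not all be identical")

    def obj(theta: np.ndarray) -> float:
        s = _sigmoid(theta[0] * x - theta[1])
        return float(np.sum((s - h) ** 2))

    def grad(theta: np.ndarray) -> np.ndarray:
        s = _sigmoid(theta[0] * x - theta[1])
        r = s - h
        ds = s * (1.0 - s)
        return np.array([2.0 * np.sum(r * ds * x), -2.0 * np.sum(r * ds)])

    best = None
    for a0 in _MULTISTART_A:
        for b0 in _MULTISTART_B:
            res = lbfgs_minimize(
                obj, grad, np.array([a0, b0]),
                eps=cfg.epsilon, memory=cfg.num, max_iter=cfg.max_iter,
            )
            if best is None or res.fun < best.fun:
                best = res
    return SigmoidWeightModel(a_est=float(best.x[0]), b_est=float(best.x[1]))


def fuse_sequences(
    u_seq: KeypointSequence, v_seq: KeypointSequence, h: float
) -> KeypointSequence:
    """Blend two aligned sequences: L' = h U' + (1 - h) V'.

    A fused joint is valid only where both inputs are valid.
    """
    if not (0.0 <= h <= 1.0):
        raise ValueError("h must lie in [0, 1]")
    if not u_seq.same_grid(v_seq):
        raise ValueError("sequences must share frame grid and joint set")
    if u_seq.unit != v_seq.unit:
        raise ValueError("sequences must share units")
    valid = u_seq.valid & v_seq.valid
    coords = np.full_like(u_seq.coords, np.nan)
    coords[valid] = h * u_seq.coords[valid] + (1.0 - h) * v_seq.coords[valid]
    return u_seq.copy(coords=coords, valid=valid, source="fused")


# ---------------------------------------------------------------------------
# Calibration across lighting conditions: model / results objects
# ---------------------------------------------------------------------------


class LightAdaptiveFusion:
    """Brightness-adaptive fusion model over several lighting conditions.

    Parameters
    ----------
    scenes : list of (x_bar, FusionDataset)
        One entry per lighting condition: the scene brightness (mean
        linear luminance in [0, 1]) and the jointly valid samples of the
        RGB stream, aligned depth stream and reference for that condition.
    cfg : LBFGSConfig, optional
        Solver settings shared by the per-condition weight search and the
        logistic fit.
    """

    def __init__(self, scenes, cfg: LBFGSConfig | None = None):
        self.scenes = [(float(x), ds) for x, ds in scenes]
        if len(self.scenes) < 3:
            raise ValueError("calibration needs at least 3 lighting conditions")
        for _, ds in self.scenes:
            if not isinstance(ds, FusionDataset):
                raise TypeError("each scene must carry a FusionDataset")
        self.cfg = cfg or LBFGSConfig()

    def fit(self) -> "LightAdaptiveFusionResults":
        rows = []
        for x_bar, ds in self.scenes:
            res = optimize_weight(ds, self.cfg)
            rows.append(
                {
                    "x_bar": x_bar,
                    "h_best": res.h,
                    "objective": res.objective,
                    "n": ds.n,
                    "iterations": res.iterations,
                }
            )
        table = pd.DataFrame(rows).sort_values("x_bar", ignore_index=True)
        model = fit_sigmoid(list(zip(table["x_bar"], table["h_best"])), self.cfg)
        return LightAdaptiveFusionResults(model=self, params=model, calibration_table=table)


@dataclass
class LightAdaptiveFusionResults:
    """Fitted brightness -> weight model plus the calibration table."""

    model: LightAdaptiveFusion
    params: SigmoidWeightModel
    calibration_table: pd.DataFrame = field(repr=False)

    @property
    def a_est(self) -> float:
        return self.params.a_est

    @property
    def b_est(self) -> float:
        return self.params.b_est

    def predict_weight(self, x_bar: float) -> float:
        return predict_weight(x_bar, self.params)

    @property
    def in_sample_residuals(self) -> np.ndarray:
        t = self.calibration_table
        pred = np.array([self.predict_weight(x) for x in t["x_bar"]])
        return pred - t["h_best"].to_numpy()

    def fuse(
        self, u_seq: KeypointSequence, v_seq: KeypointSequence, x_bar: float
    ) -> KeypointSequence:
        """Adaptively blend a scene using the predicted weight for its brightness."""
        return fuse_sequences(u_seq, v_seq, self.predict_weight(x_bar))

    def summary(self) -> str:
        t = self.calibration_table
        resid = self.in_sample_residuals
        lines = [
            "Light-adaptive fusion calibration",
            "=" * 49,
            f"conditions: {len(t)}    samples/condition: {int(t['n'].iloc[0])}",
            f"a_est (slope):  {self.a_est: .6f}",
            f"b_est (offset): {self.b_est: .6f}",
            f"in-sample weight RMSE: {float(np.sqrt(np.mean(resid ** 2))):.6f}",
            "-" * 49,
            f"{'x_bar':>8} {'h_best':>9} {'h_fit':>9} {'mse(h_best)':>12}",
        ]
        for _, r in t.iterrows():
            lines.append(
                f"{r['x_bar']:8.4f} {r['h_best']:9.4f} "
                f"{self.predict_weight(r['x_bar']):9.4f} {r['objective']:12.6g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a_est": self.a_est,
            "b_est": self.b_est,
            "calibration_table": self.calibration_table.to_dict(orient="records"),
        }


def calibrate_light_adaptation(scenes, cfg: LBFGSConfig | None = None):
    """Functional wrapper: fit the adaptive model over lighting conditions.

    Returns ``(SigmoidWeightModel, calibration_table)`` where the table has
    one row per condition with columns x_bar, h_best, objective, n.
    """
    results = LightAdaptiveFusion(scenes, cfg).fit()
    return results.params, results.calibration_table
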