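"""Evaluation metrics for keypoint streams and simulated-light images.

Trajectory metrics (mean squared error, cosine similarity, coefficient of
determination, percentage difference, joint accuracy at a pixel threshold,
coefficient of variation) compare a predicted stream F against reference
data D over jointly valid samples.  Image metrics (SSIM, PSNR) validate
that simulated low-light images resemble real ones; SSIM here uses global
whole-image statistics (a single mean/variance/covariance per image), not
the sliding-window variant — the windowed mode exists behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .illumination import ImageBuffer
from .keypoints import KeypointSequence

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _as2d(F, D) -> tuple[np.ndarray, np.ndarray]:
    F = np.asarray(F, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    if F.shape != D.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {D.shape}")
    if F.size == 0:
        raise ValueError("empty input")
    if F.ndim == 1:
        F = F[:, None]
        D = D[:, None]
    return F, D


def mse(F, D) -> float:
    """Mean squared (Euclidean) deviation: (1/n) sum_i ||F_i - D_i||^2."""
    F, D = _as2d(F, D)
    diff = F - D
    return float(np.sum(diff * diff) / F.shape[0])


def cosine_similarity(F, D) -> float:
    """Cosine of the angle between the flattened coordinate vectors."""
    F = np.asarray(F, dtype=np.float64).ravel()
    D = np.asarray(D, dtype=np.float64).ravel()
    if F.shape != D.shape:
        raise ValueError("shape mismatch")
    nf, nd = np.linalg.norm(F), np.linalg.norm(D)
    if nf == 0 or nd == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(F @ D / (nf * nd))


def r_squared(F, D) -> float:
    """Coefficient of determination 1 - SSres/SStot of F against D."""
    F = np.asarray(F, dtype=np.float64).ravel()
    D = np.asarray(D, dtype=np.float64).ravel()
    if F.shape != D.shape:
        raise ValueError("shape mismatch")
    ss_tot = float(np.sum((D - D.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: reference has zero variance")
    ss_res = float(np.sum((F - D) ** 2))
    return 1.0 - ss_res / ss_tot


def _relative_percent(f: np.ndarray, d: np.ndarray) -> float:
    """Mean of |f - d| / ((f + d)/2) * 100 over non-negative inputs."""
    denom = 0.5 * (f + d)
    if np.any(denom == 0):
        raise ValueError("percentage difference undefined: zero mean-pair denominator")
    return float(np.mean(np.abs(f - d) / denom) * 100.0)


def percentage_difference(F, D, mode: str = "magnitude") -> float:
    """Symmetric relative difference between F and D, in percent.

    The relative form |F - D| / ((F + D)/2) is ill-defined for signed
    coordinates, so it is applied to non-negative quantities:

    - ``magnitude`` (default): per-coordinate absolute values, averaged
      over all samples and axes;
    - ``distance``: per-sample Euclidean norms.
    """
    F, D = _as2d(F, D)
    if mode == "magnitude":
        return _relative_percent(np.abs(F).ravel(), np.abs(D).ravel())
    if mode == "distance":
        return _relative_percent(
            np.linalg.norm(F, axis=1), np.linalg.norm(D, axis=1)
        )
    raise ValueError(f"unknown mode {mode!r}")


def joint_accuracy(F, D, threshold: float) -> float:
    """Fraction of samples within `threshold` pixels (Euclidean) of reference."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    F, D = _as2d(F, D)
    dist = np.linalg.norm(F - D, axis=1)
    return float(np.mean(dist <= threshold))


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """Relative stability: standard deviation over mean, in percent.

    Sample (n-1) standard deviation by default; under 10% is read as low
    variability, 10-20% moderate, over 20% unstable.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=ddof) / m * 100.0)


# ---------------------------------------------------------------------------
# Image metrics
# ---------------------------------------------------------------------------


def _to_gray(img) -> tuple[np.ndarray, float]:
    """Return (grayscale array, dynamic range max)."""
    if isinstance(img, ImageBuffer):
        return img.pixels @ _LUMA, 1.0
    arr = np.asarray(img)
    rng = 255.0 if arr.dtype == np.uint8 else 1.0
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr @ _LUMA
    return arr, rng


def ssim(p, q, *, windowed: bool = False, win_size: int = 7) -> float:
    """Structural similarity from global whole-image statistics.

        SSIM = (2 mu_p mu_q + C1)(2 sigma_pq + C2)
               / ((mu_p^2 + mu_q^2 + C1)(sigma_p^2 + sigma_q^2 + C2))

    with C1 = (0.01 L)^2, C2 = (0.03 L)^2 and L the dynamic range.
    ``windowed=True`` averages the same statistic over sliding windows
    instead (a common library convention, off by default).
    """
    gp, L = _to_gray(p)
    gq, Lq = _to_gray(q)
    if gp.shape != gq.shape:
        raise ValueError("images must share dimensions")
    L = max(L, Lq)
    if windowed:
        from scipy.ndimage import uniform_filter

        mu_p = uniform_filter(gp, win_size)
        mu_q = uniform_filter(gq, win_size)
        var_p = uniform_filter(gp * gp, win_size) - mu_p**2
        var_q = uniform_filter(gq * gq, win_size) - mu_q**2
        cov = uniform_filter(gp * gq, win_size) - mu_p * mu_q
    else:
        mu_p, mu_q = gp.mean(), gq.mean()
        var_p, var_q = gp.var(), gq.var()
        cov = float(np.mean((gp - mu_p) * (gq - mu_q)))
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    val = ((2 * mu_p * mu_q + c1) * (2 * cov + c2)) / (
        (mu_p**2 + mu_q**2 + c1) * (var_p + var_q + c2)
    )
    return float(np.mean(val))


def psnr(p, q, *, max_value: float | None = None) -> float:
    """Peak signal-to-noise ratio 10 log10(MAX^2 / MSE), in dB.

    MAX defaults to the dynamic-range maximum (255 for 8-bit arrays, 1.0
    for float images); pass ``max_value`` to use the observed maximum
    instead.  Identical images return +inf.
    """
    gp, L = _to_gray(p)
    gq, Lq = _to_gray(q)
    if gp.shape != gq.shape:
        raise ValueError("images must share dimensions")
    # compare on raw channels, not luminance, for pixel fidelity
    ap = p.pixels if isinstance(p, ImageBuffer) else np.asarray(p, dtype=np.float64)
    aq = q.pixels if isinstance(q, ImageBuffer) else np.asarray(q, dtype=np.float64)
    m = max(L, Lq) if max_value is None else float(max_value)
    err = float(np.mean((ap - aq) ** 2))
    if err == 0:
        return math.inf
    return float(10.0 * math.log10(m * m / err))


# ---------------------------------------------------------------------------
# Sequence-level report
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Bundle of trajectory metrics plus a per-joint breakdown."""

    mse: float
    r_squared: float
    cosine: float
    diff_percent: float
    joint_accuracy: dict[float, float]
    cv: float | None = None
    per_joint: dict[str, dict] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        thr = sorted(self.joint_accuracy)
        accs = [self.joint_accuracy[t] for t in thr]
        if any(b < a - 1e-12 for a, b in zip(accs, accs[1:])):
            raise ValueError("joint accuracy must be monotone in threshold")

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "r_squared": self.r_squared,
            "cosine": self.cosine,
            "diff_percent": self.diff_percent,
            "joint_accuracy": {str(k): v for k, v in self.joint_accuracy.items()},
            "cv": self.cv,
            "n": self.n,
            "per_joint": self.per_joint,
        }


def evaluate_sequences(
    pred: KeypointSequence,
    ref: KeypointSequence,
    thresholds=(6.0, 8.0),
    diff_mode: str = "magnitude",
) -> MetricReport:
    """Full metric suite over jointly valid samples of two aligned streams.

    Joint accuracy uses the first two coordinates (pixel u, v) and is only
    meaningful for pixel-unit sequences.
    """
    if not pred.same_grid(ref):
        raise ValueError("sequences must share frame grid and joint set")
    mask = pred.valid & ref.valid
    if not mask.any():
        raise ValueError("no jointly valid samples")
    # pixel sequences are 2-D: the projected Z column is identically zero
    ncoord = 2 if pred.unit == "px" else 3
    F = pred.coords[mask][:, :ncoord]
    D = ref.coords[mask][:, :ncoord]
    F2, D2 = F[:, :2], D[:, :2]
    report = MetricReport(
        mse=mse(F, D),
        r_squared=r_squared(F, D),
        cosine=cosine_similarity(F, D),
        diff_percent=percentage_difference(F, D, mode=diff_mode),
        joint_accuracy={float(t): joint_accuracy(F2, D2, t) for t in thresholds},
        n=int(mask.sum()),
    )
    for k, joint in enumerate(pred.joints):
        jm = mask[:, k]
        if jm.sum() < 2:
            continue
        Fj, Dj = pred.coords[jm, k][:, :ncoord], ref.coords[jm, k][:, :ncoord]
        report.per_joint[joint] = {
            "mse": mse(Fj, Dj),
            "joint_accuracy": {
                str(float(t)): joint_accuracy(Fj[:, :2], Dj[:, :2], t) for t in thresholds
            },
            "n": int(jm.sum()),
        }
    return report
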