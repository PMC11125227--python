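"""Synthetic scenes: rehab-like trajectories, detector-like noise, images.

No public recordings exist for the fusion problem (marker-based reference,
depth-camera stream, RGB-detector stream under varying light), so every
stage is exercised on generated data:

- a smooth 12-joint ground truth built from an articulated skeleton whose
  segment directions are band-limited sinusoids of joint angles — bone
  lengths are exactly constant by construction;
- a depth-camera-like stream: truth + Gaussian jitter plus heavy-tailed
  spikes concentrated on knees/ankles, independent of illumination;
- an RGB-detector-like stream whose noise grows as the scene darkens:
  sigma = sigma_base * (1 + k * (1 - b(x))) where b(x) is scene brightness
  under gain x relative to full illumination;
- deterministic test images and a scene bundle tying the pieces together.

Two motion motifs mirror lower-limb rehabilitation exercises: gait-balance
training (large periodic knee/ankle excursion from high leg lifts) and
centre-of-gravity-transfer training (small-amplitude lateral sway).

All generators are pure functions of (spec, seed).  Noise magnitudes are
given in pixels and converted to metres through the scene's nominal
viewing geometry (focal length 500 px, subject depth 2.5 m -> 5 mm/px).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .alignment import CameraCalibration, transform_to_reference
from .fusion import FusionDataset
from .illumination import (
    ImageBuffer,
    IlluminationParams,
    mean_brightness,
    simulate_illumination,
    write_png,
)
from .keypoints import JointCatalog, KeypointSequence, write_keypoint_csv

_NOMINAL_DEPTH = 2.5  # m, subject distance used for the px <-> m conversion
_NOMINAL_FX = 500.0  # px
M_PER_PX = _NOMINAL_DEPTH / _NOMINAL_FX

_LOWER_LIMB = ("Left Knee", "Right Knee", "Left Ankle", "Right Ankle")

# segment lengths (m): upper arm, forearm, thigh, shank
_L_UA, _L_FA, _L_TH, _L_SH = 0.28, 0.25, 0.40, 0.40


@dataclass
class SceneSpec:
    """Study conditions for one synthetic recording session.

    depth_noise = (sigma_gauss px, spike_prob, spike_scale px);
    rgb_noise = (sigma_base px, darkness gain k).  Defaults give an RGB
    stream that beats the depth stream in full light and loses badly in
    the dark — the structure the brightness-adaptive weight must capture.
    """

    n_frames: int = 300
    rate: float = 30.0
    motion: str = "gait_balance"
    depth_noise: tuple[float, float, float] = (2.0, 0.15, 15.0)
    rgb_noise: tuple[float, float] = (1.0, 8.0)
    gains: tuple[float, ...] = (1.0, 0.8, 0.6, 0.45, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        sg, sp, ss = self.depth_noise
        sb, k = self.rgb_noise
        if sg < 0 or ss < 0 or sb < 0 or k < 0:
            raise ValueError("noise scales must be non-negative")
        if not (0.0 <= sp <= 1.0):
            raise ValueError("spike_prob must lie in [0, 1]")
        if self.motion not in ("gait_balance", "gravity_shift"):
            raise ValueError(f"unknown motion motif {self.motion!r}")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def default_calibration() -> CameraCalibration:
    """Nominal scene camera: 500 px focal length, VGA principal point,
    depth camera rotated 5 degrees about the vertical axis and offset a
    few centimetres from the reference camera."""
    th = np.deg2rad(5.0)
    R = np.array(
        [[np.cos(th), 0.0, np.sin(th)], [0.0, 1.0, 0.0], [-np.sin(th), 0.0, np.cos(th)]]
    )
    return CameraCalibration(fx=_NOMINAL_FX, fy=_NOMINAL_FX, dx=320.0, dy=240.0,
                             s=1.0, R=R, T=np.array([0.05, -0.02, 0.03]))


def _angle(t: np.ndarray, mean: float, amp: float, freq: float, ph: float, ph2: float) -> np.ndarray:
    """Band-limited joint angle: fundamental plus a weak first harmonic."""
    return (
        mean
        + amp * np.sin(2 * np.pi * freq * t + ph)
        + 0.3 * amp * np.sin(4 * np.pi * freq * t + ph2)
    )


def _dir_yz(theta: np.ndarray) -> np.ndarray:
    """Unit segment direction swinging in the sagittal (y-z) plane."""
    return np.stack([np.zeros_like(theta), -np.cos(theta), np.sin(theta)], axis=-1)


def generate_truth(spec: SceneSpec) -> KeypointSequence:
    """Smooth reference trajectory for the 12 limb joints.

    The skeleton is an articulated chain: a rigid pelvis/torso carries the
    hips and shoulders; arm and leg segments have fixed lengths and
    time-varying unit directions, so inter-joint bone lengths are constant
    over the whole sequence.  The gait-balance motif swings the hips and
    knees with large amplitude; the gravity-shift motif substitutes
    small-amplitude lateral sway.
    """
    rng = np.random.default_rng([spec.seed, 101])
    t = np.arange(spec.n_frames) / spec.rate
    if spec.motion == "gait_balance":
        hip_amp, knee_amp, arm_amp = 0.7, 0.9, 0.35
        f0 = 0.9
        sway_x, bob = 0.02, 0.03
    else:  # gravity_shift
        hip_amp, knee_amp, arm_amp = 0.15, 0.20, 0.15
        f0 = 0.4
        sway_x, bob = 0.06, 0.015

    ph = rng.uniform(0, 2 * np.pi, size=16)
    pelvis = np.stack(
        [
            sway_x * np.sin(2 * np.pi * f0 * t + ph[0]),
            1.0 + bob * np.sin(2 * np.pi * 2 * f0 * t + ph[1]),
            _NOMINAL_DEPTH + 0.02 * np.sin(2 * np.pi * f0 * t + ph[2]),
        ],
        axis=-1,
    )

    coords: dict[str, np.ndarray] = {}
    for side, sx, k in (("Left", -1.0, 0), ("Right", 1.0, 1)):
        hip = pelvis + np.array([sx * 0.12, 0.0, 0.0])
        shoulder = pelvis + np.array([sx * 0.20, 0.55, 0.0])
        # legs: alternate phase between sides (k * pi)
        th_hip = _angle(t, 0.0, hip_amp, f0, ph[3] + k * np.pi, ph[4] + k * np.pi)
        th_knee = th_hip + _angle(t, 0.25, knee_amp * 0.5, f0, ph[5] + k * np.pi, ph[6])
        knee = hip + _L_TH * _dir_yz(th_hip)
        ankle = knee + _L_SH * _dir_yz(th_knee)
        # arms: gentle counter-swing
        th_sh = _angle(t, 0.0, arm_amp, f0, ph[7] + (1 - k) * np.pi, ph[8])
        th_el = th_sh + _angle(t, 0.3, arm_amp * 0.6, f0, ph[9] + (1 - k) * np.pi, ph[10])
        elbow = shoulder + _L_UA * _dir_yz(th_sh)
        wrist = elbow + _L_FA * _dir_yz(th_el)
        coords[f"{side} Hip"] = hip
        coords[f"{side} Knee"] = knee
        coords[f"{side} Ankle"] = ankle
        coords[f"{side} Shoulder"] = shoulder
        coords[f"{side} Elbow"] = elbow
        coords[f"{side} Wrist"] = wrist

    joints = JointCatalog.default().names
    block = np.stack([coords[j] for j in joints], axis=1)
    return KeypointSequence(
        joints=joints,
        frame_index=np.arange(spec.n_frames),
        timestamps=t,
        coords=block,
        valid=np.ones((spec.n_frames, len(joints)), dtype=bool),
        rate=spec.rate,
        source="reference",
        unit="m",
    )


def simulate_depth_stream(truth: KeypointSequence, spec: SceneSpec) -> KeypointSequence:
    """Depth-camera-like stream: Gaussian jitter plus lower-limb spikes.

    The spike term models the depth detector briefly losing a fast-moving
    joint: with probability spike_prob a knee/ankle sample is displaced by
    at least spike_scale pixels in a random direction.  Noise is
    independent of illumination.
    """
    rng = np.random.default_rng([spec.seed, 202])
    sg, sp, ss = spec.depth_noise
    coords = truth.coords + rng.normal(0.0, sg * M_PER_PX, size=truth.coords.shape)
    if sp > 0 and ss > 0:
        lower = np.array([j in _LOWER_LIMB for j in truth.joints])
        hit = (rng.random(truth.valid.shape) < sp) & lower[None, :]
        n_hit = int(hit.sum())
        if n_hit:
            direction = rng.normal(size=(n_hit, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            magnitude = ss * M_PER_PX * (1.0 + 0.5 * np.abs(rng.standard_normal(n_hit)))
            coords[hit] += direction * magnitude[:, None]
    return truth.copy(coords=coords, source="depth_camera")


def _reference_image() -> ImageBuffer:
    return make_test_image("gradient", 32)


def relative_brightness(gain: float, t: float = 0.9) -> float:
    """Scene brightness under inverse gain, relative to full illumination."""
    base = _reference_image()
    b0 = mean_brightness(base)
    b = mean_brightness(simulate_illumination(base, IlluminationParams(x=gain, t=t)))
    return b / b0


def simulate_rgb_stream(
    truth: KeypointSequence, gain: float, spec: SceneSpec
) -> KeypointSequence:
    """RGB-detector-like stream whose noise grows as the scene darkens."""
    if not (0.0 < gain <= 1.0):
        raise ValueError("gain must lie in (0, 1]")
    sb, k = spec.rgb_noise
    sigma_px = sb * (1.0 + k * (1.0 - relative_brightness(gain)))
    rng = np.random.default_rng([spec.seed, 303, int(round(gain * 1_000_000))])
    coords = truth.coords + rng.normal(0.0, sigma_px * M_PER_PX, size=truth.coords.shape)
    return truth.copy(coords=coords, source="rgb_detector")


def make_test_image(kind: str, size: int = 64, tone: float = 0.5) -> ImageBuffer:
    """Deterministic sRGB test pattern: gradient, checker or flat gray."""
    if size < 1:
        raise ValueError("size must be positive")
    if kind == "gray":
        px = np.full((size, size, 3), tone)
    elif kind == "gradient":
        ramp = np.linspace(0.0, 1.0, size)
        px = np.broadcast_to(ramp[None, :, None], (size, size, 3)).copy()
    elif kind == "checker":
        cell = max(size // 8, 1)
        yy, xx = np.indices((size, size))
        mask = ((yy // cell) + (xx // cell)) % 2 == 0
        px = np.repeat(np.where(mask, 0.75, 0.25)[:, :, None], 3, axis=2)
    else:
        raise ValueError(f"unknown test image kind {kind!r}")
    return ImageBuffer(px, "srgb")


@dataclass
class SceneBundle:
    """Everything one synthetic session produces, keyed by gain."""

    spec: SceneSpec
    calib: CameraCalibration
    truth: KeypointSequence
    depth_raw: KeypointSequence  # in the depth camera's own frame
    depth_aligned: KeypointSequence
    rgb: dict[float, KeypointSequence]
    images: dict[float, ImageBuffer]
    x_bars: dict[float, float]
    manifest: dict = field(default_factory=dict)

    def scenes(self) -> list[tuple[float, FusionDataset]]:
        """Calibration input: (brightness, dataset) per lighting condition."""
        return [
            (
                self.x_bars[g],
                FusionDataset.from_sequences(self.rgb[g], self.depth_aligned, self.truth),
            )
            for g in self.spec.gains
        ]


def make_scene(
    spec: SceneSpec | None = None,
    out_dir=None,
    calib: CameraCalibration | None = None,
    highlight_threshold: float = 0.9,
) -> SceneBundle:
    """Generate a full reproducible scene; optionally write it to disk.

    The depth stream is produced in the depth camera's own frame (the
    inverse of the scene extrinsics applied to reference-frame samples) so
    the alignment stage has real work to do.  On write, the directory gets
    keypoint CSVs, per-gain PNGs and a YAML manifest with a content hash.
    """
    spec = spec or SceneSpec()
    calib = calib or default_calibration()
    truth = generate_truth(spec)
    depth_ref = simulate_depth_stream(truth, spec)
    depth_raw = transform_to_reference(depth_ref, calib.inverse_extrinsics()).copy(
        source="depth_camera"
    )
    depth_aligned = transform_to_reference(depth_raw, calib)

    base = _reference_image()
    rgb, images, x_bars = {}, {}, {}
    for g in spec.gains:
        rgb[g] = simulate_rgb_stream(truth, g, spec)
        images[g] = simulate_illumination(
            base, IlluminationParams(x=g, t=highlight_threshold)
        )
        x_bars[g] = mean_brightness(images[g])

    hasher = hashlib.sha256()
    for arr in (truth.coords, depth_raw.coords, *[rgb[g].coords for g in spec.gains]):
        hasher.update(np.ascontiguousarray(arr).tobytes())
    manifest = {
        "seed": spec.seed,
        "gains": list(spec.gains),
        "motion": spec.motion,
        "n_frames": spec.n_frames,
        "rate": spec.rate,
        "depth_noise": list(spec.depth_noise),
        "rgb_noise": list(spec.rgb_noise),
        "x_bars": {f"{g}": x_bars[g] for g in spec.gains},
        "hash": hasher.hexdigest(),
        "files": [],
    }

    bundle = SceneBundle(
        spec=spec, calib=calib, truth=truth, depth_raw=depth_raw,
        depth_aligned=depth_aligned, rgb=rgb, images=images, x_bars=x_bars,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {"truth.csv": truth, "depth.csv": depth_raw}
        files.update({f"rgb_gain{g:g}.csv": rgb[g] for g in spec.gains})
        for name, seq in files.items():
            write_keypoint_csv(seq, out / name)
            manifest["files"].append(name)
        for g in spec.gains:
            name = f"img_gain{g:g}.png"
            write_png(images[g], out / name)
            manifest["files"].append(name)
        manifest["calibration"] = calib.to_dict()
        with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return bundle
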