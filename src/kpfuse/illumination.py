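"""Illumination-change simulation in linear colour space.

Low-light scenes are synthesised from well-lit sRGB images by (1)
linearising with the inverse gamma transfer, (2) applying a
highlight-preserving inverse gain, and (3) re-encoding to sRGB.  A plain
multiplicative gain ``g -> x g`` with ``x < 1`` darkens highlights as much
as everything else; the highlight-preserving form

    f(x, g) = max(x g, (1 - alpha) x g + alpha g),
    alpha   = (max(x - t, 0) / (1 - t))^2

leaves the mapping exactly linear whenever the gain does not exceed the
highlight threshold t, and blends back toward the original value for
gains above it so bright detail survives mild darkening.

Scene brightness x_bar — the input to the adaptive-weight model — is the
mean linear relative luminance (Rec. 709 weights) of the sRGB image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Gamma transfer constants (sRGB encode: linear breakpoint 0.0031,
# slope 12.92, power-branch scale 1.055, offset 0.055, exponent 1/2.4).
_BREAK_LIN = 0.0031
_SLOPE = 12.92
_A = 1.055
_B = 0.055
_GAMMA = 2.4
_BREAK_SRGB = _SLOPE * _BREAK_LIN  # 0.040052

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class ImageBuffer:
    """H x W x 3 float image in [0, 1], tagged with its colour space."""

    pixels: np.ndarray
    space: str = "srgb"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.space not in ("srgb", "linear"):
            raise ValueError(f"unknown colour space {self.space!r}")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    def require(self, space: str) -> None:
        if self.space != space:
            raise ValueError(f"expected {space} image, got {self.space}")


@dataclass(frozen=True)
class IlluminationParams:
    """Inverse gain x in (0, 1] and highlight threshold t in (0, 1)."""

    x: float
    t: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.x <= 1.0):
            raise ValueError(f"inverse gain x must lie in (0, 1], got {self.x}")
        if not (0.0 < self.t < 1.0):
            raise ValueError(f"threshold t must lie in (0, 1), got {self.t}")

    @property
    def alpha(self) -> float:
        return (max(self.x - self.t, 0.0) / (1.0 - self.t)) ** 2


def linear_to_srgb(img: ImageBuffer) -> ImageBuffer:
    """Gamma-encode linear values: 12.92 f below 0.0031, else 1.055 f^(1/2.4) - 0.055."""
    img.require("linear")
    f = img.pixels
    out = np.where(f < _BREAK_LIN, _SLOPE * f, _A * np.power(f, 1.0 / _GAMMA) - _B)
    return ImageBuffer(out, "srgb")


def srgb_to_linear(img: ImageBuffer) -> ImageBuffer:
    """Exact piecewise inverse of :func:`linear_to_srgb` (breakpoint 12.92*0.0031)."""
    img.require("srgb")
    c = img.pixels
    out = np.where(c < _BREAK_SRGB, c / _SLOPE, np.power((c + _B) / _A, _GAMMA))
    return ImageBuffer(out, "linear")


def safe_inverse_gain(img: ImageBuffer, params: IlluminationParams) -> ImageBuffer:
    """Highlight-preserving inverse gain in linear space.

    For x <= t the blend weight alpha is zero and the map is exactly
    ``g -> x g``; for x > t the output is blended toward the original
    value, so it never falls below the plain gain and never exceeds
    ``max(x g, g)``.  Monotone non-decreasing in g for fixed parameters.
    """
    img.require("linear")
    g = img.pixels
    a = params.alpha
    xg = params.x * g
    out = np.maximum(xg, (1.0 - a) * xg + a * g)
    return ImageBuffer(out, "linear")


def simulate_illumination(img: ImageBuffer, params: IlluminationParams) -> ImageBuffer:
    """Relight an sRGB image: linearise, apply safe inverse gain, re-encode."""
    img.require("srgb")
    return linear_to_srgb(safe_inverse_gain(srgb_to_linear(img), params))


def mean_brightness(img: ImageBuffer) -> float:
    """Mean linear relative luminance (Rec. 709) of an sRGB image, in [0, 1]."""
    img.require("srgb")
    lin = srgb_to_linear(img)
    return float(np.mean(lin.pixels @ _LUMA))


def read_png(path) -> ImageBuffer:
    """Read an 8-bit PNG as an sRGB buffer in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return ImageBuffer(arr.astype(np.float64) / 255.0, "srgb")


def write_png(img: ImageBuffer, path) -> None:
    """Write an sRGB buffer as 8-bit PNG (round-to-nearest quantisation)."""
    import imageio.v3 as iio

    img.require("srgb")
    iio.imwrite(path, np.rint(img.pixels * 255.0).astype(np.uint8))
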