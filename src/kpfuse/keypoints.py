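"""Keypoint data model, joint-scheme harmonisation, CSV IO and resampling.

The canonical skeleton is the 12 limb joints (left/right shoulder, elbow,
wrist, hip, knee, ankle).  Depth-camera and RGB-detector skeletons index
their joints differently; :class:`JointCatalog` carries the correspondence
and :func:`harmonize_joints` relabels raw per-index detections onto the
canonical names, dropping face/hand/torso points that are not part of the
limb set.

Sequences are stored array-backed: an ``(n_frames, n_joints, 3)`` coordinate
block plus a boolean validity mask.  Invalid joints carry NaN coordinates,
never silent zeros, and are excluded from every downstream sum.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

MISSING = float("nan")

_ALLOWED_SOURCES = ("rgb_detector", "depth_camera", "reference", "fused", "aligned")
_ALLOWED_UNITS = ("m", "px")


class KeypointParseError(ValueError):
    """Raised when a keypoint CSV violates the documented schema."""


@dataclass(frozen=True)
class JointCatalog:
    """Correspondence between canonical joint names and detector indices.

    Each entry is ``(canonical name, depth-scheme index, rgb-scheme index)``.
    The mapping is a bijection in each scheme.
    """

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        depth = [e[1] for e in self.entries]
        rgb = [e[2] for e in self.entries]
        if len(self.entries) != 12:
            raise ValueError(f"catalog must have exactly 12 entries, got {len(self.entries)}")
        for label, vals in (("name", names), ("depth index", depth), ("rgb index", rgb)):
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate {label} in joint catalog")

    @classmethod
    def default(cls) -> "JointCatalog":
        """Load the packaged 12-joint limb catalog."""
        ref = importlib.resources.files("kpfuse").joinpath("data/joint_catalog.csv")
        with ref.open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls(tuple((r["joint"], int(r["depth_index"]), int(r["rgb_index"])) for r in rows))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def index_map(self, scheme: str) -> dict[int, str]:
        """Raw index -> canonical name for the named scheme."""
        if scheme == "depth":
            return {e[1]: e[0] for e in self.entries}
        if scheme == "rgb":
            return {e[2]: e[0] for e in self.entries}
        raise ValueError(f"unknown scheme {scheme!r}; expected 'depth' or 'rgb'")


@dataclass
class KeypointFrame:
    """Single-frame view: canonical joint -> coordinate triple + validity."""

    frame_index: int
    timestamp: float
    coords: dict[str, np.ndarray]
    validity: dict[str, bool]


class KeypointSequence:
    """Time-ordered per-joint 3-D (or projected 2-D pixel) coordinates.

    Parameters
    ----------
    joints : canonical joint names, fixed over the whole sequence.
    frame_index : strictly increasing integer frame numbers.
    timestamps : strictly increasing times in seconds.
    coords : ``(n_frames, n_joints, 3)`` array; NaN where invalid.
    valid : ``(n_frames, n_joints)`` boolean mask.
    rate : nominal frame rate (fps).
    source : one of ``rgb_detector, depth_camera, reference, fused, aligned``.
    unit : ``"m"`` for metric 3-D data, ``"px"`` for projected 2-D data.
    """

    def __init__(
        self,
        joints: tuple[str, ...],
        frame_index: np.ndarray,
        timestamps: np.ndarray,
        coords: np.ndarray,
        valid: np.ndarray,
        rate: float,
        source: str,
        unit: str = "m",
    ):
        self.joints = tuple(joints)
        self.frame_index = np.asarray(frame_index, dtype=np.int64)
        self.timestamps = np.asarray(timestamps, dtype=np.float64)
        self.coords = np.asarray(coords, dtype=np.float64)
        self.valid = np.asarray(valid, dtype=bool)
        self.rate = float(rate)
        self.source = source
        self.unit = unit
        self._check()

    def _check(self) -> None:
        n, j = len(self.frame_index), len(self.joints)
        if n == 0:
            raise ValueError("sequence must contain at least one frame")
        if self.coords.shape != (n, j, 3):
            raise ValueError(f"coords shape {self.coords.shape} != {(n, j, 3)}")
        if self.valid.shape != (n, j):
            raise ValueError(f"valid shape {self.valid.shape} != {(n, j)}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if np.any(self.frame_index < 0) or np.any(self.timestamps < 0):
            raise ValueError("frame_index and timestamps must be non-negative")
        if self.source not in _ALLOWED_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.unit not in _ALLOWED_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        # invalid joints must carry the missing marker, never silent values
        if np.any(np.isfinite(self.coords[~self.valid])):
            raise ValueError("invalid joints must have NaN coordinates")
        if np.any(~np.isfinite(self.coords[self.valid])):
            raise ValueError("valid joints must have finite coordinates")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    def frames(self) -> Iterator[KeypointFrame]:
        for i in range(len(self)):
            yield KeypointFrame(
                frame_index=int(self.frame_index[i]),
                timestamp=float(self.timestamps[i]),
                coords={j: self.coords[i, k].copy() for k, j in enumerate(self.joints)},
                validity={j: bool(self.valid[i, k]) for k, j in enumerate(self.joints)},
            )

    def copy(self, **overrides) -> "KeypointSequence":
        kw = dict(
            joints=self.joints,
            frame_index=self.frame_index.copy(),
            timestamps=self.timestamps.copy(),
            coords=self.coords.copy(),
            valid=self.valid.copy(),
            rate=self.rate,
            source=self.source,
            unit=self.unit,
        )
        kw.update(overrides)
        return KeypointSequence(**kw)

    def equals(self, other: "KeypointSequence") -> bool:
        return (
            self.joints == other.joints
            and np.array_equal(self.frame_index, other.frame_index)
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.coords, other.coords, equal_nan=True)
            and np.array_equal(self.valid, other.valid)
            and self.rate == other.rate
            and self.source == other.source
            and self.unit == other.unit
        )

    def same_grid(self, other: "KeypointSequence", atol: float = 1e-9) -> bool:
        """Whether two sequences share the frame grid and joint set."""
        return (
            self.joints == other.joints
            and len(self) == len(other)
            and np.array_equal(self.frame_index, other.frame_index)
            and np.allclose(self.timestamps, other.timestamps, atol=atol)
        )


def harmonize_joints(
    raw: Mapping[int, np.ndarray], scheme: str, catalog: JointCatalog
) -> dict[str, np.ndarray]:
    """Relabel raw per-index detections onto canonical joint names.

    Indices outside the catalog (nose, fingers, spine, ...) are dropped.
    """
    imap = catalog.index_map(scheme)
    return {imap[i]: np.asarray(p, dtype=np.float64) for i, p in raw.items() if i in imap}


# ---------------------------------------------------------------------------
# CSV IO.  Schema: optional '#' metadata lines (unit, rate, source), then the
# header `frame,time_s,joint,x,y,z,valid`, one row per (frame, joint).
# ---------------------------------------------------------------------------

_HEADER = ["frame", "time_s", "joint", "x", "y", "z", "valid"]


def write_keypoint_csv(seq: KeypointSequence, path) -> None:
    """Serialise a sequence losslessly (full float precision, LF endings)."""
    if len(seq) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("empty sequences are not serializable")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# unit: {seq.unit}\n")
        fh.write(f"# rate: {seq.rate!r}\n")
        fh.write(f"# source: {seq.source}\n")
        fh.write(",".join(_HEADER) + "\n")
        for i in range(len(seq)):
            for k, joint in enumerate(seq.joints):
                x, y, z = (float(c) for c in seq.coords[i, k])
                fh.write(
                    f"{int(seq.frame_index[i])},{float(seq.timestamps[i])!r},{joint},"
                    f"{x!r},{y!r},{z!r},{int(seq.valid[i, k])}\n"
                )


def read_keypoint_csv(path, catalog: JointCatalog | None = None) -> KeypointSequence:
    """Parse a keypoint CSV, enforcing every sequence invariant.

    Raises :class:`KeypointParseError` naming the offending line for
    malformed rows, unknown joints, duplicate (frame, joint) pairs,
    non-monotone timestamps or frames missing catalog joints.
    """
    catalog = catalog or JointCatalog.default()
    names = catalog.names
    name_set = set(names)

    meta = {"unit": "m", "rate": None, "source": "reference"}
    rows: list[tuple[int, float, str, float, float, float, bool]] = []
    try:
        fh = open(path, "r", encoding="utf-8")
    except FileNotFoundError as e:
        raise KeypointParseError(f"no such file: {path}") from e
    with fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            if not header_seen:
                if parts != _HEADER:
                    raise KeypointParseError(
                        f"line {lineno}: bad header {parts!r}, expected {_HEADER!r}"
                    )
                header_seen = True
                continue
            if len(parts) != 7:
                raise KeypointParseError(f"line {lineno}: expected 7 fields, got {len(parts)}")
            try:
                frame = int(parts[0])
                t = float(parts[1])
                joint = parts[2]
                xyz = (float(parts[3]), float(parts[4]), float(parts[5]))
                valid = bool(int(parts[6]))
            except ValueError as e:
                raise KeypointParseError(f"line {lineno}: malformed row ({e})") from e
            if joint not in name_set:
                raise KeypointParseError(f"line {lineno}: unknown joint {joint!r}")
            rows.append((frame, t, joint, *xyz, valid, lineno))
    if not header_seen:
        raise KeypointParseError("file has no header row")
    if not rows:
        raise KeypointParseError("file has no data rows")

    # group by frame, preserving order of first appearance
    by_frame: dict[int, dict] = {}
    order: list[int] = []
    for frame, t, joint, x, y, z, valid, lineno in rows:
        if frame not in by_frame:
            by_frame[frame] = {"t": t, "joints": {}, "lineno": lineno}
            order.append(frame)
        fr = by_frame[frame]
        if joint in fr["joints"]:
            raise KeypointParseError(
                f"line {lineno}: duplicate entry for frame {frame}, joint {joint!r}"
            )
        if t != fr["t"]:
            raise KeypointParseError(
                f"line {lineno}: inconsistent timestamp within frame {frame}"
            )
        fr["joints"][joint] = (x, y, z, valid)

    n = len(order)
    coords = np.full((n, len(names), 3), np.nan)
    valid_m = np.zeros((n, len(names)), dtype=bool)
    timestamps = np.empty(n)
    for i, frame in enumerate(order):
        fr = by_frame[frame]
        missing = name_set - set(fr["joints"])
        if missing:
            raise KeypointParseError(
                f"frame {frame} (line {fr['lineno']}): missing joint(s) "
                + ", ".join(repr(m) for m in sorted(missing))
            )
        timestamps[i] = fr["t"]
        for k, name in enumerate(names):
            x, y, z, v = fr["joints"][name]
            valid_m[i, k] = v
            if v:
                coords[i, k] = (x, y, z)
    frame_index = np.array(order, dtype=np.int64)
    if np.any(np.diff(frame_index) <= 0):
        raise KeypointParseError("frame indices are not strictly increasing")
    if np.any(np.diff(timestamps) <= 0):
        bad = int(np.nonzero(np.diff(timestamps) <= 0)[0][0])
        raise KeypointParseError(
            f"timestamps not strictly increasing at frame {order[bad + 1]}"
        )

    rate = float(meta["rate"]) if meta["rate"] is not None else _infer_rate(timestamps)
    try:
        return KeypointSequence(
            names, frame_index, timestamps, coords, valid_m, rate, meta["source"], meta["unit"]
        )
    except ValueError as e:
        raise KeypointParseError(str(e)) from e


def _infer_rate(timestamps: np.ndarray) -> float:
    if len(timestamps) < 2:
        return 30.0
    return 1.0 / float(np.median(np.diff(timestamps)))


def resample_to_rate(seq: KeypointSequence, target_rate: float) -> KeypointSequence:
    """Downsample by nearest-timestamp selection onto the target grid.

    Output timestamps lie on ``t0 + k/target_rate``; each output frame copies
    the input frame whose timestamp is nearest (ties broken toward the
    earlier frame).  Upsampling is unsupported: detector streams are
    synchronised by decimation to the slowest rate, not by interpolation.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > seq.rate:
        raise ValueError(
            f"upsampling unsupported: target rate {target_rate} > source rate {seq.rate}"
        )
    t0 = seq.timestamps[0]
    t_end = seq.timestamps[-1]
    n_out = int(np.floor((t_end - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / target_rate
    # nearest input frame per grid point, ties toward earlier
    idx = np.searchsorted(seq.timestamps, grid)
    picks = np.empty(n_out, dtype=np.int64)
    for k, (g, i) in enumerate(zip(grid, idx)):
        lo = max(i - 1, 0)
        hi = min(i, len(seq) - 1)
        picks[k] = lo if g - seq.timestamps[lo] <= seq.timestamps[hi] - g else hi
    return KeypointSequence(
        seq.joints,
        seq.frame_index[picks],
        grid,
        seq.coords[picks],
        seq.valid[picks],
        target_rate,
        seq.source,
        seq.unit,
    )
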