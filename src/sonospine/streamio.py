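"""On-disk tracked-frame streams, transforms and images.

A stream directory holds lossless PNG frames ``frame_%06d.png``, a
``poses.csv`` (columns ``index,timestamp,tx,ty,tz,alpha,beta,gamma``) and
a ``meta.yaml`` with frame size, pixel spacings, the Euler convention tag
and an optional calibration-transform reference, so streams are
self-describing.  Final coronal images are written as standard 8-bit
grayscale BMP (and PNG on request).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import (
    EULER_CONVENTION,
    FrameGeometry,
    Pose,
    RigidTransform,
    pose_to_matrix,
)
from .phantom import TrackedFrame

__all__ = [
    "StreamMetadata",
    "CorruptStreamError",
    "StreamFormatError",
    "write_stream",
    "read_stream",
    "write_bitmap",
    "read_image",
    "save_transform",
    "load_transform",
    "read_calibration_observations",
    "write_calibration_observations",
    "write_provenance",
]

POSE_COLUMNS = ["index", "timestamp", "tx", "ty", "tz", "alpha", "beta", "gamma"]


class CorruptStreamError(RuntimeError):
    """Frame files and pose rows disagree, or a frame is missing."""


class StreamFormatError(RuntimeError):
    """Stream directory is missing required metadata."""


@dataclass(frozen=True)
class StreamMetadata:
    """Self-describing stream header."""

    frame_width: int
    frame_height: int
    pixel_spacing_x: float
    pixel_spacing_y: float
    frame_rate: float
    euler_convention: str = EULER_CONVENTION
    calibration_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pixel_spacing_x <= 0 or self.pixel_spacing_y <= 0:
            raise ValueError("pixel spacings must be positive")

    def geometry(self) -> FrameGeometry:
        return FrameGeometry(
            pixel_spacing_x=self.pixel_spacing_x,
            pixel_spacing_y=self.pixel_spacing_y,
            width=self.frame_width,
            height=self.frame_height,
        )


def _frame_name(i: int) -> str:
    return f"frame_{i:06d}.png"


def write_stream(path, frames: Sequence[TrackedFrame], meta: StreamMetadata) -> Path:
    """Write a tracked-frame stream directory (PNG + poses.csv + meta.yaml)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in frames:
        Image.fromarray(f.image, mode="L").save(root / _frame_name(f.index))
        p = f.pose
        rows.append(
            [f.index, p.timestamp if p.timestamp is not None else np.nan,
             p.tx, p.ty, p.tz, p.alpha, p.beta, p.gamma]
        )
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(root / "poses.csv", index=False)
    with open(root / "meta.yaml", "w") as fh:
        yaml.safe_dump(asdict(meta), fh, sort_keys=False)
    return root


def read_stream(path) -> Tuple[StreamMetadata, Iterator[TrackedFrame]]:
    """Open a stream directory; frames are yielded lazily in index order.

    The pose row count must equal the frame file count (otherwise the
    stream is corrupt), and meta.yaml must be present.
    """
    root = Path(path)
    meta_path = root / "meta.yaml"
    if not meta_path.exists():
        raise StreamFormatError(f"missing meta.yaml in {root}")
    with open(meta_path) as fh:
        meta = StreamMetadata(**yaml.safe_load(fh))
    poses_path = root / "poses.csv"
    if not poses_path.exists():
        raise StreamFormatError(f"missing poses.csv in {root}")
    poses = pd.read_csv(poses_path)
    frame_files = sorted(root.glob("frame_*.png"))
    if len(frame_files) != len(poses):
        raise CorruptStreamError(
            f"{len(frame_files)} frame files but {len(poses)} pose rows in {root}"
        )

    def _iter() -> Iterator[TrackedFrame]:
        for _, row in poses.sort_values("index").iterrows():
            idx = int(row["index"])
            fp = root / _frame_name(idx)
            if not fp.exists():
                raise CorruptStreamError(f"missing frame file {fp.name}")
            img = np.asarray(Image.open(fp).convert("L"))
            ts = None if pd.isna(row["timestamp"]) else float(row["timestamp"])
            yield TrackedFrame(
                image=img,
                pose=Pose(row["tx"], row["ty"], row["tz"],
                          row["alpha"], row["beta"], row["gamma"], timestamp=ts),
                index=idx,
            )

    return meta, _iter()


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_bitmap(image: np.ndarray, path) -> Path:
    """Save an 8-bit grayscale image as a standard BMP (or PNG by suffix)."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("write_bitmap expects an 8-bit image")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    fmt = "PNG" if p.suffix.lower() == ".png" else "BMP"
    Image.fromarray(img, mode="L").save(p, format=fmt)
    return p


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def save_transform(transform: RigidTransform, path) -> Path:
    """Write a transform as a plain-text 4x4 row-major matrix."""
    p = Path(path)
    np.savetxt(p, transform.matrix, fmt="%.12g")
    return p


def load_transform(path) -> RigidTransform:
    """Read a transform file: 16 numbers (4x4 row-major) or 6 pose parameters."""
    vals = np.loadtxt(path).ravel()
    if vals.size == 16:
        return RigidTransform(vals.reshape(4, 4))
    if vals.size == 6:
        return pose_to_matrix(Pose(*vals))
    raise StreamFormatError(
        f"transform file must hold 16 (matrix) or 6 (pose) numbers, got {vals.size}"
    )


# ---------------------------------------------------------------------------
# Calibration observations
# ---------------------------------------------------------------------------

OBS_COLUMNS = ["frame", "u", "v", "tx", "ty", "tz", "alpha", "beta", "gamma"]


def write_calibration_observations(path, pixels: np.ndarray, poses: Sequence[Pose]) -> Path:
    rows = [
        [i, float(px[0]), float(px[1]), p.tx, p.ty, p.tz, p.alpha, p.beta, p.gamma]
        for i, (px, p) in enumerate(zip(pixels, poses))
    ]
    p = Path(path)
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(p, index=False)
    return p


def read_calibration_observations(path) -> Tuple[np.ndarray, List[Pose]]:
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise StreamFormatError(f"calibration CSV missing columns {sorted(missing)}")
    pixels = df[["u", "v"]].to_numpy(dtype=float)
    poses = [
        Pose(r.tx, r.ty, r.tz, r.alpha, r.beta, r.gamma)
        for r in df.itertuples(index=False)
    ]
    return pixels, poses


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def write_provenance(path, config: dict, seed: Optional[int]) -> Path:
    """Record config hash, seed and package version next to an output."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "sonospine_version": __version__,
        "numpy_version": np.__version__,
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return p
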