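"""Frame-sequence I/O, grayscale conversion, ROI cropping and frame sampling.

A movie arrives as a directory of per-frame PNG/TIFF rasters plus a
manifest row naming the oocyte, its rupture label and the reference
("first confirmed") frame index. Analysis crops a fixed rectangle — by
default 380 px wide by 370 px high, the smallest window that encloses a
whole oocyte in a 960x540 recording — and samples frames strictly before
the reference frame at a fixed stride of 6 frames (the smallest stride
exceeding five frames; at 30 fps, five such samples span about one
second before puncture).

Coordinates are 0-based, row-major (row, column); crops are half-open.
RGB inputs are converted with ITU-R BT.601 luma weights
(0.299 R + 0.587 G + 0.114 B) rounded to the nearest integer.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

LABELS = ("ruptured", "nonruptured")

#: Default crop size enclosing a full oocyte in a 960x540 recording.
DEFAULT_ROI_WIDTH = 380
DEFAULT_ROI_HEIGHT = 370

#: Smallest sampling stride that exceeds five frames.
DEFAULT_INTERVAL = 6

MANIFEST_COLUMNS = ("oocyte_id", "label", "n_frames", "reference_frame", "seed")


class ManifestError(ValueError):
    """Inconsistent or invalid manifest metadata."""


class GeometryError(ValueError):
    """Crop rectangle not contained in the frame."""


class SamplingError(ValueError):
    """Sequence too short for the requested sampling pattern."""


@dataclass
class FrameSequence:
    """One oocyte's ordered grayscale frames with its outcome label."""

    oocyte_id: str
    label: str
    frames: list[np.ndarray]
    reference_frame: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ManifestError(
                f"label {self.label!r} not in {LABELS} (oocyte {self.oocyte_id})"
            )
        if not self.frames:
            raise ManifestError(f"oocyte {self.oocyte_id}: empty frame list")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ManifestError(f"oocyte {self.oocyte_id}: frames differ in shape")
        if not 0 <= self.reference_frame < len(self.frames):
            raise ManifestError(
                f"oocyte {self.oocyte_id}: reference_frame {self.reference_frame} "
                f"outside [0, {len(self.frames)})"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def y(self) -> int:
        """Numeric label: ruptured -> +1 (positive class), nonruptured -> -1."""
        return 1 if self.label == "ruptured" else -1


@dataclass(frozen=True)
class RoiSpec:
    """Analysis crop rectangle: top-left ``origin`` = (x, y), then size."""

    origin: tuple[int, int] = (0, 0)
    width: int = DEFAULT_ROI_WIDTH
    height: int = DEFAULT_ROI_HEIGHT

    @staticmethod
    def centered(frame_height: int, frame_width: int,
                 width: int = DEFAULT_ROI_WIDTH,
                 height: int = DEFAULT_ROI_HEIGHT) -> "RoiSpec":
        """ROI of the given size centered in a frame."""
        x0 = (frame_width - width) // 2
        y0 = (frame_height - height) // 2
        if x0 < 0 or y0 < 0:
            raise GeometryError(
                f"ROI {width}x{height} does not fit a {frame_width}x{frame_height} frame"
            )
        return RoiSpec(origin=(x0, y0), width=width, height=height)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion of an RGB(A) raster; grayscale passes through."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(float)
        luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.rint(luma).clip(0, 255).astype(np.uint8)
    raise ValueError(f"unsupported raster shape {frame.shape}")


def crop_roi(frame: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Pure windowing: output (i, j) = input (origin_y + i, origin_x + j)."""
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    x0, y0 = roi.origin
    if x0 < 0 or y0 < 0 or x0 + roi.width > w or y0 + roi.height > h:
        raise GeometryError(
            f"ROI origin {roi.origin} size {roi.width}x{roi.height} exceeds "
            f"frame bounds {w}x{h}"
        )
    return frame[y0 : y0 + roi.height, x0 : x0 + roi.width]


def sample_frames(seq: FrameSequence, n_samples: int,
                  interval: int = DEFAULT_INTERVAL) -> list[np.ndarray]:
    """Select ``n_samples`` frames strictly before the reference frame.

    Frames sit at indices ``reference_frame - k * interval`` for
    k = n_samples .. 1, returned in chronological order.
    """
    if not 1 <= n_samples:
        raise ValueError("n_samples must be >= 1")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    first = seq.reference_frame - n_samples * interval
    if first < 0:
        raise SamplingError(
            f"oocyte {seq.oocyte_id}: reference frame {seq.reference_frame} too "
            f"early for {n_samples} samples at stride {interval} "
            f"(needs reference_frame >= {n_samples * interval})"
        )
    indices = sample_indices(seq.reference_frame, n_samples, interval)
    return [seq.frames[i] for i in indices]


def sample_indices(reference_frame: int, n_samples: int,
                   interval: int = DEFAULT_INTERVAL) -> list[int]:
    """The index rule behind :func:`sample_frames`, exposed for bookkeeping."""
    return [reference_frame - k * interval for k in range(n_samples, 0, -1)]


_FRAME_RE = re.compile(r"(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def read_sequence(path: str | Path, manifest_row: dict) -> FrameSequence:
    """Read one oocyte directory of PNG/TIFF frames using its manifest row.

    Frames are ordered by the integer index embedded in the filename.
    """
    path = Path(path)
    entries = []
    for p in path.iterdir():
        m = _FRAME_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise IOError(f"no decodable PNG/TIFF frames in {path}")
    entries.sort()
    frames = []
    for _, p in entries:
        try:
            raw = iio.imread(p)
        except Exception as exc:  # noqa: BLE001 - surface the offending file
            raise IOError(f"cannot decode frame file {p}: {exc}") from exc
        frames.append(to_grayscale(raw))
    row = dict(manifest_row)
    n_declared = row.get("n_frames")
    if n_declared is not None and int(n_declared) != len(frames):
        raise ManifestError(
            f"{path}: manifest declares {n_declared} frames, found {len(frames)}"
        )
    seed = row.get("seed")
    return FrameSequence(
        oocyte_id=str(row["oocyte_id"]),
        label=str(row["label"]),
        frames=frames,
        reference_frame=int(row["reference_frame"]),
        seed=int(seed) if seed not in (None, "") else None,
    )


def read_cohort(root: str | Path, manifest: str | Path | None = None) -> list[FrameSequence]:
    """Read every oocyte listed in a cohort manifest CSV."""
    root = Path(root)
    manifest = Path(manifest) if manifest else root / "manifest.csv"
    sequences = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            sequences.append(read_sequence(root / row["oocyte_id"], row))
    return sequences


def write_sequence(seq: FrameSequence, root: str | Path) -> Path:
    """Write one sequence as zero-padded 8-bit grayscale PNG frames."""
    out = Path(root) / seq.oocyte_id
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{i:04d}.png", frame.astype(np.uint8))
    return out


def write_cohort(sequences: list[FrameSequence], root: str | Path) -> Path:
    """Write per-oocyte frame directories plus the cohort manifest CSV."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for seq in sequences:
            write_sequence(seq, root)
            writer.writerow([seq.oocyte_id, seq.label, seq.n_frames,
                             seq.reference_frame, seq.seed if seq.seed is not None else ""])
    return manifest
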