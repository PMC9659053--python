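"""Local binary pattern (LBP) texture features on a 3x3 neighborhood.

Each interior pixel is compared with its 8 neighbors; the sign pattern of
the differences forms an 8-bit code, and the image-level feature is the
256-bin histogram of codes. With the default threshold convention, bit i
is set when the neighbor intensity is greater than or equal to the center
intensity (ties count as 1, so a constant image codes uniformly to 255).

Neighbors are enumerated clockwise starting from the top-left offset
(-1, -1); neighbor i carries weight 2**i. Any fixed enumeration yields a
permutation of the histogram bins, so the choice is frozen purely for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# clockwise from top-left, as (row offset, column offset)
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

N_NEIGHBORS = 8
N_BINS = 2 ** N_NEIGHBORS


@dataclass(frozen=True)
class LBPConfig:
    """Configuration of the 3x3, 8-neighbor LBP operator.

    Parameters
    ----------
    threshold
        ``"ge"`` (default): bit i = 1 iff neighbor - center >= 0.
        ``"prose"``: the complementary convention, bit i = 1 iff the
        neighbor is *not* greater than the center (i.e. neighbor <= center).
        On integer images the two are bit-complements of each other and
        induce a permutation of histogram bins.
    normalize
        ``"density"`` (default): histogram sums to 1, invariant to ROI
        size. ``"counts"``: raw tallies summing to the number of coded
        interior pixels.
    """

    threshold: str = "ge"
    normalize: str = "density"
    bit_order: tuple[tuple[int, int], ...] = field(default=NEIGHBOR_OFFSETS)

    def __post_init__(self) -> None:
        if self.threshold not in ("ge", "prose"):
            raise ValueError(f"unknown threshold convention: {self.threshold!r}")
        if self.normalize not in ("counts", "density"):
            raise ValueError(f"unknown normalization: {self.normalize!r}")
        if len(self.bit_order) != N_NEIGHBORS or len(set(self.bit_order)) != N_NEIGHBORS:
            raise ValueError("bit_order must list 8 distinct neighbor offsets")


@dataclass(frozen=True)
class LBPHistogram:
    """256-bin LBP code histogram for one frame."""

    bins: np.ndarray
    n_pixels: int
    source_id: tuple[str, int] | None = None


def lbp_code(patch: np.ndarray, config: LBPConfig = LBPConfig()) -> int:
    """LBP code of a single 3x3 patch.

    Returns an integer in [0, 255]; bit i reflects the sign of the
    difference between neighbor i (per ``config.bit_order``) and the
    center pixel.
    """
    patch = np.asarray(patch)
    if patch.shape != (3, 3):
        raise ValueError(f"expected a 3x3 patch, got shape {patch.shape}")
    center = int(patch[1, 1])
    code = 0
    for i, (dr, dc) in enumerate(config.bit_order):
        diff = int(patch[1 + dr, 1 + dc]) - center
        bit = diff >= 0 if config.threshold == "ge" else diff <= 0
        code |= int(bit) << i
    return code


def lbp_code_map(frame: np.ndarray, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Compute the LBP code of every interior pixel of ``frame``.

    The 1-pixel border is excluded (no padding is invented), so an H x W
    frame yields an (H-2) x (W-2) uint8 code map.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.shape[0] < 3 or frame.shape[1] < 3:
        raise ValueError(f"frame must be 2-D and at least 3x3, got shape {frame.shape}")
    f = frame.astype(np.int16, copy=False)
    center = f[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.uint8)
    h, w = frame.shape
    for i, (dr, dc) in enumerate(config.bit_order):
        neigh = f[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
        diff = neigh - center
        bit = diff >= 0 if config.threshold == "ge" else diff <= 0
        codes |= bit.astype(np.uint8) << i
    return codes


def lbp_histogram(
    code_map: np.ndarray,
    config: LBPConfig = LBPConfig(),
    source_id: tuple[str, int] | None = None,
) -> LBPHistogram:
    """Tally a code map into the 256-bin feature vector."""
    code_map = np.asarray(code_map)
    if code_map.size == 0:
        raise ValueError("empty code map: no interior pixels to tally")
    if code_map.min() < 0 or code_map.max() > N_BINS - 1:
        raise ValueError("codes must lie in [0, 255]")
    counts = np.bincount(code_map.ravel().astype(np.int64), minlength=N_BINS)
    n_pixels = int(code_map.size)
    bins = counts.astype(float)
    if config.normalize == "density":
        bins /= n_pixels
    return LBPHistogram(bins=bins, n_pixels=n_pixels, source_id=source_id)


def frame_features(frame: np.ndarray, config: LBPConfig = LBPConfig(),
                   source_id: tuple[str, int] | None = None) -> LBPHistogram:
    """Convenience: code map + histogram in one call."""
    return lbp_histogram(lbp_code_map(frame, config), config, source_id)
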