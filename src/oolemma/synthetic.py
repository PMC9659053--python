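"""Synthetic oocyte-movie generator.

Emulates the statistical structure the rupture-prediction pipeline
assumes: a cohort of short microscope movies, one per oocyte, each
showing a roughly circular cell with a darker zona-pellucida ring inside
a 960x540 frame, its cytoplasm filled with band-limited Gaussian speckle
(filtered white noise). The two outcome classes differ in the mean
correlation length and contrast of that speckle by a controllable
``class_effect``; per-oocyte parameters are drawn from the class
distributions so the oocyte — not the frame — is the independent unit,
matching the grouped cross-validation design. Frames of one movie share
the oocyte's texture field up to a small bounded per-frame jitter
(temporal correlation).

Everything is reproducible: each oocyte's seed is derived
deterministically from the cohort master seed and the oocyte index, and
any single frame can be re-rendered in isolation from its spec.

The parameter ranges are engineering choices meant to look plausible
under a 20x inverted microscope, not estimates of any clinical data;
defaults mirror the cohort geometry the pipeline was designed around
(38 ruptured + 55 nonruptured oocytes, 960x540 8-bit frames, movies of
31 frames with the puncture confirmed on the last frame).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .frame_io import FrameSequence

#: Gray-level standard deviation of the speckle at texture_contrast = 1.
CONTRAST_AMPLITUDE = 60.0

#: Relative weight of the per-frame jitter field inside the texture mix;
#: two frames of one movie differ by at most 2 * JITTER_WEIGHT *
#: CONTRAST_AMPLITUDE * texture_contrast gray levels before clamping.
JITTER_WEIGHT = 0.05


class ConfigurationError(ValueError):
    """Cohort or oocyte geometry that cannot be rendered."""


@dataclass(frozen=True)
class OocyteSpec:
    """Everything needed to render one oocyte's movie deterministically."""

    oocyte_id: str
    label: str
    center: tuple[float, float]      # (x, y) pixels
    radius: float                    # cytoplasm disc radius, pixels
    ring_width: float                # zona-pellucida annulus width, pixels
    texture_scale: float             # speckle correlation length, pixels
    texture_contrast: float          # speckle amplitude in [0, 1]
    n_frames: int
    reference_frame: int
    seed: int
    frame_width: int = 960
    frame_height: int = 540
    base_intensity: float = 128.0    # cytoplasm mean gray level
    background_intensity: float = 190.0
    ring_intensity: float = 90.0

    def __post_init__(self) -> None:
        x, y = self.center
        outer = self.radius + self.ring_width
        if (x - outer < 0 or x + outer > self.frame_width
                or y - outer < 0 or y + outer > self.frame_height):
            raise ConfigurationError(
                f"oocyte {self.oocyte_id}: radius+ring {outer:.1f} px at center "
                f"({x:.1f}, {y:.1f}) exceeds the {self.frame_width}x"
                f"{self.frame_height} frame"
            )
        if not 0 <= self.reference_frame < self.n_frames:
            raise ConfigurationError(
                f"oocyte {self.oocyte_id}: reference_frame {self.reference_frame} "
                f"outside [0, {self.n_frames})"
            )
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ConfigurationError("texture_contrast must lie in [0, 1]")
        if self.texture_scale <= 0:
            raise ConfigurationError("texture_scale must be positive")

    @property
    def max_jitter_delta(self) -> float:
        """Upper bound on |frame_a - frame_b| for two frames of this movie."""
        return 2.0 * JITTER_WEIGHT * CONTRAST_AMPLITUDE * self.texture_contrast


@dataclass(frozen=True)
class CohortConfig:
    """Study-level knobs of the synthetic cohort.

    ``class_effect`` shifts the ruptured class's mean speckle correlation
    length (by 0.5 px per unit) and contrast (by 0.05 per unit) relative
    to the nonruptured class; 0 makes the classes statistically
    identical, and the larger it is the easier the downstream
    classification task becomes.
    """

    n_ruptured: int = 38
    n_nonruptured: int = 55
    frame_width: int = 960
    frame_height: int = 540
    frames_per_movie: int = 31
    class_effect: float = 1.0
    master_seed: int = 0
    base_texture_scale: float = 3.0      # nonruptured mean, pixels
    base_texture_contrast: float = 0.35  # nonruptured mean, [0, 1]
    texture_scale_sd: float = 0.2        # oocyte-to-oocyte spread
    texture_contrast_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_ruptured < 0 or self.n_nonruptured < 0:
            raise ConfigurationError("class counts must be >= 0")
        if self.frames_per_movie < 1:
            raise ConfigurationError("frames_per_movie must be >= 1")
        if self.class_effect < 0:
            raise ConfigurationError("class_effect must be >= 0")


def oocyte_seed(master_seed: int, index: int) -> int:
    """Deterministic per-oocyte seed derived from (master_seed, index)."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31))


def _speckle_field(rng: np.random.Generator, shape: tuple[int, int],
                   scale: float) -> np.ndarray:
    """Standardized band-limited Gaussian speckle with correlation length ``scale``."""
    field = gaussian_filter(rng.standard_normal(shape), sigma=scale)
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    return field


def _geometry_masks(spec: OocyteSpec) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : spec.frame_height, 0 : spec.frame_width]
    r = np.hypot(xx - spec.center[0], yy - spec.center[1])
    interior = r < spec.radius
    ring = (r >= spec.radius) & (r < spec.radius + spec.ring_width)
    return interior, ring


def _render(spec: OocyteSpec, base_field: np.ndarray, frame_index: int,
            masks: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    interior, ring = masks
    shape = (spec.frame_height, spec.frame_width)
    jitter_rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, 1, frame_index))
    )
    jitter = _speckle_field(jitter_rng, shape, spec.texture_scale)
    peak = np.abs(jitter).max()
    if peak > 0:
        jitter = jitter / peak  # exact max-abs normalization -> hard jitter bound
    texture = base_field + JITTER_WEIGHT * jitter
    img = np.full(shape, spec.background_intensity, dtype=float)
    img[ring] = spec.ring_intensity
    img[interior] = (
        spec.base_intensity
        + spec.texture_contrast * CONTRAST_AMPLITUDE * texture[interior]
    )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _base_field(spec: OocyteSpec) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    return _speckle_field(rng, (spec.frame_height, spec.frame_width),
                          spec.texture_scale)


def render_frame(spec: OocyteSpec, frame_index: int) -> np.ndarray:
    """Render one frame of the movie as an 8-bit grayscale raster."""
    if not 0 <= frame_index < spec.n_frames:
        raise ValueError(f"frame_index {frame_index} outside [0, {spec.n_frames})")
    return _render(spec, _base_field(spec), frame_index, _geometry_masks(spec))


def render_sequence(spec: OocyteSpec) -> FrameSequence:
    """Render the whole movie (shares the base texture field across frames)."""
    base = _base_field(spec)
    masks = _geometry_masks(spec)
    frames = [_render(spec, base, i, masks) for i in range(spec.n_frames)]
    return FrameSequence(oocyte_id=spec.oocyte_id, label=spec.label,
                         frames=frames, reference_frame=spec.reference_frame,
                         seed=spec.seed)


def cohort_specs(config: CohortConfig) -> list[OocyteSpec]:
    """Draw per-oocyte parameters from the two class distributions."""
    specs: list[OocyteSpec] = []
    labels = ["ruptured"] * config.n_ruptured + ["nonruptured"] * config.n_nonruptured
    min_dim = min(config.frame_width, config.frame_height)
    for index, label in enumerate(labels):
        seed = oocyte_seed(config.master_seed, index)
        rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
        if label == "ruptured":
            scale_mean = config.base_texture_scale + 0.5 * config.class_effect
            contrast_mean = config.base_texture_contrast + 0.05 * config.class_effect
        else:
            scale_mean = config.base_texture_scale
            contrast_mean = config.base_texture_contrast
        texture_scale = max(0.5, rng.normal(scale_mean, config.texture_scale_sd))
        texture_contrast = float(
            np.clip(rng.normal(contrast_mean, config.texture_contrast_sd), 0.0, 1.0)
        )
        radius = min_dim * rng.uniform(0.28, 0.32)
        ring_width = max(2.0, 0.022 * min_dim)
        jx, jy = rng.uniform(-0.02 * min_dim, 0.02 * min_dim, size=2)
        center = (config.frame_width / 2 + jx, config.frame_height / 2 + jy)
        specs.append(OocyteSpec(
            oocyte_id=f"oo_{index:03d}",
            label=label,
            center=center,
            radius=float(radius),
            ring_width=float(ring_width),
            texture_scale=float(texture_scale),
            texture_contrast=texture_contrast,
            n_frames=config.frames_per_movie,
            reference_frame=config.frames_per_movie - 1,
            seed=seed,
            frame_width=config.frame_width,
            frame_height=config.frame_height,
        ))
    return specs


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[FrameSequence]:
    """Generate the full labeled cohort of synthetic movies."""
    return [render_sequence(spec) for spec in cohort_specs(config)]
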