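"""Label-preserving geometric augmentation of training slices.

One augmented copy applies a single random affine transform composed of
translation, rotation, zoom and shear, plus optional flips, with parameters
drawn uniformly within the configured ranges. Ranges default to mild values
(<=10% translation, <=15 deg rotation, 0.9-1.1 zoom, <=10 deg shear,
horizontal flip only) so an artifact-free slice cannot be turned into an
artifact mimic; out-of-frame pixels are filled with the nearest edge value
to avoid introducing sharp borders that resemble artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_slicing import SliceSample

__all__ = ["AugmentConfig", "TransformParams", "draw_transform",
           "apply_transform", "augment_slice", "build_augmented_set"]


@dataclass(frozen=True)
class AugmentConfig:
    max_translate: float = 0.10      # fraction of width/height
    max_rotation: float = 15.0       # degrees
    zoom_range: tuple[float, float] = (0.9, 1.1)
    max_shear: float = 10.0          # degrees
    flip_horizontal: bool = True
    flip_vertical: bool = False
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.max_translate <= 1:
            raise ValueError("max_translate must lie in [0, 1]")
        if not 0 <= self.max_rotation <= 180:
            raise ValueError("max_rotation must lie in [0, 180]")
        if not 0 <= self.max_shear <= 180:
            raise ValueError("max_shear must lie in [0, 180]")
        if self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("zoom_range must be (min, max) with min <= max")
        if self.zoom_range[0] <= 0:
            raise ValueError("zoom factors must be positive")
        object.__setattr__(self, "zoom_range", tuple(self.zoom_range))

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        """Build from a YAML/JSON mapping (lists become tuples)."""
        return cls(**d)


@dataclass(frozen=True)
class TransformParams:
    """One concrete draw from an :class:`AugmentConfig`."""

    translate: tuple[float, float]   # pixels (rows, cols)
    rotation_deg: float
    zoom: float
    shear_deg: float
    flip_h: bool
    flip_v: bool
    fill_mode: str = "nearest"


def draw_transform(cfg: AugmentConfig, shape: tuple[int, int],
                   draw_seed: int) -> TransformParams:
    """Draw transform parameters uniformly within the config ranges."""
    rng = np.random.default_rng(draw_seed)
    ty = rng.uniform(-cfg.max_translate, cfg.max_translate) * shape[0]
    tx = rng.uniform(-cfg.max_translate, cfg.max_translate) * shape[1]
    rot = rng.uniform(-cfg.max_rotation, cfg.max_rotation)
    zoom = rng.uniform(*cfg.zoom_range)
    shear = rng.uniform(-cfg.max_shear, cfg.max_shear)
    flip_h = cfg.flip_horizontal and bool(rng.integers(0, 2))
    flip_v = cfg.flip_vertical and bool(rng.integers(0, 2))
    return TransformParams((ty, tx), rot, zoom, shear, flip_h, flip_v, cfg.fill_mode)


def _affine_matrix(p: TransformParams) -> np.ndarray:
    """2x2 linear part of the output->input mapping (about the image center)."""
    th = np.deg2rad(p.rotation_deg)
    sh = np.deg2rad(p.shear_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, -np.sin(sh)], [0.0, np.cos(sh)]])
    zoom = np.eye(2) * p.zoom
    fwd = rot @ shear @ zoom  # input -> output
    return np.linalg.inv(fwd)


def apply_transform(image: np.ndarray, p: TransformParams) -> np.ndarray:
    """Apply one concrete transform; identity parameters return the input exactly."""
    out = np.asarray(image, dtype=np.float64)
    identity_affine = (
        p.rotation_deg == 0 and p.zoom == 1 and p.shear_deg == 0
        and p.translate == (0.0, 0.0)
    )
    if not identity_affine:
        mat = _affine_matrix(p)
        center = (np.array(out.shape) - 1) / 2.0
        offset = center - mat @ (center + np.array(p.translate))
        out = ndimage.affine_transform(out, mat, offset=offset, order=1,
                                       mode=p.fill_mode)
    if p.flip_h:
        out = out[:, ::-1]
    if p.flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_slice(s: SliceSample, cfg: AugmentConfig, draw_seed: int) -> SliceSample:
    """One randomly transformed copy of a slice; the label travels unchanged.

    Deterministic given ``draw_seed``; all-zero ranges with flips off give
    the identity transform.
    """
    params = draw_transform(cfg, s.image.shape, draw_seed)
    return replace(s, image=apply_transform(s.image, params))


def build_augmented_set(
    samples: list[SliceSample], cfg: AugmentConfig, multiplier: int, seed: int
) -> list[SliceSample]:
    """Originals plus ``multiplier - 1`` augmented copies of each sample.

    The output has exactly ``multiplier * len(samples)`` slices and the class
    balance of the input, since every copy keeps its source's label.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    if multiplier == 1:
        return list(samples)
    rng = np.random.default_rng(seed)
    out = list(samples)
    for _ in range(multiplier - 1):
        for s in samples:
            out.append(augment_slice(s, cfg, int(rng.integers(0, 2**31 - 1))))
    return out
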