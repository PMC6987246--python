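"""Reading 4D diffusion volumes and extracting the axial/sagittal slice sets.

A diffusion MRI acquisition is a stack of 3D gradient volumes. Quality
inspection works on 2D slices: axial slices (cut along the inferior-superior
axis) and sagittal slices (cut along the left-right axis). Peripheral slices
that contain mostly background are excluded before any classification:

* sagittal — slices entirely outside the brain plus a margin (default 5) of
  slices counted inward from the left and right brain edges;
* axial — slices inferior to the brain/cerebellum, slices superior to the
  skull, and a margin (default 5) of slices counted down from the superior
  surface.

Brain extent is located with an intensity-threshold bounding box on the
mean-over-gradients image; the threshold is a fraction of the robust
(99th-percentile) maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DwiVolume",
    "BrainExtent",
    "SliceSample",
    "LoadError",
    "ExtentError",
    "load_volume",
    "save_volume",
    "compute_brain_extent",
    "extract_sagittal_slices",
    "extract_axial_slices",
    "normalize_slice",
    "load_labels",
    "attach_labels",
]

View = Literal["axial", "sagittal"]

LABEL_ARTIFACTUAL = "artifactual"
LABEL_ARTIFACT_FREE = "artifact_free"


class LoadError(ValueError):
    """Raised when a volume cannot be read or fails basic validation."""


class ExtentError(ValueError):
    """Raised when no brain-like region can be located in a volume."""


@dataclass
class DwiVolume:
    """A 4D diffusion image: three spatial axes plus a gradient axis.

    ``axis_labels`` maps each array axis (0..2) to the anatomical axis it
    runs along: ``"LR"`` (left-right), ``"AP"`` (anterior-posterior) or
    ``"IS"`` (inferior-superior), derived from the affine's dominant
    directions.
    """

    data: np.ndarray
    affine: np.ndarray
    axis_labels: tuple[str, str, str] = ("LR", "AP", "IS")
    volume_id: str = "volume"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise LoadError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if min(self.data.shape[:3]) < 16:
            raise LoadError(
                f"spatial dimensions must be >= 16, got {self.data.shape[:3]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise LoadError("volume contains non-finite intensities")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise LoadError("affine must be 4x4")
        if sorted(self.axis_labels) != ["AP", "IS", "LR"]:
            raise LoadError(f"invalid axis labels {self.axis_labels}")

    # -- anatomical-axis helpers ------------------------------------------
    def axis_of(self, label: str) -> int:
        """Array axis running along the given anatomical axis ('LR'|'AP'|'IS')."""
        return self.axis_labels.index(label)

    @property
    def n_gradients(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def gradient_volume(self, g: int) -> np.ndarray:
        return self.data[..., g]


@dataclass(frozen=True)
class BrainExtent:
    """Inclusive [lo, hi] index range of the detected head region per anatomical axis."""

    lr: tuple[int, int]
    ap: tuple[int, int]
    is_: tuple[int, int]

    def range_of(self, label: str) -> tuple[int, int]:
        return {"LR": self.lr, "AP": self.ap, "IS": self.is_}[label]


@dataclass
class SliceSample:
    """One 2D slice cut from a gradient volume, tagged with its provenance."""

    image: np.ndarray
    view: View
    volume_id: str
    gradient_index: int
    slice_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError("slice image must be 2D")
        if self.view not in ("axial", "sagittal"):
            raise ValueError(f"view must be axial|sagittal, got {self.view!r}")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.volume_id, self.view, self.gradient_index, self.slice_index)


_AXCODE_TO_LABEL = {
    "L": "LR", "R": "LR",
    "A": "AP", "P": "AP",
    "I": "IS", "S": "IS",
}


def _axis_labels_from_affine(affine: np.ndarray) -> tuple[str, str, str]:
    codes = nib.orientations.aff2axcodes(affine)
    labels = tuple(_AXCODE_TO_LABEL[c] for c in codes)
    if sorted(labels) != ["AP", "IS", "LR"]:
        raise LoadError(f"affine does not map axes to distinct anatomical axes: {codes}")
    return labels  # type: ignore[return-value]


def load_volume(path: str | Path) -> DwiVolume:
    """Read a NIfTI file into a :class:`DwiVolume`.

    3D images are promoted to 4D with a single gradient. The anatomical
    axis of each array axis is derived from the affine.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise LoadError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise LoadError(f"{path}: expected 3 or 4 dimensions, got {data.ndim}")
    if not np.all(np.isfinite(data)):
        raise LoadError(f"{path}: non-finite intensities")
    if data.min() < 0:
        raise LoadError(f"{path}: negative magnitudes in a magnitude image")
    affine = img.affine
    return DwiVolume(
        data=data,
        affine=affine,
        axis_labels=_axis_labels_from_affine(affine),
        volume_id=path.name.removesuffix(".gz").removesuffix(".nii"),
    )


def save_volume(vol: DwiVolume, path: str | Path) -> Path:
    """Write a :class:`DwiVolume` to NIfTI-1, preserving data and affine."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))
    return path


def compute_brain_extent(vol: DwiVolume, threshold_fraction: float = 0.1) -> BrainExtent:
    """Bounding box of voxels brighter than ``threshold_fraction`` x robust max.

    The mask is computed on the mean over gradients; the robust maximum is
    the 99th percentile, which ignores isolated hot voxels.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    mean_img = vol.data.mean(axis=3)
    robust_max = np.percentile(mean_img, 99)
    mask = mean_img > threshold_fraction * robust_max
    if not mask.any():
        raise ExtentError(
            f"no voxel exceeds {threshold_fraction} x robust max in {vol.volume_id}"
        )
    ranges: dict[str, tuple[int, int]] = {}
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = mask.any(axis=other)
        idx = np.flatnonzero(profile)
        ranges[vol.axis_labels[axis]] = (int(idx[0]), int(idx[-1]))
    return BrainExtent(lr=ranges["LR"], ap=ranges["AP"], is_=ranges["IS"])


def _take_slice(vol: DwiVolume, axis: int, index: int, g: int) -> np.ndarray:
    return np.take(vol.gradient_volume(g), index, axis=axis)


def retained_sagittal_indices(extent: BrainExtent, margin: int = 5) -> list[int]:
    """Sagittal indices kept after excluding ``margin`` slices inward from each brain edge."""
    lo, hi = extent.lr
    return list(range(lo + margin, hi - margin + 1))


def retained_axial_indices(extent: BrainExtent, top_margin: int = 5) -> list[int]:
    """Axial indices kept: from the inferior brain boundary up to ``top_margin``
    slices below the superior surface."""
    lo, hi = extent.is_
    return list(range(lo, hi - top_margin + 1))


def extract_sagittal_slices(
    vol: DwiVolume, extent: BrainExtent, margin: int = 5
) -> list[SliceSample]:
    """Cut the retained sagittal slices of every gradient volume.

    Slices entirely outside the brain are excluded by construction (the
    index range is clipped to the brain extent); a further ``margin``
    slices are dropped inward from the left and right brain edges. An empty
    list is a valid result for a brain narrower than ``2 * margin``.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    axis = vol.axis_of("LR")
    samples = []
    for g in range(vol.n_gradients):
        for i in retained_sagittal_indices(extent, margin):
            samples.append(
                SliceSample(
                    image=_take_slice(vol, axis, i, g),
                    view="sagittal",
                    volume_id=vol.volume_id,
                    gradient_index=g,
                    slice_index=i,
                )
            )
    return samples


def extract_axial_slices(
    vol: DwiVolume, extent: BrainExtent, top_margin: int = 5
) -> list[SliceSample]:
    """Cut the retained axial slices of every gradient volume.

    Retained indices run from the inferior boundary of the head region (below
    it lies the neck/background, excluded) up to ``top_margin`` slices below
    the superior surface.
    """
    if top_margin < 0:
        raise ValueError("top_margin must be >= 0")
    axis = vol.axis_of("IS")
    samples = []
    for g in range(vol.n_gradients):
        for i in retained_axial_indices(extent, top_margin):
            samples.append(
                SliceSample(
                    image=_take_slice(vol, axis, i, g),
                    view="axial",
                    volume_id=vol.volume_id,
                    gradient_index=g,
                    slice_index=i,
                )
            )
    return samples


def normalize_slice(s: SliceSample) -> SliceSample:
    """Zero-center and scale to unit variance (population std).

    Constant slices map to all zeros instead of dividing by zero.
    """
    img = s.image
    std = img.std()
    if std == 0:
        norm = np.zeros_like(img)
    else:
        norm = (img - img.mean()) / std
    return replace(s, image=norm)


# -- label sidecar ---------------------------------------------------------

def load_labels(path: str | Path) -> pd.DataFrame:
    """Read a label sidecar CSV (volume_id, view, gradient_index, slice_index, label)."""
    df = pd.read_csv(path, dtype={"volume_id": str})
    required = {"volume_id", "view", "gradient_index", "slice_index", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label file missing columns: {sorted(missing)}")
    return df


def attach_labels(samples: list[SliceSample], labels: pd.DataFrame) -> list[SliceSample]:
    """Attach labels from a sidecar table to extracted slices (in place, returned)."""
    lut = {
        (str(r.volume_id), r.view, int(r.gradient_index), int(r.slice_index)): r.label
        for r in labels.itertuples()
    }
    for s in samples:
        s.label = lut.get(s.key, s.label)
    return samples
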