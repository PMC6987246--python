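"""Synthetic diffusion-MRI volumes with physics-based artifact injection.

Real labeled QC corpora are scarce, so this module generates labeled training
and test data from first principles: an ellipsoid head phantom (tissue
contrast plus a bright fat rim), per-gradient diffusion attenuation, Rician
magnitude noise, and six artifact phenotypes injected through the k-space or
image-domain mechanism that produces each one on a scanner:

=====================  ====================================================
ghosting               even/odd phase-encode-line modulation in k-space ->
                       half-FOV ghost replica along the phase-encode axis
herringbone            conjugate spike pair added to k-space -> plane-wave
                       corduroy stripes across the slice
chemical_shift         fat-rim component translated along the
                       frequency-encode axis and re-added
susceptibility         smooth Gaussian-bump displacement field along the
                       phase-encode axis (local geometric distortion)
motion_dropout         whole axial slices attenuated -> dark horizontal
                       bands in every sagittal slice
multiband_interleave   periodic through-slice intensity modulation ->
                       venetian-blind banding in the sagittal view
=====================  ====================================================

The first four manifest in (and are labeled on) axial slices; the last two
manifest across sagittal slices. Every injector is the exact identity at
zero severity and touches only its affected (slice, gradient) set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_slicing import (
    LABEL_ARTIFACT_FREE,
    LABEL_ARTIFACTUAL,
    BrainExtent,
    DwiVolume,
    compute_brain_extent,
    load_volume,
    retained_axial_indices,
    retained_sagittal_indices,
    save_volume,
)

__all__ = [
    "PhantomSpec",
    "ArtifactSpec",
    "LabeledDataset",
    "AXIAL_ARTIFACTS",
    "SAGITTAL_ARTIFACTS",
    "ARTIFACT_TYPES",
    "SEVERITY_RANGES",
    "make_phantom_volume",
    "phantom_masks",
    "add_rician_noise",
    "inject_ghosting",
    "inject_herringbone",
    "inject_chemical_shift",
    "inject_susceptibility",
    "inject_motion_dropout",
    "inject_multiband_interleave",
    "apply_artifact",
    "sample_artifact_spec",
    "generate_dataset",
]

AXIAL_ARTIFACTS = ("ghosting", "herringbone", "chemical_shift", "susceptibility")
SAGITTAL_ARTIFACTS = ("motion_dropout", "multiband_interleave")
ARTIFACT_TYPES = AXIAL_ARTIFACTS + SAGITTAL_ARTIFACTS

#: severity parameter ranges used when the dataset generator randomizes
#: artifact strength; chosen so every phenotype is visible without saturating
#: the image (ghost replica 10-50% of object intensity, spikes 2-10x the
#: 95th-percentile k-space magnitude — a reference above the noise floor, so
#: the stripes actually show — rim displaced 2-5 px, warps of a few pixels,
#: slice dropout 40-100%, interleave modulation 20-60%).
SEVERITY_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "ghosting": {"intensity": (0.1, 0.5)},
    "herringbone": {"amplitude_factor": (2.0, 10.0)},
    "chemical_shift": {"shift_px": (2, 5), "rim_intensity": (0.3, 0.8)},
    "susceptibility": {"max_displacement_px": (2.0, 6.0), "sigma_px": (4.0, 8.0)},
    "motion_dropout": {"attenuation": (0.4, 1.0)},
    "multiband_interleave": {"modulation": (0.2, 0.6), "period": (3, 6)},
}


class SpecError(ValueError):
    """Raised for degenerate phantom or artifact specifications."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in fractional grid coordinates."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head phantom.

    Geometry is expressed as fractions of the grid so the same spec scales
    to any resolution. The default anatomy is a brain-like ellipsoid with a
    deep white-matter blob and a bright CSF-like ventricle, wrapped in a
    thin high-intensity fat rim. Gradient 0 plays the role of the
    unattenuated b=0 image; diffusion-weighted gradients attenuate tissue
    signal by a random factor drawn from ``attenuation_range``.

    Two realism terms keep the phantom from being pathologically clean:
    ``texture_amplitude`` modulates intra-brain intensity with a smooth
    correlated random field (a stand-in for gyral/parenchymal texture) and
    ``bias_amplitude`` applies a very smooth multiplicative field over the
    whole head (a stand-in for coil-sensitivity inhomogeneity).
    """

    shape: tuple[int, int, int] = (64, 64, 36)
    n_gradients: int = 4
    tissues: tuple[Ellipsoid, ...] = (
        Ellipsoid((0.5, 0.5, 0.5), (0.36, 0.44, 0.40), 0.70),   # brain parenchyma
        Ellipsoid((0.5, 0.42, 0.55), (0.18, 0.22, 0.20), 0.50),  # deep WM
        Ellipsoid((0.5, 0.58, 0.55), (0.08, 0.10, 0.12), 1.00),  # CSF ventricle
    )
    rim_thickness: float = 2.0
    rim_intensity: float = 1.2
    attenuation_range: tuple[float, float] = (0.55, 0.80)
    noise_sigma: float = 0.03
    texture_amplitude: float = 0.10
    bias_amplitude: float = 0.10
    geometry_jitter: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape[:2]) < 32:
            raise SpecError("in-plane dimensions must be >= 32")
        if any(s <= 0 for e in self.tissues for s in e.semi_axes):
            raise SpecError("ellipsoid semi-axes must be positive")
        if any(e.intensity < 0 for e in self.tissues):
            raise SpecError("tissue intensities must be >= 0")
        if self.rim_thickness < 1:
            raise SpecError("rim thickness must be >= 1 voxel")
        if self.noise_sigma < 0:
            raise SpecError("noise sigma must be >= 0")


def _ellipsoid_field(shape: tuple[int, int, int], e: Ellipsoid,
                     scale: np.ndarray) -> np.ndarray:
    """Normalized squared radius of every voxel w.r.t. the (jittered) ellipsoid."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = np.zeros(shape)
    for g, c, a, n, s in zip(grids, e.center, e.semi_axes, shape, scale):
        r2 = r2 + ((g - c * n) / (a * n * s)) ** 2
    return r2


def phantom_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean tissue masks of the phantom: head, rim and one per tissue.

    Deterministic given ``spec.seed`` (the seed drives a small geometry
    jitter so different volumes are not pixel-identical anatomies).
    """
    rng = np.random.default_rng(spec.seed)
    jitter = 1.0 + spec.geometry_jitter * rng.uniform(-1, 1, size=3)
    outer = spec.tissues[0]
    brain_r2 = _ellipsoid_field(spec.shape, outer, jitter)
    rim_frac = spec.rim_thickness / (outer.semi_axes[0] * spec.shape[0])
    rim_outer_r2 = _ellipsoid_field(
        spec.shape,
        replace(outer, semi_axes=tuple(a * (1 + rim_frac) for a in outer.semi_axes)),
        jitter,
    )
    masks = {"brain": brain_r2 <= 1.0, "rim": (rim_outer_r2 <= 1.0) & (brain_r2 > 1.0)}
    for i, e in enumerate(spec.tissues[1:], start=1):
        masks[f"tissue_{i}"] = (_ellipsoid_field(spec.shape, e, jitter) <= 1.0) & masks["brain"]
    masks["head"] = masks["brain"] | masks["rim"]
    return masks


def render_tissue_image(spec: PhantomSpec) -> np.ndarray:
    """Noiseless 3D tissue image (b=0 contrast) of the phantom."""
    masks = phantom_masks(spec)
    img = np.zeros(spec.shape)
    img[masks["brain"]] = spec.tissues[0].intensity
    for i, e in enumerate(spec.tissues[1:], start=1):
        img[masks[f"tissue_{i}"]] = e.intensity
    img[masks["rim"]] = spec.rim_intensity
    return img


def add_rician_noise(image: np.ndarray, sigma: float,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Rician magnitude noise: ``|(image + n1) + i n2|`` with iid Gaussian n1, n2.

    Background (zero-signal) voxels become Rayleigh distributed with mean
    ``sigma * sqrt(pi/2)``. ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n1 = rng.normal(0.0, sigma, image.shape)
    n2 = rng.normal(0.0, sigma, image.shape)
    return np.hypot(image + n1, n2)


def make_phantom_volume(spec: PhantomSpec, volume_id: str = "phantom") -> DwiVolume:
    """Render the phantom as a 4D :class:`DwiVolume` (identity RAS affine).

    Gradient 0 is the unattenuated image; the remaining gradients attenuate
    tissue (not the fat rim) by factors drawn from ``attenuation_range``.
    Rician noise is added independently per gradient. Deterministic given
    ``spec.seed``.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed + 1)
    masks = phantom_masks(spec)
    tissue = render_tissue_image(spec)
    rim_part = np.where(masks["rim"], tissue, 0.0)
    brain_part = tissue - rim_part
    if spec.texture_amplitude > 0:
        texture = gaussian_filter(rng.standard_normal(spec.shape), sigma=2.0)
        texture /= max(texture.std(), 1e-12)
        brain_part = brain_part * (1.0 + spec.texture_amplitude * texture)
    if spec.bias_amplitude > 0:
        bias = gaussian_filter(rng.standard_normal(spec.shape),
                               sigma=min(spec.shape) / 3.0)
        bias /= max(bias.std(), 1e-12)
        bias_field = 1.0 + spec.bias_amplitude * bias
    else:
        bias_field = 1.0
    attenuations = np.concatenate(
        [[1.0], rng.uniform(*spec.attenuation_range, size=max(spec.n_gradients - 1, 0))]
    )[: spec.n_gradients]
    data = np.empty(spec.shape + (spec.n_gradients,))
    for g in range(spec.n_gradients):
        clean = (brain_part * attenuations[g] + rim_part) * bias_field
        data[..., g] = add_rician_noise(np.clip(clean, 0.0, None),
                                        spec.noise_sigma, rng)
    return DwiVolume(data=data, affine=np.eye(4), volume_id=volume_id)


# ---------------------------------------------------------------------------
# artifact injectors
# ---------------------------------------------------------------------------

def _axial_plane_info(vol: DwiVolume, axis_label: str) -> tuple[int, list[int], int]:
    """IS array axis, in-plane array axes, and the in-plane position of axis_label."""
    is_ax = vol.axis_of("IS")
    in_plane = [a for a in range(3) if a != is_ax]
    pos = in_plane.index(vol.axis_of(axis_label))
    return is_ax, in_plane, pos


def _plane_slicer(is_ax: int, z: int, g: int) -> tuple:
    sl: list = [slice(None)] * 4
    sl[is_ax] = z
    sl[3] = g
    return tuple(sl)


def _check_affected(vol: DwiVolume, slices, gradients) -> tuple[list[int], list[int]]:
    is_ax = vol.axis_of("IS")
    nz = vol.data.shape[is_ax]
    slices = [int(z) for z in slices]
    gradients = [int(g) for g in gradients]
    if not slices or not gradients:
        raise ValueError("affected slice and gradient sets must be non-empty")
    if any(z < 0 or z >= nz for z in slices):
        raise ValueError(f"affected slice index out of range 0..{nz - 1}")
    if any(g < 0 or g >= vol.n_gradients for g in gradients):
        raise ValueError("affected gradient index out of range")
    return slices, gradients


def inject_ghosting(
    vol: DwiVolume,
    intensity: float,
    affected_slices,
    affected_gradients,
    pe_axis: str = "AP",
) -> DwiVolume:
    """Nyquist (N/2) ghost: even/odd phase-encode k-space lines scaled by (1 +/- alpha).

    Modulating alternate lines by ``1 + alpha * (-1)^k`` superimposes a
    replica of the object shifted by half the field of view along the
    phase-encode axis, with relative intensity ``alpha``.
    """
    if not 0 <= intensity <= 1:
        raise ValueError("ghost intensity must lie in [0, 1]")
    if pe_axis not in ("LR", "AP"):
        raise ValueError("phase-encode axis must be in the axial plane (LR or AP)")
    out = replace(vol, data=vol.data.copy())
    if intensity == 0:
        return out
    slices, gradients = _check_affected(vol, affected_slices, affected_gradients)
    is_ax, in_plane, pe_pos = _axial_plane_info(vol, pe_axis)
    for g in gradients:
        for z in slices:
            sl = _plane_slicer(is_ax, z, g)
            plane = out.data[sl]
            kspace = np.fft.fft2(plane)
            n_pe = plane.shape[pe_pos]
            mod = 1.0 + intensity * (-1.0) ** np.arange(n_pe)
            mod = mod.reshape([-1, 1] if pe_pos == 0 else [1, -1])
            out.data[sl] = np.fft.ifft2(kspace * mod).real
    return out


def inject_herringbone(
    vol: DwiVolume,
    amplitude: float,
    k_loc: tuple[int, int],
    affected_slices,
    affected_gradients,
) -> DwiVolume:
    """Herringbone/corduroy stripes: a conjugate spike pair added to k-space.

    ``k_loc`` is the (row, col) FFT index of the spike within the axial
    plane; its conjugate partner at ``-k_loc (mod N)`` receives the same real
    amplitude, so the image-domain perturbation is a single cosine plane
    wave across the affected slices.
    """
    if amplitude < 0:
        raise ValueError("spike amplitude must be >= 0")
    out = replace(vol, data=vol.data.copy())
    if amplitude == 0:
        return out
    slices, gradients = _check_affected(vol, affected_slices, affected_gradients)
    is_ax, in_plane, _ = _axial_plane_info(vol, "AP")
    shape2d = tuple(vol.data.shape[a] for a in in_plane)
    k0 = (int(k_loc[0]) % shape2d[0], int(k_loc[1]) % shape2d[1])
    if k0 == (0, 0):
        raise ValueError("spike location must not be the DC component")
    if not (0 <= k_loc[0] < shape2d[0] and 0 <= k_loc[1] < shape2d[1]):
        raise ValueError(f"k_loc {k_loc} outside the {shape2d} k-space grid")
    k0_conj = ((-k0[0]) % shape2d[0], (-k0[1]) % shape2d[1])
    for g in gradients:
        for z in slices:
            sl = _plane_slicer(is_ax, z, g)
            kspace = np.fft.fft2(out.data[sl])
            kspace[k0] += amplitude
            if k0_conj != k0:
                kspace[k0_conj] += amplitude
            out.data[sl] = np.fft.ifft2(kspace).real
    return out


def inject_chemical_shift(
    vol: DwiVolume,
    rim_mask: np.ndarray,
    shift_px: int,
    rim_intensity: float,
    affected_slices,
    affected_gradients,
    freq_axis: str = "LR",
) -> DwiVolume:
    """Chemical-shift artifact: the fat-rim component displaced along the
    frequency-encode axis and re-added with weight ``rim_intensity``.

    Produces the classic bright/dark band pair at the rim edge. The rim
    component is taken from ``rim_mask`` (the phantom's fat-rim support).
    """
    shift_px = int(shift_px)
    if abs(shift_px) < 1:
        raise ValueError("chemical shift requires |shift_px| >= 1")
    if rim_intensity < 0:
        raise ValueError("rim_intensity must be >= 0")
    if freq_axis not in ("LR", "AP"):
        raise ValueError("frequency-encode axis must be in the axial plane")
    if rim_mask.shape != vol.data.shape[:3]:
        raise ValueError("rim_mask shape must match the volume's spatial grid")
    is_ax, in_plane, freq_pos = _axial_plane_info(vol, freq_axis)
    n_freq = vol.data.shape[in_plane[freq_pos]]
    if abs(shift_px) > n_freq // 4:
        raise ValueError(
            f"shift of {shift_px} px exceeds FOV/4 ({n_freq // 4} px): unphysical"
        )
    out = replace(vol, data=vol.data.copy())
    if rim_intensity == 0:
        return out
    slices, gradients = _check_affected(vol, affected_slices, affected_gradients)
    for g in gradients:
        for z in slices:
            sl = _plane_slicer(is_ax, z, g)
            mask_plane = np.take(rim_mask, z, axis=is_ax)
            rim_comp = np.where(mask_plane, out.data[sl], 0.0)
            out.data[sl] = out.data[sl] + rim_intensity * np.roll(
                rim_comp, shift_px, axis=freq_pos
            )
    return out


def inject_susceptibility(
    vol: DwiVolume,
    focus: tuple[float, float],
    max_displacement_px: float,
    sigma_px: float,
    affected_slices,
    affected_gradients,
    pe_axis: str = "AP",
) -> DwiVolume:
    """Susceptibility-like local distortion: a smooth Gaussian-bump
    displacement field along the phase-encode axis centered at ``focus``.

    ``focus`` is an in-plane (row, col) point; displacement amplitude decays
    as ``exp(-r^2 / (2 sigma_px^2))`` so voxels beyond a few sigma are
    untouched. Linear interpolation, edge-clamped.
    """
    from scipy.ndimage import map_coordinates

    if max_displacement_px < 0:
        raise ValueError("max_displacement_px must be >= 0")
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    out = replace(vol, data=vol.data.copy())
    if max_displacement_px == 0:
        return out
    slices, gradients = _check_affected(vol, affected_slices, affected_gradients)
    is_ax, in_plane, pe_pos = _axial_plane_info(vol, pe_axis)
    shape2d = tuple(vol.data.shape[a] for a in in_plane)
    rows, cols = np.meshgrid(
        np.arange(shape2d[0], dtype=float),
        np.arange(shape2d[1], dtype=float),
        indexing="ij",
    )
    r2 = (rows - focus[0]) ** 2 + (cols - focus[1]) ** 2
    disp = max_displacement_px * np.exp(-r2 / (2.0 * sigma_px**2))
    coords = [rows.copy(), cols.copy()]
    coords[pe_pos] -= disp
    for g in gradients:
        for z in slices:
            sl = _plane_slicer(is_ax, z, g)
            out.data[sl] = map_coordinates(out.data[sl], coords, order=1, mode="nearest")
    return out


def susceptibility_displacement_field(
    shape2d: tuple[int, int], focus: tuple[float, float],
    max_displacement_px: float, sigma_px: float,
) -> np.ndarray:
    """The scalar displacement field applied by :func:`inject_susceptibility`."""
    rows, cols = np.meshgrid(
        np.arange(shape2d[0], dtype=float), np.arange(shape2d[1], dtype=float),
        indexing="ij",
    )
    r2 = (rows - focus[0]) ** 2 + (cols - focus[1]) ** 2
    return max_displacement_px * np.exp(-r2 / (2.0 * sigma_px**2))


def inject_motion_dropout(
    vol: DwiVolume,
    attenuation: float,
    affected_axial_slices,
    affected_gradients,
) -> DwiVolume:
    """Motion-induced signal dropout: whole axial slices scaled by (1 - attenuation).

    Appears as dark horizontal bands crossing every sagittal slice of the
    affected gradient volumes — the phenotype labeled in the sagittal view.
    """
    if not 0 <= attenuation <= 1:
        raise ValueError("attenuation must lie in [0, 1]")
    out = replace(vol, data=vol.data.copy())
    if attenuation == 0:
        return out
    slices, gradients = _check_affected(vol, affected_axial_slices, affected_gradients)
    is_ax = vol.axis_of("IS")
    for g in gradients:
        for z in slices:
            sl = _plane_slicer(is_ax, z, g)
            out.data[sl] = out.data[sl] * (1.0 - attenuation)
    return out


def inject_multiband_interleave(
    vol: DwiVolume,
    period: int,
    modulation: float,
    affected_gradients,
    phase: int = 0,
) -> DwiVolume:
    """Multiband/interleave banding: every ``period``-th axial slice attenuated.

    Slice z is scaled by ``1 - modulation`` when ``(z - phase) mod period == 0``,
    giving the periodic venetian-blind pattern in the sagittal view.
    """
    if period < 2:
        raise ValueError("period must be >= 2")
    if not 0 <= modulation <= 1:
        raise ValueError("modulation must lie in [0, 1]")
    out = replace(vol, data=vol.data.copy())
    if modulation == 0:
        return out
    is_ax = vol.axis_of("IS")
    nz = vol.data.shape[is_ax]
    affected_z = [z for z in range(nz) if (z - phase) % period == 0]
    slices, gradients = _check_affected(vol, affected_z, affected_gradients)
    for g in gradients:
        for z in slices:
            sl = _plane_slicer(is_ax, z, g)
            out.data[sl] = out.data[sl] * (1.0 - modulation)
    return out


# ---------------------------------------------------------------------------
# labeled-dataset generation
# ---------------------------------------------------------------------------

@dataclass
class ArtifactSpec:
    """The ground-truth record of one injected artifact.

    ``params`` holds the severity parameters of the injector; the label
    applies in the view where the artifact class manifests (axial for
    ghosting/herringbone/chemical_shift/susceptibility, sagittal for
    motion_dropout/multiband_interleave).
    """

    artifact_type: str
    params: dict
    affected_slices: tuple[int, ...]
    affected_gradients: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.artifact_type not in ARTIFACT_TYPES:
            raise SpecError(f"unknown artifact type {self.artifact_type!r}")
        if not self.affected_gradients:
            raise SpecError("affected gradient set must be non-empty")
        if self.artifact_type != "multiband_interleave" and not self.affected_slices:
            raise SpecError("affected slice set must be non-empty")

    @property
    def view(self) -> str:
        return "axial" if self.artifact_type in AXIAL_ARTIFACTS else "sagittal"


def apply_artifact(
    vol: DwiVolume, spec: ArtifactSpec, rim_mask: np.ndarray | None = None
) -> DwiVolume:
    """Dispatch an :class:`ArtifactSpec` to the matching injector."""
    t, p = spec.artifact_type, spec.params
    if t == "ghosting":
        return inject_ghosting(vol, p["intensity"], spec.affected_slices,
                               spec.affected_gradients, p.get("pe_axis", "AP"))
    if t == "herringbone":
        return inject_herringbone(vol, p["amplitude"], tuple(p["k_loc"]),
                                  spec.affected_slices, spec.affected_gradients)
    if t == "chemical_shift":
        if rim_mask is None:
            raise ValueError("chemical_shift injection requires the phantom rim mask")
        return inject_chemical_shift(vol, rim_mask, p["shift_px"], p["rim_intensity"],
                                     spec.affected_slices, spec.affected_gradients,
                                     p.get("freq_axis", "LR"))
    if t == "susceptibility":
        return inject_susceptibility(vol, tuple(p["focus"]), p["max_displacement_px"],
                                     p["sigma_px"], spec.affected_slices,
                                     spec.affected_gradients, p.get("pe_axis", "AP"))
    if t == "motion_dropout":
        return inject_motion_dropout(vol, p["attenuation"], spec.affected_slices,
                                     spec.affected_gradients)
    if t == "multiband_interleave":
        return inject_multiband_interleave(vol, int(p["period"]), p["modulation"],
                                           spec.affected_gradients, int(p.get("phase", 0)))
    raise SpecError(f"unknown artifact type {t!r}")


def sample_artifact_spec(
    artifact_type: str,
    vol: DwiVolume,
    extent: BrainExtent,
    rng: np.random.Generator,
) -> ArtifactSpec:
    """Draw a randomized artifact of the given type, severity within the
    documented ranges, affecting a contiguous run of retained axial slices
    and a random subset of gradients."""
    ranges = SEVERITY_RANGES[artifact_type]
    retained = retained_axial_indices(extent)
    if not retained:
        raise SpecError("phantom has no retained axial slices to affect")
    run = int(rng.integers(3, min(9, len(retained)) + 1))
    start = int(rng.integers(0, len(retained) - run + 1))
    slices = tuple(retained[start : start + run])
    n_aff = int(rng.integers(1, max(2, vol.n_gradients // 2 + 1)))
    gradients = tuple(
        sorted(rng.choice(vol.n_gradients, size=n_aff, replace=False).tolist())
    )
    params: dict = {}
    if artifact_type == "ghosting":
        params["intensity"] = float(rng.uniform(*ranges["intensity"]))
    elif artifact_type == "herringbone":
        is_ax = vol.axis_of("IS")
        in_plane = [a for a in range(3) if a != is_ax]
        shape2d = tuple(vol.data.shape[a] for a in in_plane)
        mid = _plane_slicer(is_ax, slices[len(slices) // 2], gradients[0])
        ref_k = float(np.percentile(np.abs(np.fft.fft2(vol.data[mid])), 95))
        factor = float(rng.uniform(*ranges["amplitude_factor"]))
        radius = rng.uniform(0.08, 0.30)  # cycles/px, inside the texture band
        theta = rng.uniform(0, np.pi)
        k_loc = (
            int(round(radius * np.cos(theta) * shape2d[0])) % shape2d[0],
            int(round(radius * np.sin(theta) * shape2d[1])) % shape2d[1],
        )
        if k_loc == (0, 0):
            k_loc = (0, max(3, shape2d[1] // 8))
        params["amplitude"] = factor * ref_k
        params["amplitude_factor"] = factor
        params["k_loc"] = list(k_loc)
    elif artifact_type == "chemical_shift":
        lo, hi = ranges["shift_px"]
        params["shift_px"] = int(rng.integers(int(lo), int(hi) + 1)) * int(
            rng.choice([-1, 1])
        )
        params["rim_intensity"] = float(rng.uniform(*ranges["rim_intensity"]))
    elif artifact_type == "susceptibility":
        params["max_displacement_px"] = float(rng.uniform(*ranges["max_displacement_px"]))
        params["sigma_px"] = float(rng.uniform(*ranges["sigma_px"]))
        lr_lo, lr_hi = extent.lr
        ap_lo, ap_hi = extent.ap
        params["focus"] = [
            float(rng.uniform(lr_lo + 5, lr_hi - 5)),
            float(rng.uniform(ap_lo + 5, ap_hi - 5)),
        ]
    elif artifact_type == "motion_dropout":
        params["attenuation"] = float(rng.uniform(*ranges["attenuation"]))
    elif artifact_type == "multiband_interleave":
        lo, hi = ranges["period"]
        params["period"] = int(rng.integers(int(lo), int(hi) + 1))
        params["phase"] = int(rng.integers(0, params["period"]))
        params["modulation"] = float(rng.uniform(*ranges["modulation"]))
    else:
        raise SpecError(f"unknown artifact type {artifact_type!r}")
    return ArtifactSpec(
        artifact_type=artifact_type,
        params=params,
        affected_slices=slices,
        affected_gradients=gradients,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class LabeledDataset:
    """Paths and slice-level manifest of a generated dataset."""

    out_dir: Path
    paths: list[Path]
    manifest: pd.DataFrame
    artifact_specs: list[ArtifactSpec | None]

    @property
    def manifest_path(self) -> Path:
        return self.out_dir / "manifest.csv"


MANIFEST_COLUMNS = [
    "volume_id", "gradient_index", "view", "slice_index",
    "label", "artifact_type", "severity_json",
]


def _manifest_rows_for_volume(
    vol: DwiVolume, spec: ArtifactSpec | None
) -> list[dict]:
    """Slice-level labels for one written volume, derived from the retention
    rules re-run on the volume itself and the applied artifact spec."""
    extent = compute_brain_extent(vol)
    ax_idx = retained_axial_indices(extent)
    sag_idx = retained_sagittal_indices(extent)
    if spec is not None and spec.artifact_type == "multiband_interleave":
        period, phase = int(spec.params["period"]), int(spec.params.get("phase", 0))
        affected_slices = {z for z in ax_idx if (z - phase) % period == 0}
    elif spec is not None:
        affected_slices = set(spec.affected_slices)
    else:
        affected_slices = set()
    rows = []
    for g in range(vol.n_gradients):
        g_affected = spec is not None and g in spec.affected_gradients
        for view, indices in (("axial", ax_idx), ("sagittal", sag_idx)):
            for i in indices:
                if spec is not None and g_affected and spec.view == view:
                    artifactual = view == "sagittal" or i in affected_slices
                else:
                    artifactual = False
                rows.append(
                    {
                        "volume_id": vol.volume_id,
                        "gradient_index": g,
                        "view": view,
                        "slice_index": i,
                        "label": LABEL_ARTIFACTUAL if artifactual else LABEL_ARTIFACT_FREE,
                        "artifact_type": spec.artifact_type if artifactual else "none",
                        "severity_json": json.dumps(spec.params, sort_keys=True)
                        if artifactual
                        else "",
                    }
                )
    return rows


def generate_dataset(
    phantom: PhantomSpec,
    artifact_menu,
    n_volumes: int,
    artifact_fraction: float,
    seed: int,
    out_dir: str | Path,
) -> LabeledDataset:
    """Write a labeled synthetic corpus: NIfTI volumes plus a slice manifest.

    Exactly ``round(n_volumes * artifact_fraction)`` volumes receive one
    artifact drawn from ``artifact_menu`` (type names or ready
    :class:`ArtifactSpec` objects) with severity randomized within the
    documented ranges. Labels are assigned per retained slice in the view
    where the artifact class manifests; the retained-slice sets in the
    manifest are computed by re-running the slicing rules on the written
    volumes, so they match what a consumer will extract. All randomness
    derives from ``seed``; a JSON sidecar records the specs for replay.
    """
    if not 0 <= artifact_fraction <= 1:
        raise ValueError("artifact_fraction must lie in [0, 1]")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / ".write_test").write_text("")
        (out_dir / ".write_test").unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    rng = np.random.default_rng(seed)
    n_artifactual = int(round(n_volumes * artifact_fraction))
    artifact_ids = set(
        rng.choice(n_volumes, size=n_artifactual, replace=False).tolist()
    ) if n_artifactual else set()

    menu = list(artifact_menu)
    if not menu and n_artifactual:
        raise ValueError("artifact_menu is empty but artifact_fraction > 0")

    paths: list[Path] = []
    specs: list[ArtifactSpec | None] = []
    rows: list[dict] = []
    sidecar: dict = {"seed": seed, "n_volumes": n_volumes,
                     "artifact_fraction": artifact_fraction, "volumes": []}
    for v in range(n_volumes):
        vol_seed = int(rng.integers(0, 2**31 - 1))
        vspec = replace(phantom, seed=vol_seed)
        vol_id = f"vol_{v:03d}"
        vol = make_phantom_volume(vspec, volume_id=vol_id)
        spec: ArtifactSpec | None = None
        if v in artifact_ids:
            choice = menu[int(rng.integers(0, len(menu)))]
            if isinstance(choice, ArtifactSpec):
                spec = choice
            else:
                extent = compute_brain_extent(vol)
                spec = sample_artifact_spec(str(choice), vol, extent, rng)
            rim = phantom_masks(vspec)["rim"] if spec.artifact_type == "chemical_shift" else None
            vol = apply_artifact(vol, spec, rim_mask=rim)
            # magnitude images are nonnegative; injection can undershoot zero
            vol = replace(vol, data=np.clip(vol.data, 0.0, None))
        path = out_dir / f"{vol_id}.nii.gz"
        save_volume(vol, path)
        written = load_volume(path)
        rows.extend(_manifest_rows_for_volume(written, spec))
        paths.append(path)
        specs.append(spec)
        sidecar["volumes"].append(
            {
                "volume_id": vol_id,
                "phantom_seed": vol_seed,
                "artifact": None
                if spec is None
                else {
                    "artifact_type": spec.artifact_type,
                    "params": spec.params,
                    "affected_slices": list(spec.affected_slices),
                    "affected_gradients": list(spec.affected_gradients),
                    "seed": spec.seed,
                },
            }
        )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "dataset.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return LabeledDataset(out_dir=out_dir, paths=paths, manifest=manifest,
                          artifact_specs=specs)
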