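"""Phantom rendering, Rician noise, artifact injectors and dataset generation."""

import json

import numpy as np
import pandas as pd
import pytest

from dwiqc import io_slicing as ios
from dwiqc.artifact_sim import (
    ARTIFACT_TYPES,
    ArtifactSpec,
    PhantomSpec,
    SpecError,
    add_rician_noise,
    apply_artifact,
    generate_dataset,
    inject_chemical_shift,
    inject_ghosting,
    inject_herringbone,
    inject_motion_dropout,
    inject_multiband_interleave,
    inject_susceptibility,
    make_phantom_volume,
    phantom_masks,
    susceptibility_displacement_field,
)
from dwiqc.io_slicing import compute_brain_extent


# -- phantom ----------------------------------------------------------------

def test_phantom_deterministic_given_seed():
    spec = PhantomSpec(seed=1)
    a = make_phantom_volume(spec)
    b = make_phantom_volume(spec)
    np.testing.assert_array_equal(a.data, b.data)


def test_phantom_noiseless_is_piecewise_constant(clean_phantom):
    """With zero noise/texture/bias the intensities are exactly the
    configured tissue values."""
    values = set(np.unique(clean_phantom.data[..., 0]))
    assert values <= {0.0, 0.5, 0.7, 1.0, 1.2}
    assert {0.0, 0.7, 1.2} <= values  # background, parenchyma, rim all present


def test_phantom_seeds_differ_only_in_noise():
    base = dict(geometry_jitter=0.0, texture_amplitude=0.0, bias_amplitude=0.0,
                n_gradients=1)
    noiseless = make_phantom_volume(PhantomSpec(seed=1, noise_sigma=0.0, **base))
    for seed in (1, 2):
        noisy = make_phantom_volume(PhantomSpec(seed=seed, noise_sigma=0.05, **base))
        resid = noisy.data - noiseless.data
        # residual behaves like the noise floor, not structure
        assert np.abs(resid).max() < 0.4
        assert resid.std() < 0.1


def test_phantom_rejects_degenerate_ellipsoid():
    from dwiqc.artifact_sim import Ellipsoid

    with pytest.raises(SpecError):
        PhantomSpec(tissues=(Ellipsoid((0.5, 0.5, 0.5), (0.3, -0.1, 0.3), 1.0),))


def test_rim_mask_is_thin_shell_outside_brain(phantom_spec):
    masks = phantom_masks(phantom_spec)
    assert masks["rim"].any()
    assert not (masks["rim"] & masks["brain"]).any()


# -- Rician noise -----------------------------------------------------------

def test_rician_sigma_zero_is_identity():
    img = np.random.default_rng(0).random((32, 32))
    np.testing.assert_array_equal(add_rician_noise(img, 0.0, 1), img)


def test_rician_background_mean_matches_rayleigh_closed_form():
    """Zero image -> Rayleigh magnitudes with mean sigma * sqrt(pi/2)."""
    out = add_rician_noise(np.zeros(10**6), 1.0, seed=42)
    expected = np.sqrt(np.pi / 2)
    assert abs(out.mean() - expected) / expected < 0.01


def test_rician_deterministic_and_validates_sigma():
    img = np.ones((16, 16))
    np.testing.assert_array_equal(
        add_rician_noise(img, 0.3, 7), add_rician_noise(img, 0.3, 7)
    )
    with pytest.raises(ValueError):
        add_rician_noise(img, -0.1, 0)


# -- injector identities & locality -----------------------------------------

ZERO_SEVERITY_CALLS = [
    lambda v: inject_ghosting(v, 0.0, [10], [0]),
    lambda v: inject_herringbone(v, 0.0, (3, 5), [10], [0]),
    lambda v: inject_susceptibility(v, (32, 32), 0.0, 5.0, [10], [0]),
    lambda v: inject_motion_dropout(v, 0.0, [10], [0]),
    lambda v: inject_multiband_interleave(v, 4, 0.0, [0]),
]


@pytest.mark.parametrize("call", ZERO_SEVERITY_CALLS)
def test_zero_severity_is_exact_identity(phantom, call):
    out = call(phantom)
    np.testing.assert_array_equal(out.data, phantom.data)
    assert out.data is not phantom.data  # a copy, not the same array


@pytest.mark.parametrize(
    "call",
    [
        lambda v: inject_ghosting(v, 0.4, [10, 11], [1]),
        lambda v: inject_herringbone(v, 50.0, (3, 5), [10, 11], [1]),
        lambda v: inject_susceptibility(v, (32, 32), 4.0, 5.0, [10, 11], [1]),
        lambda v: inject_motion_dropout(v, 0.7, [10, 11], [1]),
    ],
)
def test_injectors_touch_only_affected_planes(phantom, call):
    out = call(phantom)
    changed = np.any(out.data != phantom.data, axis=(0, 1))  # (z, gradient)
    assert set(np.argwhere(changed)[:, 1]) <= {1}
    assert set(np.argwhere(changed)[:, 0]) <= {10, 11}


# -- ghosting ---------------------------------------------------------------

def test_ghosting_matches_image_domain_superposition_oracle(phantom):
    """k-space even/odd modulation == I(x) + alpha * I(x shifted N/2 along PE)."""
    alpha = 0.4
    out = inject_ghosting(phantom, alpha, [18], [0])
    plane = phantom.data[:, :, 18, 0]
    oracle = plane + alpha * np.roll(plane, plane.shape[1] // 2, axis=1)
    np.testing.assert_allclose(out.data[:, :, 18, 0], oracle, atol=1e-8)


def test_ghosting_cross_correlation_peaks_at_half_fov(phantom):
    out = inject_ghosting(phantom, 0.5, [18], [0])
    diff = out.data[:, :, 18, 0] - phantom.data[:, :, 18, 0]
    plane = phantom.data[:, :, 18, 0]
    # circular cross-correlation along the phase-encode axis via FFT
    xc = np.fft.ifft(
        np.fft.fft(diff, axis=1) * np.conj(np.fft.fft(plane, axis=1)), axis=1
    ).real.sum(axis=0)
    assert np.argmax(xc) == plane.shape[1] // 2


def test_ghosting_validates_intensity(phantom):
    with pytest.raises(ValueError):
        inject_ghosting(phantom, 1.5, [10], [0])


# -- herringbone ------------------------------------------------------------

def test_herringbone_spectrum_support_only_at_spike_pair(phantom):
    amp, k_loc = 80.0, (5, 9)
    out = inject_herringbone(phantom, amp, k_loc, [18], [0])
    diff_k = np.fft.fft2(out.data[:, :, 18, 0] - phantom.data[:, :, 18, 0])
    mask = np.zeros(diff_k.shape, dtype=bool)
    mask[k_loc] = mask[-k_loc[0], -k_loc[1]] = True
    assert abs(abs(diff_k[k_loc]) - amp) < 1e-8
    assert np.abs(diff_k[~mask]).max() < 1e-8


def test_herringbone_linearity_two_spikes(phantom):
    a = inject_herringbone(phantom, 40.0, (4, 6), [18], [0])
    b = inject_herringbone(phantom, 60.0, (9, 2), [18], [0])
    both = inject_herringbone(a, 60.0, (9, 2), [18], [0])
    sum_of_waves = (a.data - phantom.data) + (b.data - phantom.data)
    np.testing.assert_allclose(both.data - phantom.data, sum_of_waves, atol=1e-8)


def test_herringbone_rejects_dc_and_out_of_grid(phantom):
    with pytest.raises(ValueError):
        inject_herringbone(phantom, 10.0, (0, 0), [10], [0])
    with pytest.raises(ValueError):
        inject_herringbone(phantom, 10.0, (500, 0), [10], [0])


# -- chemical shift ----------------------------------------------------------

def test_chemical_shift_difference_confined_to_translated_rim(
    phantom_spec, phantom
):
    rim = phantom_masks(phantom_spec)["rim"]
    out = inject_chemical_shift(phantom, rim, 3, 0.5, [18], [0])
    diff = out.data[:, :, 18, 0] - phantom.data[:, :, 18, 0]
    allowed = np.roll(rim[:, :, 18], 3, axis=0)
    assert np.all(diff[~allowed] == 0)
    assert np.abs(diff[allowed]).max() > 0


def test_chemical_shift_is_invertible_on_added_component(phantom_spec, phantom):
    rim = phantom_masks(phantom_spec)["rim"]
    fwd = inject_chemical_shift(phantom, rim, 3, 0.5, [18], [0])
    added = fwd.data - phantom.data
    np.testing.assert_allclose(
        np.roll(np.roll(added, -3, axis=0), 3, axis=0), added, atol=1e-12
    )


def test_chemical_shift_validates_shift(phantom_spec, phantom):
    rim = phantom_masks(phantom_spec)["rim"]
    with pytest.raises(ValueError):
        inject_chemical_shift(phantom, rim, 0, 0.5, [10], [0])
    with pytest.raises(ValueError, match="FOV/4"):
        inject_chemical_shift(phantom, rim, 30, 0.5, [10], [0])


# -- susceptibility ----------------------------------------------------------

def test_susceptibility_field_peaks_at_focus():
    field = susceptibility_displacement_field((64, 64), (30.0, 40.0), 5.0, 6.0)
    assert abs(field.max() - 5.0) < 1e-9
    assert np.unravel_index(field.argmax(), field.shape) == (30, 40)


def test_susceptibility_far_field_untouched(phantom):
    sigma = 3.0
    out = inject_susceptibility(phantom, (32, 32), 5.0, sigma, [18], [0])
    diff = np.abs(out.data[:, :, 18, 0] - phantom.data[:, :, 18, 0])
    rows, cols = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    far = np.hypot(rows - 32, cols - 32) > 4 * sigma
    dynamic_range = np.ptp(phantom.data[:, :, 18, 0])
    assert diff[far].max() < 1e-3 * dynamic_range


# -- motion dropout / multiband ----------------------------------------------

def test_motion_dropout_full_attenuation_zeroes_slices(phantom):
    out = inject_motion_dropout(phantom, 1.0, [10, 11], [0, 1])
    assert not out.data[:, :, 10, 0].any()
    assert not out.data[:, :, 11, 1].any()
    # sagittal slice rows at those z are zero too
    sag = out.data[30, :, :, 0]
    assert not sag[:, 10].any() and not sag[:, 11].any()


def test_motion_dropout_mean_ratio_tracks_attenuation(phantom):
    att = 0.6
    out = inject_motion_dropout(phantom, att, [15], [0])
    ratio = out.data[:, :, 15, 0].mean() / phantom.data[:, :, 15, 0].mean()
    assert abs(ratio - (1 - att)) < 1e-12


def test_multiband_attenuates_every_period_th_slice(phantom):
    period, phase, mod = 4, 0, 0.3
    out = inject_multiband_interleave(phantom, period, mod, [0], phase=phase)
    nz = phantom.shape[2]
    affected = [z for z in range(nz) if (z - phase) % period == 0]
    assert len(affected) == int(np.ceil(nz / period))
    for z in range(nz):
        expected = phantom.data[:, :, z, 0] * ((1 - mod) if z in affected else 1.0)
        np.testing.assert_allclose(out.data[:, :, z, 0], expected, atol=1e-12)


def test_multiband_profile_has_spectral_peak_at_one_over_period(phantom):
    """After dividing out the anatomy envelope, the through-slice intensity
    profile is the periodic modulation comb, peaking at frequency 1/period."""
    period = 4
    out = inject_multiband_interleave(phantom, period, 0.5, [0], phase=1)
    base = phantom.data[..., 0].mean(axis=(0, 1))
    modulated = out.data[..., 0].mean(axis=(0, 1))
    profile = modulated / base
    profile = profile - profile.mean()
    spectrum = np.abs(np.fft.rfft(profile))
    freqs = np.fft.rfftfreq(len(profile))
    assert abs(freqs[np.argmax(spectrum)] - 1 / period) < 1 / len(profile)


# -- severity monotonicity ---------------------------------------------------

@pytest.mark.parametrize(
    "make, levels",
    [
        (lambda v, s: inject_ghosting(v, s, [18], [0]), [0.1, 0.2, 0.3, 0.5]),
        (lambda v, s: inject_herringbone(v, s, (5, 9), [18], [0]), [10, 30, 60, 90]),
        (lambda v, s: inject_motion_dropout(v, s, [18], [0]), [0.2, 0.5, 0.8, 1.0]),
        (lambda v, s: inject_susceptibility(v, (32, 32), s, 6.0, [18], [0]),
         [1.0, 2.0, 4.0, 6.0]),
    ],
)
def test_injection_energy_monotone_in_severity(phantom, make, levels):
    energies = [np.linalg.norm(make(phantom, s).data - phantom.data) for s in levels]
    assert all(b >= a for a, b in zip(energies, energies[1:]))


# -- dataset generation -------------------------------------------------------

@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    phantom = PhantomSpec(shape=(48, 48, 32), n_gradients=2)
    return generate_dataset(phantom, list(ARTIFACT_TYPES), n_volumes=10,
                            artifact_fraction=0.5, seed=7, out_dir=out)


def test_dataset_artifact_fraction_exact(small_dataset):
    n_art = sum(s is not None for s in small_dataset.artifact_specs)
    assert n_art == 5


def test_dataset_manifest_reproducible_byte_identical(small_dataset, tmp_path):
    phantom = PhantomSpec(shape=(48, 48, 32), n_gradients=2)
    again = generate_dataset(phantom, list(ARTIFACT_TYPES), n_volumes=10,
                             artifact_fraction=0.5, seed=7, out_dir=tmp_path)
    assert (
        small_dataset.manifest_path.read_bytes()
        == again.manifest_path.read_bytes()
    )


def test_dataset_zero_fraction_all_clean(tmp_path):
    phantom = PhantomSpec(shape=(48, 48, 32), n_gradients=1)
    ds = generate_dataset(phantom, list(ARTIFACT_TYPES), n_volumes=3,
                          artifact_fraction=0.0, seed=1, out_dir=tmp_path)
    assert set(ds.manifest["label"]) == {"artifact_free"}


def test_dataset_manifest_matches_slicing_of_written_files(small_dataset):
    """Cross-module invariant: manifest rows per (volume, view) equal the
    slice sets io_slicing retains on the written NIfTI files."""
    m = small_dataset.manifest
    for path in small_dataset.paths[:4]:
        vol = ios.load_volume(path)
        extent = compute_brain_extent(vol)
        ax = ios.extract_axial_slices(vol, extent)
        sg = ios.extract_sagittal_slices(vol, extent)
        sub = m[m["volume_id"] == vol.volume_id]
        assert len(sub[sub["view"] == "axial"]) == len(ax)
        assert len(sub[sub["view"] == "sagittal"]) == len(sg)
        got = {(r.view, r.gradient_index, r.slice_index) for r in sub.itertuples()}
        want = {(s.view, s.gradient_index, s.slice_index) for s in ax + sg}
        assert got == want


def test_dataset_labels_consistent_with_specs(small_dataset):
    m = small_dataset.manifest
    for path, spec in zip(small_dataset.paths, small_dataset.artifact_specs):
        vol_id = path.name.removesuffix(".nii.gz")
        sub = m[m["volume_id"] == vol_id]
        if spec is None:
            assert set(sub["label"]) == {"artifact_free"}
            continue
        bad = sub[sub["label"] == "artifactual"]
        assert len(bad) > 0
        assert set(bad["view"]) == {spec.view}
        assert set(bad["gradient_index"]) <= set(spec.affected_gradients)
        assert set(bad["artifact_type"]) == {spec.artifact_type}


def test_dataset_sidecar_replays(small_dataset):
    sidecar = json.loads((small_dataset.out_dir / "dataset.json").read_text())
    assert sidecar["seed"] == 7
    assert len(sidecar["volumes"]) == 10
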