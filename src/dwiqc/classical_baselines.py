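"""Classical texture-feature detectors used as comparison baselines.

Three hand-crafted feature families feed conventional classifiers:

* a Gabor filter bank (4 scales x 4 orientations; mean and standard
  deviation of each response magnitude -> 32 features),
* Zernike moment magnitudes up to order 4 (9 rotation-invariant features),
* uniform local binary patterns (P=8, R=1; 10-bin normalized histogram),

each paired with a random forest. Two hybrid baselines complete the set: the
Gabor features fed into a 256-unit fully connected network with dropout and
softmax, and CNN backbone features projected by PCA (98% retained variance)
into an SVM. All detectors expose the same ``predict_proba``/``predict``
contract as the CNN detectors, with the tie at p = 0.5 going to
"artifactual".
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.feature import local_binary_pattern
from skimage.filters import gabor_kernel
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn

__all__ = [
    "GaborBankSpec", "ZernikeSpec", "FeaturePipelineSpec", "FeatureDetector",
    "gabor_features", "zernike_features", "lbp_features",
    "train_feature_detector", "gabor_fc_detector", "cnn_pca_svm",
    "feature_matrix", "save_feature_matrix", "load_feature_matrix",
]


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborBankSpec:
    """4 scales x 4 orientations of zero-mean complex Gabor kernels.

    Frequencies are ``base_frequency * scale_multiplier**s`` in cycles/pixel;
    the defaults (0.06, 0.12, 0.24, 0.48) span coarse stripes to
    near-Nyquist texture while keeping every kernel smaller than a 64-pixel
    slice matrix. Kernels are made zero-mean so a constant
    image produces (numerically) zero response, i.e. the features are
    invariant to the image's mean level.
    """

    n_scales: int = 4
    n_orientations: int = 4
    base_frequency: float = 0.06
    scale_multiplier: float = 2.0
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.base_frequency <= 0 or self.scale_multiplier <= 0:
            raise ValueError("frequencies must be positive")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(
            self.base_frequency * self.scale_multiplier**s for s in range(self.n_scales)
        )

    @property
    def orientations(self) -> tuple[float, ...]:
        return tuple(
            np.pi * o / self.n_orientations for o in range(self.n_orientations)
        )

    @property
    def n_features(self) -> int:
        return 2 * self.n_scales * self.n_orientations


def _gabor_bank(spec: GaborBankSpec) -> list[np.ndarray]:
    kernels = []
    for f in spec.frequencies:
        for theta in spec.orientations:
            k = gabor_kernel(f, theta=theta, bandwidth=spec.bandwidth)
            kernels.append(k - k.mean())  # remove DC response
    return kernels


def gabor_features(image: np.ndarray, spec: GaborBankSpec = GaborBankSpec()) -> np.ndarray:
    """Mean and std of each Gabor response magnitude, scale-major order.

    Output layout: ``[s0o0_mean, s0o0_std, s0o1_mean, ..., s3o3_std]`` —
    32 values for the default 4x4 bank.
    """
    image = np.asarray(image, dtype=np.float64)
    feats = []
    for k in _gabor_bank(spec):
        if k.shape[0] > image.shape[0] or k.shape[1] > image.shape[1]:
            raise ValueError(
                f"image {image.shape} smaller than Gabor kernel {k.shape}"
            )
        # edge-pad so boundary windows see a full kernel support; a constant
        # image then yields an exactly-zero response everywhere
        ph, pw = k.shape[0] // 2, k.shape[1] // 2
        padded = np.pad(image, ((ph, ph), (pw, pw)), mode="edge")
        resp = np.abs(fftconvolve(padded, k, mode="valid"))
        feats.extend([resp.mean(), resp.std()])
    return np.asarray(feats)


# ---------------------------------------------------------------------------
# Zernike moments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZernikeSpec:
    """Zernike moments up to ``order`` on the centered inscribed disk.

    With ``full_set`` (default) all valid (n, m) pairs with n <= order,
    m >= 0 and n - m even are computed — 9 magnitudes for order 4. With
    ``full_set=False`` only the single (order, repetition) moment is
    returned.
    """

    order: int = 4
    repetition: int = 2
    radius_fraction: float = 0.5
    full_set: bool = True

    def __post_init__(self) -> None:
        if self.order < abs(self.repetition) or (self.order - abs(self.repetition)) % 2:
            raise ValueError("need order >= |repetition| and order - repetition even")
        if not 0 < self.radius_fraction <= 0.5:
            raise ValueError("radius_fraction must lie in (0, 0.5]")

    @property
    def moment_indices(self) -> tuple[tuple[int, int], ...]:
        if not self.full_set:
            return ((self.order, abs(self.repetition)),)
        return tuple(
            (n, m)
            for n in range(self.order + 1)
            for m in range(n % 2, n + 1, 2)
        )


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^m via its explicit factorial sum."""
    from math import factorial

    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)) / (
            factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k)
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_features(image: np.ndarray, spec: ZernikeSpec = ZernikeSpec()) -> np.ndarray:
    """Magnitudes |Z_nm| of the Zernike moments of the disk-masked image.

    The image is projected onto the orthogonal Zernike polynomials over the
    inscribed disk (radius ``radius_fraction * min(H, W)`` about the image
    center); the magnitudes are invariant to in-plane rotation.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    radius = spec.radius_fraction * min(h, w)
    if radius < 1:
        raise ValueError("disk radius is smaller than one pixel")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(yy - cy, xx - cx) / radius
    theta = np.arctan2(yy - cy, xx - cx)
    disk = rho <= 1.0
    f = image[disk]
    rho_d, theta_d = rho[disk], theta[disk]
    # area element of one pixel in normalized disk coordinates
    darea = 1.0 / radius**2
    feats = []
    for n, m in spec.moment_indices:
        basis = _radial_poly(n, m, rho_d) * np.exp(-1j * m * theta_d)
        z = (n + 1) / np.pi * np.sum(f * basis) * darea
        feats.append(abs(z))
    return np.asarray(feats)


# ---------------------------------------------------------------------------
# Local binary patterns
# ---------------------------------------------------------------------------

def lbp_features(image: np.ndarray, n_points: int = 8, radius: int = 1) -> np.ndarray:
    """Normalized histogram of uniform LBP codes (P+2 bins, summing to 1).

    The slice is first quantized to 256 gray levels (LBP's native domain;
    on continuous floats every sub-noise perturbation flips neighbor
    comparisons, which skimage warns about). Min-max quantization makes the
    histogram exactly invariant to affine gray-level shifts a*x + b, a > 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if min(image.shape) < 3:
        raise ValueError("image must be at least 3x3 for LBP")
    lo, hi = image.min(), image.max()
    if hi > lo:
        image = np.round((image - lo) / (hi - lo) * 255).astype(np.uint8)
    else:
        image = np.zeros(image.shape, dtype=np.uint8)
    codes = local_binary_pattern(image, n_points, radius, method="uniform")
    n_bins = n_points + 2
    hist, _ = np.histogram(codes, bins=n_bins, range=(0, n_bins))
    return hist / hist.sum()


def feature_matrix(images, extractor, *args, **kwargs) -> np.ndarray:
    """Stack ``extractor(image, ...)`` over a sequence of images."""
    return np.stack([extractor(np.asarray(im), *args, **kwargs) for im in images])


FEATURE_NAMES = {
    "gabor": [f"gabor_s{s}_o{o}_{stat}"
              for s in range(4) for o in range(4) for stat in ("mean", "std")],
    "zernike": [f"zernike_n{n}_m{m}" for n, m in ZernikeSpec().moment_indices],
    "lbp": [f"lbp_bin{i}" for i in range(10)],
}


def save_feature_matrix(path, features: np.ndarray, scheme: str) -> None:
    """Write a feature matrix to CSV with one named column per feature."""
    features = np.asarray(features)
    names = FEATURE_NAMES.get(scheme)
    if names is None or len(names) != features.shape[1]:
        names = [f"{scheme}_{i}" for i in range(features.shape[1])]
    pd.DataFrame(features, columns=names).to_csv(path, index=False)


def load_feature_matrix(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeaturePipelineSpec:
    """PCA retained-variance fraction and the downstream classifier kind."""

    pca_variance: float = 0.98
    classifier: str = "svm"

    def __post_init__(self) -> None:
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")


class FeatureDetector:
    """Uniform predict contract over feature vectors.

    ``predict_proba(X) -> (n, 2)`` column 1 = probability/score of
    "artifactual"; ``predict(X)`` thresholds at 0.5 with the tie going to
    the artifactual class (for QC a false positive is preferable to a miss).
    """

    def __init__(self, impl, scheme: str, pca: PCA | None = None,
                 standardizer: tuple[np.ndarray, np.ndarray] | None = None) -> None:
        self._impl = impl
        self.scheme = scheme
        self.pca = pca
        self._standardizer = standardizer

    def _prepare(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=np.float64)
        if self._standardizer is not None:
            mean, std = self._standardizer
            x = (x - mean) / std
        if self.pca is not None:
            x = self.pca.transform(x)
        return x

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = self._prepare(features)
        if isinstance(self._impl, nn.Sequential):
            return self._impl.predict_proba(x)
        if hasattr(self._impl, "predict_proba"):
            proba = self._impl.predict_proba(x)
            if proba.shape[1] == 1:  # degenerate, guarded earlier
                proba = np.hstack([1 - proba, proba])
            return proba
        score = self._impl.decision_function(x)
        p1 = 1.0 / (1.0 + np.exp(-score))
        return np.column_stack([1 - p1, p1])

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_proba(features)[:, 1] >= 0.5).astype(int)

    FORMAT_VERSION = 1

    def save(self, path) -> Path:
        """Serialize the detector (with its scheme tag and format version)."""
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump({"format_version": self.FORMAT_VERSION,
                         "scheme": self.scheme, "detector": self}, fh)
        return path

    @classmethod
    def load(cls, path) -> "FeatureDetector":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(
                f"unsupported detector format {payload.get('format_version')}"
            )
        return payload["detector"]


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    return labels


def train_feature_detector(
    features: np.ndarray, labels, classifier: str = "random_forest", seed: int = 0
) -> FeatureDetector:
    """Fit a random forest (100 trees) or RBF SVM on texture features."""
    features = np.asarray(features, dtype=np.float64)
    labels = _check_two_classes(labels)
    if classifier == "random_forest":
        impl = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif classifier == "svm":
        impl = SVC(kernel="rbf", random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {classifier!r}")
    impl.fit(features, labels)
    return FeatureDetector(impl, scheme=classifier)


def gabor_fc_detector(
    features: np.ndarray,
    labels,
    hidden: int = 256,
    dropout: float = 0.5,
    seed: int = 0,
    epochs: int = 20,
    learning_rate: float = 2e-4,
    batch_size: int = 32,
) -> FeatureDetector:
    """Gabor features into a 256-unit fully connected network with dropout
    and a two-way softmax, trained with RMSprop and cross-entropy (the same
    recipe as the CNN detectors). Features are standardized on the training
    set."""
    features = np.asarray(features, dtype=np.float64)
    labels = _check_two_classes(labels)
    mean = features.mean(axis=0)
    std = features.std(axis=0)
    std[std == 0] = 1.0
    x = (features - mean) / std
    net = nn.Sequential(
        [
            nn.Dense(x.shape[1], hidden),
            nn.ReLU(),
            nn.Dropout(dropout),
            nn.Dense(hidden, 2),
        ],
        seed=seed,
    )
    net.fit(x, labels, epochs=epochs, batch_size=batch_size,
            optimizer=nn.RMSprop(lr=learning_rate), shuffle_seed=seed + 1)
    return FeatureDetector(net, scheme="gabor_fc", standardizer=(mean, std))


def cnn_pca_svm(
    cnn_features: np.ndarray,
    labels,
    spec: FeaturePipelineSpec = FeaturePipelineSpec(),
    seed: int = 0,
) -> FeatureDetector:
    """CNN backbone features -> PCA keeping >= ``pca_variance`` of the
    variance -> SVM. The PCA is fitted on the training features only;
    prediction projects new data with the stored axes (no refit)."""
    cnn_features = np.asarray(cnn_features, dtype=np.float64)
    labels = _check_two_classes(labels)
    n_comp = spec.pca_variance if spec.pca_variance < 1 else None
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    projected = pca.fit_transform(cnn_features)
    svm = SVC(kernel="rbf", random_state=seed)
    svm.fit(projected, labels)
    return FeatureDetector(svm, scheme="cnn_pca", pca=pca)
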