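"""Trainable pixel classification over a multi-scale filter bank.

Semantic segmentation of the plaque and microglia channels follows the
interactive-machine-learning recipe: a random forest over per-pixel feature
vectors built from the raw image plus Gaussian blur, difference of
Gaussians, Gaussian gradient magnitude, Laplacian of Gaussian and Hessian
eigenvalues at a dyadic set of scales (the microglia bank adds mean and max
filters). Boundary handling is reflection everywhere.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier

from .core import ConfigurationError

BASE_FILTERS = ("gaussian", "dog", "gradient_magnitude", "log", "hessian_eig")
ALL_FILTERS = BASE_FILTERS + ("mean", "max")

# planes contributed per sigma by each filter
_PLANES_PER_SIGMA = {"gaussian": 1, "dog": 1, "gradient_magnitude": 1,
                     "log": 1, "hessian_eig": 2, "mean": 1, "max": 1}

BACKGROUND_LABEL = 1
FOREGROUND_LABEL = 2


@dataclass(frozen=True)
class FeatureBankConfig:
    """Scales (px) and filters of the feature stack; the raw image is always
    included once as the identity plane."""

    sigmas: tuple = (1, 2, 4, 8)
    filters: tuple = BASE_FILTERS

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.sigmas, self.sigmas[1:])):
            raise ConfigurationError("sigmas must be strictly increasing")
        unknown = set(self.filters) - set(ALL_FILTERS)
        if unknown:
            raise ConfigurationError(f"unknown filters: {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        per_sigma = sum(_PLANES_PER_SIGMA[f] for f in self.filters)
        return 1 + per_sigma * len(self.sigmas)


def plaque_bank() -> FeatureBankConfig:
    """Scales 2^0..2^3, the five base filters (F = 25)."""
    return FeatureBankConfig(sigmas=(1, 2, 4, 8), filters=BASE_FILTERS)


def microglia_bank() -> FeatureBankConfig:
    """Scales 2^1..2^6 with mean and max filters added (F = 49)."""
    return FeatureBankConfig(sigmas=(2, 4, 8, 16, 32, 64), filters=ALL_FILTERS)


def _filter_planes(img: np.ndarray, name: str, sigma: float) -> list[np.ndarray]:
    if name == "gaussian":
        return [ndi.gaussian_filter(img, sigma, mode="reflect")]
    if name == "dog":
        # standard blob-detection ratio: pair sigma with 1.6*sigma
        return [ndi.gaussian_filter(img, sigma, mode="reflect")
                - ndi.gaussian_filter(img, 1.6 * sigma, mode="reflect")]
    if name == "gradient_magnitude":
        return [ndi.gaussian_gradient_magnitude(img, sigma, mode="reflect")]
    if name == "log":
        return [ndi.gaussian_laplace(img, sigma, mode="reflect")]
    if name == "hessian_eig":
        h = hessian_matrix(img, sigma=sigma, mode="reflect",
                           use_gaussian_derivatives=True)
        eig = hessian_matrix_eigvals(h)  # sorted descending: eig[0] >= eig[1]
        return [eig[0], eig[1]]
    if name == "mean":
        return [ndi.uniform_filter(img, size=int(2 * sigma + 1), mode="reflect")]
    if name == "max":
        return [ndi.maximum_filter(img, size=int(2 * sigma + 1), mode="reflect")]
    raise ConfigurationError(f"unknown filter {name!r}")


def compute_feature_stack(channel: np.ndarray,
                          config: FeatureBankConfig) -> np.ndarray:
    """Per-pixel feature stack, shape (F, H, W), ordered identity first,
    then filter-major / sigma-minor."""
    img = np.asarray(channel, dtype=float)
    if img.size == 0:
        raise ValueError("channel is empty")
    if max(config.sigmas) > min(img.shape):
        warnings.warn("largest sigma exceeds image extent; computing with "
                      "boundary reflection anyway", stacklevel=2)
    planes = [img]
    for name in config.filters:
        for s in config.sigmas:
            planes.extend(_filter_planes(img, name, s))
    stack = np.stack(planes)
    assert stack.shape[0] == config.n_features
    return stack


@dataclass
class PixelClassifier:
    model: RandomForestClassifier
    config: FeatureBankConfig

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class SemanticMask:
    mask: np.ndarray  # boolean, same shape as source channel
    class_label: str = "foreground"
    provenance: str = ""


def train_classifier(stack: np.ndarray, labels: np.ndarray, *,
                     config: FeatureBankConfig | None = None,
                     n_trees: int = 100, seed: int = 0) -> PixelClassifier:
    """Fit a random forest on sparsely labelled pixels.

    labels: int image, 0 = unlabelled, 1 = background, 2 = foreground.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels[labels > 0])
    if classes.size < 2:
        raise ValueError("need at least one labelled pixel per class "
                         "(background and foreground)")
    sel = labels > 0
    X = stack[:, sel].T
    y = labels[sel]
    rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return PixelClassifier(model=rf, config=config)


def predict_mask(classifier: PixelClassifier, channel: np.ndarray,
                 config: FeatureBankConfig) -> SemanticMask:
    """Argmax-posterior binary mask over a full channel."""
    if classifier.config is not None and classifier.config != config:
        raise ValueError(
            f"feature bank mismatch: model trained with F="
            f"{classifier.config.n_features}, got F={config.n_features}")
    stack = compute_feature_stack(channel, config)
    expected = classifier.model.n_features_in_
    if stack.shape[0] != expected:
        raise ValueError(f"feature-count mismatch: model expects F={expected}, "
                         f"stack has F={stack.shape[0]}")
    X = stack.reshape(stack.shape[0], -1).T
    pred = classifier.model.predict(X).reshape(channel.shape)
    return SemanticMask(mask=pred == FOREGROUND_LABEL,
                        provenance=f"random_forest(n={classifier.model.n_estimators})")


def threshold_plaques(channel: np.ndarray,
                      method: str | float = "otsu",
                      noise_floor_sigmas: float | None = None) -> SemanticMask:
    """Global-threshold plaque mask (default Otsu).

    `method` is "otsu" or a fixed numeric threshold; pixels >= a fixed
    threshold (strictly > the Otsu value) are foreground. With
    `noise_floor_sigmas` set, an Otsu foreground whose median does not clear
    median + k * (1.4826 * MAD) of the channel is treated as a plaque-free
    FOV (Otsu on unimodal noise otherwise marks the upper noise tail).
    """
    img = np.asarray(channel, dtype=float)
    if img.size == 0:
        raise ValueError("channel is empty")
    if isinstance(method, str) and method.startswith("fixed:"):
        method = float(method.split(":", 1)[1])
    if method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("constant channel: Otsu threshold undefined, "
                          "returning empty mask", stacklevel=2)
            return SemanticMask(mask=np.zeros(img.shape, bool),
                                provenance="otsu(degenerate)")
        t = threshold_otsu(img)
        mask = img > t
        if noise_floor_sigmas is not None and mask.any():
            med = float(np.median(img))
            mad = 1.4826 * float(np.median(np.abs(img - med)))
            if np.median(img[mask]) < med + noise_floor_sigmas * mad:
                return SemanticMask(mask=np.zeros(img.shape, bool),
                                    provenance="otsu(below noise floor)")
        return SemanticMask(mask=mask, provenance=f"otsu({t:.4g})")
    t = float(method)
    return SemanticMask(mask=img >= t, provenance=f"fixed({t:g})")
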