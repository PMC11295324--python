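"""Image normalization, denoising, segmentation and feature extraction.

Feature vectors combine an intensity block (histogram + moments), a shape
block (area, perimeter, eccentricity) and a texture block (co-occurrence
statistics), and can be projected onto the probability simplex for the
Bhattacharyya machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, measure
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import gaussian as _gaussian_filter
from skimage.segmentation import flood

__all__ = [
    "NormalizationParams",
    "FeatureVector",
    "zscore_normalize",
    "zscore_inverse",
    "preprocess_image",
    "segment",
    "extract_features",
    "features_to_distribution",
]

EPS = 1e-12  # simplex floor; keeps -ln(sum sqrt(PQ)) finite on shared support


@dataclass(frozen=True)
class NormalizationParams:
    """Mean/std pair from a z-score fit, kept for the inverse transform."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError("std must be > 0")


@dataclass
class FeatureVector:
    """Named intensity / shape / texture blocks extracted from one region."""

    histogram: np.ndarray  # (hist_bins,) masked-pixel intensity histogram
    mean: float
    variance: float
    area: float  # px^2
    perimeter: float  # px
    eccentricity: float  # [0, 1]
    contrast: float
    homogeneity: float
    energy: float
    entropy: float

    def to_array(self) -> np.ndarray:
        """Concatenate all blocks into one flat vector."""
        scalars = [
            self.mean,
            self.variance,
            self.area,
            self.perimeter,
            self.eccentricity,
            self.contrast,
            self.homogeneity,
            self.energy,
            self.entropy,
        ]
        return np.concatenate([np.asarray(self.histogram, dtype=float), scalars])

    @property
    def names(self) -> list[str]:
        return [f"hist_{i}" for i in range(len(self.histogram))] + [
            "mean",
            "variance",
            "area",
            "perimeter",
            "eccentricity",
            "contrast",
            "homogeneity",
            "energy",
            "entropy",
        ]


def zscore_normalize(values) -> tuple[np.ndarray, NormalizationParams]:
    """Scale to zero mean and unit population standard deviation.

    Returns the scaled values together with the fitted parameters so the
    transform can be inverted exactly.  Constant input has no scale and is
    rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    std = float(x.std())  # population standard deviation (ddof=0)
    if std == 0.0:
        raise ValueError("zero variance: all input values are identical")
    return (x - mean) / std, NormalizationParams(mean=mean, std=std)


def zscore_inverse(normalized, params: NormalizationParams) -> np.ndarray:
    """Undo :func:`zscore_normalize`."""
    return np.asarray(normalized, dtype=float) * params.std + params.mean


def preprocess_image(image, denoise: str = "none", contrast: str = "none") -> np.ndarray:
    """Optional denoising then contrast adjustment; output stays in [0, 1].

    ``denoise``: ``median`` (3x3), ``gaussian`` (sigma 1) or ``none``.
    ``contrast``: ``stretch`` (min-max; identity on constant images),
    ``clahe`` or ``none``.  With both set to ``none`` the image passes
    through unchanged.
    """
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")

    if denoise == "median":
        img = ndimage.median_filter(img, size=3)
    elif denoise == "gaussian":
        img = _gaussian_filter(img, sigma=1.0)
    elif denoise != "none":
        raise ValueError(f"unknown denoise option {denoise!r}")

    if contrast == "stretch":
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo)
    elif contrast == "clahe":
        img = exposure.equalize_adapthist(np.clip(img, 0.0, 1.0))
    elif contrast != "none":
        raise ValueError(f"unknown contrast option {contrast!r}")

    return np.clip(img, 0.0, 1.0)


def _otsu_mask(img: np.ndarray) -> np.ndarray:
    """Otsu threshold on the 8-bit quantized histogram.

    Chooses the first (lowest) threshold maximizing between-class variance,
    exactly matching an exhaustive threshold sweep; marks pixels strictly
    above the threshold.
    """
    q = np.round(np.clip(img, 0.0, 1.0) * 255).astype(int)
    hist = np.bincount(q.ravel(), minlength=256).astype(float)
    levels = np.arange(256, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist)  # pixels <= t
    sum0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu0 = np.divide(sum0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros(256), where=w1 > 0)
    var = w0 * w1 * (mu0 - mu1) ** 2
    var[w1 == 0] = -1.0  # no foreground: invalid split
    if var.max() <= 0:  # constant image
        return np.zeros(img.shape, dtype=bool)
    t = int(np.argmax(var))  # argmax takes the first maximum
    return q > t


def segment(image, method: str = "otsu", seeds=None, tol: float = 0.1) -> np.ndarray:
    """Binary segmentation by Otsu, a fixed threshold, or region growing.

    ``method`` is ``"otsu"``, ``"fixed:<t>"`` (pixels strictly above t) or
    ``"region_grow"`` (requires ``seeds``, a list of (row, col) pixels; each
    grows a connected flood region within intensity tolerance ``tol``).
    """
    img = np.asarray(image, dtype=float)
    if method == "otsu":
        return _otsu_mask(img)
    if method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
        return img > t
    if method == "region_grow":
        if not seeds:
            raise ValueError("region_grow requires at least one seed")
        mask = np.zeros(img.shape, dtype=bool)
        for r, c in seeds:
            if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
                raise ValueError(f"seed ({r}, {c}) outside image bounds")
            mask |= flood(img, (int(r), int(c)), tolerance=tol)
        return mask
    raise ValueError(f"unknown segmentation method {method!r}")


def extract_features(image, mask, hist_bins: int = 32) -> FeatureVector:
    """Intensity, shape and texture features of one masked region.

    The histogram covers masked pixels only, over [0, 1].  Shape comes from
    the mask geometry (largest labelled region for perimeter/eccentricity,
    total pixel count for area).  Texture uses a symmetric co-occurrence
    matrix at offset (0, 1) quantized to ``hist_bins`` gray levels.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")

    pixels = img[m]
    hist, _ = np.histogram(pixels, bins=hist_bins, range=(0.0, 1.0))
    hist = hist.astype(float)

    labeled = measure.label(m)
    regions = measure.regionprops(labeled)
    main = max(regions, key=lambda r: r.area)
    area = float(m.sum())
    perimeter = float(main.perimeter)
    eccentricity = float(main.eccentricity)

    # GLCM over the masked bounding box; pixels outside the mask are mapped
    # to level 0 along with the darkest in-mask pixels (quantization floor).
    levels = hist_bins
    quant = np.clip((img * levels).astype(int), 0, levels - 1)
    rmin, rmax = np.where(m.any(axis=1))[0][[0, -1]]
    cmin, cmax = np.where(m.any(axis=0))[0][[0, -1]]
    window = quant[rmin : rmax + 1, cmin : cmax + 1]
    glcm = graycomatrix(
        window.astype(np.uint8), distances=[1], angles=[0.0], levels=levels, symmetric=True, normed=True
    )
    contrast = float(graycoprops(glcm, "contrast")[0, 0])
    homogeneity = float(graycoprops(glcm, "homogeneity")[0, 0])
    energy = float(graycoprops(glcm, "energy")[0, 0]) ** 2  # angular second moment
    p = glcm[:, :, 0, 0]
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    return FeatureVector(
        histogram=hist,
        mean=float(pixels.mean()),
        variance=float(pixels.var()),
        area=area,
        perimeter=perimeter,
        eccentricity=eccentricity,
        contrast=contrast,
        homogeneity=homogeneity,
        energy=energy,
        entropy=entropy,
    )


def features_to_distribution(v) -> np.ndarray:
    """Project a feature vector onto the probability simplex.

    Shift by the minimum, add a small floor (1e-12) and normalize to sum 1.
    Accepts a :class:`FeatureVector` or any 1-D array of finite reals.
    """
    arr = v.to_array() if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite feature components")
    shifted = arr - arr.min() + EPS
    return shifted / shifted.sum()
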