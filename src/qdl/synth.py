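"""Synthetic fixtures: phantom images, clustered features, metadata, payloads.

Everything here is seeded and deterministic so that the full pipeline is
buildable and testable offline, with no external image archives.
"""

from __future__ import annotations

import hashlib
import string
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "MetadataRecord",
    "LabeledFeatures",
    "ALPHANUMERIC_CHARSET",
    "generate_phantom_image",
    "generate_cluster_features",
    "generate_dirichlet_clusters",
    "generate_metadata_record",
    "generate_payload",
    "save_image_png",
    "load_image_png",
]

#: The 45-symbol alphabet of QR alphanumeric mode.
ALPHANUMERIC_CHARSET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ $%*+-./:"

_BYTE_CHARSET = string.digits + string.ascii_letters + string.punctuation + " "


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters for a synthetic blob-on-noise phantom image."""

    width: int = 64
    height: int = 64
    n_blobs: int = 3
    blob_radius_range: tuple[float, float] = (4.0, 8.0)
    blob_intensity_range: tuple[float, float] = (0.4, 0.8)
    background_level: float = 0.15
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("width and height must be >= 16")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        lo, hi = self.blob_radius_range
        if lo > hi:
            raise ValueError("blob_radius_range must be ordered (min, max)")
        if hi > min(self.width, self.height) / 2:
            raise ValueError("blob radius larger than min(width, height)/2")
        ilo, ihi = self.blob_intensity_range
        if not (0.0 <= ilo <= ihi <= 1.0):
            raise ValueError("blob_intensity_range must be ordered within [0, 1]")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class MetadataRecord:
    """A 12-field patient record attached to an image."""

    record_id: str
    modality: str  # XRay | CT | Picture
    image_ref: str
    datetime: str  # ISO-8601
    age: int
    sex: str  # M | F | O
    region: str
    body_part: str
    finding_label: str
    device: str
    notes: str
    checksum: str  # hex sha256 of the image bytes

    MODALITIES = ("XRay", "CT", "Picture")
    SEXES = ("M", "F", "O")

    def __post_init__(self) -> None:
        if self.modality not in self.MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.sex not in self.SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not 0 <= self.age <= 120:
            raise ValueError("age must be in [0, 120]")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dc_fields(cls)]

    def to_dict(self) -> dict[str, str]:
        return {name: str(getattr(self, name)) for name in self.field_names()}

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "MetadataRecord":
        kwargs = dict(d)
        kwargs["age"] = int(kwargs["age"])
        return cls(**kwargs)


@dataclass
class LabeledFeatures:
    """A feature matrix with per-row cluster labels."""

    matrix: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 2 or self.matrix.shape[1] < 2:
            raise ValueError("matrix must be n x d with n >= 2, d >= 2")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")
        if self.labels.shape[0] != self.matrix.shape[0]:
            raise ValueError("labels length must match matrix rows")


def generate_phantom_image(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom: soft-edged discs on a noisy flat background.

    Returns ``(image, truth_mask)``; the image is float in [0, 1], the mask
    is boolean and marks exactly the union of generated discs.  Blob
    placement is rejection-sampled to be non-overlapping where the geometry
    permits; with a fixed seed the output is bitwise reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    image = np.full((h, w), spec.background_level, dtype=float)
    mask = np.zeros((h, w), dtype=bool)

    yy, xx = np.mgrid[0:h, 0:w]
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_blobs):
        r = rng.uniform(*spec.blob_radius_range)
        amp = rng.uniform(*spec.blob_intensity_range)
        cy = cx = None
        for _attempt in range(200):
            ty = rng.uniform(r, h - 1 - r)
            tx = rng.uniform(r, w - 1 - r)
            if all((ty - py) ** 2 + (tx - px) ** 2 > (r + pr) ** 2 for py, px, pr in placed):
                cy, cx = ty, tx
                break
        if cy is None:  # crowded geometry: accept an overlapping placement
            cy = rng.uniform(r, h - 1 - r)
            cx = rng.uniform(r, w - 1 - r)
        placed.append((cy, cx, r))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= r * r
        # Gaussian radial profile: strictly positive inside the disc, so
        # every blob pixel exceeds the background before noise.
        profile = np.exp(-d2 / (2.0 * (r / 2.0) ** 2))
        image = np.where(disc, np.maximum(image, spec.background_level + amp * profile), image)
        mask |= disc

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask


def _separated_means(k: int, dim: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """k cluster means in R^dim with pairwise distance >= separation."""
    if separation == 0 or k == 1:
        return np.zeros((k, dim))
    if k <= dim:
        # random orthonormal directions scaled so pairwise distance is
        # separation * sqrt(2) >= separation
        g = rng.standard_normal((dim, k))
        q, _ = np.linalg.qr(g)
        return separation * q[:, :k].T
    # rejection sampling on a sphere whose radius grows until it fits
    radius = separation
    while True:
        means = []
        for _ in range(k):
            for _attempt in range(500):
                v = rng.standard_normal(dim)
                v *= radius / np.linalg.norm(v)
                if all(np.linalg.norm(v - m) >= separation for m in means):
                    means.append(v)
                    break
            else:
                break
        if len(means) == k:
            return np.asarray(means)
        radius *= 1.5


def generate_cluster_features(
    n_per_cluster: int,
    k_clusters: int,
    dim: int,
    separation: float,
    seed: int,
) -> LabeledFeatures:
    """Draw rows from k isotropic unit-variance Gaussians with separated means."""
    if n_per_cluster < 2:
        raise ValueError("n_per_cluster must be >= 2")
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    means = _separated_means(k_clusters, dim, separation, rng)
    rows = []
    labels = []
    for c in range(k_clusters):
        rows.append(means[c] + rng.standard_normal((n_per_cluster, dim)))
        labels.extend([c] * n_per_cluster)
    return LabeledFeatures(np.vstack(rows), np.asarray(labels, dtype=int))


def generate_dirichlet_clusters(
    n_per_cluster: int,
    k_clusters: int,
    dim: int,
    concentration: float,
    seed: int,
) -> LabeledFeatures:
    """Histogram-like rows: k Dirichlet families with distinct mean simplices.

    Each family's mean is a Dirichlet draw sharpened into a distinct corner
    of the simplex; rows are Dirichlet samples around that mean scaled by
    ``concentration`` (larger = tighter families).  Every row sums to 1.
    """
    if n_per_cluster < 2 or k_clusters < 1 or dim < 2:
        raise ValueError("need n_per_cluster >= 2, k_clusters >= 1, dim >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for c in range(k_clusters):
        base = np.full(dim, 0.5)
        # bias a distinct block of coordinates per family
        block = slice(c * dim // k_clusters, (c + 1) * dim // k_clusters)
        base[block] += 4.0
        mean = rng.dirichlet(base)
        rows.append(rng.dirichlet(concentration * mean + 1e-3, size=n_per_cluster))
        labels.extend([c] * n_per_cluster)
    return LabeledFeatures(np.vstack(rows), np.asarray(labels, dtype=int))


_REGIONS = ("North", "South", "East", "West", "Central")
_BODY_PARTS = ("chest", "skull", "abdomen", "knee", "hand", "spine")
_FINDINGS = ("normal", "mass", "fracture", "opacity")
_DEVICES = ("ScannerA-3000", "RadiX-7", "PicoCam-2", "TomoMax-9")


def generate_metadata_record(seed: int, image_ref: str | Path) -> MetadataRecord:
    """Populate all 12 record fields deterministically from a seed.

    The checksum is the SHA-256 of the referenced image file's bytes, so
    later tampering with the file is detectable.
    """
    path = Path(image_ref)
    if not path.is_file():
        raise FileNotFoundError(f"image file not found: {path}")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    rng = np.random.default_rng(seed)
    year = int(rng.integers(2015, 2025))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    hour = int(rng.integers(0, 24))
    minute = int(rng.integers(0, 60))
    return MetadataRecord(
        record_id=f"R{seed:08d}",
        modality=str(rng.choice(MetadataRecord.MODALITIES)),
        image_ref=str(path),
        datetime=f"{year:04d}-{month:02d}-{day:02d}T{hour:02d}:{minute:02d}:00",
        age=int(rng.integers(0, 121)),
        sex=str(rng.choice(MetadataRecord.SEXES)),
        region=str(rng.choice(_REGIONS)),
        body_part=str(rng.choice(_BODY_PARTS)),
        finding_label=str(rng.choice(_FINDINGS)),
        device=str(rng.choice(_DEVICES)),
        notes=f"synthetic record seed={seed}",
        checksum=digest,
    )


def generate_payload(length: int, charset: str, seed: int) -> str:
    """Uniform random payload text over one of the QR-mode charsets."""
    if length < 1:
        raise ValueError("length must be >= 1")
    alphabets = {
        "numeric": string.digits,
        "alphanumeric": ALPHANUMERIC_CHARSET,
        "byte": _BYTE_CHARSET,
    }
    try:
        alphabet = alphabets[charset]
    except KeyError:
        raise ValueError(f"unknown charset {charset!r}") from None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


def save_image_png(image: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def load_image_png(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG back to float in [0,1]."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0
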