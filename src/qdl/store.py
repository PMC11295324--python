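"""Truncated-SVD compression and the similarity-mapped deduplicating store.

Ingest extracts a feature distribution from each image and searches the
index for the most similar existing entry (Bhattacharyya coefficient).
Above the 0.70 threshold the new entry is a *tag* referencing the match
(flattened, so tag chains never form) and its QR payload carries only the
key and reference; otherwise the image is compressed by truncated SVD and
a full QR payload is generated.
"""

from __future__ import annotations

import json
import os
import struct
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from qdl.image_prep import extract_features, features_to_distribution, segment
from qdl.qr.encode import Payload, build_symbol, render
from qdl.qr.decode import decode_symbol
from qdl.synth import MetadataRecord, save_image_png
from qdl.tsne import bhattacharyya_coefficient

__all__ = [
    "SVDFactors",
    "StoreEntry",
    "StoreIndex",
    "svd_compress",
    "svd_reconstruct",
    "choose_rank",
    "similarity",
    "ingest",
    "retrieve",
    "encode_entry_payload",
    "parse_entry_payload",
]

TAG_THRESHOLD = 0.70
_FACTOR_MAGIC = b"QDLF"


@dataclass
class SVDFactors:
    """Rank-truncated SVD of an image: U (rows x rank), s, Vt (rank x cols)."""

    U: np.ndarray
    s: np.ndarray
    Vt: np.ndarray
    shape: tuple[int, int]
    rank: int

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.Vt = np.asarray(self.Vt, dtype=float)
        if self.U.shape != (self.shape[0], self.rank) or self.Vt.shape != (self.rank, self.shape[1]):
            raise ValueError("inconsistent factor shapes")
        if self.s.shape != (self.rank,):
            raise ValueError("singular value vector has wrong length")
        if np.any(np.diff(self.s) > 1e-12) or np.any(self.s < 0):
            raise ValueError("singular values must be nonnegative and nonincreasing")


@dataclass
class StoreEntry:
    """One stored record: either SVD factors or a tag to a near-duplicate."""

    key: str
    record: MetadataRecord
    qr_payload: str
    compressed: SVDFactors | None = None
    tag_ref: str | None = None
    similarity: float | None = None
    qr_image_ref: str | None = None

    def __post_init__(self) -> None:
        if (self.compressed is None) == (self.tag_ref is None):
            raise ValueError("exactly one of compressed/tag_ref must be present")
        if self.tag_ref is not None and not (self.similarity is not None and self.similarity > TAG_THRESHOLD):
            raise ValueError("tag_ref requires similarity > 0.70")

    @property
    def is_tag(self) -> bool:
        return self.tag_ref is not None


class StoreIndex:
    """Key -> entry mapping plus a per-key feature distribution index.

    Optionally bound to a directory for durable storage: ``index.json``,
    ``factors/<key>.bin`` (flat binary, see :func:`save_factors`) and
    ``qr/<key>.png``.  Writes are atomic (temp file + rename).
    """

    def __init__(self, root: str | Path | None = None):
        self.root = Path(root) if root is not None else None
        self.entries: dict[str, StoreEntry] = {}
        self.features: dict[str, np.ndarray] = {}
        if self.root is not None:
            (self.root / "factors").mkdir(parents=True, exist_ok=True)
            (self.root / "qr").mkdir(parents=True, exist_ok=True)

    def best_match(self, dist: np.ndarray) -> tuple[str | None, float]:
        best_key, best_sim = None, -1.0
        for key in sorted(self.features):
            sim = similarity(self.features[key], dist)
            if sim > best_sim:
                best_key, best_sim = key, sim
        return best_key, best_sim

    def resolve(self, key: str) -> StoreEntry:
        """Follow at most one tag hop to an entry holding factors."""
        entry = self.entries[key]
        if entry.is_tag:
            entry = self.entries[entry.tag_ref]
        return entry

    # -- persistence -------------------------------------------------------

    def save(self) -> None:
        if self.root is None:
            raise ValueError("store has no backing directory")
        doc = {
            "entries": {
                key: {
                    "record": e.record.to_dict(),
                    "qr_payload": e.qr_payload,
                    "tag_ref": e.tag_ref,
                    "similarity": e.similarity,
                    "qr_image_ref": e.qr_image_ref,
                    "features": self.features[key].tolist(),
                }
                for key, e in sorted(self.entries.items())
            }
        }
        tmp = self.root / "index.json.tmp"
        tmp.write_text(json.dumps(doc, sort_keys=True, indent=1))
        os.replace(tmp, self.root / "index.json")

    @classmethod
    def load(cls, root: str | Path) -> "StoreIndex":
        store = cls(root)
        doc = json.loads((Path(root) / "index.json").read_text())
        for key, raw in doc["entries"].items():
            record = MetadataRecord.from_dict(raw["record"])
            if raw["tag_ref"] is not None:
                entry = StoreEntry(
                    key=key,
                    record=record,
                    qr_payload=raw["qr_payload"],
                    tag_ref=raw["tag_ref"],
                    similarity=raw["similarity"],
                    qr_image_ref=raw["qr_image_ref"],
                )
            else:
                entry = StoreEntry(
                    key=key,
                    record=record,
                    qr_payload=raw["qr_payload"],
                    compressed=load_factors(store.root / "factors" / f"{key}.bin"),
                    qr_image_ref=raw["qr_image_ref"],
                )
            store.entries[key] = entry
            store.features[key] = np.asarray(raw["features"], dtype=float)
        return store


def svd_compress(image, rank: int) -> SVDFactors:
    """Best rank-``rank`` approximation factors of an image matrix.

    For strongly tall matrices a QR orthogonalization precedes the SVD of
    the small triangular factor; the result is identical up to sign.
    """
    A = np.asarray(image, dtype=float)
    if A.ndim != 2:
        raise ValueError("image must be 2-D")
    rows, cols = A.shape
    if not 1 <= rank <= min(rows, cols):
        raise ValueError(f"rank must be in [1, {min(rows, cols)}]")
    if rows >= 2 * cols:
        Q, R = np.linalg.qr(A)
        Ur, s, Vt = np.linalg.svd(R, full_matrices=False)
        U = Q @ Ur
    else:
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
    return SVDFactors(U=U[:, :rank], s=s[:rank], Vt=Vt[:rank, :], shape=(rows, cols), rank=rank)


def svd_reconstruct(f: SVDFactors, clip: bool = True) -> np.ndarray:
    """Multiply the factors back together; optionally clip into [0, 1]."""
    img = (f.U * f.s) @ f.Vt
    if img.shape != f.shape:
        raise ValueError("reconstruction shape mismatch")
    return np.clip(img, 0.0, 1.0) if clip else img


def choose_rank(singular_values, energy_fraction: float) -> int:
    """Smallest k whose leading singular values carry >= energy_fraction
    of the total squared energy."""
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular value vector")
    if not 0 < energy_fraction <= 1:
        raise ValueError("energy_fraction must be in (0, 1]")
    energy = s**2
    total = energy.sum()
    if total == 0:
        return 1
    cum = np.cumsum(energy) / total
    return int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)


def similarity(a, b) -> float:
    """Bhattacharyya coefficient exp(-Db) in [0, 1]; 1 iff identical."""
    return bhattacharyya_coefficient(a, b)


def image_distribution(image) -> np.ndarray:
    """The feature distribution the 70% rule is measured on."""
    img = np.asarray(image, dtype=float)
    mask = segment(img, method="otsu")
    if not mask.any() or mask.all():
        mask = np.ones_like(img, dtype=bool)
    return features_to_distribution(extract_features(img, mask))


def encode_entry_payload(kind: str, fields: dict[str, str]) -> str:
    """Versioned key=value payload text, values percent-escaped."""
    lines = ["QDL1", f"kind={kind}"]
    for k, v in fields.items():
        lines.append(f"{k}={urllib.parse.quote(str(v), safe='')}")
    return "\n".join(lines)


def parse_entry_payload(text: str) -> tuple[str, dict[str, str]]:
    lines = text.splitlines()
    if not lines or lines[0] != "QDL1":
        raise ValueError("not a QDL1 payload")
    kind = None
    fields: dict[str, str] = {}
    for line in lines[1:]:
        k, _, v = line.partition("=")
        if k == "kind":
            kind = v
        else:
            fields[k] = urllib.parse.unquote(v)
    if kind is None:
        raise ValueError("payload missing kind")
    return kind, fields


_MAX_PAYLOAD_BYTES = 2000  # stay safely inside version-40 byte capacity


def ingest(
    record: MetadataRecord,
    image,
    store: StoreIndex,
    energy_fraction: float = 0.95,
    threshold: float = TAG_THRESHOLD,
    ec_level: str = "M",
    dedup: bool = True,
) -> StoreEntry:
    """Add one record+image; near-duplicates become tags, others full entries."""
    key = record.record_id
    if key in store.entries:
        raise KeyError(f"duplicate key {key!r}")
    img = np.asarray(image, dtype=float)
    dist = image_distribution(img)

    best_key, best_sim = store.best_match(dist) if dedup else (None, -1.0)
    if best_key is not None and best_sim > threshold:
        target = store.resolve(best_key).key  # flatten: never tag a tag
        payload_text = encode_entry_payload(
            "tag",
            {"key": key, "tag": target, "similarity": f"{best_sim:.6f}", "checksum": record.checksum},
        )
        entry = StoreEntry(
            key=key,
            record=record,
            qr_payload=payload_text,
            tag_ref=target,
            similarity=best_sim,
        )
    else:
        full = np.linalg.svd(img, compute_uv=False)
        rank = choose_rank(full, energy_fraction)
        factors = svd_compress(img, rank)
        fields = dict(record.to_dict())
        fields["shape"] = f"{img.shape[0]}x{img.shape[1]}"
        fields["rank"] = str(rank)
        payload_text = encode_entry_payload("full", {"key": key, **fields})
        if len(payload_text.encode("latin-1")) > _MAX_PAYLOAD_BYTES:
            payload_text = encode_entry_payload("ref", {"key": key, "checksum": record.checksum})
        entry = StoreEntry(key=key, record=record, qr_payload=payload_text, compressed=factors)

    symbol = build_symbol(Payload.make(payload_text, mode="byte"), ec_level=ec_level)
    if store.root is not None:
        qr_path = store.root / "qr" / f"{key}.png"
        save_image_png(render(symbol).image, qr_path)
        entry.qr_image_ref = str(qr_path)
        if entry.compressed is not None:
            save_factors(entry.compressed, store.root / "factors" / f"{key}.bin")
    store.entries[key] = entry
    store.features[key] = dist
    if store.root is not None:
        store.save()
    return entry


def retrieve(store: StoreIndex, key_or_qr) -> tuple[MetadataRecord, np.ndarray]:
    """Fetch (record, reconstructed image) by key or by scanned QR image."""
    if isinstance(key_or_qr, str):
        key = key_or_qr
    else:
        payload = decode_symbol(key_or_qr)
        _, fields = parse_entry_payload(payload.content)
        key = fields["key"]
    if key not in store.entries:
        raise KeyError(f"unknown key {key!r}")
    entry = store.entries[key]
    source = store.resolve(key)
    if source.compressed is None:
        raise ValueError(f"entry {key!r} resolves to a tag without factors")
    return entry.record, svd_reconstruct(source.compressed)


# -- factor file format -----------------------------------------------------
# magic "QDLF" | uint32 rank, rows, cols (little endian) | float64 row-major
# arrays U (rows*rank), s (rank), Vt (rank*cols)


def save_factors(f: SVDFactors, path: str | Path) -> None:
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(_FACTOR_MAGIC)
        fh.write(struct.pack("<III", f.rank, f.shape[0], f.shape[1]))
        fh.write(f.U.astype("<f8").tobytes())
        fh.write(f.s.astype("<f8").tobytes())
        fh.write(f.Vt.astype("<f8").tobytes())


def load_factors(path: str | Path) -> SVDFactors:
    raw = Path(path).read_bytes()
    if raw[:4] != _FACTOR_MAGIC:
        raise ValueError("not a factor file")
    rank, rows, cols = struct.unpack("<III", raw[4:16])
    vals = np.frombuffer(raw[16:], dtype="<f8")
    u_n = rows * rank
    U = vals[:u_n].reshape(rows, rank)
    s = vals[u_n : u_n + rank]
    Vt = vals[u_n + rank :].reshape(rank, cols)
    return SVDFactors(U=U, s=s, Vt=Vt, shape=(rows, cols), rank=rank)
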