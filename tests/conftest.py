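"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from qdl.qr import tables
from qdl.qr.encode import QRSymbol, data_module_order


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_64():
    from qdl.synth import PhantomSpec, generate_phantom_image

    spec = PhantomSpec(width=64, height=64, n_blobs=3, noise_sigma=0.02, seed=1)
    image, mask = generate_phantom_image(spec)
    return image, mask, spec


def random_simplex(rng: np.random.Generator, dim: int) -> np.ndarray:
    return rng.dirichlet(np.ones(dim))


def knn_label_agreement(Y: np.ndarray, labels: np.ndarray, k: int = 5) -> float:
    """Fraction of k-NN neighbours sharing the query's label."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(Y))
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    return float((np.asarray(labels)[nn] == np.asarray(labels)[:, None]).mean())


def stream_byte_positions(symbol: QRSymbol) -> list[list[tuple[int, int]]]:
    """Module positions of each interleaved codeword byte in a built symbol."""
    order = data_module_order(symbol.version, symbol.reserved)
    n_codewords = tables.total_codewords(symbol.version, symbol.ec_level)
    return [order[8 * i : 8 * i + 8] for i in range(n_codewords)]


def block_to_stream_map(version: int, ec_level: str) -> dict[tuple[int, str, int], int]:
    """(block index, 'data'|'ec', byte index within block) -> stream position."""
    ec_per_block, groups = tables.block_structure(version, ec_level)
    data_lens = [d for n_blocks, d in groups for _ in range(n_blocks)]
    mapping: dict[tuple[int, str, int], int] = {}
    pos = 0
    for i in range(max(data_lens)):
        for b, dl in enumerate(data_lens):
            if i < dl:
                mapping[(b, "data", i)] = pos
                pos += 1
    for i in range(ec_per_block):
        for b in range(len(data_lens)):
            mapping[(b, "ec", i)] = pos
            pos += 1
    return mapping


def corrupt_symbol_bytes(symbol: QRSymbol, per_block: int, rng: np.random.Generator) -> QRSymbol:
    """Flip all 8 modules of ``per_block`` random codeword bytes per block."""
    import copy

    ec_per_block, groups = tables.block_structure(symbol.version, symbol.ec_level)
    data_lens = [d for n_blocks, d in groups for _ in range(n_blocks)]
    positions = stream_byte_positions(symbol)
    mapping = block_to_stream_map(symbol.version, symbol.ec_level)
    out = copy.deepcopy(symbol)
    for b, dl in enumerate(data_lens):
        slots = [("data", i) for i in range(dl)] + [("ec", i) for i in range(ec_per_block)]
        chosen = rng.choice(len(slots), size=per_block, replace=False)
        for s in chosen:
            kind, i = slots[int(s)]
            for r, c in positions[mapping[(b, kind, i)]]:
                out.matrix[r, c] = ~out.matrix[r, c]
    return out
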