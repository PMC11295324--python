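"""QR symbol construction: bit encoding, matrix placement, masking, render."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qdl.qr import tables
from qdl.qr.gf import rs_ec_codewords
from qdl.synth import ALPHANUMERIC_CHARSET

__all__ = [
    "Payload",
    "QRSymbol",
    "SymbolImage",
    "QRCapacityError",
    "classify_mode",
    "encode_payload_bits",
    "build_symbol",
    "mask_penalty",
    "render",
    "function_pattern_map",
    "data_module_order",
    "place_format_info",
    "mask_matrix",
]

_ALNUM_INDEX = {c: i for i, c in enumerate(ALPHANUMERIC_CHARSET)}


class QRCapacityError(ValueError):
    """Payload does not fit the requested (version, ec_level)."""


def classify_mode(content: str | bytes) -> str:
    """Cheapest mode able to carry the content: numeric, alphanumeric, byte."""
    if isinstance(content, bytes):
        text = content.decode("latin-1")
    else:
        text = content
    if text and all(c.isdigit() for c in text):
        return "numeric"
    if text and all(c in _ALNUM_INDEX for c in text):
        return "alphanumeric"
    return "byte"


@dataclass(frozen=True)
class Payload:
    """Content plus its (auto-selected) encoding mode."""

    content: str
    mode: str

    @classmethod
    def make(cls, content: str | bytes, mode: str | None = None) -> "Payload":
        if isinstance(content, bytes):
            content = content.decode("latin-1")
        if len(content) < 1:
            raise ValueError("payload must have length >= 1")
        selected = mode or classify_mode(content)
        if selected == "numeric" and not content.isdigit():
            raise ValueError("numeric mode requires digits only")
        if selected == "alphanumeric" and not all(c in _ALNUM_INDEX for c in content):
            raise ValueError("content outside the 45-character alphanumeric alphabet")
        if selected not in tables.MODE_INDICATOR:
            raise ValueError(f"unknown mode {selected!r}")
        return cls(content=content, mode=selected)

    def to_bytes(self) -> bytes:
        return self.content.encode("latin-1")


@dataclass
class QRSymbol:
    """A built symbol: module matrix plus the parameters that shaped it."""

    version: int
    ec_level: str
    mask_id: int
    matrix: np.ndarray  # bool, True = dark
    reserved: np.ndarray  # bool, True = function-pattern module

    @property
    def side(self) -> int:
        return tables.side_length(self.version)


@dataclass
class SymbolImage:
    """Raster rendering of a symbol (float image, 0.0 = dark, 1.0 = light)."""

    image: np.ndarray
    module_size: int
    quiet_zone: int


class _BitBuffer:
    def __init__(self) -> None:
        self.bits: list[int] = []

    def append(self, value: int, width: int) -> None:
        for shift in range(width - 1, -1, -1):
            self.bits.append((value >> shift) & 1)

    def __len__(self) -> int:
        return len(self.bits)


def _encode_data_bits(payload: Payload, buf: _BitBuffer) -> None:
    content = payload.content
    if payload.mode == "numeric":
        for i in range(0, len(content), 3):
            group = content[i : i + 3]
            buf.append(int(group), {3: 10, 2: 7, 1: 4}[len(group)])
    elif payload.mode == "alphanumeric":
        for i in range(0, len(content), 2):
            pair = content[i : i + 2]
            if len(pair) == 2:
                buf.append(_ALNUM_INDEX[pair[0]] * 45 + _ALNUM_INDEX[pair[1]], 11)
            else:
                buf.append(_ALNUM_INDEX[pair[0]], 6)
    else:
        for b in payload.to_bytes():
            buf.append(b, 8)


def _bit_cost(payload: Payload, version: int) -> int:
    n = len(payload.content)
    cc = tables.char_count_width(payload.mode, version)
    if payload.mode == "numeric":
        data = 10 * (n // 3) + {0: 0, 1: 4, 2: 7}[n % 3]
    elif payload.mode == "alphanumeric":
        data = 11 * (n // 2) + 6 * (n % 2)
    else:
        data = 8 * n
    return 4 + cc + data


def smallest_version(payload: Payload, ec_level: str) -> int:
    for v in range(1, 41):
        if _bit_cost(payload, v) <= 8 * tables.data_capacity_codewords(v, ec_level):
            return v
    raise QRCapacityError(f"payload of {len(payload.content)} characters exceeds version 40 capacity at level {ec_level}")


def encode_payload_bits(payload: Payload, version: int, ec_level: str) -> list[int]:
    """Data codewords (bytes) for one payload at a given version and level.

    Layout: mode indicator, character-count indicator, encoded data,
    terminator of at most 4 zero bits, zero-pad to a byte boundary, then
    alternating pad bytes 0xEC / 0x11 up to the data capacity.  A payload
    exactly filling the capacity receives no terminator or pad bytes.
    """
    capacity_bits = 8 * tables.data_capacity_codewords(version, ec_level)
    if _bit_cost(payload, version) > capacity_bits:
        smallest = None
        try:
            smallest = smallest_version(payload, ec_level)
        except QRCapacityError:
            pass
        hint = f"; smallest sufficient version is {smallest}" if smallest else ""
        raise QRCapacityError(
            f"payload does not fit version {version} level {ec_level}{hint}"
        )
    buf = _BitBuffer()
    buf.append(tables.MODE_INDICATOR[payload.mode], 4)
    buf.append(len(payload.content), tables.char_count_width(payload.mode, version))
    _encode_data_bits(payload, buf)
    buf.append(0, min(4, capacity_bits - len(buf)))  # terminator
    if len(buf) % 8:
        buf.append(0, 8 - len(buf) % 8)
    codewords = [
        int("".join(map(str, buf.bits[i : i + 8])), 2) for i in range(0, len(buf), 8)
    ]
    pads = (capacity_bits // 8) - len(codewords)
    for i in range(pads):
        codewords.append(0xEC if i % 2 == 0 else 0x11)
    return codewords


def split_blocks(codewords: list[int], version: int, ec_level: str) -> list[tuple[list[int], list[int]]]:
    """Split data codewords into blocks and compute EC codewords per block."""
    ec_per_block, groups = tables.block_structure(version, ec_level)
    blocks = []
    pos = 0
    for n_blocks, n_data in groups:
        for _ in range(n_blocks):
            data = codewords[pos : pos + n_data]
            pos += n_data
            blocks.append((data, rs_ec_codewords(data, ec_per_block)))
    if pos != len(codewords):
        raise ValueError("codeword count does not match block structure")
    return blocks


def interleave_blocks(blocks: list[tuple[list[int], list[int]]]) -> list[int]:
    out: list[int] = []
    max_data = max(len(d) for d, _ in blocks)
    for i in range(max_data):
        for data, _ in blocks:
            if i < len(data):
                out.append(data[i])
    max_ec = max(len(e) for _, e in blocks)
    for i in range(max_ec):
        for _, ec in blocks:
            if i < len(ec):
                out.append(ec[i])
    return out


# ---------------------------------------------------------------------------
# matrix construction


def function_pattern_map(version: int) -> tuple[np.ndarray, np.ndarray]:
    """(modules, reserved) with all function patterns placed.

    ``reserved`` flags every module not available for data: finders with
    separators, timing patterns, alignment patterns, the dark module, and
    the format/version information areas.
    """
    n = tables.side_length(version)
    modules = np.zeros((n, n), dtype=bool)
    reserved = np.zeros((n, n), dtype=bool)

    def put(r: int, c: int, dark: bool) -> None:
        modules[r, c] = dark
        reserved[r, c] = True

    def place_finder(r0: int, c0: int) -> None:
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < n and 0 <= c < n):
                    continue
                dark = (
                    (0 <= dr <= 6 and dc in (0, 6))
                    or (0 <= dc <= 6 and dr in (0, 6))
                    or (2 <= dr <= 4 and 2 <= dc <= 4)
                )
                put(r, c, dark)

    place_finder(0, 0)
    place_finder(0, n - 7)
    place_finder(n - 7, 0)

    for i in range(8, n - 8):  # timing
        put(6, i, i % 2 == 0)
        put(i, 6, i % 2 == 0)

    centers = tables.ALIGNMENT_POSITIONS[version]
    for r0 in centers:
        for c0 in centers:
            overlaps_finder = (
                (r0 <= 8 and c0 <= 8) or (r0 <= 8 and c0 >= n - 9) or (r0 >= n - 9 and c0 <= 8)
            )
            if overlaps_finder:
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    put(r0 + dr, c0 + dc, max(abs(dr), abs(dc)) != 1)

    put(n - 8, 8, True)  # dark module

    # reserve format info areas (bits written later)
    for i in range(9):
        if i != 6:
            reserved[8, i] = True
            reserved[i, 8] = True
    reserved[8, n - 8 : n] = True
    reserved[n - 7 : n, 8] = True

    if version >= 7:
        reserved[0:6, n - 11 : n - 8] = True
        reserved[n - 11 : n - 8, 0:6] = True

    return modules, reserved


def data_module_order(version: int, reserved: np.ndarray) -> list[tuple[int, int]]:
    """Zig-zag placement order over non-reserved modules (standard order)."""
    n = tables.side_length(version)
    order: list[tuple[int, int]] = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:  # timing column is skipped entirely
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for r in rows:
            for c in (col, col - 1):
                if not reserved[r, c]:
                    order.append((r, c))
        upward = not upward
        col -= 2
    return order


_MASK_FUNCS = (
    lambda r, c: (r + c) % 2 == 0,
    lambda r, c: r % 2 == 0,
    lambda r, c: c % 3 == 0,
    lambda r, c: (r + c) % 3 == 0,
    lambda r, c: (r // 2 + c // 3) % 2 == 0,
    lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    lambda r, c: ((r * c) % 3 + (r + c) % 2) % 2 == 0,
)


def mask_matrix(modules: np.ndarray, reserved: np.ndarray, mask_id: int) -> np.ndarray:
    """Flip data modules where the mask condition holds."""
    n = modules.shape[0]
    rr, cc = np.mgrid[0:n, 0:n]
    cond = np.vectorize(_MASK_FUNCS[mask_id])(rr, cc)
    return np.where(~reserved & cond, ~modules, modules)


def mask_penalty(matrix: np.ndarray) -> int:
    """Sum of the four standard penalty rules for a boolean module matrix."""
    m = np.asarray(matrix, dtype=bool)
    n = m.shape[0]
    total = 0

    def run_penalty(line: np.ndarray) -> int:
        score = 0
        run = 1
        for i in range(1, len(line)):
            if line[i] == line[i - 1]:
                run += 1
            else:
                if run >= 5:
                    score += 3 + (run - 5)
                run = 1
        if run >= 5:
            score += 3 + (run - 5)
        return score

    for i in range(n):  # rule 1: runs
        total += run_penalty(m[i]) + run_penalty(m[:, i])

    blocks = (m[:-1, :-1] == m[1:, :-1]) & (m[:-1, :-1] == m[:-1, 1:]) & (m[:-1, :-1] == m[1:, 1:])
    total += 3 * int(blocks.sum())  # rule 2: 2x2 blocks

    pat_a = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
    patterns = (pat_a, pat_a[::-1])

    def finder_like(line: np.ndarray) -> int:
        count = 0
        for start in range(len(line) - 10):
            window = line[start : start + 11]
            if any(np.array_equal(window, p) for p in patterns):
                count += 1
        return count

    for i in range(n):  # rule 3: 1:1:3:1:1 with 4-module light flank
        total += 40 * (finder_like(m[i]) + finder_like(m[:, i]))

    dark_pct = 100.0 * m.sum() / m.size  # rule 4: dark proportion
    total += 10 * int(abs(dark_pct - 50) // 5)
    return total


def place_format_info(modules: np.ndarray, ec_level: str, mask_id: int) -> None:
    """Write both copies of the 15-bit format word into the matrix."""
    n = modules.shape[0]
    bits = tables.format_info_bits(ec_level, mask_id)
    for i in range(15):
        bit = bool((bits >> i) & 1)
        # copy 1: around the top-left finder
        if i < 6:
            modules[i, 8] = bit
        elif i < 8:
            modules[i + 1, 8] = bit
        else:
            modules[n - 15 + i, 8] = bit
        # copy 2
        if i < 8:
            modules[8, n - 1 - i] = bit
        elif i < 9:
            modules[8, 15 - i - 1 + 1] = bit
        else:
            modules[8, 15 - i - 1] = bit


def _place_version_info(modules: np.ndarray, version: int) -> None:
    n = modules.shape[0]
    bits = tables.version_info_bits(version)
    for i in range(18):
        bit = bool((bits >> i) & 1)
        modules[i // 3, i % 3 + n - 11] = bit
        modules[i % 3 + n - 11, i // 3] = bit


def build_symbol(
    payload: Payload | str | bytes,
    ec_level: str = "M",
    version: int | None = None,
) -> QRSymbol:
    """Build a complete symbol, choosing the lowest-penalty mask.

    All eight masks are evaluated with the four standard penalty rules
    (including format info, which depends on the mask); ties break to the
    lowest mask id.  Construction is fully deterministic.
    """
    if not isinstance(payload, Payload):
        payload = Payload.make(payload)
    if ec_level not in tables.EC_LEVELS:
        raise ValueError(f"unknown EC level {ec_level!r}")
    if version is None:
        version = smallest_version(payload, ec_level)
    codewords = encode_payload_bits(payload, version, ec_level)
    stream = interleave_blocks(split_blocks(codewords, version, ec_level))

    base, reserved = function_pattern_map(version)
    order = data_module_order(version, reserved)
    bits = [(byte >> (7 - k)) & 1 for byte in stream for k in range(8)]
    bits += [0] * (len(order) - len(bits))  # remainder bits
    for (r, c), bit in zip(order, bits):
        base[r, c] = bool(bit)

    best = None
    for mask_id in range(8):
        candidate = mask_matrix(base, reserved, mask_id)
        place_format_info(candidate, ec_level, mask_id)
        if version >= 7:
            _place_version_info(candidate, version)
        penalty = mask_penalty(candidate)
        if best is None or penalty < best[0]:
            best = (penalty, mask_id, candidate)
    _, mask_id, matrix = best
    return QRSymbol(version=version, ec_level=ec_level, mask_id=mask_id, matrix=matrix, reserved=reserved)


def render(symbol: QRSymbol, module_size: int = 4, quiet_zone: int = 4) -> SymbolImage:
    """Rasterize with a light quiet zone (>= 4 modules by default)."""
    if module_size < 1:
        raise ValueError("module_size must be >= 1")
    if quiet_zone < 0:
        raise ValueError("quiet_zone must be >= 0")
    dark = np.kron(symbol.matrix, np.ones((module_size, module_size), dtype=bool))
    pad = quiet_zone * module_size
    image = np.ones(
        (dark.shape[0] + 2 * pad, dark.shape[1] + 2 * pad), dtype=float
    )
    inner = np.where(dark, 0.0, 1.0)
    image[pad : pad + dark.shape[0], pad : pad + dark.shape[1]] = inner
    return SymbolImage(image=image, module_size=module_size, quiet_zone=quiet_zone)
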