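"""Standard QR tables: EC block structure, alignment grid, format/version info.

The error-correction block table is shipped as ``data/ec_blocks.csv``
(columns: version, ec_level, ec_per_block, group1_blocks, group1_data,
group2_blocks, group2_data).  Consistency with the module-capacity of each
symbol version is asserted by the test suite.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

EC_LEVELS = ("L", "M", "Q", "H")

#: 2-bit error-correction level indicators used in the format information.
EC_LEVEL_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}
EC_BITS_LEVEL = {v: k for k, v in EC_LEVEL_BITS.items()}

FORMAT_MASK = 0x5412
_FORMAT_GEN = 0b10100110111  # BCH(15,5) generator
_VERSION_GEN = 0b1111100100101  # BCH(18,6) generator

MODE_INDICATOR = {"numeric": 0b0001, "alphanumeric": 0b0010, "byte": 0b0100}
INDICATOR_MODE = {v: k for k, v in MODE_INDICATOR.items()}

ALIGNMENT_POSITIONS: dict[int, tuple[int, ...]] = {
    1: (),
    2: (6, 18),
    3: (6, 22),
    4: (6, 26),
    5: (6, 30),
    6: (6, 34),
    7: (6, 22, 38),
    8: (6, 24, 42),
    9: (6, 26, 46),
    10: (6, 28, 50),
    11: (6, 30, 54),
    12: (6, 32, 58),
    13: (6, 34, 62),
    14: (6, 26, 46, 66),
    15: (6, 26, 48, 70),
    16: (6, 26, 50, 74),
    17: (6, 30, 54, 78),
    18: (6, 30, 56, 82),
    19: (6, 30, 58, 86),
    20: (6, 34, 62, 90),
    21: (6, 28, 50, 72, 94),
    22: (6, 26, 50, 74, 98),
    23: (6, 30, 54, 78, 102),
    24: (6, 28, 54, 80, 106),
    25: (6, 32, 58, 84, 110),
    26: (6, 30, 58, 86, 114),
    27: (6, 34, 62, 90, 118),
    28: (6, 26, 50, 74, 98, 122),
    29: (6, 30, 54, 78, 102, 126),
    30: (6, 26, 52, 78, 104, 130),
    31: (6, 30, 56, 82, 108, 134),
    32: (6, 34, 60, 86, 112, 138),
    33: (6, 30, 58, 86, 114, 142),
    34: (6, 34, 62, 90, 118, 146),
    35: (6, 30, 54, 78, 102, 126, 150),
    36: (6, 24, 50, 76, 102, 128, 154),
    37: (6, 28, 54, 80, 106, 132, 158),
    38: (6, 32, 58, 84, 110, 136, 162),
    39: (6, 26, 54, 82, 110, 138, 166),
    40: (6, 30, 58, 86, 114, 142, 170),
}


def side_length(version: int) -> int:
    if not 1 <= version <= 40:
        raise ValueError("version must be in 1..40")
    return 17 + 4 * version


@lru_cache(maxsize=1)
def _ec_table() -> dict[tuple[int, str], tuple[int, list[tuple[int, int]]]]:
    table: dict[tuple[int, str], tuple[int, list[tuple[int, int]]]] = {}
    with resources.files("qdl.qr").joinpath("data/ec_blocks.csv").open() as fh:
        for row in csv.DictReader(fh):
            v = int(row["version"])
            groups = [(int(row["group1_blocks"]), int(row["group1_data"]))]
            if int(row["group2_blocks"]) > 0:
                groups.append((int(row["group2_blocks"]), int(row["group2_data"])))
            table[(v, row["ec_level"])] = (int(row["ec_per_block"]), groups)
    return table


def block_structure(version: int, ec_level: str) -> tuple[int, list[tuple[int, int]]]:
    """(ec codewords per block, [(n_blocks, data codewords per block), ...])."""
    try:
        return _ec_table()[(version, ec_level)]
    except KeyError:
        raise ValueError(f"no block structure for version {version} level {ec_level!r}") from None


def data_capacity_codewords(version: int, ec_level: str) -> int:
    _, groups = block_structure(version, ec_level)
    return sum(n * d for n, d in groups)


def total_codewords(version: int, ec_level: str) -> int:
    ec, groups = block_structure(version, ec_level)
    return sum(n * (d + ec) for n, d in groups)


def char_count_width(mode: str, version: int) -> int:
    """Bit width of the character-count indicator for a mode and version."""
    cls = 0 if version <= 9 else (1 if version <= 26 else 2)
    widths = {
        "numeric": (10, 12, 14),
        "alphanumeric": (9, 11, 13),
        "byte": (8, 16, 16),
    }
    return widths[mode][cls]


def _bch_remainder(value: int, generator: int, total_bits: int, data_bits: int) -> int:
    rem = value << (total_bits - data_bits)
    gen_deg = generator.bit_length() - 1
    for shift in range(total_bits - 1, gen_deg - 1, -1):
        if rem & (1 << shift):
            rem ^= generator << (shift - gen_deg)
    return rem


def format_info_bits(ec_level: str, mask_id: int) -> int:
    """15-bit BCH-protected format word, XOR-masked with 0x5412."""
    if not 0 <= mask_id <= 7:
        raise ValueError("mask_id must be in 0..7")
    data = (EC_LEVEL_BITS[ec_level] << 3) | mask_id
    return ((data << 10) | _bch_remainder(data, _FORMAT_GEN, 15, 5)) ^ FORMAT_MASK


def version_info_bits(version: int) -> int:
    """18-bit BCH-protected version word (defined for version >= 7)."""
    if version < 7:
        raise ValueError("version information exists only for version >= 7")
    return (version << 12) | _bch_remainder(version, _VERSION_GEN, 18, 6)


@lru_cache(maxsize=1)
def all_format_words() -> dict[int, tuple[str, int]]:
    """All 32 valid format words -> (ec_level, mask_id); decoding table."""
    return {
        format_info_bits(level, mask): (level, mask)
        for level in EC_LEVELS
        for mask in range(8)
    }
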