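"""Bit-vector helpers.

Bit vectors are plain ``numpy`` ``uint8`` arrays over {0, 1}.  Byte <-> bit
conversions are MSB-first, matching the big-endian index/CRC framing used
throughout the codec.
"""

from __future__ import annotations

import numpy as np


def as_bits(obj) -> np.ndarray:
    """Coerce a sequence of 0/1 (list, str, array) to a uint8 bit vector."""
    if isinstance(obj, str):
        arr = np.frombuffer(obj.encode(), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(obj, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("bit vector must be one-dimensional")
    if arr.size and arr.max() > 1:
        raise ValueError("bit vector entries must be 0 or 1")
    return arr


def bits_from_bytes(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bytes_from_bits(bits: np.ndarray) -> bytes:
    bits = as_bits(bits)
    if bits.size % 8:
        raise ValueError("bit length must be a multiple of 8")
    return np.packbits(bits).tobytes()


def bits_from_int(value: int, width: int) -> np.ndarray:
    """Big-endian fixed-width bit representation of a non-negative int."""
    if value < 0 or value >= (1 << width):
        raise ValueError(f"value {value} does not fit in {width} bits")
    return np.array([(value >> (width - 1 - i)) & 1 for i in range(width)],
                    dtype=np.uint8)


def int_from_bits(bits: np.ndarray) -> int:
    out = 0
    for b in np.asarray(bits, dtype=np.uint8):
        out = (out << 1) | int(b)
    return out
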