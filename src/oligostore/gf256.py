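"""GF(2^8) arithmetic for the Reed-Solomon outer code.

Field generated by the primitive polynomial x^8 + x^4 + x^3 + x^2 + 1
(0x11d).  The outer code is a generalized Reed-Solomon code in evaluation
form: the k data bytes of a block column are interpolated by the unique
polynomial of degree < k through the points (x_0..x_{k-1}), and parity bytes
are its values at further distinct points.  Any k surviving points recover
the rest (MDS erasure property), which is all the erasure-only channel needs.
"""

from __future__ import annotations

import numpy as np

_PRIM = 0x11D

EXP = np.zeros(512, dtype=np.uint8)
LOG = np.zeros(256, dtype=np.int32)
_x = 1
for _i in range(255):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
EXP[255:510] = EXP[:255]


def gf_mul(a, b):
    """Elementwise product in GF(256); accepts scalars or arrays."""
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    out = EXP[(LOG[a] + LOG[b]) % 255]
    return np.where((a == 0) | (b == 0), 0, out).astype(np.uint8)


def gf_inv(a):
    a = np.asarray(a, dtype=np.uint8)
    if np.any(a == 0):
        raise ZeroDivisionError("inverse of 0 in GF(256)")
    return EXP[255 - LOG[a]].astype(np.uint8)


def lagrange_matrix(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Interpolation matrix M with values[dst] = M @ values[src] over GF(256).

    ``src`` and ``dst`` are distinct field elements (0..255 allowed); the
    polynomial through the src points (degree < len(src)) is evaluated at the
    dst points.  Addition/subtraction in GF(2^8) are both XOR.
    """
    src = np.asarray(src, dtype=np.uint8)
    dst = np.asarray(dst, dtype=np.uint8)
    if len(set(src.tolist())) != src.size:
        raise ValueError("src points must be distinct")
    k = src.size
    M = np.zeros((dst.size, k), dtype=np.uint8)
    for i in range(k):
        num = np.ones(dst.size, dtype=np.uint8)
        den = np.uint8(1)
        for j in range(k):
            if j == i:
                continue
            num = gf_mul(num, dst ^ src[j])
            den = gf_mul(den, src[i] ^ src[j])
        M[:, i] = gf_mul(num, gf_inv(den))
    return M


def gf_matmul(M: np.ndarray, V: np.ndarray) -> np.ndarray:
    """(t x k) GF matrix times (k x n) GF matrix -> (t x n)."""
    M = np.asarray(M, dtype=np.uint8)
    V = np.asarray(V, dtype=np.uint8)
    out = np.zeros((M.shape[0], V.shape[1]), dtype=np.uint8)
    for i in range(M.shape[1]):
        out ^= gf_mul(M[:, i][:, None], V[i][None, :])
    return out
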