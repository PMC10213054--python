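"""Outer code layer: whitening, segmentation, Reed-Solomon erasure parity.

A file is whitened (seeded XOR keystream, standing in for the compression +
encryption a production deployment would apply), split into fixed-size data
segments, and extended with Reed-Solomon parity segments so that whole-oligo
dropout becomes a correctable erasure.  Segments are spread over RS blocks
round-robin, so a run of consecutive-index dropouts (the typical signature of
coverage skew) is shared across blocks instead of concentrating in one.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .bits import bits_from_bytes, bytes_from_bits
from .gf256 import gf_matmul, lagrange_matrix


class ErasureError(Exception):
    """Raised when some RS block has more erasures than parity symbols."""

    def __init__(self, message: str, failed_blocks: list[int]):
        super().__init__(message)
        self.failed_blocks = failed_blocks


@dataclass(frozen=True)
class RSParams:
    """Reed-Solomon geometry: per-block k data + p parity byte-segments."""

    data_segments_per_block: int
    parity_segments_per_block: int

    def __post_init__(self):
        k, p = self.data_segments_per_block, self.parity_segments_per_block
        if k < 1 or p < 0:
            raise ValueError("need k >= 1 and p >= 0")
        if k + p > 255:
            raise ValueError("k + p must be <= 255 for GF(256) symbols")

    @property
    def k(self) -> int:
        return self.data_segments_per_block

    @property
    def p(self) -> int:
        return self.parity_segments_per_block


@dataclass
class SegmentRecord:
    """One oligo's outer-layer message: index + fixed-size payload bits."""

    index: int
    payload_bits: np.ndarray
    is_parity: bool = False

    @property
    def payload_bytes(self) -> bytes:
        return bytes_from_bits(self.payload_bits)


def whiten(data: bytes, seed: int) -> bytes:
    """XOR with a seeded pseudorandom keystream; self-inverse for one seed."""
    arr = np.frombuffer(data, dtype=np.uint8)
    key = np.random.Generator(np.random.PCG64(seed)).integers(
        0, 256, size=arr.size, dtype=np.uint8)
    return (arr ^ key).tobytes()


def dewhiten(data: bytes, seed: int) -> bytes:
    return whiten(data, seed)


def n_data_segments(file_bits: int, data_bits_per_segment: int) -> int:
    return -(-file_bits // data_bits_per_segment)


def block_count_for(n_data: int, params: RSParams) -> int:
    return -(-n_data // params.k)


def index_width(n_total_segments: int) -> int:
    """Fixed index width: ceil(log2(total segments)), at least 1 bit."""
    if n_total_segments < 1:
        raise ValueError("need at least one segment")
    return max(1, int(np.ceil(np.log2(n_total_segments))))


def segment_file(data: bytes, data_bits_per_segment: int) -> list[SegmentRecord]:
    """Split (already whitened) bytes into zero-padded data segments.

    ``data_bits_per_segment`` must be a positive multiple of 8 so RS parity
    can operate on byte columns.
    """
    if not data:
        raise ValueError("empty file")
    if data_bits_per_segment <= 0 or data_bits_per_segment % 8:
        raise ValueError("data_bits_per_segment must be a positive multiple of 8")
    bits = bits_from_bytes(data)
    n_seg = n_data_segments(bits.size, data_bits_per_segment)
    padded = np.zeros(n_seg * data_bits_per_segment, dtype=np.uint8)
    padded[:bits.size] = bits
    return [SegmentRecord(i, padded[i * data_bits_per_segment:
                                    (i + 1) * data_bits_per_segment])
            for i in range(n_seg)]


def _block_members(n_data: int, n_blocks: int, b: int) -> np.ndarray:
    """Data-segment indices of block ``b`` under round-robin interleaving."""
    return np.arange(b, n_data, n_blocks)


def rs_extend(segments: list[SegmentRecord], params: RSParams,
              block_count: int | None = None) -> list[SegmentRecord]:
    """Append RS parity segments; data segment i joins block i mod B."""
    n_data = len(segments)
    if any(s.is_parity for s in segments):
        raise ValueError("input segments must all be data segments")
    if params.p == 0:
        return list(segments)
    B = block_count if block_count is not None else block_count_for(n_data, params)
    out = list(segments)
    data = np.stack([np.frombuffer(s.payload_bytes, dtype=np.uint8)
                     for s in segments])
    for b in range(B):
        members = _block_members(n_data, B, b)
        k_b = members.size
        if k_b + params.p > 255:
            raise ValueError("block size k + p exceeds 255")
        src = np.arange(k_b, dtype=np.uint8)
        dst = np.arange(k_b, k_b + params.p, dtype=np.uint8)
        parity = gf_matmul(lagrange_matrix(src, dst), data[members])
        for j in range(params.p):
            idx = n_data + b * params.p + j
            out.append(SegmentRecord(idx, bits_from_bytes(parity[j].tobytes()),
                                     is_parity=True))
    return out


def _dedupe(received: list[SegmentRecord]) -> dict[int, np.ndarray]:
    """Per-byte majority vote across duplicate indices; ties to first seen."""
    by_index: dict[int, list[np.ndarray]] = {}
    for seg in received:
        by_index.setdefault(seg.index, []).append(
            np.frombuffer(seg.payload_bytes, dtype=np.uint8))
    out = {}
    for idx, copies in by_index.items():
        if len(copies) == 1:
            out[idx] = copies[0]
            continue
        stacked = np.stack(copies)
        if (stacked == stacked[0]).all():
            out[idx] = copies[0]
            continue
        warnings.warn(f"conflicting duplicate segments at index {idx}; "
                      "taking per-byte majority (ties to first received)")
        resolved = np.empty(stacked.shape[1], dtype=np.uint8)
        for col in range(stacked.shape[1]):
            counts = Counter(stacked[:, col].tolist())
            best = max(counts.values())
            # first received value among those with maximal count
            for v in stacked[:, col]:
                if counts[int(v)] == best:
                    resolved[col] = v
                    break
        out[idx] = resolved
    return out


def rs_recover(received: list[SegmentRecord], params: RSParams,
               n_data: int, file_len_bytes: int,
               whitening_seed: int | None = None,
               block_count: int | None = None) -> bytes:
    """Recover the original file bytes from CRC-clean received segments.

    Missing indices are erasures; any block with more than ``p`` erasures is
    unrecoverable and reported in the raised :class:`ErasureError`.
    """
    B = block_count if block_count is not None else block_count_for(n_data, params)
    have = _dedupe(received)
    seg_bytes = None
    for v in have.values():
        seg_bytes = v.size
        break
    if seg_bytes is None:
        raise ErasureError("no segments received", list(range(B)))
    data = np.zeros((n_data, seg_bytes), dtype=np.uint8)
    failed = []
    for b in range(B):
        members = _block_members(n_data, B, b)
        k_b = members.size
        pos = {int(m): i for i, m in enumerate(members)}
        avail_pts, avail_vals = [], []
        for m in members:
            if int(m) in have:
                avail_pts.append(pos[int(m)])
                avail_vals.append(have[int(m)])
        for j in range(params.p):
            idx = n_data + b * params.p + j
            if idx in have:
                avail_pts.append(k_b + j)
                avail_vals.append(have[idx])
        if len(avail_pts) < k_b:
            failed.append(b)
            continue
        pts = np.array(avail_pts[:k_b], dtype=np.uint8)
        vals = np.stack(avail_vals[:k_b])
        missing = [pos[int(m)] for m in members if int(m) not in have]
        for m in members:
            if int(m) in have:
                data[int(m)] = have[int(m)]
        if missing:
            M = lagrange_matrix(pts, np.array(missing, dtype=np.uint8))
            rec = gf_matmul(M, vals)
            for r, mpos in zip(rec, missing):
                data[int(members[mpos])] = r
    if failed:
        ok = [b for b in range(B) if b not in failed]
        raise ErasureError(
            f"blocks {failed} have more than {params.p} erasures "
            f"(recoverable blocks: {ok})", failed)
    raw = data.ravel().tobytes()[:file_len_bytes]
    if whitening_seed is not None:
        raw = dewhiten(raw, whitening_seed)
    return raw
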