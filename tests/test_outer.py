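"""Outer layer: whitening, segmentation, Reed-Solomon erasure recovery."""

import numpy as np
import pytest

from oligostore.bits import bits_from_bytes
from oligostore.dna import bits_to_bases
from oligostore.outer import (ErasureError, RSParams, SegmentRecord,
                              block_count_for, dewhiten, index_width,
                              rs_extend, rs_recover, segment_file, whiten)


class TestWhitening:
    def test_involution(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 256, 500, dtype=np.uint8).tobytes()
        assert dewhiten(whiten(data, 42), 42) == data
        assert whiten(dewhiten(data, 7), 7) == data

    def test_zero_input_yields_keystream(self):
        z = bytes(64)
        w1 = whiten(z, 1)
        assert w1 != z
        # XOR identity: whitening zeros twice with different seeds differs
        assert whiten(z, 2) != w1

    def test_whitened_zero_file_has_no_long_homopolymers(self):
        """Whitening a pathological (all-zero) file kills homopolymers.

        For 40,000 uniform random bases, P(max run > 10) ~ 0.007 and
        P(max run > 13) ~ 1e-4, so over 100 fixed seeds a keystream that
        behaves like uniform bases yields at most a few 11-runs (binomial
        P(> 4) < 1e-3) and nothing longer.  Without whitening the run would
        be 40,000.
        """
        z = bytes(10_000)
        ok = 0
        worst = 0
        for seed in range(100):
            bases = bits_to_bases(bits_from_bytes(whiten(z, seed)))
            longest = run = 1
            prev = bases[0]
            for b in bases[1:]:
                run = run + 1 if b == prev else 1
                longest = max(longest, run)
                prev = b
            ok += longest <= 10
            worst = max(worst, longest)
        assert ok >= 96
        assert worst <= 13


class TestSegmentation:
    def test_even_split(self):
        segs = segment_file(bytes(range(100)), 80)
        assert len(segs) == 10
        assert [s.index for s in segs] == list(range(10))
        assert all(s.payload_bits.size == 80 for s in segs)

    def test_one_byte_file_padding(self):
        segs = segment_file(b"\xff", 80)
        assert len(segs) == 1
        assert segs[0].payload_bits[:8].sum() == 8
        assert segs[0].payload_bits[8:].sum() == 0  # 72 pad bits

    def test_index_width(self):
        assert index_width(300) == 9
        assert index_width(2) == 1
        assert index_width(256) == 8
        assert index_width(257) == 9


def _make_segments(n, nbytes=6, seed=0):
    rng = np.random.default_rng(seed)
    return [SegmentRecord(i, bits_from_bytes(
        rng.integers(0, 256, nbytes, dtype=np.uint8).tobytes()))
            for i in range(n)]


class TestReedSolomon:
    def test_no_parity_identity(self):
        segs = _make_segments(5)
        assert rs_extend(segs, RSParams(5, 0)) == segs

    def test_erasure_recovery_at_bound(self):
        """Any p dropped segments per block are recovered (MDS property)."""
        rng = np.random.default_rng(1)
        params = RSParams(4, 2)
        segs = _make_segments(8, seed=2)
        data_bytes = b"".join(s.payload_bytes for s in segs)
        ext = rs_extend(segs, params)
        assert len(ext) == 8 + 2 * 2  # two blocks, p=2 each
        B = block_count_for(8, params)
        for _ in range(20):
            drop = set()
            for b in range(B):
                members = list(range(b, 8, B)) + [8 + b * 2, 8 + b * 2 + 1]
                drop |= set(rng.choice(members, size=2, replace=False).tolist())
            received = [s for s in ext if s.index not in drop]
            rec = rs_recover(received, params, n_data=8,
                             file_len_bytes=len(data_bytes))
            assert rec == data_bytes

    def test_beyond_bound_raises_with_block_report(self):
        params = RSParams(4, 2)
        segs = _make_segments(8, seed=3)
        ext = rs_extend(segs, params)
        # drop 3 members of block 0 (indices 0,2,4,6 are data; 8,9 parity)
        received = [s for s in ext if s.index not in (0, 2, 8)]
        with pytest.raises(ErasureError) as e:
            rs_recover(received, params, n_data=8, file_len_bytes=48)
        assert 0 in e.value.failed_blocks

    def test_erasure_threshold_is_sharp(self):
        """p erasures per block always recover; p+1 in one block never does."""
        params = RSParams(5, 3)
        segs = _make_segments(10, seed=4)
        data_bytes = b"".join(s.payload_bytes for s in segs)
        ext = rs_extend(segs, params)
        B = block_count_for(10, params)
        rng = np.random.default_rng(5)
        for trial in range(20):
            members0 = [i for i in range(10) if i % B == 0] + \
                [10 + j for j in range(params.p)]
            drop_ok = rng.choice(members0, size=params.p, replace=False)
            rec = rs_recover([s for s in ext if s.index not in set(drop_ok.tolist())],
                             params, n_data=10, file_len_bytes=len(data_bytes))
            assert rec == data_bytes
            drop_bad = rng.choice(members0, size=params.p + 1, replace=False)
            with pytest.raises(ErasureError):
                rs_recover([s for s in ext if s.index not in set(drop_bad.tolist())],
                           params, n_data=10, file_len_bytes=len(data_bytes))

    def test_duplicate_conflict_majority_vote(self):
        params = RSParams(4, 0)
        segs = _make_segments(4, seed=6)
        data_bytes = b"".join(s.payload_bytes for s in segs)
        corrupt = SegmentRecord(1, segs[1].payload_bits ^ 1)
        with pytest.warns(UserWarning, match="majority"):
            rec = rs_recover(segs + [corrupt] + [segs[1]], params,
                             n_data=4, file_len_bytes=len(data_bytes))
        assert rec == data_bytes
        # tie (1 good copy vs 1 bad copy) -> first received wins
        with pytest.warns(UserWarning, match="majority"):
            rec = rs_recover([corrupt] + segs, params, n_data=4,
                             file_len_bytes=len(data_bytes))
        assert rec != data_bytes

    def test_end_to_end_random_files(self):
        """Whiten -> segment -> extend -> drop <= p per block -> recover."""
        rng = np.random.default_rng(7)
        params = RSParams(8, 2)
        for trial in range(10):
            nbytes = int(rng.integers(500, 4000))
            data = rng.integers(0, 256, nbytes, dtype=np.uint8).tobytes()
            white = whiten(data, trial)
            segs = segment_file(white, 64)
            n_data = len(segs)
            B = block_count_for(n_data, params)
            ext = rs_extend(segs, params)
            drop = set()
            for b in range(B):
                members = list(range(b, n_data, B)) + \
                    [n_data + b * params.p + j for j in range(params.p)]
                k = int(rng.integers(0, params.p + 1))
                drop |= set(rng.choice(members, size=k, replace=False).tolist())
            received = [s for s in ext if s.index not in drop]
            rec = rs_recover(received, params, n_data=n_data,
                             file_len_bytes=nbytes, whitening_seed=trial)
            assert rec == data
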