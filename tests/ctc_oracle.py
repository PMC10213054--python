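"""Brute-force CTC codeword-scoring oracle (test helper).

Scores every possible framed message's codeword against a posterior with an
independent vectorized CTC forward algorithm (the standard interleaved-blank
lattice), entirely separate from the trellis list decoder it is used to
check.
"""

import numpy as np

from oligostore.convcode import conv_encode
from oligostore.dna import bits_to_bases

STATES = "bACGT"
NEG = -1e30


def all_frames(n_bits: int) -> np.ndarray:
    vals = np.arange(2 ** n_bits, dtype=np.int64)
    return ((vals[:, None] >> np.arange(n_bits - 1, -1, -1)) & 1).astype(np.uint8)


def codeword_bases(frame: np.ndarray, spec) -> str:
    cw = conv_encode(frame, spec)
    if cw.size % 2:
        cw = np.concatenate([cw, np.zeros(1, dtype=np.uint8)])
    return bits_to_bases(cw)


def ctc_forward_logprob_batch(mat: np.ndarray, base_idx: np.ndarray
                              ) -> np.ndarray:
    """log P(sequence | posterior) for many equal-length sequences.

    ``base_idx``: (n_seqs, n_bases) 0..3 base values.  Uses the interleaved
    blank lattice b s1 b s2 b ... sn b with the standard CTC transitions.
    """
    lp = np.log(np.maximum(mat, 1e-12))
    ncw, n = base_idx.shape
    ext = 2 * n + 1
    sym = np.zeros((ncw, ext), dtype=np.int64)  # posterior column per lattice state
    sym[:, 1::2] = base_idx + 1
    # allowed skip transition e-2 -> e (only into base states with a
    # different preceding base)
    skip_ok = np.zeros((ncw, ext), dtype=bool)
    if n > 1:
        skip_ok[:, 3::2] = base_idx[:, 1:] != base_idx[:, :-1]
    alpha = np.full((ncw, ext), NEG)
    alpha[:, 0] = lp[0, 0]
    if n:
        alpha[:, 1] = lp[0][sym[:, 1]]
    for t in range(1, mat.shape[0]):
        stay = alpha
        prev1 = np.concatenate([np.full((ncw, 1), NEG), alpha[:, :-1]], axis=1)
        prev2 = np.concatenate([np.full((ncw, 2), NEG), alpha[:, :-2]], axis=1)
        acc = np.logaddexp(stay, prev1)
        acc = np.where(skip_ok, np.logaddexp(acc, prev2), acc)
        alpha = acc + lp[t][sym]
    out = alpha[:, ext - 1]
    if n:
        out = np.logaddexp(out, alpha[:, ext - 2])
    return out


def exhaustive_best_codeword(mat: np.ndarray, spec, frame_bits: int
                             ) -> tuple[np.ndarray, float]:
    """(argmax frame, max log-score) over every possible framed message."""
    frames = all_frames(frame_bits)
    seqs = [codeword_bases(f, spec) for f in frames]
    base_idx = np.array([["ACGT".index(b) for b in s] for s in seqs],
                        dtype=np.int64)
    scores = ctc_forward_logprob_batch(mat, base_idx)
    best = int(scores.argmax())
    return frames[best], float(scores[best])
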