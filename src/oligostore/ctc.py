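"""CTC posterior decoding: greedy collapse, beam search, list-Viterbi.

A CTC posterior is a T x 5 row-stochastic matrix over (blank, A, C, G, T).
A base sequence's probability is the sum over all state paths that collapse
to it (repeated states merge, blanks separate and are removed), so all
decoders here track two scores per candidate - paths ending in blank and
paths ending in the last emitted base - and merge in log domain.

``conv_ctc_list_decode`` is the integrated decoder: candidate base sequences
are constrained to walks of the convolutional-code trellis
(:mod:`oligostore.trellis`), each trellis node keeps the top ``L`` candidate
message prefixes, prefixes reaching a node with equal message content are
merged with logsumexp, and the final list is CRC-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .convcode import ConvCodeSpec
from .crc import CRCSpec, crc_strip, crc_verify
from .trellis import build_trellis

NEG = -1e30
PROB_FLOOR = 1e-12
BLANK = "b"
_ALPHABET = "ACGT"


class UndecodableError(Exception):
    pass


@dataclass
class CTCPosterior:
    """T x 5 row-stochastic matrix, column order (blank, A, C, G, T)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 5:
            raise ValueError("posterior must be T x 5")
        if (self.matrix < 0).any():
            raise ValueError("posterior entries must be >= 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1 within 1e-9")

    @property
    def T(self) -> int:
        return self.matrix.shape[0]


def _as_matrix(posterior) -> np.ndarray:
    if isinstance(posterior, CTCPosterior):
        return posterior.matrix
    return CTCPosterior(posterior).matrix


def reverse_complement_posterior(posterior) -> np.ndarray:
    """Posterior of the reverse-complement read.

    Time runs backwards and the base columns swap A<->T and C<->G; the blank
    column stays put.  Lets a forward-strand decoder handle reverse-strand
    reads as a pre-pass.
    """
    mat = _as_matrix(posterior)
    return mat[::-1][:, [0, 4, 3, 2, 1]].copy()


def greedy_collapse(state_string: str) -> str:
    """Collapse repeats and drop blanks: AAAbCCbCCCGGbbbTTT -> ACCGT."""
    out = []
    prev = BLANK
    for ch in state_string:
        if ch != prev and ch != BLANK:
            out.append(ch)
        prev = ch
    return "".join(out)


def greedy_basecall(posterior) -> str:
    """Most probable state per time step, then collapse."""
    return greedy_basecall_with_times(posterior)[0]


def greedy_basecall_with_times(posterior) -> tuple[str, np.ndarray]:
    """Greedy basecall plus the time-step index of each emitted base.

    ``np.argmax`` takes the first maximal column, so ties resolve to blank
    first, then alphabetically (the column order is blank, A, C, G, T).
    """
    mat = _as_matrix(posterior)
    arg = mat.argmax(axis=1)
    seq, times = [], []
    prev = 0
    for t, a in enumerate(arg):
        if a != 0 and a != prev:
            seq.append(_ALPHABET[a - 1])
            times.append(t)
        prev = a
    return "".join(seq), np.array(times, dtype=np.int64)


def beam_search_basecall(posterior, beam_width: int = 32
                         ) -> list[tuple[str, float]]:
    """Ranked collapsed sequences with path-summed log-probabilities.

    Per candidate the blank-ending and non-blank-ending path masses are kept
    separately and merged in log domain; the beam is pruned to ``beam_width``
    after each step's merge.
    """
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    mat = _as_matrix(posterior)
    lp = np.log(np.maximum(mat, PROB_FLOOR))
    beams: dict[tuple[int, ...], tuple[float, float]] = {(): (0.0, NEG)}
    for t in range(mat.shape[0]):
        row = lp[t]
        new: dict[tuple[int, ...], list[float]] = {}

        def add(prefix, pb, pnb):
            if pb <= NEG and pnb <= NEG:
                return
            cur = new.setdefault(prefix, [NEG, NEG])
            cur[0] = np.logaddexp(cur[0], pb) if pb > NEG else cur[0]
            cur[1] = np.logaddexp(cur[1], pnb) if pnb > NEG else cur[1]

        for prefix, (pb, pnb) in beams.items():
            tot = np.logaddexp(pb, pnb)
            add(prefix, tot + row[0],
                (pnb + row[prefix[-1] + 1]) if prefix else NEG)
            for c in range(4):
                src = pb if (prefix and prefix[-1] == c) else tot
                add(prefix + (c,), NEG, src + row[c + 1])
        ranked = sorted(new.items(),
                        key=lambda kv: (-np.logaddexp(*kv[1]), kv[0]))
        beams = {k: (v[0], v[1]) for k, v in ranked[:beam_width]}
    out = [("".join(_ALPHABET[c] for c in prefix), float(np.logaddexp(pb, pnb)))
           for prefix, (pb, pnb) in beams.items()]
    out.sort(key=lambda kv: (-kv[1], kv[0]))
    return out


@dataclass
class ListDecodeResult:
    """Top-L candidate messages, best first."""

    candidates: list[tuple[np.ndarray, float, tuple[bool, ...]]]
    L: int

    def __post_init__(self):
        scores = [c[1] for c in self.candidates]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert len(self.candidates) <= self.L or self.L <= 0


def _shift_append(msg: np.ndarray, k: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Multiword left shift by k (<= 8) bits, OR val into the low word."""
    W = msg.shape[1]
    k64 = k.astype(np.uint64)
    out = np.empty_like(msg)
    for w in range(W - 1, 0, -1):
        carry_shift = (np.uint64(64) - k64) & np.uint64(63)
        carry = np.where(k64 == 0, np.uint64(0), msg[:, w - 1] >> carry_shift)
        out[:, w] = (msg[:, w] << k64) | carry
    out[:, 0] = (msg[:, 0] << k64) | val.astype(np.uint64)
    return out


def auto_beam_width(conv: ConvCodeSpec) -> int:
    """Default global beam: strictly proportional to the state count.

    Pruning severity should be comparable across code memories - a fixed
    beam (or a floor that binds for small codes) starves high-memory codes
    of trellis diversity relative to small ones and distorts comparisons
    between them - so the beam keeps two candidates per encoder state
    (a small floor for toy codes, a cap for very large ones).
    """
    return min(max(64, 2 * conv.n_states), 8192)


def conv_ctc_list_decode(posterior, conv: ConvCodeSpec, crc: CRCSpec,
                         expected_message_bits: int, L: int = 8,
                         beam_width: int | None | str = "auto",
                         score_window: float | None | str = "auto"
                         ) -> ListDecodeResult:
    """List-Viterbi decode of a convolutional codeword from a CTC posterior.

    ``expected_message_bits`` is the framed per-oligo message size (index +
    payload + CRC); the posterior should already be trimmed to the payload
    window.  ``beam_width`` additionally caps the number of live candidates
    per time step ("auto" scales it with the code's state count, None
    disables the cap; per-node lists are always capped at ``L``).
    ``score_window`` drops candidates more than that many log units behind
    the read's best candidate ("auto": 15, or None with ``beam_width=None``
    for the exact algorithm).
    """
    res = conv_ctc_list_decode_batch([posterior], conv, crc,
                                     expected_message_bits, L=L,
                                     beam_width=beam_width,
                                     score_window=score_window)[0]
    if isinstance(res, UndecodableError):
        raise res
    return res


def conv_ctc_list_decode_batch(posteriors, conv: ConvCodeSpec, crc: CRCSpec,
                               expected_message_bits: int, L: int = 8,
                               beam_width: int | None | str = "auto",
                               score_window: float | None | str = "auto"
                               ) -> list:
    """Decode many reads in one trellis sweep.

    Reads are front-padded with exact blank rows to a common length, which
    leaves every path score unchanged (a certain blank contributes log 1 to
    blank-ending paths and cannot plausibly extend), and all candidate sets
    advance together keyed by (read, node).  Returns one
    :class:`ListDecodeResult` per read, or an :class:`UndecodableError`
    instance in the slots of reads whose posterior is shorter than the
    codeword needs.
    """
    if beam_width == "auto":
        beam_width = auto_beam_width(conv)
    if score_window == "auto":
        score_window = 15.0 if beam_width is not None else None
    mats = [_as_matrix(p) for p in posteriors]
    tr = build_trellis(conv, expected_message_bits)
    P, S = tr.n_bases, tr.aug_size
    n_msg = tr.n_message_bits
    W = max(1, -(-n_msg // 64))
    KEY = (P + 1) * S  # per-read key span; node key = read*KEY + pos*S + aug

    results: list = [None] * len(mats)
    active = []
    for i, m in enumerate(mats):
        if m.shape[0] < P:
            results[i] = UndecodableError(
                f"posterior has {m.shape[0]} steps but the codeword needs >= {P}")
        else:
            active.append(i)
    if not active:
        return results
    R = len(active)
    T = max(mats[i].shape[0] for i in active)
    lp = np.zeros((R, T, 5))
    lp[:, :, 1:] = np.log(PROB_FLOOR)  # pad rows are certain blanks
    for r, i in enumerate(active):
        m = mats[i]
        lp[r, T - m.shape[0]:, :] = np.log(np.maximum(m, PROB_FLOOR))

    key = np.arange(R, dtype=np.int64) * KEY
    msg = np.zeros((R, W), dtype=np.uint64)
    pb = np.zeros(R)
    pnb = np.full(R, NEG)
    last = np.full(R, 255, dtype=np.uint8)

    indptr, t_to, t_base, t_msg = tr.indptr, tr.t_to_key, tr.t_base, tr.t_msg
    n_free = tr.n_free

    for t in range(T):
        rows = lp[:, t, :]  # (R, 5)
        rcand = key // KEY
        local = key - rcand * KEY
        tot = np.logaddexp(pb, pnb)
        # stay in place: emit blank, or re-emit the last base (no collapse)
        stay_pb = tot + rows[rcand, 0]
        safe_idx = np.where(last == 255, 0, last.astype(np.int64) + 1)
        stay_pnb = np.where(last == 255, NEG, pnb + rows[rcand, safe_idx])

        start = indptr[local]
        cnt = indptr[local + 1] - start
        total_ext = int(cnt.sum())
        if total_ext:
            rep = np.repeat(np.arange(key.size), cnt)
            within = np.arange(total_ext) - np.repeat(np.cumsum(cnt) - cnt, cnt)
            tidx = np.repeat(start, cnt) + within
            e_base = t_base[tidx]
            e_key = rcand[rep] * KEY + t_to[tidx]
            pos_src = local[rep] // S
            e_allow = e_base != last[rep]
            e_src = np.where(e_allow, tot[rep], pb[rep]) \
                + rows[rcand[rep], e_base.astype(np.int64) + 1]
            e_msg = _shift_append(msg[rep], n_free[pos_src], t_msg[tidx])

            key = np.concatenate([key, e_key])
            msg = np.concatenate([msg, e_msg])
            pb = np.concatenate([stay_pb, np.full(total_ext, NEG)])
            pnb = np.concatenate([stay_pnb, e_src])
            last = np.concatenate([last, e_base])
        else:
            pb, pnb = stay_pb, stay_pnb

        # drop dead and unfinishable candidates
        pos = (key % KEY) // S
        alive = (np.maximum(pb, pnb) > NEG / 2) & (P - pos <= T - t - 1)
        key, msg, pb, pnb, last = (key[alive], msg[alive], pb[alive],
                                   pnb[alive], last[alive])
        if key.size == 0:
            break

        # merge candidates with identical (read, node, message): logsumexp
        order = np.lexsort(tuple(msg[:, w] for w in range(W)) + (key,))
        key, msg, pb, pnb, last = (key[order], msg[order], pb[order],
                                   pnb[order], last[order])
        same = np.empty(key.size, dtype=bool)
        same[0] = False
        same[1:] = key[1:] == key[:-1]
        for w in range(W):
            same[1:] &= msg[1:, w] == msg[:-1, w]
        starts = np.flatnonzero(~same)
        pb = np.logaddexp.reduceat(pb, starts)
        pnb = np.logaddexp.reduceat(pnb, starts)
        key, msg, last = key[starts], msg[starts], last[starts]
        gtot = np.logaddexp(pb, pnb)

        # per-read score window: drop hopelessly trailing candidates
        if score_window is not None:
            rcand = key // KEY
            rstart = np.empty(key.size, dtype=bool)
            rstart[0] = True
            rstart[1:] = rcand[1:] != rcand[:-1]
            runs = np.flatnonzero(rstart)
            rmax = np.maximum.reduceat(gtot, runs)
            run_id = np.cumsum(rstart) - 1
            keep = gtot >= rmax[run_id] - score_window
            key, msg, pb, pnb, last, gtot = (key[keep], msg[keep], pb[keep],
                                             pnb[keep], last[keep], gtot[keep])

        # per-node top-L (ties: lexicographically smaller message wins)
        order = np.lexsort(tuple(msg[:, w] for w in range(W)) + (-gtot, key))
        key, msg, pb, pnb, last, gtot = (key[order], msg[order], pb[order],
                                         pnb[order], last[order], gtot[order])
        idx = np.arange(key.size)
        node_start = np.empty(key.size, dtype=bool)
        node_start[0] = True
        node_start[1:] = key[1:] != key[:-1]
        run_start = np.maximum.accumulate(np.where(node_start, idx, 0))
        keep = (idx - run_start) < L
        key, msg, pb, pnb, last, gtot = (key[keep], msg[keep], pb[keep],
                                         pnb[keep], last[keep], gtot[keep])

        # per-read global beam (score pruning across nodes)
        if beam_width is not None and key.size > beam_width:
            rcand = key // KEY
            order = np.lexsort(tuple(msg[:, w] for w in range(W))
                               + (key, -gtot, rcand))
            idx = np.arange(order.size)
            read_start = np.empty(order.size, dtype=bool)
            read_start[0] = True
            read_start[1:] = rcand[order][1:] != rcand[order][:-1]
            run_start = np.maximum.accumulate(np.where(read_start, idx, 0))
            sel = np.sort(order[(idx - run_start) < beam_width])
            key, msg, pb, pnb, last = (key[sel], msg[sel], pb[sel],
                                       pnb[sel], last[sel])

    ftot_all = np.logaddexp(pb, pnb)
    rcand = key // KEY
    local = key - rcand * KEY
    for r, i in enumerate(active):
        final = (rcand == r) & (local == P * S)
        if not final.any():
            results[i] = UndecodableError(
                "no candidate reached the final trellis node")
            continue
        fmsg, ftot = msg[final], ftot_all[final]
        order = np.lexsort(tuple(fmsg[:, w] for w in range(W)) + (-ftot,))[:L]
        candidates = []
        for j in order:
            val = 0
            for w in range(W):
                val |= int(fmsg[j, w]) << (64 * w)
            bits = np.array([(val >> (n_msg - 1 - b)) & 1
                             for b in range(n_msg)], dtype=np.uint8)
            candidates.append((bits, float(ftot[j]), crc_verify(bits, crc)))
        results[i] = ListDecodeResult(candidates=candidates, L=L)
    return results


def crc_filter(result: ListDecodeResult, crc: CRCSpec = CRCSpec()):
    """Accept the best-scoring candidate that passes its CRC check(s).

    Returns ``(message_bits, rank)`` with the CRC field stripped, or ``None``
    when every candidate fails.  In two-CRC mode a candidate with both halves
    clean is preferred; failing that, the best candidate with at least one
    clean half is accepted (its other half is unverified - the outer code
    tolerates the residual risk).
    """
    best_partial = None
    for rank, (bits, _score, passes) in enumerate(result.candidates):
        if all(passes):
            return crc_strip(bits, crc), rank
        if crc.segments == 2 and any(passes) and best_partial is None:
            best_partial = (crc_strip(bits, crc), rank)
    return best_partial
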