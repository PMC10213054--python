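"""Joint (convolutional state, base position) trellis.

The list-Viterbi decoder walks a trellis whose nodes are
``(augmented encoder state, position in the base sequence)``.  One base holds
two transmitted (post-puncturing) bits, but an encoder step can emit one or
two transmitted bits depending on the puncture phase, so base boundaries can
fall mid-step.  The augmented state therefore carries, besides the ``m``-bit
register, at most one *pending* transmitted bit that has been produced but
not yet emitted as part of a base.  Whether a pending bit exists at a given
position is determined by the (fixed) puncture schedule; only its value is
part of the state.

Transitions from position ``j`` to ``j + 1`` emit one base and consume the
encoder input bits whose outputs fall inside it; flush steps (zero-tail
termination) and the optional final pad bit are forced to 0 and contribute no
free message bits.  ``msg_val``/``n_free`` record the free input bits each
transition consumes, most-significant-first in consumption order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convcode import ConvCodeSpec


@dataclass
class BaseTrellis:
    spec: ConvCodeSpec
    n_message_bits: int
    n_bases: int
    pad_bits: int
    aug_size: int              # 2^(m+1): conv state | pending-bit << m
    cum_free: np.ndarray       # free message bits consumed before position j
    n_free: np.ndarray         # free bits consumed by transitions out of j
    indptr: np.ndarray         # CSR over key = pos * aug_size + from_aug
    t_to_key: np.ndarray       # destination key (pos+1, to_aug)
    t_base: np.ndarray         # emitted base value 0..3
    t_msg: np.ndarray          # free bits consumed, packed MSB-first

    @property
    def final_key(self) -> int:
        return self.n_bases * self.aug_size  # pos = n_bases, aug = 0


_CACHE: dict[tuple, BaseTrellis] = {}


def build_trellis(spec: ConvCodeSpec, n_message_bits: int) -> BaseTrellis:
    key = (spec, n_message_bits)
    if key not in _CACHE:
        _CACHE[key] = _build(spec, n_message_bits)
    return _CACHE[key]


def _build(spec: ConvCodeSpec, n_msg: int) -> BaseTrellis:
    if spec.n_streams != 2:
        raise NotImplementedError("trellis assumes a two-stream mother code")
    m = spec.memory
    S_conv = spec.n_states
    S = S_conv << 1
    outs, nxt = spec.step_tables()
    n_steps = n_msg + spec.flush_bits
    pat = spec.puncture_pattern
    streams_of_step = [
        tuple(j for j in range(2) if pat[j][s % spec.period])
        for s in range(n_steps)
    ]
    total_tx = sum(len(x) for x in streams_of_step)
    pad_bits = total_tx % 2
    n_bases = (total_tx + pad_bits) // 2

    # schedule: which steps each base consumes, and the pending structure
    plans = []  # (pending_before: bool, steps: list[(step_idx, streams, forced)], n_pad)
    step_idx = 0
    pend = 0
    for j in range(n_bases):
        consumed = []
        avail = pend
        while avail < 2 and step_idx < n_steps:
            st = streams_of_step[step_idx]
            consumed.append((step_idx, st, step_idx >= n_msg))
            avail += len(st)
            step_idx += 1
        n_pad = max(0, 2 - avail)
        avail += n_pad
        plans.append((pend == 1, consumed, n_pad))
        pend = avail - 2
    assert step_idx == n_steps and pend == 0

    states = np.arange(S_conv, dtype=np.int64)
    cum_free = np.zeros(n_bases + 1, dtype=np.int64)
    n_free_arr = np.zeros(n_bases, dtype=np.int64)
    rows_from, rows_to, rows_base, rows_msg = [], [], [], []

    for j, (has_pending, consumed, n_pad) in enumerate(plans):
        free_steps = [i for i, (_, _, forced) in enumerate(consumed) if not forced]
        n_free = len(free_steps)
        n_free_arr[j] = n_free
        cum_free[j + 1] = cum_free[j] + n_free
        for combo in range(1 << n_free):
            # input bit per consumed step (forced steps -> 0), MSB-first combo
            u_bits = []
            fi = 0
            for i, (_, _, forced) in enumerate(consumed):
                if forced:
                    u_bits.append(0)
                else:
                    u_bits.append((combo >> (n_free - 1 - fi)) & 1)
                    fi += 1
            for pending_val in ((0, 1) if has_pending else (None,)):
                cur = states
                emitted: list[np.ndarray] = []
                if has_pending:
                    emitted.append(np.full(S_conv, pending_val, dtype=np.int64))
                for (s_idx, st, _), u in zip(consumed, u_bits):
                    packed = outs[u, cur].astype(np.int64)
                    for stream_j in st:
                        emitted.append((packed >> stream_j) & 1)
                    cur = nxt[u, cur].astype(np.int64)
                for _ in range(n_pad):
                    emitted.append(np.zeros(S_conv, dtype=np.int64))
                base = emitted[0] * 2 + emitted[1]
                leftover = emitted[2] if len(emitted) > 2 else np.zeros(S_conv,
                                                                        dtype=np.int64)
                from_aug = states | ((pending_val or 0) << m)
                to_aug = cur | (leftover << m)
                rows_from.append(j * S + from_aug)
                rows_to.append((j + 1) * S + to_aug)
                rows_base.append(base)
                rows_msg.append(np.full(S_conv, combo, dtype=np.int64))

    from_key = np.concatenate(rows_from)
    to_key = np.concatenate(rows_to)
    base = np.concatenate(rows_base).astype(np.uint8)
    msg = np.concatenate(rows_msg).astype(np.uint8)
    order = np.argsort(from_key, kind="stable")
    from_key, to_key, base, msg = (from_key[order], to_key[order],
                                   base[order], msg[order])
    # one extra (empty) position so final-node lookups see zero transitions
    n_keys = (n_bases + 1) * S
    counts = np.bincount(from_key, minlength=n_keys)
    indptr = np.zeros(n_keys + 1, dtype=np.int64)
    np.cumsum(counts[:n_keys], out=indptr[1:])

    return BaseTrellis(
        spec=spec, n_message_bits=n_msg, n_bases=n_bases, pad_bits=pad_bits,
        aug_size=S, cum_free=cum_free, n_free=n_free_arr, indptr=indptr,
        t_to_key=to_key.astype(np.int64), t_base=base, t_msg=msg)
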