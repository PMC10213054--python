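"""Convolutional inner code: encoder, puncturing, hard-decision Viterbi.

The encoder is a feed-forward shift register with memory ``m``: the state is
the last ``m`` input bits and each of the (two) output streams is a modulo-2
linear combination of the current input bit and the state, selected by a
generator polynomial of width ``m + 1``.  Rates above the 1/2 mother rate are
reached by puncturing with a fixed periodic pattern; the decoder treats
punctured positions as erasures (zero metric contribution).

Bit/tap convention: for input bit ``u`` and state ``s`` (most recent input in
the most significant of the ``m`` state bits) the register window is
``(u << m) | s`` and each output bit is ``parity(window & tap)``.  The state
update is ``window >> 1``.  Generator taps are given as integers (commonly
written in octal, e.g. ``0o133, 0o171`` for m = 6).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .bits import as_bits

ERASURE = 255  # marker for punctured positions in depunctured streams

#: maximum-free-distance feed-forward generator pairs, by memory
DEFAULT_TAPS = {
    2: (0o7, 0o5),
    6: (0o133, 0o171),
    8: (0o561, 0o753),
    11: (0o5537, 0o6131),
}

#: periodic puncturing patterns from the rate-1/2 mother code, streams x period
PUNCTURE_PATTERNS = {
    "1/2": ((1,), (1,)),
    "2/3": ((1, 1), (1, 0)),
    "3/4": ((1, 1, 0), (1, 0, 1)),
    "5/6": ((1, 1, 0, 1, 0), (1, 0, 1, 0, 1)),
    "7/8": ((1, 1, 0, 1, 0, 1, 0), (1, 0, 1, 0, 1, 0, 1)),
}


@dataclass(frozen=True)
class ConvCodeSpec:
    """Parameters of the punctured convolutional code."""

    memory: int
    taps: tuple[int, ...]
    puncture_pattern: tuple[tuple[int, ...], ...] = ((1,), (1,))
    termination_bits: int | None = None  # default: memory zero flush bits

    def __post_init__(self):
        if self.memory < 1:
            raise ValueError("memory must be >= 1")
        if not self.taps or any(t == 0 for t in self.taps):
            raise ValueError("generator taps must be nonzero")
        width = self.memory + 1
        if any(t >= (1 << width) for t in self.taps):
            raise ValueError(f"taps must fit in {width} bits")
        pat = self.puncture_pattern
        if len(pat) != len(self.taps):
            raise ValueError("puncture pattern needs one row per stream")
        period = len(pat[0])
        if any(len(row) != period for row in pat):
            raise ValueError("puncture pattern rows must share one period")
        cols = np.array(pat)
        if (cols.sum(axis=0) < 1).any():
            raise ValueError("every puncture column needs >= 1 transmitted bit")

    @property
    def n_streams(self) -> int:
        return len(self.taps)

    @property
    def period(self) -> int:
        return len(self.puncture_pattern[0])

    @property
    def flush_bits(self) -> int:
        return self.memory if self.termination_bits is None else self.termination_bits

    @property
    def n_states(self) -> int:
        return 1 << self.memory

    @property
    def rate(self) -> Fraction:
        """Realized rate: input bits per transmitted bit over one period."""
        sent = int(np.sum(self.puncture_pattern))
        return Fraction(self.period, sent)

    def transmitted_per_step(self) -> np.ndarray:
        """Transmitted-bit count for each step phase (length = period)."""
        return np.array(self.puncture_pattern).sum(axis=0)

    def n_transmitted(self, n_steps: int) -> int:
        """Total transmitted bits over ``n_steps`` encoder steps (phase 0 start)."""
        per = self.transmitted_per_step()
        full, rem = divmod(n_steps, self.period)
        return int(full * per.sum() + per[:rem].sum())

    def step_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(outputs, next_state) tables indexed by [input_bit, state].

        ``outputs[u, s]`` packs the per-stream output bits, stream 0 in the
        least-significant bit.
        """
        states = np.arange(self.n_states, dtype=np.uint32)
        outs = np.zeros((2, self.n_states), dtype=np.uint8)
        nxt = np.zeros((2, self.n_states), dtype=np.uint32)
        for u in (0, 1):
            window = (np.uint32(u) << self.memory) | states
            acc = np.zeros(self.n_states, dtype=np.uint8)
            for j, tap in enumerate(self.taps):
                bit = np.bitwise_count(window & np.uint32(tap)).astype(np.uint8) & 1
                acc |= bit << j
            outs[u] = acc
            nxt[u] = window >> 1
        return outs, nxt

    def config_lines(self) -> list[str]:
        """Plain-text key = value serialization for experiment manifests."""
        return [
            f"conv_memory = {self.memory}",
            "conv_taps_octal = " + ",".join(oct(t) for t in self.taps),
            "conv_puncture = " + ";".join(
                "".join(str(b) for b in row) for row in self.puncture_pattern),
            f"conv_rate = {self.rate}",
            f"conv_flush_bits = {self.flush_bits}",
        ]


def standard_spec(memory: int, rate: str = "1/2",
                  taps: tuple[int, ...] | None = None) -> ConvCodeSpec:
    """Convenience constructor from memory and a named punctured rate."""
    if taps is None:
        try:
            taps = DEFAULT_TAPS[memory]
        except KeyError:
            raise KeyError(f"no default taps for memory {memory}; pass taps=")
    return ConvCodeSpec(memory=memory, taps=taps,
                        puncture_pattern=PUNCTURE_PATTERNS[rate])


def _encode_steps(message: np.ndarray, spec: ConvCodeSpec) -> np.ndarray:
    """Unpunctured per-step outputs (n_steps x n_streams), message + flush."""
    outs, nxt = spec.step_tables()
    stream = np.concatenate([message, np.zeros(spec.flush_bits, dtype=np.uint8)])
    out = np.zeros((stream.size, spec.n_streams), dtype=np.uint8)
    s = 0
    for i, u in enumerate(stream):
        packed = outs[u, s]
        for j in range(spec.n_streams):
            out[i, j] = (packed >> j) & 1
        s = int(nxt[u, s])
    return out


def conv_encode(message, spec: ConvCodeSpec) -> np.ndarray:
    """Encode a bit vector; output is the punctured transmitted stream.

    The encoder starts in the all-zero state, processes every message bit and
    then ``flush_bits`` zero termination bits (returning to the zero state);
    the puncturing phase runs continuously across message and flush steps.
    """
    message = as_bits(message)
    steps = _encode_steps(message, spec)
    return puncture(steps.ravel(), spec)


def puncture(stream, spec: ConvCodeSpec) -> np.ndarray:
    """Delete masked positions from an unpunctured stream.

    ``stream`` is the step-major, stream-minor flat output; its length must be
    a whole number of steps (trailing partial steps are rejected).
    """
    stream = np.asarray(stream)
    n = spec.n_streams
    if stream.size % n:
        raise ValueError("stream length must be a whole number of encoder steps")
    n_steps = stream.size // n
    mask = _step_mask(spec, n_steps)
    return stream[mask.ravel()]


def depuncture(stream, spec: ConvCodeSpec) -> np.ndarray:
    """Reinsert erasure marks (value ``ERASURE``) at punctured positions."""
    stream = np.asarray(stream, dtype=np.uint8)
    n_steps = _infer_steps(stream.size, spec)
    mask = _step_mask(spec, n_steps)
    out = np.full(mask.size, ERASURE, dtype=np.uint8)
    out[mask.ravel()] = stream
    return out


def _step_mask(spec: ConvCodeSpec, n_steps: int) -> np.ndarray:
    pat = np.array(spec.puncture_pattern, dtype=bool)  # streams x period
    reps = -(-n_steps // spec.period)
    return np.tile(pat.T, (reps, 1))[:n_steps]  # steps x streams


def _infer_steps(n_transmitted: int, spec: ConvCodeSpec) -> int:
    per = spec.transmitted_per_step()
    per_period = int(per.sum())
    full = n_transmitted // per_period
    rem = n_transmitted - full * per_period
    n_steps = full * spec.period
    i = 0
    while rem > 0:
        rem -= int(per[i])
        n_steps += 1
        i += 1
    if rem != 0:
        raise ValueError("transmitted length inconsistent with puncture pattern")
    return n_steps


def viterbi_decode_hard(received, spec: ConvCodeSpec,
                        depunctured: bool = True) -> tuple[np.ndarray, int]:
    """Maximum-likelihood decode under the Hamming metric.

    ``received`` holds hard bits with ``ERASURE`` marks at punctured (or
    otherwise unknown) positions; erasures contribute nothing to the metric.
    If ``depunctured`` is False, the input is the punctured transmitted stream
    and erasure marks are inserted first.  Returns ``(message, path_metric)``
    where the metric is the Hamming distance between the received bits and the
    re-encoded output of the decoded message.

    Tie-breaking is deterministic: among equal-metric predecessors the branch
    whose oldest state bit is 0 wins, which resolves the all-erasure input to
    the all-zero message.
    """
    received = np.asarray(received, dtype=np.uint8)
    if not depunctured:
        received = depuncture(received, spec)
    n = spec.n_streams
    if received.size % n:
        raise ValueError("received length is not a whole number of trellis steps")
    n_steps = received.size // n
    if n_steps < spec.flush_bits:
        raise ValueError("received stream shorter than the termination flush")
    n_msg = n_steps - spec.flush_bits
    outs, nxt = spec.step_tables()
    S = spec.n_states
    m = spec.memory
    INF = np.iinfo(np.int32).max // 2

    # branch metric lookup: cost[u, s, step] depends only on received bits
    rec = received.reshape(n_steps, n)
    metrics = np.full(S, INF, dtype=np.int64)
    metrics[0] = 0
    prev = np.zeros((n_steps, S), dtype=np.uint32)
    half = S >> 1 if m >= 1 else 1

    out_bits = np.zeros((2, S, n), dtype=np.uint8)
    for u in (0, 1):
        for j in range(n):
            out_bits[u, :, j] = (outs[u] >> j) & 1

    dests = np.arange(S, dtype=np.int64)
    u_of_dest = (dests >> (m - 1)) & 1  # input bit is the newest bit of the dest state
    s0 = (dests & (half - 1)) << 1      # predecessor with oldest input bit 0
    s1 = s0 | 1

    for t in range(n_steps):
        obs = rec[t]
        known = obs != ERASURE
        cost = np.zeros((2, S), dtype=np.int64)
        for u in (0, 1):
            diff = out_bits[u][:, known] != obs[known]
            cost[u] = diff.sum(axis=1)
        c0 = metrics[s0] + cost[u_of_dest, s0]
        c1 = metrics[s1] + cost[u_of_dest, s1]
        take1 = c1 < c0  # tie -> oldest-bit-0 predecessor
        new = np.where(take1, c1, c0)
        newprev = np.where(take1, s1, s0).astype(np.uint32)
        if t >= n_msg:  # flush steps force input bit 0
            new = np.where(u_of_dest == 0, new, INF)
        metrics, prev[t] = new, newprev

    end = 0  # zero-tail termination
    path_metric = int(metrics[end])
    # traceback
    msg = np.zeros(n_msg, dtype=np.uint8)
    s = end
    for t in range(n_steps - 1, -1, -1):
        p = int(prev[t, s])
        if t < n_msg:
            msg[t] = (s >> (m - 1)) & 1  # input bit = newest state bit of s
        s = p
    return msg, path_metric
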