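"""Synthetic nanopore channel emitting CTC posteriors.

The simulator models the *basecaller's output*, not raw current: each true
base becomes a dwell of one or more posterior rows concentrated on that base
(geometric dwell, configurable mean), separated by blank-dominated rows.
Substitution, insertion and deletion events perturb which base a dwell
favors or whether it exists at all, so the greedy basecall of a simulated
posterior carries a controllable edit-error rate; ``confusion_temperature``
additionally softens rows (Gaussian logit noise), degrading the posterior
without changing the event structure.  Coverage skew, per-oligo dropout and
chimeric reads are layered on top for pool-level simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctc import CTCPosterior, greedy_basecall_with_times
from .dna import BASES, OligoRecord

_LOGIT_SCALE = 4.0


@dataclass(frozen=True)
class ChannelParams:
    """Knobs of the synthetic posterior channel.

    ``target_error_rate`` is the intended greedy-basecall edit error per true
    base; when the individual event rates are left unset they are derived
    from it (40% deletions, 33% substitutions, 27% insertions, the rough
    nanopore error profile).  The default operating point of 0.055 sits in
    the middle of the 4.5-7% window typical of recent flowcells.
    """

    target_error_rate: float = 0.055
    dwell_mean: float = 2.0
    blank_bias: float = 0.35
    confusion_temperature: float = 0.25
    ins_rate: float | None = None
    del_rate: float | None = None
    sub_rate: float | None = None
    chimera_rate: float = 0.0

    def __post_init__(self):
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        for r in (self.target_error_rate, self.blank_bias, self.chimera_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def rates(self) -> tuple[float, float, float]:
        """(substitution, insertion, deletion) per-base event rates."""
        tau = self.target_error_rate
        sub = self.sub_rate if self.sub_rate is not None else 0.33 * tau
        ins = self.ins_rate if self.ins_rate is not None else 0.27 * tau
        dele = self.del_rate if self.del_rate is not None else 0.40 * tau
        return sub, ins, dele


@dataclass(frozen=True)
class CoverageModel:
    """Read-count model over a pool: skew, dropout, total depth."""

    distribution: str = "lognormal"  # or "uniform" / "empirical"
    sigma: float = 0.5
    weights: tuple[float, ...] | None = None
    dropout_prob: float = 0.0
    total_reads: int = 1000

    def __post_init__(self):
        if self.distribution not in ("uniform", "lognormal", "empirical"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")

    def oligo_weights(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "uniform":
            w = np.ones(n)
        elif self.distribution == "lognormal":
            w = rng.lognormal(mean=0.0, sigma=self.sigma, size=n)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.size != n:
                raise ValueError("empirical weights length != pool size")
        drop = rng.random(n) < self.dropout_prob
        w = np.where(drop, 0.0, w)
        if w.sum() == 0:
            raise ValueError("all oligos dropped out")
        return w / w.sum()


def _event_rows(base_idx: int, n_rows: int, rng: np.random.Generator,
                temperature: float) -> np.ndarray:
    """Posterior rows favoring CTC state ``base_idx`` (0 blank, 1..4 bases)."""
    logits = np.full((n_rows, 5), 0.0)
    logits[:, base_idx] = _LOGIT_SCALE
    if temperature > 0:
        logits += temperature * rng.standard_normal((n_rows, 5))
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    return p


def _geometric(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1:
        return 1
    return int(rng.geometric(1.0 / mean))


def simulate_posterior(true_bases: str, params: ChannelParams,
                       seed: int) -> CTCPosterior:
    """Posterior matrix for one read of ``true_bases``; deterministic per seed."""
    mat, _spans = _simulate_rows(true_bases, params,
                                 np.random.Generator(np.random.PCG64(seed)))
    return CTCPosterior(mat)


def _simulate_rows(true_bases: str, params: ChannelParams,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rows plus, per true-sequence position, the starting row index.

    ``spans[i]`` is the first posterior row attributable to true base ``i``
    (for a deleted base, the row where it would have started); ``spans[-1]``
    is one past the final row.  This anchors truth windows for trimming
    diagnostics.
    """
    if not true_bases:
        raise ValueError("true_bases must be non-empty")
    sub, ins, dele = params.rates
    base_idx = np.array([BASES.index(b) + 1 for b in true_bases])
    chunks: list[np.ndarray] = []
    spans = np.zeros(len(true_bases) + 1, dtype=np.int64)
    n_rows = 0
    prev_emitted = 0  # CTC state of the previous emitted event (0 = none)

    def gap_rows(force: bool) -> int:
        g = _geometric(rng, 1.0 / max(1e-9, 1.0 - params.blank_bias)) - 1
        return max(g, 1) if force else g

    # leading blank pad
    lead = gap_rows(False) + 1
    chunks.append(_event_rows(0, lead, rng, params.confusion_temperature))
    n_rows += lead

    for i, bi in enumerate(base_idx):
        spans[i] = n_rows
        if rng.random() < dele:
            continue
        emit = int(bi)
        if rng.random() < sub:
            emit = int(rng.choice([x for x in range(1, 5) if x != bi]))
        if emit == prev_emitted:
            g = gap_rows(True)
            chunks.append(_event_rows(0, g, rng, params.confusion_temperature))
            n_rows += g
        dwell = _geometric(rng, params.dwell_mean)
        chunks.append(_event_rows(emit, dwell, rng, params.confusion_temperature))
        n_rows += dwell
        prev_emitted = emit
        g = gap_rows(False)
        if g:
            chunks.append(_event_rows(0, g, rng, params.confusion_temperature))
            n_rows += g
            prev_emitted = 0
        if rng.random() < ins:
            extra = int(rng.integers(1, 5))
            if extra == prev_emitted:
                chunks.append(_event_rows(0, 1, rng, params.confusion_temperature))
                n_rows += 1
            dwell = _geometric(rng, params.dwell_mean)
            chunks.append(_event_rows(extra, dwell, rng,
                                      params.confusion_temperature))
            n_rows += dwell
            prev_emitted = extra
    tail = gap_rows(False) + 1
    chunks.append(_event_rows(0, tail, rng, params.confusion_temperature))
    n_rows += tail
    spans[-1] = n_rows
    return np.concatenate(chunks, axis=0), spans


@dataclass
class ReadSet:
    """Simulated reads: posteriors plus a ground-truth table."""

    read_ids: list[str]
    posteriors: list[np.ndarray]
    truth: pd.DataFrame  # read_id, oligo_index, oligo_name, chimeric, payload_t0, payload_t1

    def __len__(self) -> int:
        return len(self.read_ids)


def simulate_pool_reads(pool: list[OligoRecord], coverage: CoverageModel,
                        params: ChannelParams, seed: int,
                        primer_len: int = 25) -> ReadSet:
    """Sample reads from a pool through the channel.

    Chimeric reads carry a random fragment of another oligo as a prefix.  The
    truth table records the source oligo and the posterior-row window of the
    payload (bases between the primers), for trimming/decoding diagnostics.
    """
    if not pool:
        raise ValueError("empty pool")
    rng = np.random.Generator(np.random.PCG64(seed))
    w = coverage.oligo_weights(len(pool), rng)
    counts = rng.multinomial(coverage.total_reads, w)
    ids, posts, rows = [], [], []
    r = 0
    for oi, c in enumerate(counts):
        oligo = pool[oi]
        for _ in range(c):
            seq = oligo.sequence
            offset = 0
            chimeric = False
            if params.chimera_rate and rng.random() < params.chimera_rate and len(pool) > 1:
                other = pool[int(rng.integers(0, len(pool)))]
                frag_len = int(rng.integers(10, max(11, len(other.sequence))))
                frag = other.sequence[-frag_len:]
                seq = frag + seq
                offset = len(frag)
                chimeric = True
            mat, spans = _simulate_rows(seq, params, rng)
            p0 = offset + primer_len
            p1 = offset + len(oligo.sequence) - primer_len
            rid = f"read_{r}"
            ids.append(rid)
            posts.append(mat)
            rows.append((rid, oi, oligo.name, chimeric,
                         int(spans[p0]), int(spans[p1])))
            r += 1
    truth = pd.DataFrame(rows, columns=["read_id", "oligo_index", "oligo_name",
                                        "chimeric", "payload_t0", "payload_t1"])
    return ReadSet(read_ids=ids, posteriors=posts, truth=truth)


def save_posteriors(read_set: ReadSet, path) -> None:
    """One dense matrix per read in an npz container keyed by read id."""
    np.savez_compressed(str(path),
                        **{rid: m for rid, m in zip(read_set.read_ids,
                                                    read_set.posteriors)})


def load_posteriors(path) -> dict[str, np.ndarray]:
    with np.load(str(path)) as z:
        return {k: z[k] for k in z.files}


def phred_quals(mat: np.ndarray, times: np.ndarray) -> list[int]:
    p = mat[times].max(axis=1) if times.size else np.empty(0)
    q = -10.0 * np.log10(np.maximum(1.0 - p, 1e-4))
    return [int(min(40, max(2, round(x)))) for x in q]


def write_fastq(read_set: ReadSet, path) -> None:
    """Greedy basecalls as FASTQ; quality = per-base max posterior, Phred."""
    with open(path, "w") as fh:
        for rid, mat in zip(read_set.read_ids, read_set.posteriors):
            seq, times = greedy_basecall_with_times(mat)
            quals = phred_quals(mat, times)
            fh.write(f"@{rid}\n{seq}\n+\n"
                     + "".join(chr(q + 33) for q in quals) + "\n")
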