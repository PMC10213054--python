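"""Experiment orchestration: encode -> simulate -> decode -> report.

The manifest is the decoding contract: everything needed to recover the file
from reads with no other context (geometry, code parameters, whitening seed,
primers) is serialized to JSON next to the pool FASTA.  ``run_pipeline``
exposes the four pipeline verbs on directories of artifacts; the library
functions below work purely in memory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bits import bits_from_int, int_from_bits
from .convcode import ConvCodeSpec, PUNCTURE_PATTERNS, conv_encode, standard_spec
from .crc import CRCSpec, crc_append
from .costs import CostReport, reading_cost, writing_cost
from .ctc import (UndecodableError, conv_ctc_list_decode,
                  conv_ctc_list_decode_batch, crc_filter,
                  greedy_basecall_with_times)
from .dna import OligoRecord, assemble_oligo, make_primers, trim_read, write_pool
from .outer import (ErasureError, RSParams, SegmentRecord, block_count_for,
                    index_width, rs_extend, rs_recover, segment_file, whiten)
from .simulate import (ChannelParams, CoverageModel, ReadSet, load_posteriors,
                       save_posteriors, simulate_pool_reads, write_fastq)


@dataclass
class Manifest:
    """Sidecar metadata sufficient to decode a pool."""

    file_id: str
    file_len_bytes: int
    whitening_seed: int
    data_bits_per_segment: int
    n_data_segments: int
    rs_k: int
    rs_p: int
    block_count: int
    n_total_segments: int
    index_width: int
    message_bits: int          # framed per-oligo bits: index + data + CRC
    payload_len_bases: int
    pad_bit: int               # value appended when the punctured stream is odd
    conv_memory: int
    conv_taps: list[int]
    conv_rate: str
    crc_polynomial: int
    crc_init: int
    crc_final_xor: int
    crc_segments: int
    fwd_primer: str
    rev_primer: str

    @property
    def conv_spec(self) -> ConvCodeSpec:
        return ConvCodeSpec(memory=self.conv_memory, taps=tuple(self.conv_taps),
                            puncture_pattern=PUNCTURE_PATTERNS[self.conv_rate])

    @property
    def crc_spec(self) -> CRCSpec:
        return CRCSpec(polynomial=self.crc_polynomial, init=self.crc_init,
                       final_xor=self.crc_final_xor, segments=self.crc_segments)

    @property
    def rs_params(self) -> RSParams:
        return RSParams(self.rs_k, self.rs_p)

    def to_json(self, path=None) -> str:
        txt = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(txt)
        return txt

    @classmethod
    def from_json(cls, source) -> "Manifest":
        p = Path(str(source))
        txt = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(txt))


@dataclass
class ExperimentConfig:
    """Fully seeded description of one encode/simulate/decode experiment."""

    file_size_bytes: int = 128
    file_path: str | None = None
    file_id: str = "file0"
    conv_memory: int = 6
    conv_rate: str = "1/2"
    data_bits_per_segment: int = 64
    rs_k: int = 8
    rs_p: int = 2
    crc_segments: int = 1
    channel: ChannelParams = field(default_factory=ChannelParams)
    coverage: CoverageModel = field(default_factory=lambda: CoverageModel(
        distribution="lognormal", sigma=0.5, total_reads=120))
    L: int = 8
    beam_width: int | str | None = "auto"
    n_subsample_trials: int = 10
    seed: int = 0

    def payload_bytes(self) -> bytes:
        if self.file_path is not None:
            return Path(self.file_path).read_bytes()
        rng = np.random.Generator(np.random.PCG64(self.seed + 1))
        return rng.integers(0, 256, self.file_size_bytes,
                            dtype=np.uint8).tobytes()


def encode_file(data: bytes, config: ExperimentConfig,
                primers: tuple[str, str] | None = None
                ) -> tuple[list[OligoRecord], Manifest]:
    """Whiten, segment, RS-extend, frame, convolutionally encode a file."""
    conv = standard_spec(config.conv_memory, config.conv_rate)
    crc = CRCSpec(segments=config.crc_segments)
    rs = RSParams(config.rs_k, config.rs_p)
    wseed = config.seed + 101
    white = whiten(data, wseed)
    segs = segment_file(white, config.data_bits_per_segment)
    n_data = len(segs)
    B = block_count_for(n_data, rs)
    all_segs = rs_extend(segs, rs, block_count=B)
    n_total = len(all_segs)
    w = index_width(n_total)
    if primers is None:
        primers = make_primers(1, config.seed + 202)[0]
    msg_bits = w + config.data_bits_per_segment + crc.total_check_bits

    pool = []
    payload_len = None
    for seg in all_segs:
        frame = crc_append(
            np.concatenate([bits_from_int(seg.index, w), seg.payload_bits]),
            crc)
        codeword = conv_encode(frame, conv)
        if codeword.size % 2:
            codeword = np.concatenate([codeword, np.zeros(1, dtype=np.uint8)])
        rec = assemble_oligo(codeword, primers[0], primers[1],
                             file_id=config.file_id, index=seg.index)
        payload_len = len(rec.payload_bases)
        pool.append(rec)

    manifest = Manifest(
        file_id=config.file_id, file_len_bytes=len(data), whitening_seed=wseed,
        data_bits_per_segment=config.data_bits_per_segment,
        n_data_segments=n_data, rs_k=rs.k, rs_p=rs.p, block_count=B,
        n_total_segments=n_total, index_width=w, message_bits=msg_bits,
        payload_len_bases=payload_len, pad_bit=0,
        conv_memory=config.conv_memory, conv_taps=list(conv.taps),
        conv_rate=config.conv_rate, crc_polynomial=crc.polynomial,
        crc_init=crc.init, crc_final_xor=crc.final_xor,
        crc_segments=crc.segments, fwd_primer=primers[0],
        rev_primer=primers[1])
    return pool, manifest


def trim_window(mat: np.ndarray, manifest: Manifest) -> np.ndarray | None:
    """Payload-window posterior rows of one read, or None on trim failure.

    The greedy basecall anchors each emitted base to the time step where its
    dwell starts; the base window from primer trimming maps to
    [first payload base's dwell start, first rev-primer base's dwell start),
    so no primer dwell rows leak into the decoder's input.
    """
    seq, times = greedy_basecall_with_times(mat)
    tr = trim_read(seq, manifest.fwd_primer, manifest.rev_primer)
    if tr.status == "not_found":
        return None
    b0, b1 = tr.payload_window
    T = mat.shape[0]
    if b0 >= len(times) or b1 < 1 or b1 > len(times):
        return None
    # [first payload base's dwell start, next base's dwell start): keeps the
    # trailing blank gap but no primer rows
    t0 = int(times[b0])
    t1 = T if b1 == len(times) else int(times[b1])
    return mat[t0:t1]


def _segment_from_result(result, manifest: Manifest
                         ) -> tuple[str, SegmentRecord | None]:
    if isinstance(result, UndecodableError):
        return "undecodable", None
    accepted = crc_filter(result, manifest.crc_spec)
    if accepted is None:
        return "crc_rejected", None
    msg, _rank = accepted
    w = manifest.index_width
    idx = int_from_bits(msg[:w])
    if idx >= manifest.n_total_segments:
        return "bad_index", None
    return "decoded", SegmentRecord(idx, msg[w:],
                                    is_parity=idx >= manifest.n_data_segments)


def decode_read(mat: np.ndarray, manifest: Manifest, L: int = 8,
                beam_width="auto",
                try_reverse_complement: bool = False
                ) -> tuple[str, SegmentRecord | None]:
    """Decode one posterior matrix to a segment; returns (status, segment).

    With ``try_reverse_complement`` a read whose primers are not found on
    the forward strand is retried on the reverse-complemented posterior
    (the simulator emits forward-strand reads only, so this is off by
    default).
    """
    window = trim_window(mat, manifest)
    if window is None and try_reverse_complement:
        from .ctc import reverse_complement_posterior
        window = trim_window(reverse_complement_posterior(mat), manifest)
    if window is None:
        return "trim_failed", None
    try:
        result = conv_ctc_list_decode(window, manifest.conv_spec,
                                      manifest.crc_spec,
                                      expected_message_bits=manifest.message_bits,
                                      L=L, beam_width=beam_width)
    except UndecodableError as e:
        return "undecodable", None
    return _segment_from_result(result, manifest)


def decode_all_reads(read_set: ReadSet, manifest: Manifest, L: int = 8,
                     beam_width="auto", batch_size: int = 64
                     ) -> list[tuple[str, SegmentRecord | None]]:
    """Trim every read, then list-decode the payload windows in batches."""
    windows = [trim_window(m, manifest) for m in read_set.posteriors]
    out: list = [("trim_failed", None)] * len(windows)
    todo = [i for i, w in enumerate(windows) if w is not None]
    for lo in range(0, len(todo), batch_size):
        chunk = todo[lo:lo + batch_size]
        results = conv_ctc_list_decode_batch(
            [windows[i] for i in chunk], manifest.conv_spec,
            manifest.crc_spec, expected_message_bits=manifest.message_bits,
            L=L, beam_width=beam_width)
        for i, res in zip(chunk, results):
            out[i] = _segment_from_result(res, manifest)
    return out


@dataclass
class DecodeOutcome:
    data: bytes | None
    per_read: pd.DataFrame  # read_id, status, index, correct
    segments: list[SegmentRecord]
    cost: CostReport | None
    error: str | None = None
    per_read_segments: list | None = None  # read-aligned (None on rejection)


def decode_read_set(read_set: ReadSet, manifest: Manifest,
                    pool: list[OligoRecord] | None = None, L: int = 8,
                    beam_width="auto") -> DecodeOutcome:
    """Decode every read, merge segments, run the outer recovery.

    When the designed pool is given, each accepted segment is additionally
    scored against its read's true source oligo, giving the correctly-decoded
    read fraction.
    """
    per_read_results = decode_all_reads(read_set, manifest, L=L,
                                        beam_width=beam_width)
    truth_by_read = None
    if pool is not None:
        truth_by_read = dict(zip(read_set.truth.read_id,
                                 read_set.truth.oligo_index))
    rows = []
    segments = []
    for rid, (status, seg) in zip(read_set.read_ids, per_read_results):
        correct = None
        if seg is not None:
            segments.append(seg)
            if pool is not None:
                src = pool[int(truth_by_read[rid])]
                correct = (seg.index == src.index and
                           _reencode_bases(seg, manifest) == src.payload_bases)
        rows.append((rid, status, seg.index if seg else None, correct))
    per_read = pd.DataFrame(rows, columns=["read_id", "status", "index",
                                           "correct"])
    file_bits = manifest.file_len_bytes * 8
    decoded_fraction = float((per_read.correct == True).mean()) if pool is not None \
        else float((per_read.status == "decoded").mean())  # noqa: E712
    try:
        data = rs_recover(segments, manifest.rs_params,
                          n_data=manifest.n_data_segments,
                          file_len_bytes=manifest.file_len_bytes,
                          whitening_seed=manifest.whitening_seed,
                          block_count=manifest.block_count)
        cost = CostReport(
            writing_cost=writing_cost(file_bits, manifest.n_total_segments,
                                      manifest.payload_len_bases),
            reading_cost=reading_cost(file_bits, len(read_set),
                                      manifest.payload_len_bases),
            decoded_fraction=decoded_fraction)
        return DecodeOutcome(data, per_read, segments, cost,
                             per_read_segments=[s for _, s in per_read_results])
    except ErasureError as e:
        cost = CostReport(
            writing_cost=writing_cost(file_bits, manifest.n_total_segments,
                                      manifest.payload_len_bases),
            reading_cost=reading_cost(file_bits, len(read_set),
                                      manifest.payload_len_bases),
            decoded_fraction=decoded_fraction)
        return DecodeOutcome(None, per_read, segments, cost, error=str(e),
                             per_read_segments=[s for _, s in per_read_results])


def _reencode_bases(seg: SegmentRecord, manifest: Manifest) -> str:
    from .dna import bits_to_bases
    frame = crc_append(
        np.concatenate([bits_from_int(seg.index, manifest.index_width),
                        seg.payload_bits]), manifest.crc_spec)
    cw = conv_encode(frame, manifest.conv_spec)
    if cw.size % 2:
        cw = np.concatenate([cw, np.zeros(1, dtype=np.uint8)])
    return bits_to_bases(cw)


def min_reads_for_decode(read_set: ReadSet, manifest: Manifest,
                         original: bytes, n_trials: int = 10, seed: int = 0,
                         L: int = 8, beam_width="auto",
                         per_read_segments: list | None = None
                         ) -> tuple[int | None, pd.DataFrame]:
    """Smallest subsample size whose every seeded trial recovers the file.

    Inner decoding is deterministic per read, so it is done once and cached;
    subsampling then only repeats the outer recovery.  The size grid is
    geometric (factor 1.25) refined by bisection around the transition.
    Success requires byte-exact recovery in all ``n_trials`` trials.
    """
    n_reads = len(read_set)
    if per_read_segments is None:
        per_read_segments = [s for _, s in decode_all_reads(
            read_set, manifest, L=L, beam_width=beam_width)]

    def trial_ok(size: int, rng: np.random.Generator) -> bool:
        pick = rng.choice(n_reads, size=size, replace=False)
        segs = [per_read_segments[i] for i in pick if per_read_segments[i] is not None]
        try:
            rec = rs_recover(segs, manifest.rs_params,
                             n_data=manifest.n_data_segments,
                             file_len_bytes=manifest.file_len_bytes,
                             whitening_seed=manifest.whitening_seed,
                             block_count=manifest.block_count)
        except ErasureError:
            return False
        return rec == original

    def all_ok(size: int) -> bool:
        rng = np.random.Generator(np.random.PCG64(seed + size))
        return all(trial_ok(size, rng) for _ in range(n_trials))

    sizes = []
    s = max(1, manifest.n_total_segments)
    while s < n_reads:
        sizes.append(s)
        s = max(s + 1, int(s * 1.25))
    sizes.append(n_reads)
    curve = []
    first_ok = None
    prev = 0
    for s in sizes:
        ok = all_ok(s)
        curve.append((s, ok))
        if ok and first_ok is None:
            first_ok = s
            lo = prev
            break
        prev = s
    if first_ok is None:
        return None, pd.DataFrame(curve, columns=["size", "all_trials_ok"])
    hi = first_ok
    while hi - lo > 1:
        mid = (lo + hi) // 2
        ok = all_ok(mid)
        curve.append((mid, ok))
        if ok:
            hi = mid
        else:
            lo = mid
    curve.sort()
    return hi, pd.DataFrame(curve, columns=["size", "all_trials_ok"])


def run_experiment(config: ExperimentConfig,
                   compute_min_reads: bool = False) -> dict:
    """In-memory end-to-end run; returns pool, manifest, outcome, cost."""
    data = config.payload_bytes()
    pool, manifest = encode_file(data, config)
    reads = simulate_pool_reads(pool, config.coverage, config.channel,
                                seed=config.seed + 303)
    outcome = decode_read_set(reads, manifest, pool=pool, L=config.L,
                              beam_width=config.beam_width)
    result = {"pool": pool, "manifest": manifest, "reads": reads,
              "outcome": outcome, "ok": outcome.data == data}
    if compute_min_reads and outcome.data == data:
        mr, curve = min_reads_for_decode(
            reads, manifest, data, n_trials=config.n_subsample_trials,
            seed=config.seed + 404,
            per_read_segments=outcome.per_read_segments)
        outcome.cost.min_reads = mr
        if mr is not None:
            fb = manifest.file_len_bytes * 8
            outcome.cost.reading_cost = reading_cost(
                fb, mr, manifest.payload_len_bases)
        result["min_reads_curve"] = curve
    return result


def run_pipeline(config: ExperimentConfig, verb: str, out_dir) -> dict:
    """Disk-artifact pipeline verbs: encode, simulate, decode, report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if verb == "encode":
        data = config.payload_bytes()
        pool, manifest = encode_file(data, config)
        write_pool(pool, out / "pool.fasta")
        manifest.to_json(out / "manifest.json")
        (out / "code_config.txt").write_text("\n".join(
            manifest.conv_spec.config_lines()
            + manifest.crc_spec.config_lines()) + "\n")
        (out / "payload.bin.txt").write_text(data.hex())
        return {"pool_fasta": out / "pool.fasta", "n_oligos": len(pool)}
    if verb == "simulate":
        from .dna import read_pool
        manifest = Manifest.from_json(out / "manifest.json")
        pool = read_pool(out / "pool.fasta")
        reads = simulate_pool_reads(pool, config.coverage, config.channel,
                                    seed=config.seed + 303)
        save_posteriors(reads, out / "posteriors.npz")
        write_fastq(reads, out / "reads.fastq")
        reads.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        return {"n_reads": len(reads)}
    if verb == "decode":
        from .dna import read_pool
        manifest = Manifest.from_json(out / "manifest.json")
        conv = standard_spec(config.conv_memory, config.conv_rate)
        if (manifest.conv_memory, manifest.conv_rate) != (
                config.conv_memory, config.conv_rate):
            raise ValueError(
                "manifest/config mismatch: pool was encoded with "
                f"m={manifest.conv_memory}, r={manifest.conv_rate}; refusing "
                "to decode with a different inner code")
        posts = load_posteriors(out / "posteriors.npz")
        truth = pd.read_csv(out / "truth.tsv", sep="\t")
        reads = ReadSet(read_ids=list(posts.keys()),
                        posteriors=list(posts.values()), truth=truth)
        pool = read_pool(out / "pool.fasta")
        outcome = decode_read_set(reads, manifest, pool=pool, L=config.L,
                                  beam_width=config.beam_width)
        if outcome.data is not None:
            (out / "recovered.bin.txt").write_text(outcome.data.hex())
        outcome.per_read.to_csv(out / "read_log.tsv", sep="\t", index=False)
        (out / "cost_report.json").write_text(
            json.dumps(outcome.cost.to_dict(), indent=2))
        return {"recovered": outcome.data is not None,
                "decoded_fraction": outcome.cost.decoded_fraction}
    if verb == "report":
        rows = []
        for m in (6, 8, 11):
            for r in ("1/2", "3/4"):
                cfg = replace(config, conv_memory=m, conv_rate=r)
                res = run_experiment(cfg)
                rows.append((m, r, res["outcome"].cost.decoded_fraction,
                             res["outcome"].cost.writing_cost,
                             res["outcome"].cost.reading_cost, res["ok"]))
        df = pd.DataFrame(rows, columns=["memory", "rate", "decoded_fraction",
                                         "writing_cost", "reading_cost",
                                         "recovered"])
        df.to_csv(out / "sweep_report.csv", index=False)
        return {"report": out / "sweep_report.csv", "table": df}
    raise ValueError(f"unknown verb {verb!r}")
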