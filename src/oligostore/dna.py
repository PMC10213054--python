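"""Bit <-> base mapping, oligo assembly with primer flanks, read trimming.

The codebook is the standard 2 bits/base mapping 00:A, 01:C, 10:G, 11:T.
Oligos are ``fwd_primer + payload + rev_primer`` with 25-nt primers by
default and a total length kept under 200 nt.  Trimming locates the primer
pair in a (basecalled) read by local alignment; a trimming penalty lets
terminally truncated primers still be accepted at a controlled discount,
while complete primer hits are preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bits import as_bits

BASES = "ACGT"
_BASE_TO_VAL = {b: i for i, b in enumerate(BASES)}

MAX_OLIGO_LEN = 200


def bits_to_bases(bits) -> str:
    """Map an even-length bit vector to bases, 2 bits/base (00:A .. 11:T)."""
    bits = as_bits(bits)
    if bits.size % 2:
        raise ValueError("bit length must be even for exact 2 bits/base mapping")
    vals = bits[0::2] * 2 + bits[1::2]
    return "".join(BASES[v] for v in vals)


def bases_to_bits(seq: str) -> np.ndarray:
    """Inverse of :func:`bits_to_bases`."""
    out = np.empty(2 * len(seq), dtype=np.uint8)
    for i, b in enumerate(seq):
        try:
            v = _BASE_TO_VAL[b]
        except KeyError:
            raise ValueError(f"non-ACGT base {b!r}")
        out[2 * i] = v >> 1
        out[2 * i + 1] = v & 1
    return out


@dataclass
class OligoRecord:
    """One designed oligo: primer-flanked encoded payload."""

    file_id: str
    index: int
    fwd_primer: str
    payload_bases: str
    rev_primer: str

    @property
    def sequence(self) -> str:
        return self.fwd_primer + self.payload_bases + self.rev_primer

    @property
    def name(self) -> str:
        return f"{self.file_id}_{self.index}"


def assemble_oligo(codeword_bits, fwd_primer: str, rev_primer: str,
                   file_id: str = "file0", index: int = 0,
                   strict_length: bool = False) -> OligoRecord:
    """Flank the base-mapped codeword with primers.

    Codeword bit length must be even (pad upstream if the punctured stream is
    odd).  Total lengths of 200 nt or more trigger a warning, or a hard error
    with ``strict_length=True``.
    """
    payload = bits_to_bases(codeword_bits)
    rec = OligoRecord(file_id, index, fwd_primer, payload, rev_primer)
    if len(rec.sequence) >= MAX_OLIGO_LEN:
        msg = (f"oligo {rec.name} is {len(rec.sequence)} nt "
               f"(designs target < {MAX_OLIGO_LEN} nt)")
        if strict_length:
            raise ValueError(msg)
        warnings.warn(msg)
    return rec


def write_pool(pool: list[OligoRecord], path) -> None:
    records = [SeqRecord(Seq(o.sequence), id=o.name, description="")
               for o in pool]
    SeqIO.write(records, str(path), "fasta")


def read_pool(path, primer_len: int = 25) -> list[OligoRecord]:
    """Read a pool FASTA written by :func:`write_pool`."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        file_id, idx = rec.id.rsplit("_", 1)
        seq = str(rec.seq)
        out.append(OligoRecord(file_id, int(idx), seq[:primer_len],
                               seq[primer_len:len(seq) - primer_len],
                               seq[len(seq) - primer_len:]))
    return out


def write_primer_table(table: dict[str, tuple[str, str]], path) -> None:
    df = pd.DataFrame(
        [(fid, f, r) for fid, (f, r) in table.items()],
        columns=["file_id", "fwd_primer", "rev_primer"])
    df.to_csv(path, sep="\t", index=False)


def read_primer_table(path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.file_id: (row.fwd_primer, row.rev_primer)
            for row in df.itertuples()}


def make_primers(n: int, seed: int, length: int = 25) -> list[tuple[str, str]]:
    """Seeded random primer pairs (no homopolymers > 3), one pair per file."""
    rng = np.random.Generator(np.random.PCG64(seed))
    pairs = []
    while len(pairs) < n:
        seq = "".join(BASES[v] for v in rng.integers(0, 4, 2 * length))
        if any(b * 4 in seq for b in BASES):
            continue
        pairs.append((seq[:length], seq[length:]))
    return pairs


@dataclass
class TrimResult:
    """Payload window located in a read, with primer alignment diagnostics."""

    payload_window: tuple[int, int]
    fwd_score: float
    rev_score: float
    status: str  # ok | start_late_chimera_suspect | not_found


def _make_aligner(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = match
    aln.mismatch_score = mismatch
    aln.open_gap_score = gap_open
    aln.extend_gap_score = gap_extend
    return aln


def _best_hit(aligner, read: str, primer: str):
    """(adjusted basis) best local alignment of primer in read.

    Returns (raw_score, read_span, primer_span, missing_terminal_bases) or
    None when there is no positive-score alignment.
    """
    if not read:
        return None
    alns = aligner.align(read, primer)
    if len(alns) == 0 or alns.score <= 0:
        return None
    a = alns[0]
    tb, qb = a.aligned
    c, d = int(tb[0][0]), int(tb[-1][1])
    qa, qe = int(qb[0][0]), int(qb[-1][1])
    missing_prefix = max(0, qa - c)
    missing_suffix = max(0, (len(primer) - qe) - (len(read) - d))
    return float(a.score), (c, d), (qa, qe), missing_prefix + missing_suffix


def trim_read(read: str, fwd_primer: str, rev_primer: str,
              penalty: float = 0.5, threshold_frac: float = 0.6,
              chimera_offset: int = 50) -> TrimResult:
    """Locate the payload window between the primer pair in a read.

    A primer hit is accepted when ``raw_score - penalty * missing`` clears
    ``threshold_frac * len(primer)``, where ``missing`` counts primer bases
    truncated off a read end; this admits trimmed primers at a discount while
    preferring complete hits.  A forward-primer hit starting beyond
    ``chimera_offset`` flags the read as a chimera suspect but still trims at
    that hit.
    """
    if len(read) < 1:
        raise ValueError("empty read")
    aligner = _make_aligner()
    fhit = _best_hit(aligner, read, fwd_primer)
    rhit = _best_hit(aligner, read, rev_primer)

    def accepted(hit, primer):
        if hit is None:
            return False
        score, _, _, missing = hit
        return score - penalty * missing >= threshold_frac * len(primer)

    f_ok = accepted(fhit, fwd_primer)
    r_ok = accepted(rhit, rev_primer)
    if not (f_ok and r_ok):
        return TrimResult((0, 0), fhit[0] if fhit else 0.0,
                          rhit[0] if rhit else 0.0, "not_found")
    fscore, (fc, fd), (fa, fe), _ = fhit
    rscore, (rc, rd), (ra, re_), _ = rhit
    start = min(len(read), fd + (len(fwd_primer) - fe))
    end = max(0, rc - ra)
    if start >= end:
        return TrimResult((0, 0), fscore, rscore, "not_found")
    status = "start_late_chimera_suspect" if fc > chimera_offset else "ok"
    return TrimResult((start, end), fscore, rscore, status)
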