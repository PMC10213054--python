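"""Combinatorial barcode addresses (CBA): design, assembly, k-mer decoding.

An address is a word of 6 subunits, each in one of 8 states, so 48 designed
20-mer barcodes span 8^6 = 262,144 addresses.  Barcodes and the 7 scaffold
spacers are generated by rejection sampling so that no two of the 55
sequences share any 9-mer; a barcode is then identifiable in noisy reads by
counting how many of its 12 constituent 9-mers appear in a subunit window.
The strict inclusion criterion additionally requires every competing
barcode's k-mer count to be zero at every subunit.  Hierarchical access is
modeled as six sequential selection rounds with a per-round gain for
matching constructs and a leak fraction for the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dna import BASES, OligoRecord


@dataclass(frozen=True)
class CBAAddress:
    """One address: a state digit per subunit (an octal word by default)."""

    digits: tuple[int, ...]

    def __str__(self) -> str:
        return "".join(str(d) for d in self.digits)

    @classmethod
    def from_string(cls, s: str) -> "CBAAddress":
        return cls(tuple(int(c) for c in s))


@dataclass
class CBADesign:
    """Barcode/scaffold sequence set with its slot assignment."""

    barcodes: list[str]
    scaffolds: list[str]
    linker: str
    subunits: int = 6
    states_per_subunit: int = 8
    k: int = 9

    def barcode(self, subunit: int, state: int) -> str:
        return self.barcodes[subunit * self.states_per_subunit + state]

    @property
    def barcode_to_slot(self) -> dict[str, tuple[int, int]]:
        return {self.barcode(su, st): (su, st)
                for su in range(self.subunits)
                for st in range(self.states_per_subunit)}

    def kmers(self, seq: str) -> set[str]:
        return {seq[i:i + self.k] for i in range(len(seq) - self.k + 1)}

    def validate(self) -> None:
        """Exhaustive pairwise k-mer disjointness check."""
        seqs = self.barcodes + self.scaffolds + [self.linker]
        pools = [self.kmers(s) for s in seqs]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if pools[i] & pools[j]:
                    raise ValueError(f"sequences {i} and {j} share a {self.k}-mer")


class DesignInfeasibleError(Exception):
    pass


def design_barcode_set(n_sequences: int = 56, length: int = 20, k: int = 9,
                       seed: int = 0, subunits: int = 6,
                       states_per_subunit: int = 8,
                       max_rejections: int = 10 ** 6) -> CBADesign:
    """Rejection-sample a pairwise k-mer-disjoint sequence set.

    The first ``subunits * states_per_subunit`` accepted sequences become
    barcodes (eight consecutive sequences per subunit), the next
    ``subunits + 1`` the flanking scaffolds, and one more the payload linker.
    """
    need = subunits * states_per_subunit + subunits + 1 + 1
    if n_sequences < need:
        n_sequences = need
    if length < k:
        raise ValueError("length must be >= k")
    rng = np.random.Generator(np.random.PCG64(seed))
    accepted: list[str] = []
    pool: set[str] = set()
    rejections = 0
    while len(accepted) < n_sequences:
        seq = "".join(BASES[v] for v in rng.integers(0, 4, length))
        kmers = {seq[i:i + k] for i in range(length - k + 1)}
        if len(kmers) < length - k + 1 or kmers & pool:
            rejections += 1
            if rejections > max_rejections:
                raise DesignInfeasibleError(
                    f"stalled after {max_rejections} consecutive rejections")
            continue
        rejections = 0
        accepted.append(seq)
        pool |= kmers
    nb = subunits * states_per_subunit
    return CBADesign(barcodes=accepted[:nb],
                     scaffolds=accepted[nb:nb + subunits + 1],
                     linker=accepted[nb + subunits + 1],
                     subunits=subunits, states_per_subunit=states_per_subunit,
                     k=k)


def address_space(subunits: int, states: int) -> tuple[int, int]:
    """(number of addresses, number of subunit oligos needed)."""
    return states ** subunits, subunits * states


def assemble_cba(address: CBAAddress, design: CBADesign,
                 payload: OligoRecord | str) -> str:
    """scaffold1-barcode-scaffold2-...-scaffold7-linker-payload construct."""
    if len(address.digits) != design.subunits:
        raise ValueError("address length != number of subunits")
    parts = []
    for su, d in enumerate(address.digits):
        if not 0 <= d < design.states_per_subunit:
            raise ValueError(f"digit {d} out of range at subunit {su}")
        parts.append(design.scaffolds[su])
        parts.append(design.barcode(su, d))
    parts.append(design.scaffolds[design.subunits])
    parts.append(design.linker)
    seq = payload.sequence if isinstance(payload, OligoRecord) else str(payload)
    parts.append(seq)
    return "".join(parts)


def kmer_decode_subunit(window: str, design: CBADesign, subunit: int
                        ) -> tuple[int | None, np.ndarray]:
    """Count matching k-mers per candidate barcode of one subunit.

    Returns ``(best_state, counts)``; a tie for the maximum (including the
    all-zero case) yields no call.
    """
    if not window:
        raise ValueError("empty window")
    k = design.k
    window_kmers = {window[i:i + k] for i in range(max(0, len(window) - k + 1))}
    counts = np.zeros(design.states_per_subunit, dtype=np.int64)
    for st in range(design.states_per_subunit):
        counts[st] = len(design.kmers(design.barcode(subunit, st)) & window_kmers)
    best = int(counts.argmax())
    if counts[best] == 0 or (counts == counts[best]).sum() > 1:
        return None, counts
    return best, counts


@dataclass
class CBACallResult:
    """Per-subunit calls plus the full-address verdict."""

    per_subunit: list[tuple[int | None, int, int]]  # (state, best count, runner-up count)
    full_address: CBAAddress | None
    strict_pass: bool
    has_tag: bool = True


def _scaffold_anchors(read: str, design: CBADesign
                      ) -> dict[int, tuple[int, bool]]:
    """Estimated start of each scaffold found in the read.

    Maps scaffold index to ``(position, exact)``; ``exact`` means every
    scaffold k-mer matched at one consistent offset, so the position carries
    no uncertainty.
    """
    k = design.k
    anchors: dict[int, tuple[int, bool]] = {}
    read_kmers: dict[str, int] = {}
    for i in range(len(read) - k + 1):
        read_kmers.setdefault(read[i:i + k], i)
    for si, scaf in enumerate(design.scaffolds):
        hits = []
        for off in range(len(scaf) - k + 1):
            pos = read_kmers.get(scaf[off:off + k])
            if pos is not None:
                hits.append(pos - off)
        if hits:
            exact = (len(hits) == len(scaf) - k + 1
                     and len(set(hits)) == 1)
            anchors[si] = (int(np.median(hits)), exact)
    return anchors


def decode_cba(read: str, design: CBADesign, mode: str = "strict",
               slack: int = 5) -> CBACallResult:
    """Decode the address region of a read by scaffold-anchored k-mer matching.

    Subunit windows are taken between consecutive scaffold anchors; ``slack``
    nt of margin is added only on sides whose anchor position is uncertain
    (imperfect or inferred), so error-free constructs get exact windows with
    no junction-spanning k-mers.  A missing scaffold is inferred from its
    nearest found neighbour assuming the designed spacing.  Fewer than two
    scaffold anchors means the read carries no recognizable address tag.
    """
    if mode not in ("strict", "best_match"):
        raise ValueError("mode must be 'strict' or 'best_match'")
    anchors = _scaffold_anchors(read, design)
    if len(anchors) < 2:
        return CBACallResult([], None, False, has_tag=False)
    unit = len(design.scaffolds[0]) + len(design.barcodes[0])  # designed spacing
    # fill in missing scaffold anchors from the nearest found neighbour
    full = {si: pos for si, (pos, _) in anchors.items()}
    exact = {si: ex for si, (_, ex) in anchors.items()}
    for si in range(design.subunits + 1):
        if si in full:
            continue
        ref = min(anchors, key=lambda s: abs(s - si))
        full[si] = full[ref] + (si - ref) * unit
        exact[si] = False
    per = []
    digits = []
    strict = True
    slen = len(design.scaffolds[0])
    for su in range(design.subunits):
        s0 = 0 if exact[su] else slack
        s1 = 0 if exact[su + 1] else slack
        w0 = max(0, full[su] + slen - s0)
        w1 = min(len(read), full[su + 1] + s1)
        if w0 >= w1:
            per.append((None, 0, 0))
            digits.append(None)
            strict = False
            continue
        best, counts = kmer_decode_subunit(read[w0:w1], design, su)
        top = int(np.sort(counts)[-1])
        runner = int(np.sort(counts)[-2]) if counts.size > 1 else 0
        per.append((best, top, runner))
        digits.append(best)
        if best is None or runner != 0:
            strict = False
    ok = all(d is not None for d in digits)
    if mode == "strict":
        success = ok and strict
    else:
        success = ok
    addr = CBAAddress(tuple(digits)) if success else None
    return CBACallResult(per, addr, strict_pass=(ok and strict))


def build_lookup_table(reads: list[tuple[str, str]], design: CBADesign
                       ) -> dict[str, str]:
    """Address -> payload-id lookup table from (read, payload_id) pairs.

    Mirrors ground-truth table construction: only reads decoding under the
    strict inclusion criterion (zero competing k-mer counts at every
    subunit) enter the table; conflicting payloads for one address evict
    the entry.
    """
    table: dict[str, str] = {}
    conflicted: set[str] = set()
    for read, payload_id in reads:
        res = decode_cba(read, design, mode="strict")
        if res.full_address is None:
            continue
        key = str(res.full_address)
        if key in conflicted:
            continue
        if key in table and table[key] != payload_id:
            warnings.warn(f"conflicting payloads for address {key}; dropping")
            del table[key]
            conflicted.add(key)
            continue
        table[key] = payload_id
    return table


def per_subunit_failure(overall_success: float, subunits: int) -> float:
    """Per-subunit failure rate under independence: 1 - s**(1/n)."""
    if not 0 < overall_success <= 1:
        raise ValueError("overall_success must be in (0, 1]")
    return 1.0 - overall_success ** (1.0 / subunits)


def traverse_address(tagged_pool: list[tuple[CBAAddress, str, float]],
                     target: CBAAddress, gain: float = 500.0,
                     leak: float = 0.05) -> "pd.DataFrame":
    """Simulate sequential per-subunit selection rounds.

    Round ``i`` multiplies the abundance of constructs whose digit ``i``
    matches the target by ``gain`` and of all others by ``leak``, then
    renormalizes (the dilution between reactions).  Returns the final
    abundance table with the fold-enrichment of the target payload versus
    the median payload.
    """
    import pandas as pd
    if not tagged_pool:
        raise ValueError("empty pool")
    addrs = [a for a, _, _ in tagged_pool]
    ab = np.array([x for _, _, x in tagged_pool], dtype=float)
    ab = ab / ab.sum()
    for i, tdigit in enumerate(target.digits):
        match = np.array([a.digits[i] == tdigit for a in addrs])
        if not match.any():
            warnings.warn(f"no construct matches target digit at subunit {i}; "
                          "enrichment will be empty")
        ab = np.where(match, ab * gain, ab * leak)
        tot = ab.sum()
        if tot > 0:
            ab = ab / tot
    df = pd.DataFrame({
        "address": [str(a) for a in addrs],
        "payload_id": [p for _, p, _ in tagged_pool],
        "abundance": ab,
    })
    is_target = np.array([a.digits == target.digits for a in addrs])
    med = float(np.median(ab[~is_target])) if (~is_target).any() else 0.0
    tgt = float(ab[is_target].sum()) if is_target.any() else 0.0
    df.attrs["target_abundance"] = tgt
    df.attrs["median_other_abundance"] = med
    df.attrs["fold_enrichment_vs_median"] = tgt / med if med > 0 else np.inf
    return df
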