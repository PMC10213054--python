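"""Writing/reading cost metrics.

Writing cost is bases synthesized per information bit, reading cost bases
sequenced per information bit; coverage is their ratio and coding density
(bits/base) the reciprocal of writing cost.  Primer bases are excluded from
the oligo length in both costs.
"""

from __future__ import annotations

from dataclasses import dataclass


def writing_cost(file_bits: int, n_oligos: int, payload_len_bases: int) -> float:
    """Bases synthesized per information bit (primers excluded)."""
    if file_bits <= 0 or n_oligos <= 0 or payload_len_bases <= 0:
        raise ValueError("all inputs must be > 0")
    return n_oligos * payload_len_bases / file_bits


def reading_cost(file_bits: int, n_reads_used: int, payload_len_bases: int) -> float:
    """Bases sequenced per information bit (primers excluded)."""
    if file_bits <= 0 or n_reads_used <= 0 or payload_len_bases <= 0:
        raise ValueError("all inputs must be > 0")
    return n_reads_used * payload_len_bases / file_bits


def coding_density(write_cost: float) -> float:
    """Bits per base: the reciprocal of writing cost."""
    return 1.0 / write_cost


@dataclass
class CostReport:
    """Cost/coverage summary of one decode experiment."""

    writing_cost: float
    reading_cost: float
    decoded_fraction: float
    min_reads: int | None = None

    @property
    def coverage(self) -> float:
        return self.reading_cost / self.writing_cost

    @property
    def density(self) -> float:
        return coding_density(self.writing_cost)

    def to_dict(self) -> dict:
        return {
            "writing_cost_bases_per_bit": self.writing_cost,
            "reading_cost_bases_per_bit": self.reading_cost,
            "coverage": self.coverage,
            "coding_density_bits_per_base": self.density,
            "decoded_fraction": self.decoded_fraction,
            "min_reads": self.min_reads,
        }
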