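"""Combinatorial barcode addresses: design, decoding, traversal."""

import numpy as np
import pytest

from oligostore.cba import (CBAAddress, address_space, assemble_cba,
                            decode_cba, design_barcode_set,
                            kmer_decode_subunit, per_subunit_failure,
                            traverse_address)
from oligostore.ctc import greedy_basecall
from oligostore.simulate import ChannelParams, simulate_posterior


@pytest.fixture(scope="module")
def design():
    return design_barcode_set(seed=11)


def brute_force_disjoint(seqs, k):
    """Independent enumeration oracle for pairwise k-mer disjointness."""
    pools = [{s[i:i + k] for i in range(len(s) - k + 1)} for s in seqs]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if pools[i] & pools[j]:
                return False
    return True


class TestDesign:
    def test_counts_and_lengths(self, design):
        assert len(design.barcodes) == 48
        assert len(design.scaffolds) == 7
        assert all(len(s) == 20 for s in design.barcodes + design.scaffolds)

    def test_pairwise_kmer_disjoint(self, design):
        seqs = design.barcodes + design.scaffolds + [design.linker]
        assert brute_force_disjoint(seqs, design.k)
        design.validate()

    def test_each_barcode_has_twelve_kmers(self, design):
        assert all(len(design.kmers(b)) == 12 for b in design.barcodes)

    def test_single_sequence_always_succeeds(self):
        d = design_barcode_set(n_sequences=1, subunits=1,
                               states_per_subunit=1, seed=0)
        assert len(d.barcodes) == 1

    def test_deterministic(self):
        a = design_barcode_set(seed=3)
        b = design_barcode_set(seed=3)
        assert a.barcodes == b.barcodes and a.scaffolds == b.scaffolds


class TestAddressSpace:
    @pytest.mark.parametrize("su,st,n_addr,n_oligo", [
        (6, 8, 262_144, 48),
        (1, 1, 1, 1),
        (3, 2, 8, 6),
    ])
    def test_arithmetic(self, su, st, n_addr, n_oligo):
        assert address_space(su, st) == (n_addr, n_oligo)


class TestSubunitDecoding:
    def test_exact_barcode_full_count(self, design):
        bc = design.barcode(2, 5)
        best, counts = kmer_decode_subunit(bc, design, 2)
        assert best == 5
        assert counts[5] == 12
        assert counts.sum() == 12  # every other candidate at zero

    def test_central_substitution_drops_to_three(self, design):
        bc = list(design.barcode(1, 0))
        bc[10] = "A" if bc[10] != "A" else "C"
        window = "".join(bc)
        best, counts = kmer_decode_subunit(window, design, 1)
        # position 10 is covered by 9 of the 12 9-mers; 3 survive
        assert counts[0] == 3
        assert best == 0
        assert (counts[1:] == 0).all()

    def test_random_windows_rarely_match(self, design):
        rng = np.random.default_rng(0)
        n_hits = 0
        for _ in range(1000):
            w = "".join("ACGT"[v] for v in rng.integers(0, 4, 30))
            _, counts = kmer_decode_subunit(w, design, 0)
            n_hits += counts.sum() > 0
        # 22 random 9-mers vs 96 designed ones out of 4^9 ~ 0.8% hit rate
        assert n_hits < 40


class TestFullDecode:
    def test_error_free_round_trip(self, design):
        rng = np.random.default_rng(1)
        payload = "".join("ACGT"[v] for v in rng.integers(0, 4, 60))
        for trial in range(20):
            addr = CBAAddress(tuple(rng.integers(0, 8, 6).tolist()))
            read = assemble_cba(addr, design, payload)
            res = decode_cba(read, design, mode="strict")
            assert res.full_address == addr
            assert res.strict_pass

    def test_scrambled_subunit_fails_alone(self, design):
        rng = np.random.default_rng(2)
        addr = CBAAddress((1, 2, 3, 4, 5, 6))
        read = assemble_cba(addr, design, "ACGT" * 10)
        # scramble subunit 3's barcode window
        pos = 3 * 40 + 20
        read = read[:pos] + "".join(
            "ACGT"[v] for v in rng.integers(0, 4, 20)) + read[pos + 20:]
        res = decode_cba(read, design, mode="best_match")
        assert res.full_address is None
        states = [s for s, _, _ in res.per_subunit]
        assert states[3] is None
        assert [states[i] for i in (0, 1, 2, 4, 5)] == [1, 2, 3, 5, 6]

    def test_no_tag_signal(self, design):
        rng = np.random.default_rng(3)
        read = "".join("ACGT"[v] for v in rng.integers(0, 4, 300))
        assert not decode_cba(read, design).has_tag

    def test_strict_never_beats_best_match(self, design):
        rng = np.random.default_rng(4)
        params = ChannelParams()
        strict = best = 0
        for i in range(60):
            addr = CBAAddress(tuple(rng.integers(0, 8, 6).tolist()))
            read = greedy_basecall(simulate_posterior(
                assemble_cba(addr, design, "ACGT" * 10), params, seed=i))
            rs = decode_cba(read, design, mode="strict")
            rb = decode_cba(read, design, mode="best_match")
            strict += rs.full_address == addr
            best += rb.full_address == addr
        assert strict <= best
        assert best > 30  # k-mer decoding tolerates channel noise


class TestFailureModel:
    def test_paper_operating_point(self):
        """70% full-address success over 6 subunits -> ~6% per subunit."""
        assert per_subunit_failure(0.70, 6) == pytest.approx(0.0577, abs=5e-4)

    @pytest.mark.parametrize("s,n,expect", [(1.0, 6, 0.0), (0.25, 2, 0.5)])
    def test_closed_form(self, s, n, expect):
        assert per_subunit_failure(s, n) == pytest.approx(expect)

    def test_inverts_independence_model(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = float(rng.uniform(0.01, 1.0))
            n = int(rng.integers(1, 10))
            f = per_subunit_failure(s, n)
            assert (1 - f) ** n == pytest.approx(s, abs=1e-12)


class TestTraversal:
    def _pool(self, n, seed, target):
        rng = np.random.default_rng(seed)
        pool = [(target, "target_payload", 1.0)]
        for i in range(n - 1):
            pool.append((CBAAddress(tuple(rng.integers(0, 8, 6).tolist())),
                         f"p{i}", 1.0))
        return pool

    def test_perfect_selection(self):
        target = CBAAddress((0, 1, 2, 3, 4, 5))
        df = traverse_address(self._pool(500, 0, target), target,
                              gain=100.0, leak=0.0)
        ab = df.set_index("payload_id").abundance
        others = ab.drop("target_payload")
        assert ab["target_payload"] == pytest.approx(1.0)
        assert (others == 0).all()

    def test_identity_when_gain_equals_leak(self):
        target = CBAAddress((7, 7, 7, 7, 7, 7))
        pool = self._pool(100, 1, target)
        df = traverse_address(pool, target, gain=1.0, leak=1.0)
        assert np.allclose(df.abundance, 1.0 / 100)

    def test_enrichment_exceeds_ten_thousand_fold(self):
        """g=500, leak 5%, 10,000 uniform addresses: >1e4-fold vs median."""
        target = CBAAddress((5, 1, 2, 2, 3, 7))
        df = traverse_address(self._pool(10_000, 2, target), target,
                              gain=500.0, leak=0.05)
        assert df.attrs["fold_enrichment_vs_median"] > 1e4


class TestLookupTable:
    def test_strict_table_from_clean_reads(self):
        from oligostore.cba import build_lookup_table
        design = design_barcode_set(seed=11)
        rng = np.random.default_rng(9)
        reads = []
        truth = {}
        for i in range(30):
            addr = CBAAddress(tuple(rng.integers(0, 8, 6).tolist()))
            pid = f"oligo_{i}"
            reads.append((assemble_cba(addr, design, "ACGT" * 12), pid))
            truth.setdefault(str(addr), pid)
        table = build_lookup_table(reads, design)
        assert table == truth

    def test_conflicting_address_evicted(self):
        from oligostore.cba import build_lookup_table
        design = design_barcode_set(seed=11)
        addr = CBAAddress((1, 2, 3, 4, 5, 6))
        read = assemble_cba(addr, design, "ACGT" * 12)
        with pytest.warns(UserWarning, match="conflicting payloads"):
            table = build_lookup_table([(read, "a"), (read, "b"),
                                        (read, "a")], design)
        assert str(addr) not in table
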