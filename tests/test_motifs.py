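import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odnscreen import (
    FingerprintDictionary,
    MotifToken,
    OdnRecord,
    build_dictionary,
    dedup_by_similarity,
    encode_fingerprint,
    enumerate_motifs,
    occurrence_rates,
    tanimoto,
)

from conftest import random_sequence

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


def brute_force_tokens(seq: str, lo: int = 2, hi: int = 6) -> set[MotifToken]:
    out = set()
    for start in range(len(seq)):
        for k in range(lo, hi + 1):
            if start + k <= len(seq):
                out.add(MotifToken(seq[start : start + k], start + 1))
    return out


class TestEnumerateMotifs:
    def test_tcg_worked_example(self):
        assert enumerate_motifs("TCG") == {
            MotifToken("TC", 1),
            MotifToken("CG", 2),
            MotifToken("TCG", 1),
        }

    def test_minimal_and_short(self):
        assert enumerate_motifs("AA") == {MotifToken("AA", 1)}
        assert enumerate_motifs("A") == set()

    def test_length_six_count(self):
        assert len(enumerate_motifs("ACGTAC")) == 15

    @settings(derandomize=True, max_examples=60)
    @given(dna)
    def test_matches_closed_form_and_oracle(self, seq):
        tokens = enumerate_motifs(seq)
        assert tokens == brute_force_tokens(seq)
        L = len(seq)
        expected = sum(max(L - k + 1, 0) for k in range(2, 7))
        assert len(tokens) == expected


class TestOccurrenceRates:
    def test_fraction_of_containing_odns(self):
        recs = [OdnRecord(f"r{i}", s) for i, s in enumerate(["CGA", "CGT", "TTT", "ATT"])]
        rates = occurrence_rates(recs)
        assert rates[MotifToken("CG", 1)] == 0.5
        assert MotifToken("GG", 1) not in rates
        assert rates[MotifToken("TT", 2)] == 0.5

    def test_requested_token_absent_everywhere(self):
        recs = [OdnRecord("r", "AAA")]
        assert occurrence_rates(recs, [MotifToken("CG", 1)]) == {MotifToken("CG", 1): 0.0}

    def test_all_containing(self):
        recs = [OdnRecord(f"r{i}", s) for i, s in enumerate(["CGA", "CGC", "CGG"])]
        assert occurrence_rates(recs)[MotifToken("CG", 1)] == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            occurrence_rates([])


class TestBuildDictionary:
    def test_hand_enumeration(self):
        high = [OdnRecord("h1", "CGT"), OdnRecord("h2", "CGA")]
        low = [OdnRecord("l1", "TTT"), OdnRecord("l2", "CGT")]
        d = build_dictionary(high, low, threshold=0.10)
        cg1 = MotifToken("CG", 1)
        assert cg1 in d.tokens
        assert d.rate_high[cg1] == 1.0
        assert d.rate_low[cg1] == 0.5

    def test_zero_difference_excluded(self):
        high = [OdnRecord("h", "CGT")]
        low = [OdnRecord("l", "CGT")]
        assert len(build_dictionary(high, low)) == 0

    def test_threshold_zero_keeps_everything(self):
        high = [OdnRecord("h", "CGT")]
        low = [OdnRecord("l", "TAA")]
        d = build_dictionary(high, low, threshold=0.0)
        assert set(d.tokens) == enumerate_motifs("CGT") | enumerate_motifs("TAA")

    def test_threshold_inclusive(self):
        # rates 1.0 vs 0.9 -> diff exactly 0.10 must be kept
        high = [OdnRecord(f"h{i}", "CGTT") for i in range(10)]
        low = [OdnRecord(f"l{i}", "CGTT") for i in range(9)] + [OdnRecord("l9", "AAAA")]
        d = build_dictionary(high, low)
        assert MotifToken("CG", 1) in d.tokens

    def test_deterministic_ordering(self):
        high = [OdnRecord("h", "CGTA"), OdnRecord("h2", "CGTT")]
        low = [OdnRecord("l", "TTTT"), OdnRecord("l2", "ATAT")]
        d1 = build_dictionary(high, low)
        d2 = build_dictionary(high, low)
        assert d1.tokens == d2.tokens
        diffs = [abs(d1.rate_high[t] - d1.rate_low[t]) for t in d1.tokens]
        assert diffs == sorted(diffs, reverse=True)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            build_dictionary([], [OdnRecord("l", "ACGT")])

    def test_tsv_round_trip(self, tmp_path):
        d = build_dictionary([OdnRecord("h", "CGTA")], [OdnRecord("l", "TTTT")])
        p = tmp_path / "dict.tsv"
        d.to_tsv(p)
        back = FingerprintDictionary.from_tsv(p)
        assert back.tokens == d.tokens
        assert back.rate_high == d.rate_high


class TestEncodeFingerprint:
    def test_positional_matching(self):
        d = FingerprintDictionary(
            tokens=[MotifToken("CG", 1), MotifToken("TC", 1), MotifToken("GG", 3)],
            rate_high={}, rate_low={},
        )
        assert encode_fingerprint("CGG", d).tolist() == [1, 0, 0]

    def test_empty_dictionary(self):
        d = FingerprintDictionary(tokens=[], rate_high={}, rate_low={})
        assert encode_fingerprint("ACGT", d).size == 0

    def test_consistent_with_enumeration(self, rng):
        seq = random_sequence(rng, 24)
        other = random_sequence(rng, 24)
        tokens = sorted(enumerate_motifs(seq) | enumerate_motifs(other))
        d = FingerprintDictionary(tokens=tokens, rate_high={}, rate_low={})
        bits = encode_fingerprint(seq, d)
        membership = enumerate_motifs(seq)
        assert bits.tolist() == [1 if t in membership else 0 for t in tokens]


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 1, 0], [1, 1, 0], 1.0),
            ([1, 0, 0], [0, 1, 1], 0.0),
            ([1, 1, 0], [1, 0, 1], 1 / 3),
            ([0, 0, 0], [0, 0, 0], 1.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert tanimoto(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.array([1, 0]), np.array([1, 0, 1]))


def _slot_record(rid: str, on_slots: set[int], n_slots: int = 30) -> OdnRecord:
    """Sequence of n_slots 2-base slots, 'GG' when the slot is on else 'AT'."""
    seq = "".join("GG" if k in on_slots else "AT" for k in range(1, n_slots + 1))
    return OdnRecord(rid, seq)


def _slot_dictionary(n_slots: int = 30) -> FingerprintDictionary:
    tokens = [MotifToken("GG", 2 * k - 1) for k in range(1, n_slots + 1)]
    return FingerprintDictionary(tokens=tokens, rate_high={}, rate_low={})


class TestDedup:
    def test_identical_second_removed(self):
        d = _slot_dictionary()
        a = _slot_record("a", set(range(1, 11)))
        b = _slot_record("b", set(range(1, 11)))
        kept, removed = dedup_by_similarity([a, b], d)
        assert [r.id for r in kept] == ["a"]
        assert [r.id for r in removed] == ["b"]

    def test_dissimilar_all_kept(self):
        d = _slot_dictionary()
        recs = [
            _slot_record("a", {1, 2, 3}),
            _slot_record("b", {10, 11, 12}),
            _slot_record("c", {20, 21, 22}),
        ]
        kept, removed = dedup_by_similarity(recs, d)
        assert len(kept) == 3 and not removed

    def test_greedy_chain_keeps_endpoints(self):
        # sim(a,b) = 23/27 ≈ 0.852 ≥ 0.85, sim(b,c) ≈ 0.852, sim(a,c) ≈ 0.724
        d = _slot_dictionary()
        a = _slot_record("a", set(range(1, 26)))
        b = _slot_record("b", set(range(1, 24)) | {26, 27})
        c = _slot_record("c", set(range(1, 22)) | {26, 27, 28, 29})
        kept, removed = dedup_by_similarity([a, b, c], d)
        assert [r.id for r in kept] == ["a", "c"]
        assert [r.id for r in removed] == ["b"]

    def test_idempotent_and_partitions(self, rng):
        d = _slot_dictionary()
        recs = [
            _slot_record(f"r{i}", set(rng.choice(30, size=8, replace=False) + 1))
            for i in range(12)
        ]
        kept, removed = dedup_by_similarity(recs, d)
        assert {r.id for r in kept} | {r.id for r in removed} == {r.id for r in recs}
        kept2, removed2 = dedup_by_similarity(kept, d)
        assert kept2 == kept and not removed2
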