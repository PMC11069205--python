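"""Insertion decomposition: TSD, poly-tail, body classification, consequences."""

import random

import pytest

from aluscan import mei, synthetic
from aluscan.mei import (
    DecompositionParams,
    InsertionCall,
    coding_consequence,
    classify_body,
    decompose_insertion,
    detect_poly_tail,
    detect_tsd,
    hgvs_describe,
)
from aluscan.synthetic import DeletionSpec, InsertionSpec, revcomp


def _call_from(locus, spec):
    pair = synthetic.build_alleles(locus, spec)
    a = spec.insert_after - locus.ref_offset + 1
    return InsertionCall(
        ref_position=spec.insert_after,
        insert_sequence=spec.insert_sequence,
        left_flank=pair.wt[:a],
        right_flank=pair.wt[a:],
    )


@pytest.fixture(scope="module")
def eys_call(eys):
    return _call_from(eys.insertion_locus, eys.insertion)


class TestDetectTsd:
    def test_eys_fixture_recovers_15bp_tsd(self, eys_call):
        hit = detect_tsd(eys_call)
        assert hit is not None
        assert len(hit) == 15
        assert revcomp(hit.sequence) == "AACATTGTATCCTTC"

    def test_no_shared_string_returns_none(self):
        call = InsertionCall(100, "GGGG" * 10, "C" * 60, "C" * 60)
        assert detect_tsd(call) is None

    def test_short_flanks_rejected(self):
        call = InsertionCall(100, "ACGTACGT", "ACGT", "ACGT")
        with pytest.raises(ValueError, match="flank"):
            detect_tsd(call, max_tsd=50)

    def test_planted_duplication_matches_brute_force(self):
        rng = random.Random(21)
        for _ in range(25):
            locus, spec = synthetic.random_insertion_spec(rng)
            call = _call_from(locus, spec)
            hit = detect_tsd(call)
            assert hit is not None and hit.sequence == spec.tsd
            # independent brute force: longest shared suffix/prefix length
            ins, L, R = call.insert_sequence, call.left_flank, call.right_flank
            best = 0
            for n in range(5, 51):
                if n <= len(ins) and (ins[-n:] == L[-n:] or ins[:n] == R[:n]):
                    best = n
            assert best == len(hit)


class TestDetectPolyTail:
    def test_eys_tail_is_56(self, eys_call):
        hit = detect_tsd(eys_call)
        remainder = eys_call.insert_sequence[: -len(hit)]
        assert detect_poly_tail(remainder, "tail") == ("A", 56)

    def test_all_g_has_no_tail(self):
        assert detect_poly_tail("G" * 40, "tail") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            detect_poly_tail("", "tail")

    @pytest.mark.parametrize("search_end", ["head", "tail"])
    def test_interrupted_run_matches_window_oracle(self, search_end):
        rng = random.Random(33)
        for _ in range(50):
            n = rng.randint(15, 60)
            seq = list("A" * n)
            for i in rng.sample(range(1, n - 1), k=rng.randint(0, 2)):
                seq[i] = rng.choice("CGT")
            seq = "".join(seq) + synthetic.random_sequence(30, rng)
            if search_end == "head":
                probe = seq
            else:
                probe = seq[::-1]
            got = detect_poly_tail(probe, search_end, min_len=10, purity=0.9)
            # brute force over all end-anchored windows
            s = probe[::-1] if search_end == "tail" else probe
            best = 0
            for L in range(1, len(s) + 1):
                window = s[:L]
                if window[0] == "A" and window[-1] == "A" and window.count("A") / L >= 0.9:
                    best = L
            expected = ("A", best) if best >= 10 else None
            assert got == expected


class TestClassifyBody:
    def test_exact_body_hits_library_at_identity_one(self, eys, consensus_library):
        family, ident, orient = classify_body(eys.insertion.body, consensus_library)
        assert family == "AluYa5_synthetic"
        assert ident == 1.0
        assert orient == "plus"

    def test_reverse_complement_flips_orientation(self, eys, consensus_library):
        family, ident, orient = classify_body(revcomp(eys.insertion.body), consensus_library)
        assert family == "AluYa5_synthetic"
        assert ident == 1.0
        assert orient == "minus"

    def test_planted_substitutions_lower_identity_proportionally(self, eys, consensus_library):
        rng = random.Random(44)
        body = list(eys.insertion.body)
        for i in rng.sample(range(len(body)), k=28):  # ~10%
            body[i] = rng.choice([b for b in "ACGT" if b != body[i]])
        _, ident, _ = classify_body("".join(body), consensus_library)
        assert abs(ident - 0.90) <= 0.03

    def test_unrelated_sequence_returns_none(self, consensus_library):
        rng = random.Random(45)
        assert classify_body(synthetic.random_sequence(200, rng), consensus_library) is None


class TestDecompose:
    def test_eys_anatomy(self, eys_call, consensus_library):
        rep = decompose_insertion(eys_call, consensus_library)
        assert (rep.body_len, rep.tail_len, rep.tsd_len) == (282, 56, 15)
        assert rep.family == "AluYa5_synthetic"
        assert rep.body_orientation == "plus"
        assert rep.hgvs == "g.64430524_64430525ins353"

    def test_transcript_strand_report_mirrors(self, eys_call, consensus_library):
        rep = decompose_insertion(eys_call, consensus_library, reporting_strand="minus")
        assert rep.tsd_sequence == "AACATTGTATCCTTC"
        assert rep.tail_base == "T"
        assert (rep.body_len, rep.tail_len, rep.tsd_len) == (282, 56, 15)
        assert rep.body_orientation == "minus"

    def test_bare_body_has_no_tsd_or_tail(self, consensus_library):
        rng = random.Random(55)
        flanks = synthetic.random_sequence(60, rng), synthetic.random_sequence(60, rng)
        body = dict(consensus_library)["AluYa5_synthetic"]
        # guard against coincidental flank agreement at the junction bases
        call = InsertionCall(500, body, "C" + flanks[0][:-1] + "T", "C" + flanks[1][1:])
        rep = decompose_insertion(call, consensus_library)
        assert rep.tsd_sequence is None and rep.tail_len == 0
        assert rep.body_len == len(body)

    def test_round_trip_100_random_specs(self, consensus_library):
        rng = random.Random(66)
        for _ in range(100):
            locus, spec = synthetic.random_insertion_spec(rng)
            call = _call_from(locus, spec)
            rep = decompose_insertion(call, [("x", spec.body)])
            assert rep.tsd_len == len(spec.tsd)
            assert rep.tail_len == spec.tail_len
            assert rep.body_len == len(spec.body)
            assert rep.tsd_len + rep.tail_len + rep.body_len == len(spec)

    def test_strand_involution(self, eys_call, consensus_library):
        mirrored = InsertionCall(
            ref_position=eys_call.ref_position,
            insert_sequence=revcomp(eys_call.insert_sequence),
            left_flank=revcomp(eys_call.right_flank),
            right_flank=revcomp(eys_call.left_flank),
        )
        fwd = decompose_insertion(eys_call, consensus_library)
        rev = decompose_insertion(mirrored, consensus_library)
        assert (rev.tsd_len, rev.tail_len, rev.body_len) == (
            fwd.tsd_len, fwd.tail_len, fwd.body_len,
        )
        assert {fwd.tail_base, rev.tail_base} == {"A", "T"}
        assert {fwd.body_orientation, rev.body_orientation} == {"plus", "minus"}


class TestHgvs:
    @pytest.mark.parametrize(
        "variant,expected",
        [
            (InsertionSpec(64_430_524, "", "A" * 352), "g.64430524_64430525ins352"),
            (DeletionSpec(64_764_235, 64_820_592), "g.64764235_64820592del"),
            (DeletionSpec(100, 100), "g.100del"),
        ],
    )
    def test_rendering(self, variant, expected):
        assert hgvs_describe(variant) == expected

    def test_invalid_deletion_rejected(self):
        with pytest.raises(ValueError):
            DeletionSpec(10, 5)


class TestCodingConsequence:
    def test_in_frame_single_codon(self):
        c = coding_consequence("GCT", 0)
        assert c.aberrant_aa_count == 1 and not c.premature_stop

    def test_stop_in_frame(self):
        c = coding_consequence("GCTGCATAA", 0)
        assert c.premature_stop and c.aberrant_aa_count == 2

    def test_eys_insert_truncates_protein(self, eys):
        # transcript-strand insert of the fixture; compared against a direct
        # three-frame translation oracle
        insert = revcomp(eys.insertion.insert_sequence)
        downstream = "GCTGCA" * 40  # stop-free read-through context
        for phase, upstream in [(0, ""), (1, "G"), (2, "GA")]:
            c = coding_consequence(insert, phase, upstream=upstream, downstream=downstream)
            seq = upstream[-phase:] if phase else ""
            seq += insert + downstream
            codons = [seq[i:i + 3] for i in range(0, len(seq) - 2, 3)]
            stops = [i for i, cod in enumerate(codons) if cod in ("TAA", "TAG", "TGA")]
            if stops:
                first = stops[0]
                assert c.premature_stop == (first * 3 < phase + len(insert) or len(insert) % 3 != 0)
                assert c.aberrant_aa_count <= first
            else:
                assert not c.premature_stop

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            coding_consequence("ACGN", 0)
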