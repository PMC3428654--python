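"""SSR detection and classification against examples and a brute-force oracle."""

import itertools

import numpy as np
import pytest

from ssrmine import (
    MiningConfig,
    TranscriptRecord,
    classify_catalogue,
    detect_imperfect_ssrs,
    find_perfect_ssrs,
)

CFG15 = MiningConfig(min_tract_bp=15)
CFG18 = MiningConfig(min_tract_bp=18)


def _triples(loci):
    return {(l.start, l.end, l.motif) for l in loci}


class TestPerfect:
    def test_long_dinucleotide_run(self):
        rec = TranscriptRecord("t", "CGTCAGTC" + "AG" * 26 + "TCAGTCGA")
        (locus,) = find_perfect_ssrs(rec, CFG15)
        assert (locus.motif, locus.copies, locus.tract_length) == ("AG", 26, 52)
        assert locus.unit_size == 2 and locus.classification == "perfect"

    def test_poly_a_run(self):
        rec = TranscriptRecord("t", "GTCGC" + "A" * 25 + "CGTCG")
        (locus,) = find_perfect_ssrs(rec, CFG15)
        assert (locus.motif, locus.tract_length) == ("A", 25)
        assert locus.end - locus.start == locus.unit_size * locus.copies

    def test_below_threshold_not_reported(self):
        rec = TranscriptRecord("t", "GTCGC" + "AT" * 7 + "CGTCG")
        assert find_perfect_ssrs(rec, CFG15) == []

    def test_non_primitive_motif_reported_under_primitive_unit(self):
        rec = TranscriptRecord("t", "CGTC" + "AGAG" * 5 + "TCGA")
        (locus,) = find_perfect_ssrs(rec, CFG15)
        assert locus.motif == "AG" and locus.copies == 10

    def test_runs_do_not_cross_n(self):
        rec = TranscriptRecord("t", "AG" * 5 + "N" + "AG" * 5)
        assert find_perfect_ssrs(rec, CFG15) == []


class TestOracleEquivalence:
    def test_exhaustive_two_letter_alphabet(self, perfect_oracle):
        """Every {A,G} sequence up to 12 bp gives the same perfect loci."""
        cfg = MiningConfig(min_tract_bp=6)
        for n in range(1, 13):
            for tup in itertools.product("AG", repeat=n):
                seq = "".join(tup)
                rec = TranscriptRecord("t", seq)
                assert _triples(find_perfect_ssrs(rec, cfg)) == perfect_oracle(
                    seq, range(1, 7), 6
                ), seq

    def test_exhaustive_four_letter_alphabet(self, perfect_oracle):
        cfg = MiningConfig(min_tract_bp=4)
        for n in range(1, 8):
            for tup in itertools.product("ACGT", repeat=n):
                seq = "".join(tup)
                rec = TranscriptRecord("t", seq)
                assert _triples(find_perfect_ssrs(rec, cfg)) == perfect_oracle(
                    seq, range(1, 7), 4
                ), seq

    def test_random_sequences_with_planted_repeats(self, perfect_oracle, rng):
        bases = np.array(list("ACGT"))
        motifs = ["A", "AG", "CT", "GAA", "ATAC", "AAAAG", "GAAAAA"]
        for i in range(200):
            seq = "".join(rng.choice(bases, size=60))
            m = motifs[int(rng.integers(len(motifs)))]
            copies = int(rng.integers(2, 12))
            pos = int(rng.integers(0, 30))
            seq = seq[:pos] + m * copies + seq[pos:]
            rec = TranscriptRecord("t", seq)
            assert _triples(find_perfect_ssrs(rec, CFG15)) == perfect_oracle(
                seq, range(1, 7), 15
            ), seq

    def test_threshold_monotonicity(self, rng, make_random_record):
        for i in range(50):
            rec = make_random_record(rng, 300, f"t{i}")
            assert _triples(find_perfect_ssrs(rec, CFG18)) <= _triples(
                find_perfect_ssrs(rec, CFG15)
            )

    def test_no_reported_locus_is_unit_extendable(self, rng, make_random_record):
        cfg = MiningConfig(min_tract_bp=6)
        for i in range(50):
            rec = make_random_record(rng, 200, f"t{i}")
            for l in find_perfect_ssrs(rec, cfg):
                assert rec.seq[l.start - l.unit_size : l.start] != l.motif or l.start < l.unit_size
                assert rec.seq[l.end : l.end + l.unit_size] != l.motif


class TestImperfect:
    def test_interrupted_poly_a(self):
        rec = TranscriptRecord("t", "CGTCGGTC" + "A" * 8 + "G" + "A" * 9 + "CCGTCTGC")
        (locus,) = detect_imperfect_ssrs(rec, CFG15)
        assert locus.classification == "imperfect"
        assert locus.tract_length == 18 and locus.copies == 17
        assert locus.canonical.display_pair == "A/T"

    def test_gap_above_limit_not_joined(self):
        rec = TranscriptRecord(
            "t", "CG" + "AG" * 5 + "TCTGCT" + "AG" * 5 + "CG"
        )
        assert detect_imperfect_ssrs(rec, CFG15) == []

    def test_single_run_never_imperfect(self):
        rec = TranscriptRecord("t", "CGTCG" + "AG" * 10 + "TCTGC")
        assert detect_imperfect_ssrs(rec, CFG15) == []
        (locus,) = classify_catalogue(rec, CFG15)
        assert locus.classification == "perfect"


class TestCompound:
    def test_di_di_compound_perfect(self):
        rec = TranscriptRecord("t", "CGTCGTTC" + "AG" * 8 + "TT" + "CA" * 8 + "GCGTCTGC")
        (locus,) = classify_catalogue(rec, CFG18)
        assert locus.classification == "compound_perfect"
        assert locus.subtype == "di-di"
        assert [c.motif for c in locus.components] == ["AG", "CA"]
        # the components are not double-reported
        assert len(classify_catalogue(rec, CFG18)) == 1

    def test_mono_tri_subtype(self):
        rec = TranscriptRecord("t", "CGTCGTTC" + "A" * 16 + "T" + "GAA" * 6 + "GCCGTCTGC")
        (locus,) = classify_catalogue(rec, CFG18)
        assert locus.classification == "compound_perfect"
        assert locus.subtype == "mono-tri"

    def test_spacer_above_limit_keeps_loci_separate(self):
        rec = TranscriptRecord(
            "t", "CGTCG" + "AG" * 10 + "TCGATCGTATC" + "CA" * 10 + "GTCTG"
        )
        loci = classify_catalogue(rec, CFG18)
        assert [l.classification for l in loci] == ["perfect", "perfect"]

    def test_interrupted_member_makes_compound_imperfect(self):
        rec = TranscriptRecord(
            "t", "CGTCGTTC" + "AG" * 4 + "T" + "AG" * 4 + "TT" + "CA" * 8 + "GCGTCTGC"
        )
        (locus,) = classify_catalogue(rec, CFG18)
        assert locus.classification == "compound_imperfect"
        assert locus.subtype == "di-di"


class TestDisjointness:
    def test_clean_run_is_single_perfect_locus(self):
        rec = TranscriptRecord("t", "CGTCGTTC" + "GAA" * 6 + "CCGTCTGC")
        loci = classify_catalogue(rec, CFG18)
        assert [l.classification for l in loci] == ["perfect"]

    def test_each_base_in_at_most_one_locus(self, rng, make_random_record):
        from ssrmine.synthetic_data import SimulationSpec, generate_transcripts

        ts, _ = generate_transcripts(
            SimulationSpec(n_transcripts=60, ssr_plant_rate=2.0, seed=99)
        )
        for rec in ts:
            loci = sorted(classify_catalogue(rec, CFG18), key=lambda l: l.start)
            for a, b in zip(loci, loci[1:]):
                assert a.end <= b.start
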