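import numpy as np
import pytest

from gambi._errors import GambiError
from gambi.primer_insilico import (
    AmplificationCall,
    PrimerPair,
    PrimerScoringConfig,
    bases_match,
    best_local_alignment,
    degeneracy,
    expand_degenerate,
    find_best_site,
    locate_primer_region,
    predict_amplification,
    reverse_complement,
    score_primer_binding,
    species_amplification_summary,
    testable_sequences as find_testable_sequences,
)
from gambi.reference_library import SequenceRecord


def rec(id, seq, species="Abra alba", phylum="Mollusca"):
    return SequenceRecord(id=id, species=species, phylum=phylum, marker="CO1", seq=seq)


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def planted_template(fwd_primer, rev_primer, insert_len=300, flank=40, seed=0):
    """Template with perfect forward site and reverse-complemented reverse site."""
    rng = np.random.default_rng(seed)

    def rand(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    return (
        rand(flank) + fwd_primer + rand(insert_len) + reverse_complement(rev_primer) + rand(flank)
    )


FWD = "ACGTACGGTCACAAAGATAT"  # 20-mer, concrete
REV = "TGGTGGGCTCATACAATAAA"  # 20-mer, concrete


class TestIupacMachinery:
    def test_reverse_complement_plain(self):
        assert reverse_complement("ACGT") == "ACGT"
        assert reverse_complement("AACGTG") == "CACGTT"

    def test_reverse_complement_degenerate(self):
        assert reverse_complement("RYN") == "NRY"

    def test_degeneracy_product(self):
        assert degeneracy("ACGT") == 1
        assert degeneracy("ACGN") == 4
        assert degeneracy("RYN") == 2 * 2 * 4

    def test_expand_degenerate(self):
        assert sorted(expand_degenerate("AR")) == ["AA", "AG"]
        assert len(expand_degenerate("NN")) == 16

    def test_bases_match_intersection(self):
        assert bases_match("R", "A")
        assert bases_match("R", "G")
        assert not bases_match("R", "C")
        assert bases_match("N", "Y")  # template ambiguity: liberal call


class TestScorePrimerBinding:
    def test_perfect_match(self):
        assert score_primer_binding(FWD, FWD) == 0.0

    def test_single_mismatch_outside_3prime_window(self):
        site = "T" + FWD[1:] if FWD[0] != "T" else "A" + FWD[1:]
        assert score_primer_binding(FWD, site) == pytest.approx(0.4)

    def test_mismatch_inside_3prime_window(self):
        site = list(FWD)
        site[-3] = "C" if site[-3] != "C" else "G"
        assert score_primer_binding(FWD, "".join(site)) == pytest.approx(1.0)

    def test_terminal_mismatch_exceeds_threshold(self):
        site = list(FWD)
        site[-1] = "C" if site[-1] != "C" else "G"
        score = score_primer_binding(FWD, "".join(site))
        assert score == pytest.approx(3.0)
        assert score > PrimerScoringConfig().amplify_threshold

    def test_length_mismatch_errors(self):
        with pytest.raises(GambiError):
            score_primer_binding(FWD, FWD[:-1])

    def test_monotone_in_mismatches(self):
        site = list(FWD)
        prev = score_primer_binding(FWD, "".join(site))
        for i in range(len(site)):
            site[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[i]]
            score = score_primer_binding(FWD, "".join(site))
            assert score >= prev
            prev = score

    def test_degenerate_matches_brute_force_expansion(self):
        # score via set intersection == min over concrete expansions (<=4 degenerate)
        rng = np.random.default_rng(42)
        primers = ["ACGRACGTKCWT", "NACGTACGTACG", "ACMGTRACGYAC", "ACGTACGTACGT"]
        for primer in primers:
            assert degeneracy(primer) <= 4**4
            for _ in range(25):
                site = "".join(rng.choice(list("ACGT"), size=len(primer)))
                direct = score_primer_binding(primer, site)
                oracle = min(
                    score_primer_binding(exp, site) for exp in expand_degenerate(primer)
                )
                assert direct == pytest.approx(oracle)


class TestFindBestSite:
    def test_exact_substring_located(self):
        template = planted_template(FWD, REV, seed=1)
        score, start = find_best_site(FWD, template)
        assert score == 0.0
        assert start == 40

    def test_degenerate_primer_located(self):
        degen = "R" + FWD[1:-1] + FWD[-1]  # widen one 5' base
        template = planted_template(FWD, REV, seed=2)
        score, start = find_best_site(degen, template)
        assert score == 0.0
        assert start == 40


class TestLocatePrimerRegion:
    def test_planted_offsets_recovered(self):
        template = planted_template(FWD, REV, insert_len=300, flank=40, seed=3)
        reference = rec("ref", template)
        pair = PrimerPair(name="p", forward=FWD, reverse=REV)
        start, end = locate_primer_region(reference, pair)
        assert start == 40
        assert end == 40 + 20 + 300 + 20
        assert pair.expected_amplicon_length == 340

    def test_unlocatable_errors(self):
        reference = rec("ref", random_seq(200, seed=4))
        pair = PrimerPair(name="p", forward=FWD, reverse=REV)
        with pytest.raises(GambiError, match="not locatable"):
            locate_primer_region(reference, pair)


class TestTestableSequences:
    @pytest.fixture
    def located(self):
        template = planted_template(FWD, REV, insert_len=200, flank=50, seed=5)
        reference = rec("ref", template)
        pair = PrimerPair(name="p", forward=FWD, reverse=REV)
        locate_primer_region(reference, pair)
        return reference, pair

    def test_full_copy_testable(self, located):
        reference, pair = located
        copy = rec("copy", reference.seq)
        assert find_testable_sequences([copy], pair, reference) == [copy]

    def test_fragment_missing_forward_site_excluded(self, located):
        reference, pair = located
        fragment = rec("frag", reference.seq[pair.ref_start + 30 :])
        assert find_testable_sequences([fragment], pair, reference) == []

    def test_known_truncation_points(self, located):
        reference, pair = located
        full = rec("full", reference.seq)
        spans_both = rec("both", reference.seq[pair.ref_start - 5 : pair.ref_end + 5])
        missing_rev = rec("norev", reference.seq[: pair.ref_end - 25])
        got = find_testable_sequences([full, spans_both, missing_rev], pair, reference)
        assert [r.id for r in got] == ["full", "both"]

    def test_unalignable_record_excluded(self, located):
        reference, pair = located
        noise = rec("noise", random_seq(300, seed=99))
        assert find_testable_sequences([noise], pair, reference) == []


class TestBestLocalAlignment:
    def test_exact_fragment(self):
        ref = random_seq(400, seed=6)
        aln = best_local_alignment(ref[100:250], ref)
        assert aln is not None
        assert (aln.r_start, aln.r_end) == (100, 250)
        assert aln.score == 150

    def test_mutated_fragment_still_spans(self):
        ref = random_seq(400, seed=7)
        frag = list(ref[50:350])
        frag[100] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[100]]
        aln = best_local_alignment("".join(frag), ref)
        assert aln is not None
        assert aln.r_start <= 55 and aln.r_end >= 345

    def test_no_seed_returns_none(self):
        assert best_local_alignment("A" * 50, "C" * 50) is None


class TestPredictAmplification:
    def make_pair_and_ref(self, seed=8, insert=300):
        template = planted_template(FWD, REV, insert_len=insert, flank=40, seed=seed)
        reference = rec("ref", template)
        pair = PrimerPair(name="p", forward=FWD, reverse=REV)
        locate_primer_region(reference, pair)
        return pair, reference

    def test_perfect_sites_amplify(self):
        pair, reference = self.make_pair_and_ref()
        call = predict_amplification(pair, reference)
        assert call.amplifies
        assert call.amplicon_length == 20 + 300 + 20

    def test_destroyed_forward_terminal_base_fails(self):
        pair, reference = self.make_pair_and_ref()
        seq = list(reference.seq)
        pos = pair.ref_start + len(FWD) - 1  # 3'-terminal base of the forward site
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        call = predict_amplification(pair, rec("mut", "".join(seq)))
        assert not call.amplifies
        assert call.forward_score >= 3.0

    def test_reverse_upstream_of_forward_fails(self):
        rng_seq = random_seq(60, seed=9)
        template = reverse_complement(REV) + rng_seq + FWD + random_seq(30, seed=10)
        pair = PrimerPair(name="p", forward=FWD, reverse=REV)
        call = predict_amplification(pair, rec("inv", template))
        assert not call.amplifies


class TestSpeciesAmplificationSummary:
    def test_any_sequence_amplifying_makes_species_positive(self):
        records = [
            rec("r1", "ACGTACGTAC", species="Abra alba"),
            rec("r2", "ACGTACGTAC", species="Abra alba"),
        ]
        calls = [
            AmplificationCall("r1", 5.0, 5.0, amplifies=False),
            AmplificationCall("r2", 0.0, 0.0, amplifies=True, amplicon_start=0, amplicon_end=9),
        ]
        summary = species_amplification_summary(calls, records)
        assert summary.per_species["Abra alba"] is True

    def test_removing_one_of_two_amplifying_keeps_positive(self):
        records = [
            rec("r1", "ACGTACGTAC"),
            rec("r2", "ACGTACGTAC"),
        ]
        amp = lambda i: AmplificationCall(i, 0.0, 0.0, True, 0, 9)
        both = species_amplification_summary([amp("r1"), amp("r2")], records)
        one = species_amplification_summary([amp("r1")], records[:1])
        assert both.per_species["Abra alba"] and one.per_species["Abra alba"]

    def test_untested_phylum_absent_not_zero(self):
        records = [rec("r1", "ACGT", species="Abra alba", phylum="Mollusca")]
        calls = [AmplificationCall("r1", 0.0, 0.0, True, 0, 3)]
        summary = species_amplification_summary(calls, records)
        assert "Annelida" not in summary.per_phylum.index

    def test_toy_hand_counts(self):
        records = [
            rec("a1", "ACGT", species="Ann one", phylum="Annelida"),
            rec("a2", "ACGT", species="Ann two", phylum="Annelida"),
            rec("m1", "ACGT", species="Mol one", phylum="Mollusca"),
            rec("m2", "ACGT", species="Mol two", phylum="Mollusca"),
        ]
        calls = [
            AmplificationCall("a1", 0.0, 0.0, True, 0, 3),
            AmplificationCall("a2", 5.0, 0.0, False),
            AmplificationCall("m1", 0.0, 0.0, True, 0, 3),
            AmplificationCall("m2", 0.0, 0.0, True, 0, 3),
        ]
        summary = species_amplification_summary(calls, records)
        assert summary.per_phylum.loc["Annelida", "pct_positive"] == pytest.approx(50.0)
        assert summary.per_phylum.loc["Mollusca", "pct_positive"] == pytest.approx(100.0)
        assert summary.n_tested == 4


class TestPrimerPairValidation:
    def test_short_primer_rejected(self):
        with pytest.raises(GambiError, match="shorter"):
            PrimerPair(name="p", forward="ACGTACGT", reverse=REV)

    def test_non_iupac_rejected(self):
        with pytest.raises(GambiError, match="non-IUPAC"):
            PrimerPair(name="p", forward="ACGTACGTACJ", reverse=REV)
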