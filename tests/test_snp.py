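import itertools

import numpy as np
import pytest

from genespace import snp, synthetic as syn
from genespace.errors import ParameterError, UndefinedRatioError
from genespace.formats import AlignedRead, PileupAlignment

from .oracles import call_snps_bruteforce

EG_COUNTS = {"C/T": 12_391, "G/A": 12_397, "A/T": 1_928, "C/G": 180, "G/T": 696, "A/C": 650}
EO_COUNTS = {"C/T": 5_638, "G/A": 5_464, "A/T": 866, "C/G": 97, "G/T": 226, "A/C": 287}


def _stack(column_bases, contig="c"):
    """Pileup with one column per string position list: column_bases is a
    list of strings, each string the bases observed in that column."""
    depth = max(len(c) for c in column_bases)
    reads = []
    for i in range(depth):
        bases = "".join(c[i] if i < len(c) else "N" for c in column_bases)
        reads.append(AlignedRead(f"r{i}", 0, bases))
    consensus = "".join(c[0] for c in column_bases)
    return PileupAlignment(contig, consensus, reads)


def _column(bases, pad_depth=None):
    """Single-column pileup from one string of observed bases."""
    reads = [AlignedRead(f"r{i}", 0, b) for i, b in enumerate(bases)]
    return PileupAlignment("c", bases[0], reads)


class TestClassifySubstitution:
    def test_ct_is_transition(self):
        assert snp.classify_substitution("C", "T") == ("transition", "C/T")

    def test_symmetry(self):
        assert snp.classify_substitution("T", "C") == ("transition", "C/T")

    def test_at_is_transversion(self):
        assert snp.classify_substitution("A", "T") == ("transversion", "A/T")

    def test_all_pairs_symmetric_and_labelled(self):
        for a, b in itertools.permutations("ACGT", 2):
            cls, label = snp.classify_substitution(a, b)
            assert snp.classify_substitution(b, a) == (cls, label)
            assert label in snp.PAIR_LABELS
            expected = "transition" if {a, b} in ({"C", "T"}, {"A", "G"}) else "transversion"
            assert cls == expected

    @pytest.mark.parametrize("pair", [("A", "A"), ("A", "N"), ("X", "T")])
    def test_invalid_alleles_rejected(self, pair):
        with pytest.raises(ParameterError):
            snp.classify_substitution(*pair)


class TestCallSnps:
    def test_two_supported_alleles_called(self):
        records = snp.call_snps([_column("AAAGG")])
        assert len(records) == 1
        r = records[0]
        assert (r.allele_a, r.allele_b, r.support_a, r.support_b) == ("A", "G", 3, 2)

    def test_undersupported_second_allele_not_called(self):
        assert snp.call_snps([_column("AAAAG")]) == []

    def test_depth_over_30_excluded(self):
        assert snp.call_snps([_column("A" * 16 + "G" * 16)]) == []

    def test_depth_exactly_30_kept(self):
        assert len(snp.call_snps([_column("A" * 15 + "G" * 15)])) == 1

    def test_auto_depth_cutoff_is_mean_plus_2sd(self):
        deep = _column("A" * 20 + "G" * 20)
        shallow = [_column("AT" + "A" * 2) for _ in range(50)]
        # pooled depth: mean ~ 4.7, sd small -> depth-40 column excluded in auto mode
        records = snp.call_snps([deep] + shallow, max_depth="auto")
        assert all(r.depth <= 40 - 1 for r in records)
        # absolute cutoff large enough keeps it
        records_abs = snp.call_snps([deep], max_depth=50)
        assert len(records_abs) == 1

    def test_gaps_and_n_count_toward_depth_not_alleles(self):
        # 29 nucleotide observations + 2 gaps = depth 31 > 30: excluded
        records = snp.call_snps([_column("A" * 15 + "G" * 14 + "--")])
        assert records == []
        # 2 gaps within depth 30: called, gaps not alleles
        records = snp.call_snps([_column("A" * 14 + "G" * 14 + "--")])
        assert len(records) == 1
        assert records[0].depth == 30
        # gap support alone never creates an allele
        assert snp.call_snps([_column("AA---")]) == []

    def test_multiallelic_flagged_with_two_best(self):
        (r,) = snp.call_snps([_column("AAAAGGGTT")])
        assert r.multiallelic
        assert (r.allele_a, r.allele_b) == ("A", "G")

    def test_empty_pileup_list(self):
        assert snp.call_snps([]) == []

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ParameterError):
            snp.call_snps([_column("AAGG")], min_allele_support=0)

    def test_matches_bruteforce_counter_on_fixtures(self):
        rng = np.random.default_rng(12)
        cols = []
        for _ in range(50):
            depth = int(rng.integers(1, 12))
            cols.append("".join(rng.choice(list("ACGT-N"), depth,
                                           p=[0.4, 0.2, 0.2, 0.1, 0.05, 0.05])))
        pile = _stack(cols)
        got = [(r.position, r.allele_a, r.allele_b) for r in snp.call_snps([pile])]
        assert got == call_snps_bruteforce(pile)

    def test_truth_recovery_on_error_free_pileups(self, small_genome):
        variants = syn.inject_variants(small_genome, 200, seed=21)
        piles = syn.build_pileups(small_genome, variants, depth_mean=10,
                                  error_rate=0.0, seed=22, window=500)
        calls = snp.call_snps(piles, 2, 30)
        truth = {pos: frozenset((ref, alt)) for pos, ref, alt in variants}
        for c in calls:
            wstart = int(c.contig_id.split(":")[1].split("-")[0])
            gpos = wstart + c.position
            assert gpos in truth, "false positive"
            assert frozenset((c.allele_a, c.allele_b)) == truth[gpos]


class TestTiTvAndSpectrum:
    def test_table_counts_give_reported_ratios(self):
        eg = snp.substitution_spectrum(EG_COUNTS)
        eo = snp.substitution_spectrum(EO_COUNTS)
        assert snp.format_titv(snp.titv_ratio(eg)) == "7.17"
        assert snp.format_titv(snp.titv_ratio(eo)) == "7.52"

    def test_spectrum_subtotals(self):
        eg = snp.substitution_spectrum(EG_COUNTS)
        assert eg.transitions == 24_788
        assert eg.transversions == 3_454
        assert eg.total == 28_242

    def test_combined_total_is_abstract_value(self):
        eg = snp.substitution_spectrum(EG_COUNTS)
        eo = snp.substitution_spectrum(EO_COUNTS)
        assert eg.total + eo.total == 40_820

    def test_equal_counts_unity_ratio(self):
        assert snp.titv_ratio((10, 10)) == pytest.approx(1.0)

    def test_zero_transversions_undefined(self):
        with pytest.raises(UndefinedRatioError):
            snp.titv_ratio((5, 0))

    def test_truncation_not_rounding(self):
        assert snp.format_titv(7.179) == "7.17"
        assert snp.format_titv(7.5216) == "7.52"

    def test_spectrum_conserves_record_count(self):
        recs = snp.call_snps([_column("AAAGG"), _stack(["CCCTT", "AAATT"], contig="d")])
        spectrum = snp.substitution_spectrum(recs)
        assert spectrum.total == len(recs)

    def test_empty_spectrum(self):
        spectrum = snp.substitution_spectrum([])
        assert spectrum.total == 0

    def test_planted_titv_recovered_through_caller(self, small_genome):
        wti, wtv = syn.titv_weights(7.5)
        variants = syn.inject_variants(small_genome, 2000, seed=31,
                                       transition_weight=wti, transversion_weight=wtv)
        piles = syn.build_pileups(small_genome, variants, depth_mean=12,
                                  error_rate=0.0, seed=32, window=400)
        calls = snp.call_snps(piles, 2, 30)
        assert len(calls) > 1000
        assert abs(snp.titv_ratio(calls) - 7.5) <= 0.1 * 7.5


class TestSnpDensity:
    def test_arithmetic(self):
        profile = snp.DepthProfile(np.full(200, 10))
        assert snp.snp_density(5, profile) == pytest.approx(2.5)

    def test_zero_snps(self):
        profile = snp.DepthProfile(np.full(100, 10))
        assert snp.snp_density(0, profile) == 0.0

    def test_eligible_length_bounds_inclusive(self):
        profile = snp.DepthProfile(np.array([3, 4, 10, 30, 31]))
        assert profile.eligible_length == 3

    def test_no_eligible_positions_undefined(self):
        profile = snp.DepthProfile(np.array([1, 2, 50]))
        with pytest.raises(UndefinedRatioError):
            snp.snp_density(1, profile)

    def test_simulated_density_recovery(self, small_genome):
        variants = syn.inject_variants(small_genome, 400, seed=41)
        piles = syn.build_pileups(small_genome, variants, depth_mean=10,
                                  error_rate=0.0, seed=42, window=500,
                                  only_variant_windows=False)
        calls = snp.call_snps(piles, 2, 30)
        profile = snp.DepthProfile.from_pileups(piles)
        density = snp.snp_density(len(calls), profile)
        # callable sites are thinned by the >=2-support rule; density is
        # bounded by the planted rate and within 3 s.e. of the observed calls
        planted = 100.0 * len(variants) / len(small_genome)
        se = 100.0 * np.sqrt(len(calls)) / profile.eligible_length
        assert density <= planted + 3 * se
        assert density >= 0.5 * planted
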