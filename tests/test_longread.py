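import numpy as np
import pytest

import greycnv as g
from greycnv.longread import UnitPlacement, longest_common_flank, reverse_complement
from greycnv.simulate import build_fragment
from oracles import longest_common_flank_oracle


class TestReadClassification:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (7_700, 1), (12_300, 2), (16_900, 3),  # exact fragment sizes
            (13_000, 2), (17_000, 3),  # the two dominant observed sizes
            (2_000, None),  # off-scale read rejected
            (10_000, None),  # halfway between one- and two-copy fragments
        ],
    )
    def test_length_to_copy_number(self, locus_model, length, expected):
        assert g.classify_read_copy_number(length, locus_model) == expected

    def test_monotone_in_read_length(self, locus_model):
        ks = [
            g.classify_read_copy_number(length, locus_model)
            for length in range(6_000, 30_000, 100)
        ]
        called = [k for k in ks if k is not None]
        assert all(b >= a for a, b in zip(called, called[1:]))

    def test_recovers_simulated_allele_under_bounded_noise(self, small_locus_model):
        for copies in (1, 2, 3):
            reads, _ = g.simulate_allele_reads(
                g.GreyAllele(copies), small_locus_model, n_reads=30,
                length_noise_sd=small_locus_model.unit_length_bp / 8, seed=copies,
            )
            for read in reads:
                assert g.classify_read_copy_number(
                    read.length, small_locus_model
                ) == copies


class TestBinAndConsensus:
    def test_error_free_reads_give_exact_consensus(self, small_locus_model,
                                                   unit_and_flanks):
        unit, flanks = unit_and_flanks
        reads, _ = g.simulate_allele_reads(
            g.GreyAllele(2), small_locus_model, unit, flanks, n_reads=5, seed=3
        )
        bins = g.bin_and_consensus(reads, small_locus_model)
        assert len(bins) == 1
        assert bins[0].consensus == build_fragment(g.GreyAllele(2), unit, flanks)
        assert not bins[0].low_confidence

    def test_heterozygote_yields_two_bins(self, small_locus_model, unit_and_flanks):
        unit, flanks = unit_and_flanks
        reads2, _ = g.simulate_allele_reads(
            g.GreyAllele(2), small_locus_model, unit, flanks, n_reads=20,
            length_noise_sd=20, per_base_error=0.02, seed=4, read_id_prefix="g2_",
        )
        reads3, _ = g.simulate_allele_reads(
            g.GreyAllele(3), small_locus_model, unit, flanks, n_reads=20,
            length_noise_sd=20, per_base_error=0.02, seed=5, read_id_prefix="g3_",
        )
        bins = g.bin_and_consensus(list(reads2) + list(reads3), small_locus_model)
        assert [b.copies for b in bins] == [2, 3]
        assert all(b.n_reads == 20 for b in bins)

    def test_consensus_error_rate_bounded(self, small_locus_model, unit_and_flanks):
        # 50 reads at 3% substitution error: majority vote leaves
        # essentially no consensus errors (>= 99.9% identity).
        unit, flanks = unit_and_flanks
        template = build_fragment(g.GreyAllele(3), unit, flanks)
        reads, _ = g.simulate_allele_reads(
            g.GreyAllele(3), small_locus_model, unit, flanks, n_reads=50,
            per_base_error=0.03, seed=6,
        )
        consensus = g.bin_and_consensus(reads, small_locus_model)[0].consensus
        matches = sum(a == b for a, b in zip(consensus, template))
        assert matches / len(template) >= 0.999

    def test_small_bins_flagged_low_confidence(self, small_locus_model,
                                               unit_and_flanks):
        unit, flanks = unit_and_flanks
        reads, _ = g.simulate_allele_reads(
            g.GreyAllele(1), small_locus_model, unit, flanks, n_reads=2, seed=7
        )
        assert g.bin_and_consensus(reads, small_locus_model)[0].low_confidence

    def test_no_classifiable_reads_raises(self, small_locus_model):
        junk = [g.SpanningRead(id="x", sequence="ACGT" * 10)]
        with pytest.raises(ValueError):
            g.bin_and_consensus(junk, small_locus_model)


class TestTandemStructure:
    def test_triplication_is_tandem_head_to_tail(self, unit_and_flanks):
        unit, flanks = unit_and_flanks
        consensus = build_fragment(g.GreyAllele(3), unit, flanks)
        report = g.detect_tandem_structure(consensus, unit)
        assert report.classification == "tandem_head_to_tail"
        assert len(report.placements) == 3
        assert all(p.orientation == "+" for p in report.placements)
        starts = [p.start for p in report.placements]
        assert starts == sorted(starts)

    def test_single_copy(self, unit_and_flanks):
        unit, flanks = unit_and_flanks
        consensus = build_fragment(g.GreyAllele(1), unit, flanks)
        report = g.detect_tandem_structure(consensus, unit)
        assert report.classification == "single"

    def test_inverted_copy_detected(self, unit_and_flanks):
        unit, flanks = unit_and_flanks
        consensus = flanks[0] + unit + reverse_complement(unit) + flanks[1]
        report = g.detect_tandem_structure(consensus, unit)
        assert report.classification == "inverted"
        assert {p.orientation for p in report.placements} == {"+", "-"}

    def test_strand_consistency(self, unit_and_flanks):
        unit, flanks = unit_and_flanks
        consensus = build_fragment(g.GreyAllele(2), unit, flanks)
        fwd = g.detect_tandem_structure(consensus, unit)
        rev = g.detect_tandem_structure(reverse_complement(consensus), unit)
        assert rev.classification == fwd.classification
        assert [p.orientation for p in rev.placements] == [
            "-" for _ in fwd.placements
        ]

    def test_noisy_consensus_still_resolved(self, small_locus_model, unit_and_flanks):
        unit, flanks = unit_and_flanks
        reads, _ = g.simulate_allele_reads(
            g.GreyAllele(3), small_locus_model, unit, flanks, n_reads=30,
            per_base_error=0.03, seed=8,
        )
        consensus = g.bin_and_consensus(reads, small_locus_model)[0].consensus
        report = g.detect_tandem_structure(consensus, unit)
        assert report.classification == "tandem_head_to_tail"
        assert len(report.placements) == 3

    def test_no_unit_match_raises(self, unit_and_flanks):
        unit, _ = unit_and_flanks
        rng = np.random.default_rng(1)
        noise = "".join(rng.choice(list("ACGT"), size=len(unit) * 2))
        with pytest.raises(ValueError):
            g.detect_tandem_structure(noise, unit)


class TestJunctionMicrohomology:
    def test_planted_motif_recovered(self, unit_and_flanks):
        unit, flanks = unit_and_flanks
        consensus = build_fragment(g.GreyAllele(3), unit, flanks)
        report = g.detect_tandem_structure(consensus, unit)
        jr = g.find_junction_microhomology(consensus, report.placements, flanks[1])
        assert jr.motifs == ["TCTCAG", "TCTCAG"]
        assert all(j.length == 6 for j in jr.junctions)

    def test_no_shared_bases_gives_empty_motif(self):
        # Upstream ends in A's, downstream reference starts with C: no flank.
        consensus = "G" * 50 + "A" * 50
        placements = [
            UnitPlacement(0, 50, "+", 10), UnitPlacement(50, 100, "+", 10)
        ]
        jr = g.find_junction_microhomology(consensus, placements, "CCCCTTTT")
        assert jr.motifs == [""]
        assert jr.junctions[0].length == 0

    def test_non_adjacent_placements_rejected(self):
        placements = [
            UnitPlacement(0, 50, "+", 10), UnitPlacement(200, 250, "+", 10)
        ]
        with pytest.raises(ValueError):
            g.find_junction_microhomology("A" * 300, placements, "ACGT")

    def test_requires_a_junction(self):
        with pytest.raises(ValueError):
            g.find_junction_microhomology(
                "A" * 100, [UnitPlacement(0, 50, "+", 10)], "ACGT"
            )

    def test_matches_brute_force_oracle_on_random_junctions(self):
        # 200 random junctions with planted homology lengths 0..10.
        rng = np.random.default_rng(77)
        bases = np.array(list("ACGT"))
        for trial in range(200):
            h = int(rng.integers(0, 11))
            core = "".join(rng.choice(bases, size=60))
            shared = "".join(rng.choice(bases, size=h))
            upstream = core + shared
            downstream = shared + "".join(rng.choice(bases, size=60))
            motif = longest_common_flank(upstream, downstream)
            assert motif == longest_common_flank_oracle(upstream, downstream)
            assert len(motif) >= h  # at least the planted homology
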