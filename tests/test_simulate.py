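import math

import numpy as np
import pytest

import greycnv as g
from greycnv.simulate import build_fragment, transmit_allele


class TestTransmission:
    def test_no_mutation_transmits_a_parental_allele(self):
        rng = np.random.default_rng(0)
        gt = g.CnvGenotype.from_copies(3, 2)
        for _ in range(200):
            allele, event = transmit_allele(gt, rng)
            assert event is None
            assert allele.copies in (3, 2)

    def test_gamete_frequency_is_binomial(self):
        # 10,000 gametes from a (3,2) parent: the 3-copy allele is transmitted
        # with frequency 1/2; tolerance 0.015 ~ 3 binomial SE.
        rng = np.random.default_rng(42)
        gt = g.CnvGenotype.from_copies(3, 2)
        n3 = sum(transmit_allele(gt, rng)[0].copies == 3 for _ in range(10_000))
        assert abs(n3 / 10_000 - 0.5) < 0.015

    def test_forced_contraction_records_event(self):
        config = g.SimulationConfig(seed=1, contraction_rate=1.0)
        ped = g.simulate_pedigree(
            config,
            n_founders=2,
            n_generations=2,
            offspring_per_mating=1,
            founder_genotypes=[
                g.CnvGenotype.from_copies(3, 3),
                g.CnvGenotype.from_copies(1, 1),
            ],
        )
        child = [i for i in ped if i.generation == 1][0]
        # The (3,3) parent's gamete always contracts 3 -> 2; the wild-type
        # parent has no duplicated copy to lose.
        assert child.true_genotype.as_sorted_tuple() == (2, 1)
        assert len(ped.mutation_events) == 1
        ev = ped.mutation_events[0]
        assert (ev.from_copies, ev.to_copies, ev.direction) == (3, 2, "contraction")


class TestPedigreeSimulation:
    def test_copy_number_conservation_without_mutation(self):
        config = g.SimulationConfig(seed=7)
        ped = g.simulate_pedigree(config, n_founders=8, n_generations=3)
        assert not ped.mutation_events
        for ind in ped:
            gt = ind.true_genotype
            assert ind.measured_total_copies == gt.total_copies
            if ind.dam_id is None:
                continue
            dam = ped[ind.dam_id].true_genotype
            sire = ped[ind.sire_id].true_genotype
            assert gt.maternal.copies in (dam.maternal.copies, dam.paternal.copies)
            assert gt.paternal.copies in (sire.maternal.copies, sire.paternal.copies)

    def test_mutation_bookkeeping_matches_mismatches(self):
        # Homozygous founders make every mutated gamete a visible mismatch.
        config = g.SimulationConfig(seed=3, contraction_rate=0.3, expansion_rate=0.1)
        ped = g.simulate_pedigree(
            config,
            n_founders=6,
            n_generations=2,
            offspring_per_mating=3,
            founder_genotypes=[
                g.CnvGenotype.from_copies(3, 3),
                g.CnvGenotype.from_copies(2, 2),
            ],
        )
        mismatches = 0
        for ind in ped:
            if ind.dam_id is None:
                continue
            for side, pid in (("maternal", ind.dam_id), ("paternal", ind.sire_id)):
                child_allele = getattr(ind.true_genotype, side).copies
                parent = ped[pid].true_genotype
                if child_allele not in (parent.maternal.copies, parent.paternal.copies):
                    mismatches += 1
        assert mismatches == len(ped.mutation_events) > 0

    def test_phenotypes_follow_genotypes(self):
        ped = g.simulate_pedigree(g.SimulationConfig(seed=5), n_founders=10)
        for ind in ped:
            assert ind.phenotype == g.phenotype_from_genotype(ind.true_genotype)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            g.SimulationConfig(allele_frequencies={1: 0.5, 3: 0.6})


class TestCoverageSimulation:
    @pytest.mark.parametrize("pair, factor", [((3, 2), 5 / 2), ((1, 3), 4 / 2)])
    def test_cnv_windows_scale_with_copy_number(self, locus_model, pair, factor):
        gt = g.CnvGenotype.from_copies(*pair)
        track = g.simulate_coverage_track(gt, locus_model, mean_depth=30, seed=2)
        cnv_mask = track.window_mask(locus_model.cnv_interval)
        assert cnv_mask.sum() >= 4
        in_mean = track.depths[cnv_mask].mean()
        assert in_mean == pytest.approx(30 * factor, rel=0.05)

    def test_wildtype_track_is_flat(self, locus_model):
        gt = g.CnvGenotype.from_copies(1, 1)
        track = g.simulate_coverage_track(gt, locus_model, mean_depth=30, seed=2)
        assert track.depths.mean() == pytest.approx(30, rel=0.02)

    def test_coverage_ratio_law_at_high_depth(self, locus_model):
        # In-CNV / baseline depth ratio converges to total_copies / 2.
        gt = g.CnvGenotype.from_copies(3, 2)
        track = g.simulate_coverage_track(gt, locus_model, mean_depth=1000, seed=8)
        cnv_mask = track.window_mask(locus_model.cnv_interval)
        base = g.GenomicInterval(
            "chr25", locus_model.cnv_interval.start - 40_000,
            locus_model.cnv_interval.start - 2000,
        )
        base_mask = track.window_mask(base)
        ratio = track.depths[cnv_mask].mean() / track.depths[base_mask].mean()
        assert ratio == pytest.approx(2.5, rel=0.02)


class TestDropletSimulation:
    def test_equal_channels_for_two_copies(self):
        assay = g.simulate_droplet_assay(2, n_droplets=50_000, seed=1)
        f_t = assay.target_positive / assay.target_total
        f_r = assay.reference_positive / assay.reference_total
        assert f_t == pytest.approx(f_r, abs=0.02)

    def test_positive_fraction_follows_poisson_partition(self):
        # lambda_target = 0.5 * 6/2 = 1.5 -> fraction 1 - e^{-1.5}.
        assay = g.simulate_droplet_assay(6, n_droplets=20_000, base_lambda=0.5, seed=4)
        expected = 1 - math.exp(-1.5)
        assert assay.target_positive / 20_000 == pytest.approx(expected, abs=0.01)
        assert assay.reference_positive / 20_000 == pytest.approx(
            1 - math.exp(-0.5), abs=0.01
        )


class TestSnpSimulation:
    def test_full_sharing_gives_zero_opposite_homozygotes(self):
        iv = g.GenomicInterval("chr25", 0, 10_000_000)
        m = g.simulate_snp_genotypes(
            500, ["a", "b"], ibd_interval=iv, ibd_pairs=[("a", "b", 2)],
            chrom_length=10_000_000, seed=6,
        )
        a, b = m.column("a"), m.column("b")
        assert (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum() == 0

    def test_sharing_confined_to_interval(self):
        iv = g.GenomicInterval("chr25", 4_000_000, 6_000_000)
        m = g.simulate_snp_genotypes(
            4000, ["a", "b"], ibd_interval=iv, ibd_pairs=[("a", "b", 2)],
            chrom_length=10_000_000, seed=6,
        )
        a, b = m.column("a"), m.column("b")
        opp = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
        inside = (m.positions >= iv.start) & (m.positions < iv.end)
        assert opp[inside].sum() == 0
        assert opp[~inside].mean() > 0.01


class TestReadSimulation:
    def test_noise_free_reads_have_exact_length(self, small_locus_model, unit_and_flanks):
        unit, flanks = unit_and_flanks
        reads, _ = g.simulate_allele_reads(
            g.GreyAllele(2), small_locus_model, unit, flanks, n_reads=5, seed=1
        )
        expected = small_locus_model.expected_fragment_length(2)
        assert all(r.length == expected for r in reads)

    def test_triplication_mean_length_at_genomic_scale(self, locus_model):
        reads, _ = g.simulate_allele_reads(
            g.GreyAllele(3), locus_model, n_reads=10, length_noise_sd=100, seed=2
        )
        mean_len = np.mean([r.length for r in reads])
        assert mean_len == pytest.approx(16_900, rel=0.01)

    def test_junction_carries_planted_motif(self, small_locus_model, unit_and_flanks):
        unit, flanks = unit_and_flanks
        assert unit.endswith("TCTCAG")
        assert flanks[1].startswith("TCTCAG")
        # Each copy-copy junction ends with the motif, and the reference
        # sequence that follows the breakpoint (the right flank) begins with
        # it: the motif flanks the breakpoint on each side.
        fragment = build_fragment(g.GreyAllele(2), unit, flanks)
        junction = len(flanks[0]) + len(unit)
        assert fragment[junction - 6 : junction] == "TCTCAG"
        assert fragment.count("TCTCAG") == 3  # once per copy + right flank

    def test_motif_longer_than_unit_rejected(self, small_locus_model):
        with pytest.raises(ValueError):
            g.simulate_allele_reads(
                g.GreyAllele(1),
                small_locus_model,
                microhomology_motif="A" * 1000,
                n_reads=1,
            )


class TestPileupSimulation:
    def test_no_hets_no_errors_means_pure_major(self):
        pt = g.simulate_pileup(
            5000, het_density=0.0, depth=30, error_rate=0.0, seed=3
        )
        counts = pt.frame[["A", "C", "G", "T"]].to_numpy()
        assert (np.sort(counts, axis=1)[:, :3] == 0).all()

    def test_het_sites_split_reads_evenly(self):
        pt = g.simulate_pileup(
            20_000, het_density=1.0, depth=40, error_rate=0.0, seed=3
        )
        counts = np.sort(pt.frame[["A", "C", "G", "T"]].to_numpy(), axis=1)
        # Reads at a het site split Binomial(depth, 1/2) between the two
        # alleles, so each allele's count averages depth / 2 = 20.
        assert (counts[:, 2:].mean(axis=0) / 20).mean() == pytest.approx(1, abs=0.03)
        assert counts[:, :2].sum() == 0
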