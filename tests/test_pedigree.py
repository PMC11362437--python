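import itertools

import numpy as np
import pytest

import greycnv as g
from conftest import make_trio


def enumerate_configs(total, phenotype, dam_alleles, sire_alleles, max_allele):
    """Exhaustive oracle over ordered (maternal, paternal) pairs for a single
    individual given transmissible parental alleles."""
    out = set()
    for m, p in itertools.product(range(1, max_allele + 1), repeat=2):
        if total is not None and m + p != total:
            continue
        top = max(m, p)
        if phenotype == g.FAST and top < 3:
            continue
        if phenotype == g.SLOW and top != 2:
            continue
        if phenotype == g.NON_GREY and top != 1:
            continue
        if dam_alleles is not None and m not in dam_alleles:
            continue
        if sire_alleles is not None and p not in sire_alleles:
            continue
        out.add((max(m, p), min(m, p)))
    return out


class TestDeduceAlleles:
    def test_wildtype_dam_forces_offspring_split(self):
        # A fast-greying sire with 5 total copies mated to wild-type dams:
        # 4-copy progeny are 3+1 and 3-copy progeny 2+1.
        ped = g.Pedigree()
        ped.add(g.Individual("sire", phenotype=g.FAST, measured_total_copies=5))
        ped.add(g.Individual("dam", phenotype=g.NON_GREY, measured_total_copies=2))
        ped.add(g.Individual("fast_kid", sire_id="sire", dam_id="dam",
                             phenotype=g.FAST, measured_total_copies=4))
        ped.add(g.Individual("slow_kid", sire_id="sire", dam_id="dam",
                             phenotype=g.SLOW, measured_total_copies=3))
        ded = g.deduce_alleles(ped)
        assert ded["sire"].configurations == {(3, 2)}
        assert ded["fast_kid"].configurations == {(3, 1)}
        assert ded["slow_kid"].configurations == {(2, 1)}
        assert all(ded[i].unique for i in ("sire", "dam", "fast_kid", "slow_kid"))

    def test_five_copies_without_parents_needs_allele_cap(self):
        ped = g.Pedigree([
            g.Individual("x", phenotype=g.FAST, measured_total_copies=5)
        ])
        ded4 = g.deduce_alleles(ped, max_allele=4)
        assert ded4["x"].configurations == {(3, 2), (4, 1)}
        assert ded4["x"].configurations == enumerate_configs(5, g.FAST, None, None, 4)
        # Capping the allele size at the largest germ-line allele observed
        # makes the deduction unique.
        ded3 = g.deduce_alleles(ped, max_allele=3)
        assert ded3["x"].configurations == {(3, 2)}
        assert ded3["x"].unique

    def test_matches_enumeration_oracle_on_trios(self):
        for dam_t, sire_t, child_t in itertools.product((2, 3, 4, 5, 6), repeat=3):
            ped = make_trio(dam_t, sire_t, child_t)
            ded = g.deduce_alleles(ped)
            dam_alleles = {a for pair in enumerate_configs(dam_t, g.UNKNOWN, None, None, 3)
                           for a in pair}
            sire_alleles = {a for pair in enumerate_configs(sire_t, g.UNKNOWN, None, None, 3)
                            for a in pair}
            expected = enumerate_configs(child_t, g.UNKNOWN, dam_alleles, sire_alleles, 3)
            assert ded["child"].configurations == expected, (dam_t, sire_t, child_t)

    def test_deduction_contains_simulated_truth(self):
        for seed in range(20):
            ped = g.simulate_pedigree(
                g.SimulationConfig(seed=seed), n_founders=6, n_generations=3
            )
            ded = g.deduce_alleles(ped)
            for ind in ped:
                assert ind.true_genotype.as_sorted_tuple() in ded[ind.id].configurations

    def test_wildtype_matings_always_unique(self):
        # The mapping design: every mating has one wild-type parent, so every
        # offspring's deduction is unique.
        rng = np.random.default_rng(12)
        for trial in range(50):
            sire_pair = tuple(rng.integers(1, 4, size=2))
            ped = g.Pedigree()
            sire_gt = g.CnvGenotype.from_copies(*sire_pair)
            ped.add(g.Individual("sire", phenotype=g.phenotype_from_genotype(sire_gt),
                                 measured_total_copies=sire_gt.total_copies))
            ped.add(g.Individual("dam", phenotype=g.NON_GREY, measured_total_copies=2))
            for k in range(4):
                allele = sire_pair[rng.integers(0, 2)]
                gt = g.CnvGenotype.from_copies(1, allele)
                ped.add(g.Individual(
                    f"kid{k}", sire_id="sire", dam_id="dam",
                    phenotype=g.phenotype_from_genotype(gt),
                    measured_total_copies=gt.total_copies,
                ))
            ded = g.deduce_alleles(ped)
            for k in range(4):
                assert ded[f"kid{k}"].unique


class TestMutationEvents:
    def test_consistent_pedigree_yields_no_events(self):
        ped = make_trio(4, 2, 3, child_phenotype=g.SLOW)
        assert g.detect_cnv_mutation_events(ped) == []

    def test_contraction_in_homozygous_dam_identified(self):
        # G3/G3 dam x G1/G1 sire with a 3-copy (G2/G1) child: the two-copy
        # allele must be a de-novo 3 -> 2 contraction in the dam's meiosis.
        ped = make_trio(6, 2, 3, child_phenotype=g.SLOW,
                        dam_phenotype=g.FAST, sire_phenotype=g.NON_GREY)
        events = g.detect_cnv_mutation_events(ped)
        assert len(events) == 1
        ev = events[0]
        assert ev.parent_id == "dam"
        assert (ev.expected_copies, ev.transmitted_copies) == (3, 2)
        assert ev.direction == "contraction"
        assert not ev.complex

    def test_expansion_between_wildtype_parents_is_unattributable(self):
        ped = make_trio(2, 2, 3)
        events = g.detect_cnv_mutation_events(ped)
        assert len(events) == 1
        ev = events[0]
        assert ev.parent_id is None
        assert (ev.expected_copies, ev.transmitted_copies) == (1, 2)
        assert ev.direction == "expansion"

    def test_unrepairable_inconsistency_flagged_complex(self):
        # A fast phenotype with only 2 total copies contradicts any genotype;
        # no single-gamete change can repair it.
        ped = make_trio(2, 2, 2, child_phenotype=g.FAST)
        events = g.detect_cnv_mutation_events(ped)
        assert len(events) == 1
        assert events[0].complex

    def test_no_false_events_on_simulated_pedigrees(self):
        for seed in range(200):
            ped = g.simulate_pedigree(
                g.SimulationConfig(seed=seed), n_founders=6, n_generations=3
            )
            assert g.detect_cnv_mutation_events(ped) == []

    def test_soundness_on_informative_pedigrees(self):
        # Homozygous G3/G3 x G1/G1 founders with contraction-only mutation:
        # every simulated event manifests as a Mendelian inconsistency and
        # must be detected; single events must be attributed to the dam/sire
        # that actually mutated whenever a parent is reported.
        n_detected = n_events = 0
        for seed in range(1000):
            config = g.SimulationConfig(seed=seed, contraction_rate=0.04)
            ped = g.simulate_pedigree(
                config, n_founders=4, n_generations=2, offspring_per_mating=2,
                founder_genotypes=[
                    g.CnvGenotype.from_copies(3, 3),
                    g.CnvGenotype.from_copies(1, 1),
                ],
            )
            detected = {ev.child_id: ev for ev in g.detect_cnv_mutation_events(ped)}
            by_child: dict[str, list] = {}
            for rec in ped.mutation_events:
                by_child.setdefault(rec.child_id, []).append(rec)
            for child_id, recs in by_child.items():
                n_events += len(recs)
                assert child_id in detected
                ev = detected[child_id]
                n_detected += 1
                if len(recs) == 1 and not ev.complex:
                    rec = recs[0]
                    assert ev.direction == rec.direction
                    assert (ev.expected_copies, ev.transmitted_copies) == (
                        rec.from_copies, rec.to_copies,
                    )
                    if ev.parent_id is not None:
                        assert ev.parent_id == rec.parent_id
            # No detection without a simulated event.
            assert set(detected) <= set(by_child)
        assert n_events > 50  # the scenario actually exercised mutation
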