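"""Deduce per-chromosome Grey alleles from total copy numbers in a pedigree.

Builds the mapping family: a fast-greying sire with 5 total copies mated to
wild-type dams, with fast (4-copy) and slow (3-copy) offspring, then a second
family in which a slow 3-copy foal appears from a G3/G3 dam and a G1/G1 sire
— only explicable by a de-novo copy-number contraction in the dam's meiosis.
"""

import greycnv as g

ped = g.Pedigree()
ped.add(g.Individual("sire", phenotype=g.FAST, measured_total_copies=5))
ped.add(g.Individual("dam", phenotype=g.NON_GREY, measured_total_copies=2))
ped.add(g.Individual("fast_foal", sire_id="sire", dam_id="dam",
                     phenotype=g.FAST, measured_total_copies=4))
ped.add(g.Individual("slow_foal", sire_id="sire", dam_id="dam",
                     phenotype=g.SLOW, measured_total_copies=3))

print("Allele deduction (allele cap 3):")
for ind_id, ded in g.deduce_alleles(ped).items():
    configs = " or ".join(f"{a}+{b}" for a, b in sorted(ded.configurations))
    print(f"  {ind_id:10s} total={ped[ind_id].measured_total_copies}  ->  {configs}"
          f"{'  (unique)' if ded.unique else ''}")

trio = g.Pedigree()
trio.add(g.Individual("dam", phenotype=g.FAST, measured_total_copies=6))
trio.add(g.Individual("sire", phenotype=g.NON_GREY, measured_total_copies=2))
trio.add(g.Individual("X", dam_id="dam", sire_id="sire",
                      phenotype=g.SLOW, measured_total_copies=3))
for ev in g.detect_cnv_mutation_events(trio):
    print(f"\nDe-novo event in {ev.child_id}: {ev.direction} "
          f"{ev.expected_copies} -> {ev.transmitted_copies} copies "
          f"during meiosis in parent {ev.parent_id!r}")
# The contraction 3 -> 2 in the dam is the birth of a slow-greying G2 allele
# from a fast-greying G3 allele.
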