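"""Opposite-homozygote IBD scan and run-of-homozygosity calling.

Simulates two samples sharing both haplotypes across a 350 kb segment
(chr25:6.45-6.80 Mb, the region shared by all slow- and fast-greying
haplotypes) and recovers it from sliding 100-SNP windows of
opposite-homozygote fractions.  Then simulates pileup data for an individual
homozygous across a 16 Mb region and recovers the ROH from windowed
nucleotide diversity with the 3-minor-read noise filter.
"""

import greycnv as g

ibd_true = g.parse_region("chr25:6450001-6800000")
snps = g.simulate_snp_genotypes(
    20_000, ["g2_homozygote", "carrier"], ibd_interval=ibd_true,
    ibd_pairs=[("g2_homozygote", "carrier", 2)], chrom_length=12_000_000, seed=17,
)
scan = g.opposite_homozygote_fractions("g2_homozygote", "carrier", snps,
                                       window_snps=100)
best = max(g.call_ibd_intervals(scan, max_fraction=0.0), key=len)
print(f"true IBD segment    chr25:{ibd_true.start}-{ibd_true.end}")
print(f"called IBD segment  {best.chrom}:{best.start}-{best.end} "
      f"({len(best)/1000:.0f} kb)")

roh_true = g.parse_region("chr25:2-18Mb")
pileup = g.simulate_pileup(20_000_000, het_density=0.01, roh_interval=roh_true,
                           depth=45, error_rate=0.001, site_spacing=400, seed=17)
track = g.pileup_diversity(pileup, min_minor_reads=3, window_bp=500_000)
roh = max(g.call_roh(track, max_diversity=1e-4), key=len)
print(f"called ROH          {roh.chrom}:{roh.start}-{roh.end} "
      f"({len(roh)/1e6:.0f} Mb)")
# The called boundaries land within one window of the planted segments; the
# 16 Mb ROH is what identifies a recent homozygous-by-descent chromosome.
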