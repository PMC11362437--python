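"""Estimate diploid copy number from read depth and from droplet digital PCR.

Simulates a G3/G2 compound heterozygote (5 total copies): a Poisson coverage
track around the CNV interval and a 20,000-droplet ddPCR assay.  Both
estimators should call 5 copies; the printed confidence intervals show the
two assays' precision at these settings.
"""

import greycnv as g

locus = g.CnvLocusModel()  # unit 4.6 kb in STX17 intron 6
genotype = g.CnvGenotype.from_copies(3, 2)

track = g.simulate_coverage_track(genotype, locus, mean_depth=30, seed=17)
baseline = g.GenomicInterval("chr25", locus.cnv_interval.start - 40_000,
                             locus.cnv_interval.start - 2_000)
cov = g.estimate_copy_number_from_coverage(track, locus.cnv_interval, baseline)
print(f"coverage: estimate={cov.estimate:.2f} call={cov.call} "
      f"95% CI [{cov.ci_low:.2f}, {cov.ci_high:.2f}]")

assay = g.simulate_droplet_assay(genotype.total_copies, n_droplets=20_000,
                                 base_lambda=0.5, seed=17)
dd = g.ddpcr_copy_number(assay)
print(f"ddPCR:    estimate={dd.estimate:.2f} call={dd.call} "
      f"95% CI [{dd.ci_low:.2f}, {dd.ci_high:.2f}]")
# Both integer calls equal the simulated total of 5 copies (3 + 2), the
# signature of a G2/G3 heterozygote.
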