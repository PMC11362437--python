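# greycnv

Analysis toolkit for the allelic series at the horse *Grey* locus — a tandem
copy number variant (CNV) of a 4.6 kb sequence in intron 6 of *STX17*.
Alleles carry one (G1, wild type), two (G2, slow greying) or three (G3, fast
greying) tandem copies of the unit; the largest allele dominates the
phenotype, and the G3 allele additionally carries a high melanoma risk.

The package is aimed at researchers working on tandem CNV genotyping in
pedigreed populations.  It implements the full inference chain needed to
resolve such a locus when assays report only *total* diploid copy number:

* **Copy-number genotyping** — diploid copy number from windowed read depth
  (2 × CNV/baseline depth ratio) and from droplet digital PCR (Poisson
  inversion `λ = −ln(1 − p)`, copy number `2 λ_target / λ_reference`), each
  with delta-method confidence intervals.
* **Pedigree allele deduction** — constraint propagation of Mendelian
  transmission over a pedigree turns total copy numbers into per-chromosome
  alleles (e.g. a 4-copy foal of a wild-type dam must be 3 + 1), and
  explains Mendelian inconsistencies as minimal de-novo copy-number
  mutation events (contraction preferred at ties), as in the observed birth
  of a G2 allele from a G3/G3 dam.
* **Association statistics** — exact χ² goodness of fit (no continuity
  correction), the two-sided Fisher exact test (point-probability method),
  a dominance-model (carrier vs non-carrier) per-SNP scan, and Bonferroni
  thresholds.
* **IBD scanning** — fractions of opposite-homozygote calls in sliding
  100-SNP windows between sample pairs (zero across segments shared
  identical-by-descent), the heterozygous-comparator variant, interval
  calling, and pileup-based nucleotide diversity with a ≤2-minor-read noise
  filter feeding a runs-of-homozygosity caller.
* **Long-read allele typing** — spanning-read classification by length
  (flank + k × unit ≈ 7.7/12.3/16.9 kb for k = 1/2/3), per-allele binning
  and majority-vote consensus, k-mer dotplot detection of head-to-tail
  tandem structure, and breakpoint microhomology (the 6 bp TCTCAG motif).
* **Methylation** — per-site CpG methylation fractions from per-read
  5mC/5hmC calls, 5-CpG sliding-window smoothing, and enhancer
  hypomethylation contrasts.
* **Breed population genetics** — genotype deduction from copy-number
  histograms (totals 2/3/5/6 are unambiguous; 4-copy horses are counted as
  G1/G3 under the no-G2/G2 assumption), allele counting
  `fG2 = (n3 + n5)/2n`, `fG3 = (n4 + n5 + 2 n6)/2n`, and Hardy–Weinberg
  expectations.
* **Synthetic data** — first-class simulators for every input: pedigrees
  with CNV transmission and mutation, coverage tracks, droplet assays, SNP
  matrices with planted IBD segments, long spanning reads with CpG calls,
  and pileups with planted ROH.

## Worked example

```bash
python examples/pedigree_deduction.py
```

```
Allele deduction (allele cap 3):
  sire       total=5  ->  3+2  (unique)
  dam        total=2  ->  1+1  (unique)
  fast_foal  total=4  ->  3+1  (unique)
  slow_foal  total=3  ->  2+1  (unique)

De-novo event in X: contraction 3 -> 2 copies during meiosis in parent 'dam'
```

The 5-copy fast-greying sire resolves uniquely to a G3/G2 heterozygote once
alleles are capped at three copies; his foals by wild-type (G1/G1) dams
resolve to G3/G1 (fast, 4 copies) and G2/G1 (slow, 3 copies).  In the second
family a slow 3-copy foal born to a G3/G3 dam and G1/G1 sire is Mendelian-
impossible without mutation; the detector attributes a single 3 → 2
contraction to the dam's meiosis — a new G2 allele born from a G3 allele.

Other examples (`examples/*.py`) cover copy-number estimation, the
association scan, the IBD/ROH scans, long-read typing and methylation
profiling, each printing the numbers it computes and what they mean.

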