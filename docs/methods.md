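# Methods

This note describes the models behind `greycnv`, the defaults and why they
were chosen, what the simulators do and do not emulate, and the numerical
conventions used throughout.

## The locus model

The *Grey* locus is modelled as a tandem array of a duplicated unit inside a
fixed genomic interval.  `CnvLocusModel` carries the unit length (default
4,600 bp), the pooled flanking length captured around the array (default
3,100 bp) and the CNV interval on chr25.  A captured fragment spanning an
allele with `k` copies has expected length `flank + k × unit`, which at the
genomic defaults gives 7.7, 12.3 and 16.9 kb for one, two and three copies.
`CnvLocusModel.scaled_down()` divides both lengths by ten (unit 460 bp,
flank 310 bp) so that sequence-level simulations run at desk scale; all
classification logic depends only on length ratios and is unchanged.

Phenotype follows a dominance-of-the-largest-allele rule: any allele with at
least three copies gives fast greying, a largest allele of exactly two
copies slow greying, and two single-copy alleles a non-grey horse.  One
known limitation: a G2/G2 homozygote has been described with a coat
phenotype intermediate between slow and fast greying; a discrete three-class
phenotype cannot express "intermediate", so the model classifies G2/G2 as
slow and this is accepted as a deliberate simplification.

## Copy-number estimation

**Read depth.**  The point estimate is `2 × mean(depth in CNV windows) /
mean(depth in baseline windows)`.  The baseline is a user-supplied interval
set rather than a genome-wide mean because the supported tracks are short
regional extracts, and because a nearby CNV-free control region is the
natural control for a single-locus assay.  The 95% CI uses the delta method
on the log ratio with sample variances of the window means (Poisson variance
`mean/window_bp` when only one window exists).  Integer calls round half
away from zero, which is symmetric around true integer copy numbers.

**ddPCR.**  Positive-droplet fractions are Poisson-corrected per channel,
`λ = −ln(1 − p)`, and the copy number is `2 λ_target / λ_reference`, the
standard partition model for digital PCR; how the original assay converted
concentration ratios to integers is not documented, so this inversion is a
design decision of the package.  Binomial standard errors of the positive
fractions propagate through the log transform to a 95% CI.  Saturated
(all-positive) and empty channels are rejected with errors naming the
channel, since `λ` is then undefined.

At the default simulation settings (depth 20 with ten windows across the
CNV; 20,000 droplets with a reference mean of 0.5 molecules per droplet)
both estimators make the correct integer call in ≥ 99% of simulations for
all diploid totals from 2 to 6, and the two assays agree with each other at
the same rate — this is what licenses treating the measured total as exact
in the pedigree machinery below.

## Pedigree allele deduction and mutation events

Deduction is purely combinatorial, mirroring how such deductions are made by
hand: no probabilities are assigned.  Each individual starts with every
ordered (maternal, paternal) allele pair consistent with its measured total
copy number and phenotype, with alleles capped at `max_allele` (default 3,
because screening ~1,400 horses has revealed no germ-line allele beyond
three copies; the cap is configurable).  Two constraint families are then
applied to a fixed point: a child's maternal (paternal) allele must be
transmissible by its dam (sire), and a parent's genotype must be able to
serve every child.  Genotypes are reported unordered unless parental data
forces an orientation.  A full Bayesian treatment was rejected as
unnecessary: the assays are effectively exact (previous section) and the
published deductions are combinatorial.

An individual whose candidate set empties is a Mendelian inconsistency.  The
mutation detector searches for the smallest single-gamete copy change that
restores consistency — increasing |Δ|, trying contraction before expansion
at each |Δ| — and reports the implicated parent only when a single parent's
meiosis can host the event.  Inconsistencies that no single event repairs
are flagged complex.  Contraction-first tie-breaking encodes the empirical
asymmetry that the one directly observed germ-line event was a contraction,
and that expansions beyond three copies appear absent.

A structural limitation, not an implementation one: a mutation whose product
coincides with an allele the parent could legitimately transmit (e.g. a
2 → 1 contraction from a (2,1) parent) produces no Mendelian inconsistency
and is invisible to any method based on total copy numbers.  The soundness
tests therefore use informative pedigrees (homozygous founders, matching
the published families' design) in which every simulated event is
detectable; on general pedigrees the guarantee is one-sided — no false
events are ever reported.

## Association statistics

The χ² goodness-of-fit statistic is `Σ(O−E)²/E` without continuity
correction (this choice reproduces both published statistics exactly), with
an upper-tail χ² p-value.  The Fisher exact test is two-sided by the
point-probability method — the sum of hypergeometric probabilities of all
tables, at fixed margins, no more probable than the observed table — which
is the construction used by the major implementations; the tests verify it
against an exact integer-arithmetic enumeration oracle for every 2×2 table
with n ≤ 30.  The dominance scan encodes each sample as carrier (genotype
≥ 1) versus non-carrier, tests each site's 2×2 carrier-by-phenotype table
with the Fisher test, and assigns p = 1 to sites monomorphic in carrier
status.  Missing genotypes are excluded per site.

One documented discrepancy: the melanoma contrast is described in prose as
"80% vs 0%", but the printed statistic (χ² = 25.0, P = 6 × 10⁻⁷) is
arithmetically the one-sample test of 0 affected out of 25 against an
expected proportion of 0.5 — the lower bound of the 50–80% incidence range
cited for aged fast-greying horses.  The package reproduces the printed
computation (p₀ = 0.5) and takes no position on intent.

## IBD scan and homozygosity

A site is an opposite-homozygote call when one sample is genotype 0 and the
other 2; such sites are impossible within a segment where the pair shares
both haplotypes IBD.  Window fractions use windows of 100 SNPs sliding one
SNP at a time (the step is configurable; "sliding" windows with unspecified
step are taken as step 1).  Sites with a missing genotype in either sample
are excluded from numerator and denominator, and windows are defined over
the remaining comparable sites.  For a compound heterozygote comparator the
scan splits into a homozygous-difference track and a heterozygous-difference
track (comparison sample het, reference homozygous), reflecting divergence
from each of the two haplotypes.  Interval calling reports maximal runs of
windows at or below a threshold fraction, in bp from the first to the last
SNP of the run.

Pileup diversity is the per-site non-major read fraction, zeroed when fewer
than `min_minor_reads` (default 3) reads support a non-major allele — the
filter that suppresses long-read basecalling noise — and averaged in 500 kb
windows.  ROH are maximal runs of windows at or below a diversity threshold.
Mapping-quality filtering is assumed to have happened upstream of the
pileup abstraction.  Coordinates are 0-based half-open internally and in
BED output; VCF positions are 1-based.

## Long-read allele typing

Reads are classified to the copy number whose expected fragment length is
nearest, rejecting reads whose residual is at least half a unit length.
Binned reads are collapsed by per-column majority vote after anchoring at
the captured-fragment start and normalising to the bin's modal length; with
substitution-only errors at the simulated rates this is exact enough that a
partial-order aligner would add nothing (50 reads at 3% error leave the
consensus ≥ 99.9% identical to truth), and the original study's consensus
method is not documented.  Bins with fewer than three reads are flagged
low-confidence.

Structure detection is a programmatic dotplot: exact 15-mers sampled every
15 bp of the consensus are matched against both strands of the reference
unit and grouped by diagonal; diagonals with at least five matches become
unit placements.  Substitution errors leave diagonals intact, and ambiguous
(`N`) bases simply break k-mers.  Two or more same-orientation placements,
each adjacent within 10% of the unit length, classify as head-to-tail
tandem; mixed orientations as inverted; one placement as single.

Junction microhomology follows the standard structural-variant convention:
at each copy–copy boundary the reported motif is the longest sequence that
is simultaneously a suffix of the sequence ending at the junction and a
prefix of the reference sequence following the corresponding breakpoint
(the downstream flank).  The junction position is the reference-unit end
coordinate, and the motif belongs to the junction rather than to either
copy.

## Methylation

Per-read calls at known CpG positions aggregate to per-site fractions;
5hmC counts as methylated when merging (total methylation), and sites with
zero calls are omitted rather than imputed.  Smoothing averages five
adjacent CpGs, moving one site at a time; the window position is reported
as the mean of member positions (needed for interval overlap; unspecified
upstream).  The hypomethylation contrast is simply mean(flank sites) −
mean(target sites).  Note that sliding-window smoothing preserves the
global mean only approximately (edge sites are down-weighted); the exact
identity holds for constant profiles only.

## Breed allele frequencies

Totals 2, 3, 5 and 6 map uniquely to G1/G1, G1/G2, G2/G3 and G3/G3.
Four-copy horses are counted entirely as G1/G3 under the assumption that no
G2/G2 homozygote is present, justified within each breed by the scarcity of
G1/G2 and G2/G3 heterozygotes; when G2/G2 individuals do exist this
deduction under-counts G2, and the simulation tests assert that directional
bias explicitly.  Frequencies are allele counts over 2n; report output
rounds half away from zero to two decimals.  Histogram entries above six
total copies are rejected (they would require a ≥4-copy allele, never
observed in the germ line); the cap is configurable.  Hardy–Weinberg
expectations map genotype probabilities to total copy number, pooling G1/G3
with G2/G2 at four copies.

## Simulators: what they emulate and what they do not

The generators produce every input with the statistical structure the
inference assumes: Mendelian allele transmission with per-meiosis
contraction/expansion of ≥2-copy alleles (defaults 0 — the one directly
observed event makes rates of order 10⁻² a stress-test setting, not a
default); founder genotypes in Hardy–Weinberg proportions at frequencies
G1 = 0.60, G2 = 0.05, G3 = 0.35 (the Connemara breed histogram, the breed
of the mapping pedigree); Poisson window depths proportional to local copy
number; binomial droplet partitions; linkage-equilibrium haplotypes with an
optionally planted IBD segment (only segment structure matters to the
scan); spanning reads with Gaussian length noise and substitution errors
only; CpG calls drawn per molecule from a two-level (background/enhancer)
pattern; and pileups with binomially split heterozygous sites.

Deliberately not emulated: read alignment and mapping artefacts, indels and
quality scores, GC/mappability bias in coverage, linkage disequilibrium
outside the planted segment, basecalling signal, and ascertainment bias in
breed sampling.  Passing tests therefore demonstrate correctness of the
inference given the assumed generative structure, not robustness to
alignment or chemistry artefacts of real data.

All randomness flows from a single integer seed per call (documented
default 17).

## Problem sizes

The test suite and the reproduction script run everything at desk scale:
sequence simulations use the tenfold-scaled-down locus; estimator accuracy
uses 250–1,000 replicates per copy number; the IBD scan plants a 350 kb
segment in 12–25 Mb of 6,000–20,000 SNPs; the ROH simulation samples a
20 Mb chromosome at 400 bp spacing; and the exhaustive Fisher cross-check
covers all 2×2 tables with n ≤ 30.  These sizes were chosen so the entire
suite completes in well under a minute of compute beyond the Fisher sweep
while keeping every statistical tolerance meaningful.
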