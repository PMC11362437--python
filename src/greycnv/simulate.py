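"""Synthetic-data generators for every stage of the analysis.

The generators emulate the statistical structure the inference assumes:
Mendelian transmission of CNV alleles with rare per-meiosis copy-number
mutation, Poisson read depth proportional to local copy number, Poisson
partitioning of molecules into ddPCR droplets, haplotype sharing inside a
designated IBD segment, long spanning reads whose length encodes allele copy
count, per-read CpG methylation calls with an enhancer dip, and pileup base
counts with heterozygous sites absent inside a run of homozygosity.

All randomness flows from a single integer seed per call (default 17).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import CoverageTrack, DropletAssay
from .model import (
    FAST,
    CnvGenotype,
    CnvLocusModel,
    GenomicInterval,
    GreyAllele,
    Individual,
    MutationRecord,
    Pedigree,
    SnpMatrix,
    phenotype_from_genotype,
)

__all__ = [
    "DEFAULT_SEED",
    "SimulationConfig",
    "MethylationPattern",
    "SpanningRead",
    "transmit_allele",
    "simulate_pedigree",
    "simulate_coverage_track",
    "simulate_droplet_assay",
    "simulate_snp_genotypes",
    "simulate_allele_reads",
    "simulate_pileup",
    "random_unit_and_flanks",
]

DEFAULT_SEED = 17

#: Founder allele frequencies matching the Connemara pony breed, the breed of
#: the mapping pedigree (total-copy-number histogram deduction; G1 by
#: complement).
DEFAULT_ALLELE_FREQUENCIES: Mapping[int, float] = {1: 0.60, 2: 0.05, 3: 0.35}


@dataclass
class SimulationConfig:
    """Bundle of simulator parameters.

    ``allele_frequencies`` maps allele copy counts to founder frequencies;
    ``contraction_rate``/``expansion_rate`` are per-meiosis probabilities that
    a transmitted allele with >= 2 copies loses/gains one copy.  Depth and
    error parameters are the defaults used by the per-assay generators.
    """

    seed: int = DEFAULT_SEED
    allele_frequencies: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_FREQUENCIES)
    )
    contraction_rate: float = 0.0
    expansion_rate: float = 0.0
    mean_depth: float = 30.0
    n_droplets: int = 20_000
    base_lambda: float = 0.5
    per_base_error: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.allele_frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"allele frequencies must sum to 1, got {total}")
        if any(c < 1 for c in self.allele_frequencies):
            raise ValueError("allele copy counts must be >= 1")
        for rate in (self.contraction_rate, self.expansion_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("mutation rates must lie in [0, 1]")


def _draw_allele(freqs: Mapping[int, float], rng: np.random.Generator) -> GreyAllele:
    copies = list(freqs)
    probs = np.array([freqs[c] for c in copies], dtype=float)
    return GreyAllele(int(rng.choice(copies, p=probs)))


def transmit_allele(
    genotype: CnvGenotype,
    rng: np.random.Generator,
    contraction_rate: float = 0.0,
    expansion_rate: float = 0.0,
) -> tuple[GreyAllele, Optional[tuple[int, int]]]:
    """One meiosis: pick a random parental allele, then apply at most one
    copy-number mutation.

    Mutation requires >= 2 tandem copies (contraction 2->1 removes the
    duplication; expansion adds a copy).  Returns the transmitted allele and,
    when a mutation occurred, the ``(from_copies, to_copies)`` pair.
    """
    parental = genotype.maternal if rng.random() < 0.5 else genotype.paternal
    copies = parental.copies
    if copies >= 2:
        u = rng.random()
        if u < contraction_rate:
            return GreyAllele(copies - 1), (copies, copies - 1)
        if u < contraction_rate + expansion_rate:
            return GreyAllele(copies + 1), (copies, copies + 1)
    return parental, None


def simulate_pedigree(
    config: SimulationConfig,
    n_founders: int = 8,
    n_generations: int = 3,
    offspring_per_mating: int = 2,
    founder_genotypes: Optional[Sequence[CnvGenotype]] = None,
    measure_all: bool = True,
) -> Pedigree:
    """Simulate a multi-generation pedigree segregating for the CNV.

    Founders (generation 0) draw two alleles from ``allele_frequencies``
    (Hardy-Weinberg) unless explicit ``founder_genotypes`` are supplied.
    Each later generation pairs the previous generation's individuals into
    dam/sire matings; every transmitted allele may mutate (see
    :func:`transmit_allele`) and every mutation is recorded in
    ``pedigree.mutation_events``.  Phenotypes follow
    :func:`~greycnv.model.phenotype_from_genotype`; ``measure_all`` stores the
    true total copy number as the measured value for every individual.
    """
    rng = np.random.default_rng(config.seed)
    ped = Pedigree()

    founders: list[Individual] = []
    for i in range(n_founders):
        if founder_genotypes is not None:
            gt = founder_genotypes[i % len(founder_genotypes)]
        else:
            gt = CnvGenotype(
                _draw_allele(config.allele_frequencies, rng),
                _draw_allele(config.allele_frequencies, rng),
            )
        ind = Individual(
            id=f"F{i}",
            phenotype=phenotype_from_genotype(gt),
            measured_total_copies=gt.total_copies if measure_all else None,
            true_genotype=gt,
            generation=0,
        )
        ped.add(ind)
        founders.append(ind)

    previous = founders
    counter = 0
    for gen in range(1, n_generations):
        if len(previous) < 2:
            break
        order = rng.permutation(len(previous))
        current: list[Individual] = []
        for j in range(0, len(order) - 1, 2):
            dam = previous[order[j]]
            sire = previous[order[j + 1]]
            for _ in range(offspring_per_mating):
                m_allele, m_mut = transmit_allele(
                    dam.true_genotype, rng,
                    config.contraction_rate, config.expansion_rate,
                )
                p_allele, p_mut = transmit_allele(
                    sire.true_genotype, rng,
                    config.contraction_rate, config.expansion_rate,
                )
                gt = CnvGenotype(m_allele, p_allele)
                child = Individual(
                    id=f"I{gen}_{counter}",
                    sire_id=sire.id,
                    dam_id=dam.id,
                    phenotype=phenotype_from_genotype(gt),
                    measured_total_copies=gt.total_copies if measure_all else None,
                    true_genotype=gt,
                    generation=gen,
                )
                counter += 1
                ped.add(child)
                current.append(child)
                if m_mut is not None:
                    ped.mutation_events.append(
                        MutationRecord(child.id, dam.id, *m_mut)
                    )
                if p_mut is not None:
                    ped.mutation_events.append(
                        MutationRecord(child.id, sire.id, *p_mut)
                    )
        previous = current
    return ped


def simulate_coverage_track(
    genotype: CnvGenotype,
    locus_model: CnvLocusModel,
    mean_depth: float = 30.0,
    window_bp: int = 1000,
    seed: int = DEFAULT_SEED,
    n_flank_windows: int = 50,
) -> CoverageTrack:
    """Per-window Poisson coverage around the CNV interval.

    Window depth is a Poisson total of base-level coverage divided by the
    window size; the expected per-base depth is ``mean_depth`` outside the CNV
    interval and ``mean_depth * total_copies / 2`` inside it (partial overlap
    interpolates linearly).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    cnv = locus_model.cnv_interval
    start = cnv.start - n_flank_windows * window_bp
    end = cnv.end + n_flank_windows * window_bp
    if start < 0:
        raise ValueError("flank extends past the chromosome start")
    if end - start < window_bp:
        raise ValueError("window larger than the simulated track")
    rng = np.random.default_rng(seed)
    starts = np.arange(start, end - window_bp + 1, window_bp, dtype=np.int64)
    ratio = genotype.total_copies / 2.0
    lam = np.empty(len(starts))
    for i, ws in enumerate(starts):
        win = GenomicInterval(cnv.chrom, int(ws), int(ws + window_bp))
        frac = win.overlap(cnv) / window_bp
        lam[i] = mean_depth * (1.0 + (ratio - 1.0) * frac) * window_bp
    depths = rng.poisson(lam) / window_bp
    return CoverageTrack(chrom=cnv.chrom, starts=starts, depths=depths, window_bp=window_bp)


def simulate_droplet_assay(
    total_copies: int,
    n_droplets: int = 20_000,
    base_lambda: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> DropletAssay:
    """Droplet digital PCR counts for target and reference channels.

    ``base_lambda`` is the mean molecules per droplet for a 2-copy locus (the
    reference assay); the target channel scales with ``total_copies / 2``.
    Positive-droplet counts are Binomial(n, 1 - exp(-lambda)).
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if base_lambda <= 0:
        raise ValueError("base_lambda must be positive")
    rng = np.random.default_rng(seed)
    lam_target = base_lambda * total_copies / 2.0
    p_target = 1.0 - math.exp(-lam_target)
    p_ref = 1.0 - math.exp(-base_lambda)
    return DropletAssay(
        target_positive=int(rng.binomial(n_droplets, p_target)),
        target_total=n_droplets,
        reference_positive=int(rng.binomial(n_droplets, p_ref)),
        reference_total=n_droplets,
    )


def simulate_snp_genotypes(
    n_snps: int,
    samples: Sequence[str],
    ibd_interval: Optional[GenomicInterval] = None,
    ibd_pairs: Sequence[tuple[str, str, int]] = (),
    chrom: str = "chr25",
    chrom_length: int = 40_000_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = DEFAULT_SEED,
) -> SnpMatrix:
    """Diploid genotypes with optional haplotype sharing in an IBD segment.

    Haplotypes are drawn independently per site from per-site background
    allele frequencies (no linkage disequilibrium).  Each ``(a, b, n_shared)``
    entry of ``ibd_pairs`` copies ``n_shared`` (1 or 2) haplotypes of sample
    ``a`` onto sample ``b`` at every site inside ``ibd_interval``.
    """
    rng = np.random.default_rng(seed)
    # Draw distinct positions without materialising the whole coordinate range.
    pool = np.unique(rng.integers(0, chrom_length, size=2 * n_snps + 16, dtype=np.int64))
    while len(pool) < n_snps:
        pool = np.unique(
            np.concatenate(
                [pool, rng.integers(0, chrom_length, size=2 * n_snps, dtype=np.int64)]
            )
        )
    positions = np.sort(rng.choice(pool, size=n_snps, replace=False))
    if ibd_interval is not None and ibd_interval.chrom != chrom:
        raise ValueError("ibd_interval chromosome does not match")
    freqs = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    n_samples = len(samples)
    haps = (rng.random((n_snps, n_samples, 2)) < freqs[:, None, None]).astype(np.int8)

    if ibd_pairs:
        if ibd_interval is None:
            raise ValueError("ibd_pairs given without an ibd_interval")
        inside = (positions >= ibd_interval.start) & (positions < ibd_interval.end)
        if not inside.any():
            raise ValueError("ibd_interval contains no simulated sites")
        index = {s: i for i, s in enumerate(samples)}
        for a, b, n_shared in ibd_pairs:
            if n_shared not in (1, 2):
                raise ValueError("n_shared haplotypes must be 1 or 2")
            for h in range(n_shared):
                haps[inside, index[b], h] = haps[inside, index[a], h]

    genotypes = haps.sum(axis=2).astype(np.int8)
    return SnpMatrix(
        chrom=chrom,
        positions=positions,
        samples=list(samples),
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# Long spanning reads and methylation calls
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MethylationPattern:
    """Per-CpG methylation probabilities on the simulated molecule.

    ``enhancer_interval_in_unit`` delimits the regulatory subinterval of each
    unit copy (the MITF-binding-site region) where methylation drops from
    ``background`` to ``enhancer``.  A fraction ``hydroxymethyl_fraction`` of
    methylated calls is emitted as 5hmC rather than 5mC.
    """

    background: float = 0.85
    enhancer: float = 0.10
    enhancer_interval_in_unit: tuple[int, int] = (150, 250)
    hydroxymethyl_fraction: float = 0.10


@dataclass
class SpanningRead:
    """A long read covering the whole captured CNV fragment."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def random_unit_and_flanks(
    locus_model: CnvLocusModel,
    microhomology_motif: str = "TCTCAG",
    seed: int = DEFAULT_SEED,
) -> tuple[str, tuple[str, str]]:
    """Random unit and (left, right) flank sequences with the microhomology
    motif planted at the copy-copy junction.

    The unit ends with the motif and the right flank begins with it, so every
    tandem junction carries the motif as an exact shared flank on both sides
    of the breakpoint — the configuration the junction finder must recover.
    """
    motif = microhomology_motif.upper()
    unit_len = locus_model.unit_length_bp
    if len(motif) >= unit_len:
        raise ValueError("microhomology motif longer than the unit")
    rng = np.random.default_rng(seed)
    left_len = locus_model.flank_length_bp // 2
    right_len = locus_model.flank_length_bp - left_len
    if len(motif) > right_len:
        raise ValueError("motif longer than the right flank")

    def _avoiding(length: int) -> str:
        # Rejection-sample so the motif occurs nowhere by chance.
        while True:
            s = _random_seq(length, rng)
            if motif not in s:
                return s

    unit = _avoiding(unit_len - len(motif)) + motif
    left = _avoiding(left_len)
    right = motif + _avoiding(right_len - len(motif))
    return unit, (left, right)


def build_fragment(allele: GreyAllele, unit_seq: str, flank_seqs: tuple[str, str]) -> str:
    """Error-free captured fragment: left flank + k tandem units + right flank."""
    left, right = flank_seqs
    return left + unit_seq * allele.copies + right


def simulate_allele_reads(
    allele: GreyAllele,
    locus_model: CnvLocusModel,
    unit_seq: Optional[str] = None,
    flank_seqs: Optional[tuple[str, str]] = None,
    microhomology_motif: str = "TCTCAG",
    n_reads: int = 50,
    length_noise_sd: float = 0.0,
    per_base_error: float = 0.0,
    meth_pattern: Optional[MethylationPattern] = None,
    seed: int = DEFAULT_SEED,
    read_id_prefix: str = "read",
) -> tuple[list[SpanningRead], pd.DataFrame]:
    """Simulate spanning reads of one allele plus per-read CpG calls.

    Reads cover the full captured fragment; their length is the expected
    fragment length plus Gaussian noise (applied at the right end, reads stay
    anchored at the fragment start), with substitution errors at
    ``per_base_error``.  CpG calls are drawn per molecule and per site from
    ``meth_pattern`` and returned as a tidy frame ``(read_id, cpg_pos, call)``
    with calls in {5mC, 5hmC, unmethylated}; positions refer to the clean
    fragment.
    """
    rng = np.random.default_rng(seed)
    if unit_seq is None or flank_seqs is None:
        unit_seq, flank_seqs = random_unit_and_flanks(
            locus_model, microhomology_motif, seed=seed
        )
    if len(unit_seq) != locus_model.unit_length_bp:
        raise ValueError("unit_seq length must equal the locus model unit length")
    fragment = build_fragment(allele, unit_seq, flank_seqs)
    frag_arr = np.frombuffer(fragment.encode(), dtype="S1")

    # CpG sites of the clean fragment and their per-site methylation probability.
    cpg_positions = np.array(
        [i for i in range(len(fragment) - 1) if fragment[i : i + 2] == "CG"],
        dtype=np.int64,
    )
    if meth_pattern is not None and len(cpg_positions):
        left_len = len(flank_seqs[0])
        unit_len = len(unit_seq)
        lo, hi = meth_pattern.enhancer_interval_in_unit
        offset = cpg_positions - left_len
        copy_idx = offset // unit_len
        in_units = (copy_idx >= 0) & (copy_idx < allele.copies)
        pos_in_unit = offset - copy_idx * unit_len
        in_enhancer = in_units & (pos_in_unit >= lo) & (pos_in_unit < hi)
        site_prob = np.where(
            in_enhancer, meth_pattern.enhancer, meth_pattern.background
        )
    else:
        site_prob = None

    reads: list[SpanningRead] = []
    call_rows: list[tuple[str, int, str]] = []
    true_len = len(fragment)
    for r in range(n_reads):
        rid = f"{read_id_prefix}{r}"
        seq = frag_arr.copy()
        if per_base_error > 0:
            err = rng.random(true_len) < per_base_error
            n_err = int(err.sum())
            if n_err:
                seq[err] = rng.choice(_BASES, size=n_err)
        target_len = true_len
        if length_noise_sd > 0:
            target_len = max(1, int(round(true_len + rng.normal(0, length_noise_sd))))
        if target_len < true_len:
            seq = seq[:target_len]
        elif target_len > true_len:
            seq = np.concatenate([seq, rng.choice(_BASES, size=target_len - true_len)])
        reads.append(SpanningRead(id=rid, sequence=seq.tobytes().decode()))

        if site_prob is not None:
            meth = rng.random(len(cpg_positions)) < site_prob
            hydro = meth & (
                rng.random(len(cpg_positions)) < meth_pattern.hydroxymethyl_fraction
            )
            for pos, m, h in zip(cpg_positions, meth, hydro):
                call = "5hmC" if h else ("5mC" if m else "unmethylated")
                call_rows.append((rid, int(pos), call))

    calls = pd.DataFrame(call_rows, columns=["read_id", "cpg_pos", "call"])
    return reads, calls


def simulate_pileup(
    chromosome_length: int,
    het_density: float = 0.001,
    roh_interval: Optional[GenomicInterval] = None,
    depth: float = 45.0,
    error_rate: float = 0.001,
    chrom: str = "chr25",
    site_spacing: int = 1,
    seed: int = DEFAULT_SEED,
):
    """Per-site pileup base counts for a diploid individual.

    Outside ``roh_interval`` a site is heterozygous with probability
    ``het_density`` (reads split ~50/50 between two bases); inside it only
    sequencing errors produce non-major counts.  Returns a
    :class:`~greycnv.ibd.PileupTable`.
    """
    from .ibd import PileupTable

    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    positions = np.arange(0, chromosome_length, site_spacing, dtype=np.int64)
    n = len(positions)
    depths = rng.poisson(depth, size=n)

    in_roh = np.zeros(n, dtype=bool)
    if roh_interval is not None:
        in_roh = (positions >= roh_interval.start) & (positions < roh_interval.end)
    het = (rng.random(n) < het_density) & ~in_roh

    major_idx = rng.integers(0, 4, size=n)
    counts = np.zeros((n, 4), dtype=np.int64)
    # Heterozygous sites: binomial split between major and a distinct minor base.
    minor_idx = (major_idx + rng.integers(1, 4, size=n)) % 4
    minor_reads = np.where(het, rng.binomial(depths, 0.5), 0)
    counts[np.arange(n), major_idx] = depths - minor_reads
    counts[np.arange(n), minor_idx] += minor_reads
    # Sequencing errors relocate reads to a random base.
    if error_rate > 0:
        n_err = rng.binomial(depths, error_rate)
        for i in np.nonzero(n_err)[0]:
            for _ in range(n_err[i]):
                src = rng.integers(0, 4)
                if counts[i, src] > 0:
                    counts[i, src] -= 1
                    counts[i, rng.integers(0, 4)] += 1

    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "depth": depths,
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
        }
    )
    return PileupTable(frame)
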