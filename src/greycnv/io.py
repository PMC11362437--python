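"""File formats and region parsing.

TSV is the lingua franca for pedigrees, pileups, methylation calls and scan
outputs; genotype matrices round-trip through a minimal GT-only VCF dialect
(written directly, read back with pysam); intervals use BED (0-based,
half-open) and sequences FASTA via Biopython.  ``parse_region`` converts
1-based inclusive ``chrom:start-end`` region strings (with optional kb/Mb
suffixes) into 0-based half-open intervals.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GenomicInterval, Individual, Pedigree, SnpMatrix

__all__ = [
    "parse_region",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "read_methylation_calls",
    "write_methylation_calls",
]

PathLike = Union[str, Path]

_REGION_RE = re.compile(
    r"^(?P<chrom>[\w.]+):(?P<start>\d+(?:\.\d+)?)(?P<start_unit>kb|mb)?"
    r"-(?P<end>\d+(?:\.\d+)?)(?P<end_unit>kb|mb)?$",
    re.IGNORECASE,
)

_UNIT_BP = {None: 1, "kb": 1_000, "mb": 1_000_000}


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (1-based, inclusive; optional kb/Mb suffixes)
    into a 0-based half-open :class:`GenomicInterval`.

    A trailing unit applies to both coordinates: ``"chr25:2-18Mb"`` spans
    2,000,000-18,000,000 (1-based), i.e. interval (1999999, 18000000).
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed region {text!r}")
    start_unit = m.group("start_unit")
    end_unit = m.group("end_unit")
    if start_unit is None and end_unit is not None:
        start_unit = end_unit  # "chr25:2-18Mb" form
    start = float(m.group("start")) * _UNIT_BP[
        start_unit.lower() if start_unit else None
    ]
    end = float(m.group("end")) * _UNIT_BP[end_unit.lower() if end_unit else None]
    start_i, end_i = int(round(start)), int(round(end))
    if start_i < 1 or start_i >= end_i:
        raise ValueError(f"invalid coordinates in region {text!r}")
    return GenomicInterval(m.group("chrom"), start_i - 1, end_i)


# ---------------------------------------------------------------------------
# Pedigree TSV: id, sire, dam, phenotype, total_copies ("." for missing)
# ---------------------------------------------------------------------------

def write_pedigree_tsv(pedigree: Pedigree, path: PathLike) -> None:
    rows = []
    for ind in pedigree:
        rows.append(
            {
                "id": ind.id,
                "sire": ind.sire_id if ind.sire_id is not None else ".",
                "dam": ind.dam_id if ind.dam_id is not None else ".",
                "phenotype": ind.phenotype,
                "total_copies": (
                    ind.measured_total_copies
                    if ind.measured_total_copies is not None
                    else "."
                ),
                "generation": ind.generation,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path: PathLike) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sire", "dam", "phenotype", "total_copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree TSV missing columns: {sorted(missing)}")
    ped = Pedigree()
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ped.add(
                Individual(
                    id=row.id,
                    sire_id=None if row.sire == "." else row.sire,
                    dam_id=None if row.dam == "." else row.dam,
                    phenotype=row.phenotype,
                    measured_total_copies=(
                        None if row.total_copies == "." else int(row.total_copies)
                    ),
                    generation=int(getattr(row, "generation", 0) or 0),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"pedigree TSV row {row_num}: {exc}") from exc
    return ped


# ---------------------------------------------------------------------------
# BED (0-based half-open)
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for row_num, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED row {row_num}: fewer than 3 columns")
            try:
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise ValueError(f"BED row {row_num}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Minimal VCF (GT only)
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(snps: SnpMatrix, path: PathLike) -> None:
    """Write a minimal GT-only VCF (positions converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={snps.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(snps.samples)
            + "\n"
        )
        for i in range(snps.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in snps.genotypes[i])
            fh.write(
                f"{snps.chrom}\t{snps.positions[i] + 1}\t.\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: PathLike) -> SnpMatrix:
    """Read a GT-only VCF back into a SnpMatrix (genotypes as alt dosage)."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        positions: list[int] = []
        rows: list[list[int]] = []
        chrom: Optional[str] = None
        for rec in vf:
            chrom = rec.chrom if chrom is None else chrom
            if rec.chrom != chrom:
                raise ValueError("multi-chromosome VCFs are not supported")
            positions.append(rec.pos - 1)  # back to 0-based
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(-1)
                else:
                    row.append(int(sum(gt)))
            rows.append(row)
    if chrom is None:
        raise ValueError("VCF contains no records")
    return SnpMatrix(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        samples=samples,
        genotypes=np.array(rows, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# Pileup and methylation-call TSVs
# ---------------------------------------------------------------------------

def write_pileup_tsv(pileup, path: PathLike) -> None:
    pileup.frame.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: PathLike):
    from .ibd import PileupTable

    df = pd.read_csv(path, sep="\t")
    return PileupTable(df)


def write_methylation_calls(calls: pd.DataFrame, path: PathLike) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_methylation_calls(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "cpg_pos": int, "call": str})
    required = {"read_id", "cpg_pos", "call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"methylation TSV missing columns: {sorted(missing)}")
    return df
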