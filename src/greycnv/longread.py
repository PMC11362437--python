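"""Allele typing from long spanning reads.

A Cas9-enriched long read spanning the whole CNV region has a length that
directly encodes the allele's copy count: flank plus k units (~7.7 / ~12.3 /
~16.9 kb for one, two and three copies at the genomic locus geometry).  Reads
are classified by length, binned per allele and collapsed to a consensus;
the consensus is then compared against the reference unit with a k-mer
dotplot to establish the tandem head-to-tail structure, and each copy-copy
junction is inspected for breakpoint microhomology (the shared motif found
immediately adjacent to the breakpoints on each side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import CnvLocusModel
from .simulate import SpanningRead

__all__ = [
    "AlleleBin",
    "UnitPlacement",
    "StructureReport",
    "Junction",
    "JunctionReport",
    "classify_read_copy_number",
    "bin_and_consensus",
    "detect_tandem_structure",
    "find_junction_microhomology",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_read_copy_number(
    read_length: int, locus_model: CnvLocusModel
) -> Optional[int]:
    """Copy count whose expected fragment length is nearest the read length.

    Returns ``None`` when the best residual is at least half a unit length
    (off-scale reads, e.g. non-spanning fragments).
    """
    if read_length <= 0:
        raise ValueError("read length must be positive")
    unit = locus_model.unit_length_bp
    k = max(1, round((read_length - locus_model.flank_length_bp) / unit))
    # The rounding above already minimises the residual over k >= 1.
    residual = abs(read_length - locus_model.expected_fragment_length(k))
    if residual >= unit / 2:
        return None
    return int(k)


@dataclass
class AlleleBin:
    """Reads assigned to one allele copy count, with their consensus."""

    copies: int
    read_ids: list[str]
    consensus: str
    low_confidence: bool = False  # fewer than 3 supporting reads

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def _majority_consensus(seqs: list[str], target_len: int) -> str:
    """Per-column majority vote after anchoring all reads at position 0.

    Reads are trimmed or treated as absent past their end; ties resolve to
    the lexicographically smallest base for determinism.
    """
    mat = np.full((len(seqs), target_len), b"-", dtype="S1")
    for i, s in enumerate(seqs):
        arr = np.frombuffer(s[:target_len].encode(), dtype="S1")
        mat[i, : len(arr)] = arr
    out = np.empty(target_len, dtype="S1")
    letters = np.array([b"A", b"C", b"G", b"T", b"N"], dtype="S1")
    counts = np.stack([(mat == base).sum(axis=0) for base in letters])
    best = counts.argmax(axis=0)
    out = letters[best]
    covered = counts.sum(axis=0) > 0
    out[~covered] = b"N"
    return out.tobytes().decode()


def bin_and_consensus(
    reads: Sequence[SpanningRead], locus_model: CnvLocusModel
) -> list[AlleleBin]:
    """Group spanning reads by inferred copy count and build per-bin consensi.

    Reads are anchored at the captured-fragment start and length-normalised
    to the modal read length of the bin before a per-column majority vote.
    Bins with fewer than three reads are flagged low-confidence; unclassifiable
    reads are dropped.
    """
    groups: dict[int, list[SpanningRead]] = {}
    for read in reads:
        k = classify_read_copy_number(read.length, locus_model)
        if k is not None:
            groups.setdefault(k, []).append(read)
    if not groups:
        raise ValueError("no classifiable spanning reads")
    bins: list[AlleleBin] = []
    for k in sorted(groups):
        members = groups[k]
        lengths = [r.length for r in members]
        values, cnts = np.unique(lengths, return_counts=True)
        modal_len = int(values[cnts.argmax()])
        consensus = _majority_consensus([r.sequence for r in members], modal_len)
        bins.append(
            AlleleBin(
                copies=k,
                read_ids=[r.id for r in members],
                consensus=consensus,
                low_confidence=len(members) < 3,
            )
        )
    return bins


@dataclass(frozen=True)
class UnitPlacement:
    """One placement of the reference unit on the consensus."""

    start: int
    end: int
    orientation: str  # "+" or "-"
    n_matches: int  # supporting k-mer matches


@dataclass
class StructureReport:
    placements: list[UnitPlacement]
    classification: str  # single | tandem_head_to_tail | inverted | complex
    kmer_size: int


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue  # ambiguous bases break k-mer matching
        index.setdefault(kmer, []).append(i)
    return index


def detect_tandem_structure(
    consensus: str,
    reference_unit_seq: str,
    kmer_size: int = 15,
    min_chain: int = 5,
    gap_tolerance_frac: float = 0.10,
) -> StructureReport:
    """Locate copies of the reference unit on a consensus via k-mer chaining.

    Exact ``kmer_size``-mers shared between consensus and unit (both strands)
    are grouped by diagonal into collinear segments — the programmatic
    equivalent of reading a dotplot.  Diagonals supported by at least
    ``min_chain`` matches become unit placements, reported in consensus
    order with orientation.  Classification: one placement is ``single``;
    two or more same-orientation placements, each adjacent to the next within
    ``gap_tolerance_frac`` of the unit length, are ``tandem_head_to_tail``;
    mixed orientations are ``inverted``; anything else is ``complex``.
    """
    unit_len = len(reference_unit_seq)
    if len(consensus) <= unit_len:
        raise ValueError("consensus must be longer than the unit")
    index_fwd = _kmer_index(reference_unit_seq, kmer_size)
    index_rev = _kmer_index(reverse_complement(reference_unit_seq), kmer_size)

    # diagonal -> match count; forward: cpos - upos, reverse: cpos - upos on
    # the reverse-complemented unit (placement start is the diagonal either way)
    diag_fwd: dict[int, int] = {}
    diag_rev: dict[int, int] = {}
    for cpos in range(0, len(consensus) - kmer_size + 1, kmer_size):
        kmer = consensus[cpos : cpos + kmer_size]
        if "N" in kmer:
            continue
        for upos in index_fwd.get(kmer, ()):
            d = cpos - upos
            diag_fwd[d] = diag_fwd.get(d, 0) + 1
        for upos in index_rev.get(kmer, ()):
            d = cpos - upos
            diag_rev[d] = diag_rev.get(d, 0) + 1

    def _merge(diags: dict[int, int], orientation: str) -> list[UnitPlacement]:
        # Diagonals within a few bp of each other belong to one placement
        # (substitution errors leave the diagonal intact; small drift merges).
        placements = []
        for d in sorted(diags):
            n = diags[d]
            if placements and d - placements[-1][0] <= kmer_size:
                prev_d, prev_n = placements[-1]
                placements[-1] = (prev_d if prev_n >= n else d, prev_n + n)
            else:
                placements.append((d, n))
        return [
            UnitPlacement(start=max(0, d), end=min(len(consensus), d + unit_len),
                          orientation=orientation, n_matches=n)
            for d, n in placements
            if n >= min_chain
        ]

    placements = _merge(diag_fwd, "+") + _merge(diag_rev, "-")
    placements.sort(key=lambda p: p.start)
    if not placements:
        raise ValueError("no match of the reference unit in the consensus")

    orientations = {p.orientation for p in placements}
    tol = gap_tolerance_frac * unit_len
    if len(placements) == 1:
        classification = "single"
    elif len(orientations) > 1:
        classification = "inverted"
    else:
        adjacent = all(
            abs(placements[i + 1].start - placements[i].end) <= tol
            for i in range(len(placements) - 1)
        )
        classification = "tandem_head_to_tail" if adjacent else "complex"
    return StructureReport(
        placements=placements, classification=classification, kmer_size=kmer_size
    )


@dataclass(frozen=True)
class Junction:
    position: int  # consensus coordinate of the copy-copy boundary
    microhomology: str

    @property
    def length(self) -> int:
        return len(self.microhomology)


@dataclass
class JunctionReport:
    junctions: list[Junction]

    @property
    def motifs(self) -> list[str]:
        return [j.microhomology for j in self.junctions]


def longest_common_flank(upstream: str, downstream: str, max_len: int = 100) -> str:
    """Longest sequence that is simultaneously a suffix of ``upstream`` and a
    prefix of ``downstream`` (capped at ``max_len``)."""
    limit = min(len(upstream), len(downstream), max_len)
    for k in range(limit, 0, -1):
        if upstream[-k:] == downstream[:k]:
            return upstream[-k:]
    return ""


def find_junction_microhomology(
    consensus: str,
    unit_placements: Sequence[UnitPlacement],
    reference_downstream: str,
    gap_tolerance: int = 10,
) -> JunctionReport:
    """Microhomology at each copy-copy junction of a tandem array.

    At a junction the sequence ending there (suffix of the upstream copy) is
    compared with the reference sequence that follows the corresponding
    breakpoint on the other side (``reference_downstream``, the sequence
    immediately after the unit in the reference); the microhomology is their
    longest exact shared flank.  Placements must be adjacent.
    """
    if len(unit_placements) < 2:
        raise ValueError("at least two unit placements (one junction) required")
    placements = sorted(unit_placements, key=lambda p: p.start)
    junctions: list[Junction] = []
    for left, right in zip(placements, placements[1:]):
        if abs(right.start - left.end) > gap_tolerance:
            raise ValueError(
                f"placements at {left.end} and {right.start} are not adjacent"
            )
        jpos = left.end
        motif = longest_common_flank(consensus[:jpos], reference_downstream)
        junctions.append(Junction(position=jpos, microhomology=motif))
    return JunctionReport(junctions=junctions)
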