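"""Pedigree-constrained deduction of per-chromosome CNV alleles.

Assays report only the diploid total copy number.  Within a pedigree the
per-chromosome alleles can nevertheless often be deduced combinatorially: a
horse with 4 total copies whose dam is wild type (1+1) must be 3+1, because
the dam can only transmit a single-copy allele.  This module propagates such
transmission constraints to a fixed point over the whole pedigree, and
explains any remaining Mendelian inconsistency as a minimal de-novo
copy-number mutation during one parental meiosis (the mechanism by which a
two-copy allele was observed to arise from a three-copy allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import FAST, NON_GREY, SLOW, Individual, Pedigree

__all__ = [
    "AlleleDeduction",
    "MutationEvent",
    "deduce_alleles",
    "detect_cnv_mutation_events",
    "DEFAULT_MAX_ALLELE",
]

#: Largest germ-line allele ever observed (no expansion beyond three tandem
#: copies among 1400 genotyped horses); configurable in every entry point.
DEFAULT_MAX_ALLELE = 3


@dataclass
class AlleleDeduction:
    """Deduced genotype configurations for one individual.

    ``configurations`` holds unordered genotypes as ``(larger, smaller)``
    copy-count pairs; ``unique`` is set when exactly one configuration
    survives constraint propagation.  An empty set marks a Mendelian
    inconsistency (input to :func:`detect_cnv_mutation_events`).
    """

    individual_id: str
    configurations: frozenset[tuple[int, int]]
    constraints_used: tuple[str, ...] = ()

    @property
    def unique(self) -> bool:
        return len(self.configurations) == 1

    @property
    def consistent(self) -> bool:
        return len(self.configurations) > 0

    @property
    def genotype(self) -> Optional[tuple[int, int]]:
        """The single deduced genotype, or ``None`` when not unique."""
        if self.unique:
            return next(iter(self.configurations))
        return None


@dataclass
class MutationEvent:
    """A de-novo copy-number change inferred from a Mendelian inconsistency."""

    child_id: str
    parent_id: Optional[str]  # None when the mutated gamete's parent is ambiguous
    expected_copies: int
    transmitted_copies: int
    complex: bool = False

    @property
    def direction(self) -> str:
        if self.complex:
            return "complex"
        return (
            "contraction"
            if self.transmitted_copies < self.expected_copies
            else "expansion"
        )


def _phenotype_ok(m: int, p: int, phenotype: str) -> bool:
    top = max(m, p)
    if phenotype == FAST:
        return top >= 3
    if phenotype == SLOW:
        return top == 2
    if phenotype == NON_GREY:
        return m == 1 and p == 1
    return True


def _initial_candidates(ind: Individual, max_allele: int) -> set[tuple[int, int]]:
    """Ordered (maternal, paternal) pairs consistent with the individual's own
    measured total and phenotype."""
    pairs = set()
    for m in range(1, max_allele + 1):
        for p in range(1, max_allele + 1):
            if (
                ind.measured_total_copies is not None
                and m + p != ind.measured_total_copies
            ):
                continue
            if not _phenotype_ok(m, p, ind.phenotype):
                continue
            pairs.add((m, p))
    return pairs


def _transmissible(cands: set[tuple[int, int]], max_allele: int) -> set[int]:
    """Alleles a parent with these candidate genotypes could transmit
    (assuming faithful, mutation-free meiosis)."""
    if not cands:
        # Unconstrained fallback; an inconsistent parent no longer constrains.
        return set(range(1, max_allele + 1))
    return {a for pair in cands for a in pair}


def _propagate(
    ped: Pedigree, max_allele: int, skip_children: frozenset[str] = frozenset()
) -> dict[str, set[tuple[int, int]]]:
    """Arc-consistent fixed point of transmission constraints.

    Candidate genotypes are ordered (maternal, paternal) pairs.  Downward
    constraints prune a child's pair when a parent cannot transmit the
    corresponding allele; upward constraints prune a parent's pair when some
    child could not have received any allele from it.  Individuals listed in
    ``skip_children`` (or whose candidate set has emptied) stop constraining
    their parents, so a single inconsistent meiosis does not poison the rest
    of the pedigree.
    """
    cand: dict[str, set[tuple[int, int]]] = {
        ind.id: _initial_candidates(ind, max_allele) for ind in ped
    }
    unconstrained = set(range(1, max_allele + 1))

    changed = True
    while changed:
        changed = False
        for ind in ped:
            if ind.id in skip_children:
                continue
            dam_ok = (
                _transmissible(cand[ind.dam_id], max_allele)
                if ind.dam_id is not None and ind.dam_id in ped
                else unconstrained
            )
            sire_ok = (
                _transmissible(cand[ind.sire_id], max_allele)
                if ind.sire_id is not None and ind.sire_id in ped
                else unconstrained
            )
            kept = {(m, p) for (m, p) in cand[ind.id] if m in dam_ok and p in sire_ok}
            if kept != cand[ind.id]:
                cand[ind.id] = kept
                changed = True
        # Upward: a parent's genotype must be able to serve every consistent child.
        for parent in ped:
            pid = parent.id
            for child in ped.children_of(pid):
                if child.id in skip_children or not cand[child.id]:
                    continue
                side = 0 if child.dam_id == pid else 1
                needed = {pair[side] for pair in cand[child.id]}
                kept = {
                    pair for pair in cand[pid] if needed & set(pair)
                }
                if kept != cand[pid]:
                    cand[pid] = kept
                    changed = True
    return cand


def _unordered(cands: set[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    return frozenset((max(m, p), min(m, p)) for m, p in cands)


def deduce_alleles(
    pedigree: Pedigree, max_allele: int = DEFAULT_MAX_ALLELE
) -> dict[str, AlleleDeduction]:
    """Deduce per-chromosome allele configurations for every individual.

    Enumerates all genotypes compatible with each individual's measured total
    copy number and phenotype, then propagates Mendelian transmission
    constraints through the pedigree to a fixed point.  ``max_allele`` caps
    the allele size considered (default 3, the largest germ-line allele
    observed).  Genotypes are reported unordered; an empty configuration set
    flags a Mendelian inconsistency.
    """
    inconsistent: set[str] = set()
    # Iterate: each newly discovered inconsistent child is excluded from
    # constraining others, then constraints are re-propagated.
    while True:
        cand = _propagate(pedigree, max_allele, frozenset(inconsistent))
        newly = {
            ind.id
            for ind in pedigree
            if not cand[ind.id] and ind.id not in inconsistent
        }
        if not newly:
            break
        inconsistent |= newly

    out: dict[str, AlleleDeduction] = {}
    for ind in pedigree:
        if ind.id in inconsistent:
            # Re-propagation skipped this individual, restoring its own-data
            # candidates; report the Mendelian conflict as an empty set.
            cand[ind.id] = set()
        notes = []
        if ind.measured_total_copies is not None:
            notes.append(f"total={ind.measured_total_copies}")
        if ind.phenotype != "unknown":
            notes.append(f"phenotype={ind.phenotype}")
        if ind.dam_id or ind.sire_id:
            notes.append("mendelian")
        out[ind.id] = AlleleDeduction(
            individual_id=ind.id,
            configurations=_unordered(cand[ind.id]),
            constraints_used=tuple(notes),
        )
    return out


def detect_cnv_mutation_events(
    pedigree: Pedigree, max_allele: int = DEFAULT_MAX_ALLELE
) -> list[MutationEvent]:
    """Explain Mendelian inconsistencies as single de-novo CNV mutations.

    For every individual whose constraint set empties, search for the minimal
    single-gamete copy-number change (one event, smallest ``|delta|``, ties
    resolved contraction first) that restores consistency with both parents.
    The implicated parent is reported when only one parent's meiosis can host
    the event; an inconsistency no single event can repair is flagged
    ``complex``.
    """
    deductions = deduce_alleles(pedigree, max_allele)
    bad_children = [
        ind for ind in pedigree if not deductions[ind.id].consistent
    ]
    if not bad_children:
        return []

    # Parent candidates computed with all inconsistent children excluded from
    # constraining the rest of the pedigree.
    skip = frozenset(ind.id for ind in bad_children)
    cand = _propagate(pedigree, max_allele, skip)
    unconstrained = set(range(1, max_allele + 1))

    events: list[MutationEvent] = []
    for child in bad_children:
        own = _initial_candidates(child, max_allele)
        dam_ok = (
            _transmissible(cand[child.dam_id], max_allele)
            if child.dam_id is not None and child.dam_id in pedigree
            else unconstrained
        )
        sire_ok = (
            _transmissible(cand[child.sire_id], max_allele)
            if child.sire_id is not None and child.sire_id in pedigree
            else unconstrained
        )
        event = _repair_single_event(
            child, own, dam_ok, sire_ok, max_allele
        )
        events.append(event)
    return events


def _repair_single_event(
    child: Individual,
    own_pairs: set[tuple[int, int]],
    dam_ok: set[int],
    sire_ok: set[int],
    max_allele: int,
) -> MutationEvent:
    """Smallest single-allele repair of one trio inconsistency."""
    # delta is the absolute copy change of the mutated gamete; contraction is
    # preferred at ties.  The mutated allele may exceed max_allele's reach by
    # at most the search bound.
    for delta in range(1, max_allele + 2):
        for direction in ("contraction", "expansion"):
            found: list[tuple[str, int, int]] = []  # (parent_side, from, to)
            for m, p in own_pairs:
                for side, transmitted, other_ok, other in (
                    ("dam", m, sire_ok, p),
                    ("sire", p, dam_ok, m),
                ):
                    if other not in other_ok:
                        continue
                    source = (
                        transmitted + delta
                        if direction == "contraction"
                        else transmitted - delta
                    )
                    if source < 1:
                        continue
                    parent_alleles = dam_ok if side == "dam" else sire_ok
                    if source in parent_alleles:
                        found.append((side, source, transmitted))
            if found:
                sides = {f[0] for f in found}
                if len(sides) == 1:
                    side, source, transmitted = found[0]
                    parent_id = child.dam_id if side == "dam" else child.sire_id
                else:
                    parent_id = None
                    source, transmitted = found[0][1], found[0][2]
                return MutationEvent(
                    child_id=child.id,
                    parent_id=parent_id,
                    expected_copies=source,
                    transmitted_copies=transmitted,
                )
    return MutationEvent(
        child_id=child.id,
        parent_id=None,
        expected_copies=0,
        transmitted_copies=0,
        complex=True,
    )
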