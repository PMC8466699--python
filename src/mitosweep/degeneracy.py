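"""Degenerate-site classification and synonymous divergence counting.

Substitutions at third codon positions of fourfold-degenerate codons (all
four bases give the same amino acid) and of twofold-degenerate codons
(pyrimidine pair vs purine pair give two amino acids) are treated as
selectively neutral.  This module classifies such sites between an ingroup
and an outgroup sequence, counts synonymous differences at them, and
counts segregating neutral sites within a sample — the raw ingredients of
the mutation-rate calibration and of the sweep-age estimator.

A third position enters the shared mask only when the codon context (the
first two positions) is identical, unambiguous and gap-free in both
sequences and the degeneracy class agrees; this symmetric rule keeps the
fourfold/twofold site totals well-defined for the pair.  An asymmetric
mode that classifies on one reference sequence alone is available behind
``mode="reference"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from Bio.Data import CodonTable

from .data_model import UNAMBIGUOUS, LocusAlignment

__all__ = [
    "FOURFOLD",
    "TWOFOLD",
    "OTHER",
    "DegeneracyMask",
    "DivergenceCounts",
    "classify_codon_degeneracy",
    "shared_degenerate_sites",
    "count_synonymous_differences",
    "count_segregating_neutral_sites",
]

FOURFOLD = "fourfold"
TWOFOLD = "twofold"
OTHER = "other"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class DegeneracyMask:
    """Degenerate third-position sites for one locus (0-based columns)."""

    locus: str
    fourfold_sites: list[int]
    twofold_sites: list[int]
    excluded_sites: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.fourfold_sites) & set(self.twofold_sites)
        if overlap:
            raise ValueError(f"sites classified both fourfold and twofold: {sorted(overlap)}")

    @property
    def l(self) -> int:  # noqa: E743 - matches the estimator's operand name
        """Number of fourfold-degenerate sites."""
        return len(self.fourfold_sites)

    @property
    def m(self) -> int:
        """Number of twofold-degenerate sites."""
        return len(self.twofold_sites)


@dataclass
class DivergenceCounts:
    """Synonymous differences between two aligned sequences at masked sites.

    ``flagged_twofold`` lists twofold sites whose difference crosses the
    purine/pyrimidine partition; those changes are nonsynonymous and are
    excluded from ``d2``.
    """

    d4: int
    l: int  # noqa: E741
    d2: int
    m: int
    flagged_twofold: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.d4 <= self.l and 0 <= self.d2 <= self.m):
            raise ValueError(f"inconsistent divergence counts: {self}")


@lru_cache(maxsize=None)
def _forward_table(code_table: int):
    table = CodonTable.unambiguous_dna_by_id[code_table]
    return table.forward_table, frozenset(table.stop_codons)


def classify_codon_degeneracy(codon_prefix: str, code_table: int = 5) -> str:
    """Degeneracy class of the third position given the first two bases.

    Returns ``"fourfold"`` when all four third-position bases encode one
    amino acid, ``"twofold"`` when they encode exactly two amino acids
    split as pyrimidine pair vs purine pair, and ``"other"`` for
    everything else (threefold patterns, 2+1 splits, stop-containing
    boxes, or an ambiguous/gapped prefix).
    """
    prefix = codon_prefix.upper()
    if len(prefix) != 2:
        raise ValueError(f"codon prefix must be 2 bases, got {codon_prefix!r}")
    if not set(prefix) <= UNAMBIGUOUS:
        return OTHER
    forward, stops = _forward_table(code_table)
    by_base: dict[str, str] = {}
    for base in "ACGT":
        codon = prefix + base
        if codon in stops:
            return OTHER
        by_base[base] = forward[codon]
    aas = set(by_base.values())
    if len(aas) == 1:
        return FOURFOLD
    if len(aas) == 2:
        groups = {aa: {b for b, a in by_base.items() if a == aa} for aa in aas}
        if set(map(frozenset, groups.values())) == {frozenset(PURINES), frozenset(PYRIMIDINES)}:
            return TWOFOLD
    return OTHER


def shared_degenerate_sites(
    seqA: str,
    seqB: str,
    frame_offset: int = 0,
    code_table: int = 5,
    locus: str = "locus",
    mode: str = "shared",
) -> DegeneracyMask:
    """Third positions whose degeneracy class is defined for the aligned pair.

    A site is retained iff, in both sequences, the codon is gap-free, the
    first two positions are unambiguous and identical between the
    sequences, and the class (fourfold or twofold) is the same.  With
    ``mode="reference"`` only ``seqA`` determines the class (the codon
    must still be gap/ambiguity-free in both).
    """
    if len(seqA) != len(seqB):
        raise ValueError(f"sequences not aligned: lengths {len(seqA)}, {len(seqB)}")
    if mode not in ("shared", "reference"):
        raise ValueError(f"unknown mode {mode!r}")
    seqA, seqB = seqA.upper(), seqB.upper()
    length = len(seqA)
    four: list[int] = []
    two: list[int] = []
    excluded: list[tuple[int, str]] = []
    n_codons = 0
    for start in range(frame_offset, length - 2, 3):
        n_codons += 1
        third = start + 2
        codA = seqA[start : start + 3]
        codB = seqB[start : start + 3]
        if "-" in codA or "-" in codB:
            excluded.append((third, "gap"))
            continue
        if not (set(codA) <= UNAMBIGUOUS and set(codB) <= UNAMBIGUOUS):
            excluded.append((third, "ambiguous_context"))
            continue
        if codA[:2] != codB[:2]:
            excluded.append((third, "context_mismatch"))
            continue
        cls = classify_codon_degeneracy(codA[:2], code_table)
        if mode == "shared":
            # identical prefixes imply identical classes; kept explicit so the
            # rule survives a future relaxation of the context check
            clsB = classify_codon_degeneracy(codB[:2], code_table)
            if cls != clsB:
                excluded.append((third, "class_mismatch"))
                continue
        if cls == FOURFOLD:
            four.append(third)
        elif cls == TWOFOLD:
            two.append(third)
        else:
            excluded.append((third, "not_degenerate"))
    if n_codons == 0:
        raise ValueError("frame yields zero complete codons")
    return DegeneracyMask(locus, four, two, excluded)


def count_synonymous_differences(
    seqA: str, seqB: str, mask: DegeneracyMask
) -> DivergenceCounts:
    """Count differing bases at the mask's fourfold and twofold sites.

    At twofold sites only within-partition differences (transitions) are
    synonymous; a purine-vs-pyrimidine difference is flagged and excluded
    from ``d2``.
    """
    seqA, seqB = seqA.upper(), seqB.upper()
    d4 = sum(1 for j in mask.fourfold_sites if seqA[j] != seqB[j])
    d2 = 0
    flagged: list[int] = []
    for j in mask.twofold_sites:
        a, b = seqA[j], seqB[j]
        if a == b:
            continue
        same_partition = ({a, b} <= PURINES) or ({a, b} <= PYRIMIDINES)
        if same_partition:
            d2 += 1
        else:
            flagged.append(j)
    return DivergenceCounts(d4=d4, l=mask.l, d2=d2, m=mask.m, flagged_twofold=flagged)


def count_segregating_neutral_sites(
    alignments: Sequence[LocusAlignment] | LocusAlignment,
    masks: Sequence[DegeneracyMask] | DegeneracyMask | None = None,
    all_sites: bool = False,
) -> int:
    """Number of segregating sites among a set of sequences.

    By default only the masked degenerate sites are scanned ("neutral
    polymorphisms"); with ``all_sites=True`` every alignment column is
    scanned instead, for comparison.  A site segregates when at least two
    distinct unambiguous bases occur among the non-missing states.
    Totals are summed over loci.
    """
    if isinstance(alignments, LocusAlignment):
        alignments = [alignments]
    if isinstance(masks, DegeneracyMask):
        masks = [masks]
    if not alignments or not alignments[0].rows:
        raise ValueError("empty subset")
    if not all_sites and masks is None:
        raise ValueError("masks required unless all_sites=True")

    total = 0
    for i, aln in enumerate(alignments):
        seqs = [seq for _, seq in aln.rows]
        if all_sites:
            columns = range(aln.length)
        else:
            mask = masks[i]
            columns = mask.fourfold_sites + mask.twofold_sites
        for j in columns:
            states = {s[j] for s in seqs} & UNAMBIGUOUS
            if len(states) >= 2:
                total += 1
    return total
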