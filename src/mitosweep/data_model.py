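"""Core data types and I/O: sample metadata, locus alignments, haplotype tables.

The pipeline's unit of sequence data is a :class:`LocusAlignment` — one
aligned coding region (e.g. a mitochondrial gene fragment) with a reading
frame and a genetic-code table id.  Specimens are described by
:class:`SampleRecord` rows read from a plain TSV.  Haplotype analysis
collapses identical sequences (after a column-filtering policy) into a
:class:`HaplotypeTable`.

Coordinates are 0-based half-open internally; user-facing reports are
1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SampleRecord",
    "LocusAlignment",
    "HaplotypeTable",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "retained_columns",
    "collapse_haplotypes",
    "observed_haplotype_diversity",
]

#: Characters treated as unambiguous nucleotides everywhere.
UNAMBIGUOUS = frozenset("ACGT")

#: Full accepted sequence alphabet (IUPAC ambiguity codes, gap, N).
ALPHABET = frozenset("ACGTUNRYSWKMBDHV-")

SEXES = ("F", "M", "unknown")
MORPHS = ("A", "I", "O", "unknown")

UNINFECTED = "uninfected"


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one specimen.

    ``infection`` is a strain label (e.g. ``"wEle1"``), ``"uninfected"``
    or ``"unknown"``.  ``morph`` encodes the heritable female colour
    polymorphism (A androchrome, I infuscans, O obsoleta); males carry
    ``"unknown"``.
    """

    sample_id: str
    species: str = "unknown"
    population: str = "unknown"
    country: str = "unknown"
    sex: str = "unknown"
    morph: str = "unknown"
    infection: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(
                f"sample {self.sample_id!r}: sex {self.sex!r} not in {SEXES}"
            )
        if self.morph not in MORPHS:
            raise ValueError(
                f"sample {self.sample_id!r}: morph {self.morph!r} "
                f"not one of the allowed codes {MORPHS}"
            )
        if self.morph != "unknown" and self.sex != "F":
            warnings.warn(
                f"sample {self.sample_id!r}: colour morph {self.morph!r} "
                f"recorded for sex {self.sex!r}; morphs are female-limited",
                stacklevel=2,
            )

    @property
    def infected(self) -> bool | None:
        """True/False when the status is known, None for ``"unknown"``."""
        if self.infection == "unknown":
            return None
        return self.infection != UNINFECTED


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus.

    ``frame_offset`` is the 0-based column of the first complete codon's
    first position; ``code_table`` is an NCBI genetic-code id (5 =
    invertebrate mitochondrial, 1 = standard).
    """

    locus: str
    rows: list[tuple[str, str]]
    frame_offset: int = 0
    code_table: int = 5

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"locus {self.locus!r}: empty alignment")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(
                f"locus {self.locus!r}: ragged alignment, row lengths {sorted(lengths)}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        if self.frame_offset >= self.length:
            raise ValueError("frame_offset beyond alignment length")
        if self.length - self.frame_offset < 3:
            raise ValueError(
                f"locus {self.locus!r}: no complete codon after frame offset"
            )
        ids = [sid for sid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s): {', '.join(dup)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def sequence(self, sample_id: str) -> str:
        for sid, seq in self.rows:
            if sid == sample_id:
                return seq
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        wanted = set(sample_ids)
        rows = [(sid, seq) for sid, seq in self.rows if sid in wanted]
        if not rows:
            raise ValueError(f"locus {self.locus!r}: subset selects no rows")
        return LocusAlignment(self.locus, rows, self.frame_offset, self.code_table)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into ordered ``(id, SEQUENCE)`` pairs.

    Sequences are uppercased.  Duplicate ids and ragged alignments are
    rejected with informative errors.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(
                f"{path}: sequence {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        rows.append((rec.id, seq))
    if not rows:
        raise ValueError(f"{path}: no FASTA records found")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    return rows


def write_fasta(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (inverse of :func:`read_fasta`)."""
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in rows]
    SeqIO.write(records, str(path), "fasta")


_REQUIRED_COLUMNS = ("sample_id", "infection")
_OPTIONAL_COLUMNS = ("species", "population", "country", "sex", "morph")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the specimen metadata TSV.

    Requires ``sample_id`` and ``infection`` columns; the optional columns
    (species, population, country, sex, morph) default to ``"unknown"``
    when absent or empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _REQUIRED_COLUMNS}
        for c in _OPTIONAL_COLUMNS:
            if c in df.columns and row[c] != "":
                kwargs[c] = row[c]
        records.append(SampleRecord(**kwargs))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sample_id(s) {dup}")
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write SampleRecords as the TSV :func:`read_metadata` consumes."""
    cols = ["sample_id", "species", "population", "country", "sex", "morph", "infection"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df.to_csv(path, sep="\t", index=False)


def retained_columns(
    sequences: Sequence[str], column_policy: str = "complete_deletion"
) -> list[int]:
    """Column indices kept under the given missing-data policy.

    ``complete_deletion`` drops every column in which any sequence carries
    a gap, N or IUPAC ambiguity code; ``pairwise`` keeps all columns
    (per-pair filtering is then the caller's concern).
    """
    if column_policy not in ("complete_deletion", "pairwise"):
        raise ValueError(f"unknown column_policy {column_policy!r}")
    if not sequences:
        return []
    length = len(sequences[0])
    if column_policy == "pairwise":
        return list(range(length))
    return [
        j
        for j in range(length)
        if all(seq[j] in UNAMBIGUOUS for seq in sequences)
    ]


@dataclass
class HaplotypeTable:
    """Haplotypes collapsed from an alignment.

    ``haplotypes`` maps id ("H1", "H2", ...) to the canonical sequence over
    the retained columns; ``assignment`` maps each sample to its haplotype.
    Ids are assigned by descending count, ties broken by first occurrence.
    """

    haplotypes: dict[str, str]
    assignment: dict[str, str]
    retained: list[int] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {h: 0 for h in self.haplotypes}
        for hap in self.assignment.values():
            out[hap] += 1
        return out

    def counts_by(self, group_of: Mapping[str, str]) -> dict[tuple[str, str], int]:
        """Counts keyed by ``(haplotype_id, group)`` for annotated networks."""
        out: dict[tuple[str, str], int] = {}
        for sid, hap in self.assignment.items():
            key = (hap, group_of.get(sid, "unknown"))
            out[key] = out.get(key, 0) + 1
        return out

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def frequencies(self) -> list[float]:
        n = self.n_samples
        return [c / n for c in self.counts.values()]


def collapse_haplotypes(
    alignment: LocusAlignment | Sequence[tuple[str, str]],
    column_policy: str = "complete_deletion",
) -> HaplotypeTable:
    """Collapse identical sequences (over retained columns) into haplotypes.

    Two samples share a haplotype iff their sequences are identical after
    applying the column policy.  Haplotype ids H1, H2, ... are assigned in
    descending count order, ties broken by order of first occurrence, so
    the labelling is deterministic and row-order changes only permute
    labels among equal-count haplotypes.
    """
    rows = alignment.rows if isinstance(alignment, LocusAlignment) else list(alignment)
    if not rows:
        raise ValueError("cannot collapse an empty alignment")
    keep = retained_columns([seq for _, seq in rows], column_policy)
    reduced = [(sid, "".join(seq[j] for j in keep)) for sid, seq in rows]

    first_seen: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for order, (sid, seq) in enumerate(reduced):
        if seq not in first_seen:
            first_seen[seq] = order
            members[seq] = []
        members[seq].append(sid)

    ordered = sorted(members, key=lambda s: (-len(members[s]), first_seen[s]))
    haplotypes = {f"H{i + 1}": seq for i, seq in enumerate(ordered)}
    hap_of_seq = {seq: hid for hid, seq in haplotypes.items()}
    assignment = {
        sid: hap_of_seq[seq] for seq, sids in members.items() for sid in sids
    }
    return HaplotypeTable(haplotypes=haplotypes, assignment=assignment, retained=keep)


def observed_haplotype_diversity(
    table: HaplotypeTable, group: Iterable[str] | None = None
) -> float:
    """Observed haplotype diversity Ho = N_H / N_t.

    ``group`` optionally restricts to a set of sample ids (e.g. one
    population); N_H then counts the distinct haplotypes carried by that
    group.  Ho * N_t is always the integer number of distinct haplotypes.
    """
    if group is None:
        assigned = table.assignment
    else:
        wanted = set(group)
        assigned = {s: h for s, h in table.assignment.items() if s in wanted}
    n_t = len(assigned)
    if n_t == 0:
        raise ValueError("observed_haplotype_diversity: empty group")
    n_h = len(set(assigned.values()))
    return n_h / n_t
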