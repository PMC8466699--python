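"""Per-group diversity and neutrality statistics.

Implements the frequency-spectrum summaries used to contrast infected and
uninfected mitochondrial (or nuclear) samples: nucleotide diversity pi,
haplotype diversity Hd, Tajima's D, and Fu & Li's D/F (outgroup form) and
D*/F* (folded form), the latter with the Simonsen, Churchill & Aquadro
(1995) corrected variance coefficients.

All statistics operate on the columns retained after complete deletion of
gapped/ambiguous sites (configurable), matching the common default of
desktop polymorphism software.  S counts segregating sites, eta counts
mutations (a k-allele site carries k-1 mutations), eta_s counts folded
singletons and eta_e outgroup-polarised external (derived-singleton)
mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .data_model import (
    UNAMBIGUOUS,
    LocusAlignment,
    SampleRecord,
    collapse_haplotypes,
    retained_columns,
)

__all__ = [
    "PolymorphismSummary",
    "NotComputable",
    "summarize_polymorphism",
    "nucleotide_diversity",
    "haplotype_diversity",
    "tajimas_D",
    "fu_li_tests",
    "compare_groups",
]


class NotComputable(ValueError):
    """A statistic's preconditions are not met (e.g. S=0 or n too small)."""


@dataclass
class PolymorphismSummary:
    """Site-frequency summaries of one group of aligned sequences.

    ``k_bar`` is the mean pairwise difference count (not per site);
    ``eta_e`` is None when no outgroup was supplied.
    """

    n: int
    L: int
    S: int
    eta: int
    eta_s: int
    k_bar: float
    eta_e: int | None = None

    def __post_init__(self) -> None:
        if self.S > self.eta or self.eta_s > self.eta or self.k_bar < 0:
            raise ValueError(f"inconsistent polymorphism summary: {self}")


def _sequences(rows: Sequence[tuple[str, str]] | LocusAlignment) -> list[str]:
    if isinstance(rows, LocusAlignment):
        return [seq for _, seq in rows.rows]
    return [seq for _, seq in rows]


def summarize_polymorphism(
    rows: Sequence[tuple[str, str]] | LocusAlignment,
    outgroup: str | None = None,
    column_policy: str = "complete_deletion",
) -> PolymorphismSummary:
    """Scan an alignment into the counts the neutrality tests consume.

    When an ``outgroup`` sequence is given it participates in column
    filtering and polarises mutations: a mutation is *external* (counted
    in ``eta_e``) when the derived state — any state differing from the
    outgroup's — occurs in exactly one sequence.
    """
    seqs = _sequences(rows)
    n = len(seqs)
    if n < 2:
        raise NotComputable(f"need at least 2 sequences, got {n}")
    pool = seqs + [outgroup.upper()] if outgroup is not None else seqs
    if outgroup is not None and len(outgroup) != len(seqs[0]):
        raise ValueError("outgroup length does not match alignment")
    keep = retained_columns(pool, column_policy)
    if column_policy == "pairwise":
        # statistics here are column-wise; restrict to fully resolved columns
        keep = retained_columns(pool, "complete_deletion")
    L = len(keep)

    S = eta = eta_s = 0
    eta_e = 0 if outgroup is not None else None
    total_pair_diffs = 0
    for j in keep:
        states: dict[str, int] = {}
        for s in seqs:
            states[s[j]] = states.get(s[j], 0) + 1
        k = len(states)
        if k < 2:
            continue
        S += 1
        eta += k - 1
        # a k-allele site carries k-1 mutations, so at most k-1 of its
        # states can be singleton mutations (relevant at n=2 and for
        # fully distinct columns)
        eta_s += min(sum(1 for c in states.values() if c == 1), k - 1)
        if outgroup is not None:
            anc = outgroup.upper()[j]
            derived_singletons = sum(
                1 for b, c in states.items() if b != anc and c == 1
            )
            eta_e += min(derived_singletons, k - 1)
        # pairwise differences at this column: total pairs minus same-state pairs
        same = sum(c * (c - 1) // 2 for c in states.values())
        total_pair_diffs += n * (n - 1) // 2 - same
    k_bar = total_pair_diffs / (n * (n - 1) / 2)
    return PolymorphismSummary(n=n, L=L, S=S, eta=eta, eta_s=eta_s, k_bar=k_bar, eta_e=eta_e)


def nucleotide_diversity(
    rows: Sequence[tuple[str, str]] | LocusAlignment,
    column_policy: str = "complete_deletion",
) -> float:
    """Nucleotide diversity pi: mean pairwise differences per retained site.

    Under ``pairwise`` column policy each pair is compared over the
    columns resolved in that pair, and pi is the mean of per-pair
    per-site differences.
    """
    seqs = _sequences(rows)
    n = len(seqs)
    if n < 2:
        raise NotComputable(f"nucleotide diversity needs n >= 2, got {n}")
    if column_policy == "pairwise":
        vals = []
        for a, b in combinations(seqs, 2):
            cols = [j for j in range(len(a)) if a[j] in UNAMBIGUOUS and b[j] in UNAMBIGUOUS]
            if not cols:
                raise NotComputable("a pair shares no resolved columns")
            vals.append(sum(a[j] != b[j] for j in cols) / len(cols))
        return sum(vals) / len(vals)
    summary = summarize_polymorphism(rows, column_policy=column_policy)
    if summary.L == 0:
        raise NotComputable("no columns retained after complete deletion")
    return summary.k_bar / summary.L


def haplotype_diversity(
    rows: Sequence[tuple[str, str]] | LocusAlignment,
    column_policy: str = "complete_deletion",
) -> float:
    """Haplotype (gene) diversity Hd = n/(n-1) * (1 - sum p_i^2).

    The unbiased probability that two randomly drawn sequences carry
    different haplotypes.
    """
    table = collapse_haplotypes(
        rows.rows if isinstance(rows, LocusAlignment) else rows, column_policy
    )
    n = table.n_samples
    if n < 2:
        raise NotComputable(f"haplotype diversity needs n >= 2, got {n}")
    return (n / (n - 1)) * (1.0 - sum(p * p for p in table.frequencies()))


def _harmonics(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    return a1, a2


def tajimas_D(summary: PolymorphismSummary) -> float:
    """Tajima's (1989) D from a polymorphism summary.

    Contrasts mean pairwise diversity with the segregating-site estimate
    of theta; negative values indicate an excess of rare variants, as
    expected after a sweep.
    """
    n, S = summary.n, summary.S
    if n < 4:
        raise NotComputable(f"Tajima's D needs n >= 4, got {n}")
    if S < 1:
        raise NotComputable("Tajima's D is undefined when S = 0")
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (summary.k_bar - S / a1) / math.sqrt(var)


def _fu_li_coefficients(n: int) -> dict[str, float]:
    """Variance coefficients for Fu & Li's tests.

    Follows Fu & Li (1993) with the corrections of Simonsen, Churchill &
    Aquadro (1995) for u_F / v_F and the starred statistics.
    """
    a1, a2 = _harmonics(n)
    an1 = a1 + 1.0 / n  # a_{n+1}
    if n > 2:
        cn = 2 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        cn = 1.0
    # D (outgroup)
    vD = 1 + (a1 * a1 / (a2 + a1 * a1)) * (cn - (n + 1) / (n - 1))
    uD = a1 - 1 - vD
    # F (outgroup)
    vF = (cn + 2 * (n * n + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (a1 * a1 + a2)
    uF = (
        1
        + (n + 1) / (3 * (n - 1))
        - 4 * ((n + 1) / ((n - 1) ** 2)) * (an1 - 2 * n / (n + 1))
    ) / a1 - vF
    # starred (no outgroup)
    if n > 2:
        dn = (
            cn
            + (n - 2) / ((n - 1) ** 2)
            + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
        )
    else:
        dn = 2.0
    vDs = (
        (n / (n - 1)) ** 2 * a2
        + a1 * a1 * dn
        - 2 * (n * a1 * (a1 + 1)) / ((n - 1) ** 2)
    ) / (a1 * a1 + a2)
    uDs = (n / (n - 1)) * (a1 - n / (n - 1)) - vDs
    vFs = (
        dn
        + 2 * (n * n + n + 3) / (9 * n * (n - 1))
        - (2 / (n - 1)) * (4 * a2 - 6 + 8.0 / n)
    ) / (a1 * a1 + a2)
    uFs = (
        n / (n - 1)
        + (n + 1) / (3 * (n - 1))
        - 4 / (n * (n - 1))
        + 2 * (n + 1) / ((n - 1) ** 2) * (an1 - 2 * n / (n + 1))
    ) / a1 - vFs
    return {"a1": a1, "uD": uD, "vD": vD, "uF": uF, "vF": vF,
            "uDs": uDs, "vDs": vDs, "uFs": uFs, "vFs": vFs}


def fu_li_tests(summary: PolymorphismSummary, with_outgroup: bool = False) -> dict[str, float]:
    """Fu & Li's D and F (``with_outgroup=True``) or D* and F*.

    The outgroup form contrasts total mutations eta with external-branch
    mutations eta_e; the starred form substitutes folded singletons
    eta_s.  Returns ``{"D": ..., "F": ...}`` or ``{"D*": ..., "F*": ...}``.
    """
    n = summary.n
    if n < 4:
        raise NotComputable(f"Fu & Li tests need n >= 4, got {n}")
    if summary.S < 1:
        raise NotComputable("Fu & Li tests are undefined when S = 0")
    c = _fu_li_coefficients(n)
    eta, k_bar = summary.eta, summary.k_bar
    if with_outgroup:
        if summary.eta_e is None:
            raise ValueError("outgroup mode requires eta_e (supply an outgroup)")
        eta_e = summary.eta_e
        D = (eta - c["a1"] * eta_e) / math.sqrt(c["uD"] * eta + c["vD"] * eta * eta)
        F = (k_bar - eta_e) / math.sqrt(c["uF"] * eta + c["vF"] * eta * eta)
        return {"D": D, "F": F}
    eta_s = summary.eta_s
    Ds = ((n / (n - 1)) * eta - c["a1"] * eta_s) / math.sqrt(
        c["uDs"] * eta + c["vDs"] * eta * eta
    )
    Fs = (k_bar - ((n - 1) / n) * eta_s) / math.sqrt(
        c["uFs"] * eta + c["vFs"] * eta * eta
    )
    return {"D*": Ds, "F*": Fs}


def _group_label(record: SampleRecord, grouping: str) -> str:
    if grouping == "infection":
        if record.infection == "unknown":
            return "unknown"
        return "uninfected" if record.infection == "uninfected" else "infected"
    if grouping == "strain":
        return record.infection
    if grouping == "population":
        return record.population
    raise ValueError(f"unknown grouping {grouping!r}")


def compare_groups(
    alignments: Sequence[LocusAlignment] | LocusAlignment,
    samples: Sequence[SampleRecord],
    grouping: str = "infection",
    outgroup: Mapping[str, str] | None = None,
    column_policy: str = "complete_deletion",
) -> pd.DataFrame:
    """Per-group diversity/neutrality table (one row per group).

    Loci are concatenated over the samples genotyped at every locus.
    Columns: n, N_H, Ho, Hd, S, pi, tajimas_D, fu_li_D_star, fu_li_F_star
    and, when ``outgroup`` (a locus -> sequence map) is supplied, fu_li_D
    and fu_li_F.  Cells whose preconditions fail hold NaN.
    """
    if isinstance(alignments, LocusAlignment):
        alignments = [alignments]
    common = set(alignments[0].sample_ids)
    for aln in alignments[1:]:
        common &= set(aln.sample_ids)
    order = [sid for sid in alignments[0].sample_ids if sid in common]
    concat = {
        sid: "".join(aln.sequence(sid) for aln in alignments) for sid in order
    }
    out_seq = None
    if outgroup is not None:
        out_seq = "".join(outgroup[aln.locus] for aln in alignments)

    by_group: dict[str, list[tuple[str, str]]] = {}
    label_of = {r.sample_id: _group_label(r, grouping) for r in samples}
    for sid in order:
        if sid in label_of:
            by_group.setdefault(label_of[sid], []).append((sid, concat[sid]))

    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        n = len(members)
        row: dict[str, object] = {"group": group, "n": n}
        try:
            table = collapse_haplotypes(members, column_policy)
            row["N_H"] = table.n_haplotypes
            row["Ho"] = table.n_haplotypes / n
        except ValueError:
            row["N_H"] = row["Ho"] = float("nan")
        stats = ["Hd", "S", "pi", "tajimas_D", "fu_li_D_star", "fu_li_F_star"]
        if outgroup is not None:
            stats += ["fu_li_D", "fu_li_F"]
        for key in stats:
            row[key] = float("nan")
        if n >= 2:
            try:
                row["Hd"] = haplotype_diversity(members, column_policy)
            except NotComputable:
                pass
            try:
                summary = summarize_polymorphism(members, outgroup=out_seq, column_policy=column_policy)
                row["S"] = summary.S
                row["pi"] = summary.k_bar / summary.L if summary.L else float("nan")
                try:
                    row["tajimas_D"] = tajimas_D(summary)
                except NotComputable:
                    pass
                try:
                    starred = fu_li_tests(summary, with_outgroup=False)
                    row["fu_li_D_star"] = starred["D*"]
                    row["fu_li_F_star"] = starred["F*"]
                except NotComputable:
                    pass
                if out_seq is not None:
                    try:
                        unfolded = fu_li_tests(summary, with_outgroup=True)
                        row["fu_li_D"] = unfolded["D"]
                        row["fu_li_F"] = unfolded["F"]
                    except NotComputable:
                        pass
            except NotComputable:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
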