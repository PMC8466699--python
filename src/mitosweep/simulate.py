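"""Synthetic datasets with the statistical structure of a symbiont sweep.

The generator emulates the study design the pipeline analyses: a
near-fixed infected clade descending from a single founding haplotype t
years ago (a star genealogy, each lineage accumulating Poisson-distributed
neutral mutations at degenerate third positions), an uninfected pool with
much higher haplotype diversity, an outgroup sequence diverged T years
ago for rate calibration, and categorical specimen metadata (sex, three
female colour morphs) with configurable infection probabilities.

Defaults mirror the study conditions the pipeline targets: four
mitochondrial protein-coding loci totalling ~790 codons under the
invertebrate mitochondrial code, 16 infected sequences genotyped at every
locus, minimum-divergence calibrated rates (2.71% and 1.61% per site per
My at fourfold/twofold sites), a sweep age of ~21 kyr giving E[S] = 4,
and a divergence time of 10.4 My to the outgroup.

Mutations are placed by independent per-site Poisson processes, so a site
may be hit repeatedly (no back-mutation bookkeeping) — exactly the
saturation the Jukes-Cantor correction compensates for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import LocusAlignment, SampleRecord, write_fasta, write_metadata
from .degeneracy import DegeneracyMask, shared_degenerate_sites
from .rates import NeutralRates

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_ancestor",
    "simulate_sweep",
    "simulate_outgroup_pair",
    "write_dataset",
]

PURINES = "AG"
PYRIMIDINES = "CT"

#: Default loci: four mitochondrial coding fragments, ~2373 bp in total.
DEFAULT_LOCI = (
    ("COI", 199, 5),
    ("COIb", 200, 5),
    ("COIIa", 197, 5),
    ("NDI", 195, 5),
)

#: Default neutral rates: the minimum-divergence calibration, percent per
#: site per My at fourfold / twofold sites.
DEFAULT_RATES = NeutralRates.from_per_My_percent(2.71, 1.61)


@dataclass(frozen=True)
class LocusSpec:
    name: str
    codons: int
    code_table: int = 5

    def __post_init__(self) -> None:
        if self.codons < 1:
            raise ValueError("codons must be >= 1")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``uninfected_theta`` is the expected pairwise difference count within
    the uninfected pool; ``infection_prob_by`` optionally maps
    ``(sex, morph)`` cells to infection probabilities (default: one
    probability for everyone, near-fixation as in a swept population).
    """

    seed: int = 0
    sweep_age_years: float = 20_860.0
    n_infected: int = 16
    n_uninfected: int = 20
    loci: tuple[LocusSpec, ...] = tuple(LocusSpec(*spec) for spec in DEFAULT_LOCI)
    rates: NeutralRates = field(default_factory=lambda: DEFAULT_RATES)
    uninfected_theta: float = 5.0
    outgroup_divergence_years: float = 10.4e6
    infection_prob: float = 0.977
    infection_prob_by: Mapping[tuple[str, str], float] | None = None
    morph_freqs: tuple[float, float, float] = (0.45, 0.3, 0.25)
    female_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.sweep_age_years < 0 or self.uninfected_theta < 0:
            raise ValueError("ages and theta must be non-negative")
        if self.n_infected < 0 or self.n_uninfected < 0:
            raise ValueError("sample sizes must be non-negative")


@dataclass
class SimulatedDataset:
    """Alignments (ingroup + outgroup row), metadata, and true masks."""

    alignments: list[LocusAlignment]
    samples: list[SampleRecord]
    masks: list[DegeneracyMask]
    outgroup: dict[str, str]
    founder: dict[str, str]


def _stop_free_codons(rng: np.random.Generator, n: int, code_table: int) -> str:
    from Bio.Data import CodonTable

    stops = set(CodonTable.unambiguous_dna_by_id[code_table].stop_codons)
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        draw = bases[rng.integers(0, 4, size=(n - len(out), 3))]
        for row in draw:
            codon = "".join(row)
            if codon not in stops:
                out.append(codon)
    return "".join(out)


def simulate_ancestor(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[DegeneracyMask]]:
    """Random stop-free coding sequence per locus, plus its degeneracy mask.

    Masks come from the degeneracy module's self-comparison, so they are
    exactly what the pipeline would recompute on the output.
    """
    rng = np.random.default_rng(config.seed)
    ancestors: dict[str, str] = {}
    masks: list[DegeneracyMask] = []
    for spec in config.loci:
        seq = _stop_free_codons(rng, spec.codons, spec.code_table)
        ancestors[spec.name] = seq
        masks.append(
            shared_degenerate_sites(seq, seq, 0, spec.code_table, locus=spec.name)
        )
    return ancestors, masks


def _mutate(
    seq: str,
    mask: DegeneracyMask,
    years: float,
    rates: NeutralRates,
    rng: np.random.Generator,
) -> str:
    """Evolve one lineage: per-site Poisson hits at degenerate positions."""
    chars = list(seq)
    for sites, mu, states in (
        (mask.fourfold_sites, rates.mu4, None),
        (mask.twofold_sites, rates.mu2, "partition"),
    ):
        if not sites or mu * years == 0:
            continue
        hits = rng.poisson(mu * years, size=len(sites))
        for idx in np.nonzero(hits)[0]:
            site, h = sites[idx], hits[idx]
            for _ in range(h):
                cur = chars[site]
                if states is None:
                    choices = [b for b in "ACGT" if b != cur]
                    chars[site] = choices[rng.integers(0, 3)]
                else:
                    pair = PURINES if cur in PURINES else PYRIMIDINES
                    chars[site] = pair[0] if cur == pair[1] else pair[1]
    return "".join(chars)


def _draw_metadata(
    config: SimulationConfig, rng: np.random.Generator
) -> list[SampleRecord]:
    """Assign sex/morph cells and infection per the configured probabilities."""
    n = config.n_infected + config.n_uninfected
    statuses = ["wEle1"] * config.n_infected + ["uninfected"] * config.n_uninfected
    records = []
    for i, status in enumerate(statuses):
        sex = "F" if rng.random() < config.female_fraction else "M"
        morph = "unknown"
        if sex == "F":
            morph = "AIO"[rng.choice(3, p=np.asarray(config.morph_freqs))]
        records.append(
            SampleRecord(
                sample_id=f"s{i + 1:03d}",
                species="synthetic",
                population="SIM",
                country="synthetic",
                sex=sex,
                morph=morph,
                infection=status,
            )
        )
    return records


def simulate_sweep(config: SimulationConfig) -> SimulatedDataset:
    """One synthetic sweep dataset.

    Infected lineages are independent descendants of the founder
    haplotype over ``sweep_age_years`` (star genealogy); uninfected
    lineages descend from a diverged uninfected founder with per-lineage
    mutation counts calibrated so the expected pairwise difference equals
    ``uninfected_theta``.  The outgroup row evolves independently for
    ``outgroup_divergence_years`` on both branches.
    """
    rng = np.random.default_rng(config.seed)
    ancestors, masks = simulate_ancestor(config)
    rates = config.rates

    # founders: infected founder is the ancestor; the uninfected pool
    # descends from a moderately diverged copy so the clades are distinct
    uninfected_founder = {
        name: _mutate(seq, mask, 10 * config.sweep_age_years + 1e4, rates, rng)
        for (name, seq), mask in zip(ancestors.items(), masks)
    }

    samples = _draw_metadata(config, rng)
    # per-lineage expected mutation count in the uninfected pool: pairwise
    # expectation ~ 2 * lambda under independent accumulation
    total_rate = sum(
        rates.mu4 * mask.l + rates.mu2 * mask.m for mask in masks
    )
    lam_years = (
        (config.uninfected_theta / 2.0) / total_rate if total_rate > 0 else 0.0
    )

    alignments = []
    outgroup: dict[str, str] = {}
    for spec, mask in zip(config.loci, masks):
        anc = ancestors[spec.name]
        rows = []
        for rec in samples:
            if rec.infection == "uninfected":
                seq = _mutate(uninfected_founder[spec.name], mask, lam_years, rates, rng)
            else:
                seq = _mutate(anc, mask, config.sweep_age_years, rates, rng)
            rows.append((rec.sample_id, seq))
        alignments.append(LocusAlignment(spec.name, rows, 0, spec.code_table))
        # outgroup: two independent branches of length T from the ancestor;
        # the ingroup-side branch is already represented by the founder, so
        # evolve the outgroup for 2T to realise the full patristic distance
        outgroup[spec.name] = _mutate(
            anc, mask, 2.0 * config.outgroup_divergence_years, rates, rng
        )
    return SimulatedDataset(
        alignments=alignments,
        samples=samples,
        masks=masks,
        outgroup=outgroup,
        founder=ancestors,
    )


def simulate_outgroup_pair(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], list[DegeneracyMask]]:
    """Two sequences diverged ``outgroup_divergence_years`` ago per locus.

    Each copy of the ancestor evolves independently for T years at the
    configured degenerate-site rates; calibrating rates on the pair
    recovers the inputs within sampling error.
    """
    if config.outgroup_divergence_years <= 0:
        raise ValueError("outgroup divergence time must be positive")
    rng = np.random.default_rng(config.seed)
    ancestors, masks = simulate_ancestor(config)
    T = config.outgroup_divergence_years
    a_side: dict[str, str] = {}
    b_side: dict[str, str] = {}
    for (name, anc), mask in zip(ancestors.items(), masks):
        a_side[name] = _mutate(anc, mask, T, config.rates, rng)
        b_side[name] = _mutate(anc, mask, T, config.rates, rng)
    return a_side, b_side, masks


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as the FASTA + TSV files the pipeline consumes.

    The outgroup goes into ``<locus>.outgroup.fasta`` beside each
    ``<locus>.fasta``.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for aln in dataset.alignments:
        p = outdir / f"{aln.locus}.fasta"
        write_fasta(aln.rows, p)
        paths[aln.locus] = p
        po = outdir / f"{aln.locus}.outgroup.fasta"
        write_fasta([("outgroup", dataset.outgroup[aln.locus])], po)
        paths[f"{aln.locus}.outgroup"] = po
    meta = outdir / "metadata.tsv"
    write_metadata(dataset.samples, meta)
    paths["metadata"] = meta
    return paths
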