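"""End-to-end orchestration: degeneracy -> rates -> sweep dating ->
population statistics -> association tests -> haplotype network.

A :class:`RunConfig` (loadable from YAML) names the per-locus alignment
FASTAs, an outgroup FASTA per locus, the metadata TSV, and the analysis
parameters.  :func:`run_pipeline` executes the stages in order, writes
one TSV/JSON report per stage plus a combined summary carrying every
parameter and an MD5 checksum of every input, and fails fast with the
stage name on any error.  Given identical inputs and config the whole
bundle is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import association, network, popgen
from .data_model import (
    LocusAlignment,
    SampleRecord,
    collapse_haplotypes,
    read_fasta,
    read_metadata,
)
from .degeneracy import (
    DivergenceCounts,
    count_segregating_neutral_sites,
    count_synonymous_differences,
    shared_degenerate_sites,
)
from .rates import calibrate_rates
from .sweep import LocusSample, sweep_age_interval

logger = logging.getLogger("mitosweep")

__all__ = ["LocusConfig", "RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class LocusConfig:
    name: str
    fasta: str
    outgroup_fasta: str
    frame_offset: int = 0
    code_table: int = 5


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    loci: list[LocusConfig]
    metadata: str
    outdir: str
    t_low_years: float = 10.4e6
    t_high_years: float = 21.7e6
    column_policy: str = "complete_deletion"
    epsilon: int = 0
    rate_mode: str = "full_precision"
    s_mode: str = "neutral"  # or "all_sites"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        loci = [LocusConfig(**entry) for entry in raw.pop("loci")]
        return cls(loci=loci, **raw)

    def validate(self) -> None:
        for loc in self.loci:
            for p in (loc.fasta, loc.outgroup_fasta):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if not Path(self.metadata).exists():
            raise FileNotFoundError(self.metadata)
        if self.t_low_years <= 0 or self.t_low_years > self.t_high_years:
            raise ValueError("need 0 < t_low_years <= t_high_years")
        if self.s_mode not in ("neutral", "all_sites"):
            raise ValueError(f"unknown s_mode {self.s_mode!r}")


def _md5(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _infected_ids(samples: Sequence[SampleRecord]) -> list[str]:
    return [r.sample_id for r in samples if r.infected]


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns the combined summary dictionary (also written as
    ``summary.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        samples = read_metadata(config.metadata)
        alignments: list[LocusAlignment] = []
        outgroups: dict[str, str] = {}
        for loc in config.loci:
            rows = read_fasta(loc.fasta)
            alignments.append(
                LocusAlignment(loc.name, rows, loc.frame_offset, loc.code_table)
            )
            out_rows = read_fasta(loc.outgroup_fasta)
            outgroups[loc.name] = out_rows[0][1]
        infected = _infected_ids(samples)
        if not infected:
            raise ValueError("no infected samples in metadata; cannot date a sweep")

        stage = "degeneracy"
        masks = []
        counts_per_locus = []
        mask_rows = []
        for aln, loc in zip(alignments, config.loci):
            ref_id = next((sid for sid in aln.sample_ids if sid in set(infected)),
                          aln.sample_ids[0])
            ref_seq = aln.sequence(ref_id)
            mask = shared_degenerate_sites(
                ref_seq, outgroups[aln.locus], aln.frame_offset, aln.code_table,
                locus=aln.locus,
            )
            masks.append(mask)
            counts_per_locus.append(
                count_synonymous_differences(ref_seq, outgroups[aln.locus], mask)
            )
            for site in mask.fourfold_sites:
                mask_rows.append((aln.locus, site, "fourfold"))
            for site in mask.twofold_sites:
                mask_rows.append((aln.locus, site, "twofold"))
            for site, reason in mask.excluded_sites:
                mask_rows.append((aln.locus, site, f"excluded:{reason}"))
        pd.DataFrame(mask_rows, columns=["locus", "site0", "class"]).sort_values(
            ["locus", "site0"]
        ).to_csv(outdir / "degeneracy.tsv", sep="\t", index=False)

        stage = "rates"
        pooled = DivergenceCounts(
            d4=sum(c.d4 for c in counts_per_locus),
            l=sum(c.l for c in counts_per_locus),
            d2=sum(c.d2 for c in counts_per_locus),
            m=sum(c.m for c in counts_per_locus),
        )
        rates_report = {}
        for label, T in (("T_low", config.t_low_years), ("T_high", config.t_high_years)):
            r = calibrate_rates(pooled, T)
            mu4_pct, mu2_pct = r.per_My_percent()
            p4, p2 = r.rounded_as_printed().per_My_percent()
            rates_report[label] = {
                "T_years": T,
                "mu4_percent_per_My": mu4_pct,
                "mu2_percent_per_My": mu2_pct,
                "mu4_percent_per_My_as_printed": p4,
                "mu2_percent_per_My_as_printed": p2,
            }
        rates_report["counts"] = {
            "d4": pooled.d4, "l": pooled.l, "d2": pooled.d2, "m": pooled.m,
        }
        _write_json(rates_report, outdir / "rates.json")

        stage = "sweep_dating"
        infected_alns = [aln.subset([s for s in infected if s in aln.sample_ids])
                         for aln in alignments]
        S = count_segregating_neutral_sites(
            infected_alns, masks, all_sites=(config.s_mode == "all_sites")
        )
        loci_samples = [
            LocusSample(aln.locus, len(aln.rows), mask.l, mask.m)
            for aln, mask in zip(infected_alns, masks)
        ]
        t_min, t_max = sweep_age_interval(
            S, loci_samples, pooled, config.t_low_years, config.t_high_years,
            rate_mode=config.rate_mode,
        )
        sweep_report = {
            "S": S,
            "s_mode": config.s_mode,
            "rate_mode": config.rate_mode,
            "t_min_years": t_min.t_years,
            "t_max_years": t_max.t_years,
            "t_min_operands": t_min.operands,
            "t_max_operands": t_max.operands,
        }
        _write_json(sweep_report, outdir / "sweep.json")

        stage = "popgen_stats"
        stats = popgen.compare_groups(
            alignments, samples, grouping="infection", outgroup=outgroups,
            column_policy=config.column_policy,
        )
        stats.to_csv(outdir / "popstats.tsv", sep="\t", index=False, float_format="%.6g")

        stage = "association"
        assoc_report = {}
        sex_tab = _sex_table(samples)
        if sex_tab is not None:
            assoc_report["infection_by_sex"] = {
                "table": sex_tab.counts.tolist(),
                **association.select_test(sex_tab),
            }
        morph_tab = _morph_table(samples)
        if morph_tab is not None:
            assoc_report["infection_by_morph"] = {
                "table": morph_tab.counts.tolist(),
                **association.select_test(morph_tab),
            }
        _write_json(assoc_report, outdir / "association.json")

        stage = "network"
        common = set(alignments[0].sample_ids)
        for aln in alignments[1:]:
            common &= set(aln.sample_ids)
        order = [sid for sid in alignments[0].sample_ids if sid in common]
        concat_rows = [
            (sid, "".join(aln.sequence(sid) for aln in alignments)) for sid in order
        ]
        table = collapse_haplotypes(concat_rows, config.column_policy)
        group_of = {
            r.sample_id: ("infected" if r.infected else "uninfected")
            for r in samples if r.infected is not None
        }
        if table.n_haplotypes >= 2:
            net = network.from_haplotype_table(table, group_of, epsilon=config.epsilon)
            network.write_gml(net, outdir / "network.gml")
            network.write_nexus_network(net, outdir / "network.nex")
            net_summary = {
                "n_observed": len(net.observed_nodes),
                "n_median": len(net.median_nodes),
                "n_edges": net.graph.number_of_edges(),
                "total_cost": net.total_cost,
            }
        else:
            net_summary = {"n_observed": table.n_haplotypes, "n_median": 0,
                           "n_edges": 0, "total_cost": 0}
        _write_json(net_summary, outdir / "network.json")

        stage = "summary"
        checksums = {loc.fasta: _md5(loc.fasta) for loc in config.loci}
        checksums.update({loc.outgroup_fasta: _md5(loc.outgroup_fasta) for loc in config.loci})
        checksums[config.metadata] = _md5(config.metadata)
        summary = {
            "parameters": {
                "t_low_years": config.t_low_years,
                "t_high_years": config.t_high_years,
                "column_policy": config.column_policy,
                "epsilon": config.epsilon,
                "rate_mode": config.rate_mode,
                "s_mode": config.s_mode,
                "seed": config.seed,
            },
            "input_checksums": checksums,
            "rates": rates_report,
            "sweep": sweep_report,
            "association": assoc_report,
            "network": net_summary,
            "n_samples": len(samples),
            "n_infected": len(infected),
        }
        _write_json(summary, outdir / "summary.json")
        logger.info("pipeline complete: %s", outdir)
        return summary
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        raise PipelineError(stage, exc) from exc


def _sex_table(samples: Sequence[SampleRecord]):
    rows = {}
    for status in ("infected", "uninfected"):
        rows[status] = {"F": 0, "M": 0}
    for r in samples:
        if r.infected is None or r.sex == "unknown":
            continue
        rows["infected" if r.infected else "uninfected"][r.sex] += 1
    counts = [[rows[s]["F"], rows[s]["M"]] for s in ("infected", "uninfected")]
    if min(sum(row) for row in counts) == 0 or min(sum(col) for col in zip(*counts)) == 0:
        return None
    return association.ContingencyTable(
        counts, row_labels=["infected", "uninfected"], col_labels=["F", "M"]
    )


def _morph_table(samples: Sequence[SampleRecord]):
    rows = {s: {"A": 0, "I": 0, "O": 0} for s in ("infected", "uninfected")}
    for r in samples:
        if r.infected is None or r.sex != "F" or r.morph == "unknown":
            continue
        rows["infected" if r.infected else "uninfected"][r.morph] += 1
    counts = [[rows[s][m] for m in "AIO"] for s in ("infected", "uninfected")]
    if min(sum(row) for row in counts) == 0 or min(sum(col) for col in zip(*counts)) == 0:
        return None
    return association.ContingencyTable(
        counts, row_labels=["infected", "uninfected"], col_labels=["A", "I", "O"]
    )
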