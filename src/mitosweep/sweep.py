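"""Star-genealogy dating of a symbiont-driven mitochondrial sweep.

After a recent selective sweep every sampled infected lineage descends
independently from the sweeping founder haplotype, so neutral mutations
accumulate linearly in time on each of the n sampled branches.  The
expected number of neutral polymorphisms is then

    E[S] = t * (mu_a * sum_i n_i l_i  +  mu_b * sum_i n_i m_i)

over loci i with n_i sampled sequences, l_i fourfold and m_i twofold
degenerate sites, and per-year rates mu_a (fourfold) and mu_b (twofold).
Inverting gives the method-of-moments age estimator implemented here:

    t = S / (mu_a * sum n_i l_i + mu_b * sum n_i m_i)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .degeneracy import DivergenceCounts
from .rates import NeutralRates, calibrate_rates

__all__ = ["LocusSample", "SweepInput", "estimate_sweep_age", "sweep_age_interval"]


@dataclass(frozen=True)
class LocusSample:
    """Per-locus operands: sample size and degenerate-site totals."""

    locus: str
    n: int
    l: int  # noqa: E741 - fourfold sites, the estimator's own symbol
    m: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"locus {self.locus!r}: need at least one sequence")
        if self.l < 0 or self.m < 0:
            raise ValueError(f"locus {self.locus!r}: negative site counts")


@dataclass
class SweepInput:
    """Everything the age estimator consumes.

    ``rate_mode="full_precision"`` uses the calibrated rates as computed;
    ``"as_printed"`` first rounds the per-My percentage rates to two
    decimal places, reproducing arithmetic done from published rounded
    rates.
    """

    S: int
    loci: list[LocusSample]
    rates: NeutralRates
    rate_mode: str = "full_precision"

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("S must be non-negative")
        if not self.loci:
            raise ValueError("at least one locus required")
        if all(loc.l + loc.m == 0 for loc in self.loci):
            raise ValueError("no neutral mutational opportunity: all l_i + m_i are 0")
        if self.rate_mode not in ("full_precision", "as_printed"):
            raise ValueError(f"unknown rate_mode {self.rate_mode!r}")

    @property
    def nl_sum(self) -> int:
        return sum(loc.n * loc.l for loc in self.loci)

    @property
    def nm_sum(self) -> int:
        return sum(loc.n * loc.m for loc in self.loci)

    def effective_rates(self) -> NeutralRates:
        if self.rate_mode == "as_printed":
            return self.rates.rounded_as_printed()
        return self.rates


@dataclass
class SweepAge:
    """Age estimate with full provenance of the operands."""

    t_years: float
    operands: dict[str, Any] = field(default_factory=dict)

    def __float__(self) -> float:
        return self.t_years


def estimate_sweep_age(inp: SweepInput) -> SweepAge:
    """Point estimate of the sweep age in years (star-genealogy moments)."""
    rates = inp.effective_rates()
    denom = rates.mu4 * inp.nl_sum + rates.mu2 * inp.nm_sum
    if denom <= 0:
        raise ValueError("no neutral mutational opportunity: zero rate denominator")
    t = inp.S / denom
    mu4_pct, mu2_pct = rates.per_My_percent()
    return SweepAge(
        t_years=t,
        operands={
            "S": inp.S,
            "sum_n_l": inp.nl_sum,
            "sum_n_m": inp.nm_sum,
            "mu4_per_site_per_year": rates.mu4,
            "mu2_per_site_per_year": rates.mu2,
            "mu4_percent_per_My": mu4_pct,
            "mu2_percent_per_My": mu2_pct,
            "rate_mode": inp.rate_mode,
            "loci": [
                {"locus": loc.locus, "n": loc.n, "l": loc.l, "m": loc.m}
                for loc in inp.loci
            ],
        },
    )


def sweep_age_interval(
    S: int,
    loci: list[LocusSample],
    counts: DivergenceCounts,
    T_low: float,
    T_high: float,
    rate_mode: str = "full_precision",
) -> tuple[SweepAge, SweepAge]:
    """Sweep-age bounds from a divergence-time interval.

    Rates are calibrated at each end of ``(T_low, T_high)``; the smaller
    divergence time gives the faster rates and hence the younger bound,
    so the result is returned as ``(t_min, t_max)``.
    """
    if T_low > T_high:
        raise ValueError(f"T_low {T_low} exceeds T_high {T_high}")
    ages = []
    for T in (T_low, T_high):
        rates = calibrate_rates(counts, T)
        ages.append(
            estimate_sweep_age(SweepInput(S=S, loci=list(loci), rates=rates, rate_mode=rate_mode))
        )
    t_min, t_max = sorted(ages, key=lambda a: a.t_years)
    return t_min, t_max
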