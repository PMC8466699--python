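"""Jukes–Cantor corrections and neutral-rate calibration against an outgroup.

An observed proportion p of differing sites underestimates the number of
substitutions per site once multiple hits accumulate.  The Jukes–Cantor
correction inverts the expected saturation curve:

    4-state (fourfold sites):  d = -(3/4) ln(1 - (4/3) p),  p < 3/4
    2-state (twofold sites):   d = -(1/2) ln(1 - 2 p),      p < 1/2

Dividing the corrected per-site distance by twice the species divergence
time (substitutions accrue on both branches) yields a neutral mutation
rate per site per year for each degeneracy class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .degeneracy import DivergenceCounts

__all__ = ["NeutralRates", "SaturationError", "jc_corrected_distance", "calibrate_rates"]


class SaturationError(ValueError):
    """Observed difference proportion at or beyond the JC saturation bound."""


@dataclass(frozen=True)
class NeutralRates:
    """Neutral per-site per-year mutation rates for the two site classes.

    ``mu4``/``mu2`` apply at fourfold/twofold degenerate third positions.
    Rates are stored per year; per-million-year percentages are a
    reporting-layer rendering (see :meth:`per_My_percent`).
    """

    mu4: float
    mu2: float
    T: float | None = None
    source_counts: DivergenceCounts | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu4) and math.isfinite(self.mu2)):
            raise ValueError("rates must be finite")
        if self.mu4 < 0 or self.mu2 < 0:
            raise ValueError("rates must be non-negative")

    def per_My_percent(self) -> tuple[float, float]:
        """(mu4, mu2) as percent per site per million years."""
        return self.mu4 * 1e6 * 100, self.mu2 * 1e6 * 100

    @classmethod
    def from_per_My_percent(cls, mu4_pct: float, mu2_pct: float, T: float | None = None) -> "NeutralRates":
        """Build from percent-per-site-per-My figures (as printed in reports)."""
        return cls(mu4=mu4_pct / 1e8, mu2=mu2_pct / 1e8, T=T)

    def rounded_as_printed(self, decimals: int = 2) -> "NeutralRates":
        """Rates with the per-My percentages rounded to ``decimals`` places.

        Mirrors how calibrated rates are quoted in reports (e.g. 2.71%/My,
        0.77%/My); feeding these back into the sweep estimator reproduces
        published round-number arithmetic exactly.
        """
        p4, p2 = self.per_My_percent()
        return NeutralRates.from_per_My_percent(
            round(p4, decimals), round(p2, decimals), T=self.T
        )


def jc_corrected_distance(p: float, k: str) -> float:
    """Jukes–Cantor corrected substitutions per site from proportion ``p``.

    ``k`` selects the state space: ``"fourfold"`` (4-state) or
    ``"twofold"`` (2-state, the transition pair at a twofold site).
    """
    if k == "fourfold":
        bound, scale = 3.0 / 4.0, 3.0 / 4.0
    elif k == "twofold":
        bound, scale = 1.0 / 2.0, 1.0 / 2.0
    else:
        raise ValueError(f"k must be 'fourfold' or 'twofold', got {k!r}")
    if not 0 <= p:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= bound:
        raise SaturationError(
            f"proportion {p:.4f} at/above the {k} saturation bound {bound}"
        )
    return -scale * math.log(1.0 - p / scale)


def calibrate_rates(counts: DivergenceCounts, T_years: float) -> NeutralRates:
    """Neutral rates from ingroup/outgroup divergence counts and a split time.

    mu4 = JC4(d4/l) / (2T), mu2 = JC2(d2/m) / (2T): the per-site corrected
    distance divides over the two branches separating the species.
    Zero-site classes yield a zero rate.
    """
    if T_years <= 0:
        raise ValueError(f"divergence time must be positive, got {T_years}")
    d_four = jc_corrected_distance(counts.d4 / counts.l, "fourfold") if counts.l else 0.0
    d_two = jc_corrected_distance(counts.d2 / counts.m, "twofold") if counts.m else 0.0
    return NeutralRates(
        mu4=d_four / (2.0 * T_years),
        mu2=d_two / (2.0 * T_years),
        T=T_years,
        source_counts=counts,
    )
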