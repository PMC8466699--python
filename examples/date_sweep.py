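"""Date a symbiont-driven mitochondrial sweep from published-style inputs.

Inputs: synonymous divergence to an outgroup (97 of 245 fourfold sites,
81 of 332 twofold sites differ), a 10.4-21.7 My divergence-time interval,
S=4 neutral polymorphisms among infected lineages, 16 sequences per locus.
"""

from mitosweep import DivergenceCounts, LocusSample, calibrate_rates, sweep_age_interval

counts = DivergenceCounts(d4=97, l=245, d2=81, m=332)
loci = [LocusSample("pooled", n=16, l=245, m=332)]

for T in (10.4e6, 21.7e6):
    mu4, mu2 = calibrate_rates(counts, T).per_My_percent()
    print(f"T = {T / 1e6:.1f} My  ->  mu4 = {mu4:.2f}, mu2 = {mu2:.2f}  (%/site/My)")

t_min, t_max = sweep_age_interval(4, loci, counts, 10.4e6, 21.7e6, rate_mode="as_printed")
print(f"sweep age: {t_min.t_years:,.0f} - {t_max.t_years:,.0f} years before present")
print("(faster rates from the smaller divergence time give the younger bound)")
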