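# Methods

## The sweep-age estimator and its assumptions

A maternally inherited symbiont spreading through a host population fixes
the mitochondrial haplotype it happens to ride on. Immediately after the
sweep the infected clade is monomorphic; polymorphism then re-accumulates
by mutation. Under a **star genealogy** — every sampled infected lineage
descending independently from the founder, a good approximation when the
sweep was rapid and recent relative to coalescent timescales — neutral
mutations accumulate on each sampled branch at a constant rate, so the
number of observed neutral polymorphisms S is Poisson with mean

    E[S] = t · (μ_a Σᵢ nᵢ lᵢ + μ_b Σᵢ nᵢ mᵢ),

giving the moment estimator `t = S / (μ_a Σ nᵢlᵢ + μ_b Σ nᵢmᵢ)`
(`sweep.estimate_sweep_age`). The estimator is exactly linear in S and
inversely proportional to a uniform scaling of the sample sizes; loci
with equal nᵢ may be pooled without changing the estimate. It assumes
(i) complete linkage of the mitochondrion to the infection, (ii)
selective neutrality of the masked sites, (iii) negligible coalescence
within the infected clade since the sweep, and (iv) no recurrent
mutation at the same site within the sample (infinite-sites at the
within-clade timescale; multiple hits over the much longer outgroup
branch are handled separately, below). No sampling interval is attached
to a single estimate: the reported interval reflects only the
uncertainty in the outgroup divergence time.

## Neutral-site classification

Only third positions of **fourfold** boxes (all four bases synonymous,
e.g. CTx → Leu) and **twofold** boxes (the two pyrimidines give one
amino acid and the two purines another, e.g. AAx → Asn/Lys) are treated
as neutral. Boxes with 3+1 splits or containing stop codons are
excluded — their third-position changes are not uniformly synonymous.
Genetic codes are taken from the NCBI tables via Biopython; the default
is table 5 (invertebrate mitochondrial) for mtDNA and table 1 for
nuclear loci.

For an ingroup/outgroup pair a third position enters the shared mask only
when the codon is gap-free in both sequences and the first two positions
are unambiguous and **identical** between them. This symmetric rule makes
the site totals lᵢ, mᵢ well defined for the pair (each excluded codon is
reported with a reason code); an asymmetric mode classifying on the
ingroup alone is available via `mode="reference"`. At twofold sites a
purine↔pyrimidine difference is nonsynonymous: it is flagged in the
output but never counted in d2.

S is counted at the masked sites by default ("neutral polymorphisms");
an all-sites mode is reported alongside for comparison, since in a
clean dataset nonsynonymous polymorphism among recently swept lineages
is expected to be rare and the two counts coincide.

## Rate calibration

Observed difference proportions p at the two site classes are corrected
for multiple hits with the Jukes–Cantor transformations
d₄ = −(3/4)ln(1−(4/3)p) and d₂ = −(1/2)ln(1−2p); the 2-state form
applies at twofold sites because only the within-partition flip is
synonymous. Proportions at or beyond the saturation bounds (3/4, 1/2)
raise an explicit error. Rates are `μ = d / (2T)` — divergence accrues on
both branches since the species split at time T. Internally rates are
stored **per site per year** so the estimator works in years; percent
per million years is a reporting rendering.

Two rate modes exist. `full_precision` (default) propagates the
calibrated rates unrounded. `as_printed` first rounds the %/My figures
to two decimals — the precision at which such rates are conventionally
quoted — which is needed to reproduce round-number desk arithmetic
exactly: with the study-scale inputs the as-printed interval endpoints
are 20,859.93 and 43,543.39 years, versus 20,881.6 and 43,570.3 with
unrounded rates (a ~0.1% difference, documented rather than hidden).

## Diversity and neutrality statistics

All statistics use **complete deletion**: columns containing a gap, N or
IUPAC ambiguity anywhere in the group (and in the outgroup, when used)
are dropped first. This matches the common default of desktop
polymorphism software; a pairwise-deletion mode exists for π and for
haplotype collapsing. π = mean pairwise difference count / retained
sites; Hd = n/(n−1)·(1−Σpᵢ²); Ho = N_H/N_t (so Ho·N_t is always the
integer number of distinct haplotypes). Haplotype ids H1, H2, … are
assigned by descending count with ties broken by first occurrence, making
labels deterministic and order changes a pure relabelling.

Tajima's D uses the 1989 variance coefficients. Fu & Li's D/F (outgroup
form, using external mutations η_e) and D*/F* (folded form, using
singletons η_s) use the corrected variance coefficients of Simonsen,
Churchill & Aquadro (1995). Because the data can violate infinite sites,
a k-allele column is counted as k−1 mutations (η), and the number of
singleton mutations credited to a column is capped at k−1 — relevant
only for n=2 and fully distinct columns, where counting every
count-one state would double-count mutations. η_e counts derived
(≠ outgroup state) singleton alleles with the same cap. When an outgroup
is supplied both the outgroup and starred forms are reported. Statistics
whose preconditions fail (S=0, or n<4 where the variance coefficients
degenerate) are reported as "not computable", never as 0, and no
p-values are attached — significance should be read off published
critical-value tables or coalescent simulation, which is out of scope
here.

## Exact association tests

The r×c Fisher test enumerates every non-negative integer table with the
observed margins (last row and last cell of each row are forced, so only
free cells branch; a guard errors beyond 10⁷ candidates and suggests
chi-square). Point probabilities use log-factorials, stable to totals of
a few hundred. The two-sided p-value is the conventional sum of point
probabilities ≤ that of the observed table, with a 1e−7 relative
tolerance absorbing floating-point ties. For 2×2 tables the enumeration
agrees with the hypergeometric closed form to machine precision. The
chi-square test applies no continuity correction; `select_test` routes a
table to the exact test whenever any expected count is below five.

## Median-joining networks

Gapped/ambiguous columns are dropped before network construction and
edge weights are Hamming counts over the retained columns. The minimum
spanning network is built weight class by weight class (all edges of a
class joining components that were distinct before the class enter, so
ties are kept — the union of all minimum spanning trees); an integer
ε ≥ 0 admits links within ε of each merging threshold. Median joining
then iterates: for every mutually connected triplet, quasi-median
vectors are generated (per-column majority; columns with three distinct
states contribute all three, capped at 81 combinations per triplet);
candidates are added greedily while each strictly reduces the minimum
spanning cost of the node set; medians of degree ≤ 2 lying on no
weighted shortest path between observed nodes are deleted and never
re-proposed, which guarantees termination (cost is a non-increasing
integer). With ε=0 the final network contains a minimum spanning tree of
the observed haplotypes, every observed haplotype appears exactly once,
and output is deterministic for a fixed input order. Networks are
written as GML and as a PopART-style NEXUS Network block; per-group
counts are node annotations (rendering is out of scope).

## The synthetic-data generator

`simulate` emulates the study design end to end: a random stop-free
coding ancestor per locus; an infected clade of independent descendants
of that founder over the sweep age t, with per-site Poisson mutation at
the degenerate positions only (symmetric 4-state at fourfold sites,
partition flip at twofold); an uninfected pool drawn as independent
descendants of a diverged founder with per-lineage mutation calibrated so
the expected pairwise difference equals `uninfected_theta`; an outgroup
evolved for the full 2T patristic distance; and categorical metadata
(sex, three female-limited colour morphs, infection probabilities).
Defaults are the study conditions the estimator targets: four
mitochondrial loci of 199/200/197/195 codons (table 5), n_infected=16,
rates 2.71/1.61 %/site/My (the minimum-divergence calibration),
sweep age 20,860 y — which makes E[S] ≈ 4 — T = 10.4 My,
n_uninfected=20 and θ=5 (giving uninfected Hd near 1, comfortably above
the infected clade's). Everything derives from a single seed and is
byte-reproducible.

Deliberate simplifications: the uninfected pool is **not** a coalescent
sample — lineages are exchangeable independent draws, so its site
frequency spectrum is star-like (neutrality statistics computed on the
uninfected group in simulations are negative by construction and should
not be read as sweep evidence); there is no recombination, migration,
selection on the masked sites, or infection loss/transfer dynamics; and
back mutation is allowed silently (the JC correction is exactly what
compensates on the long outgroup branch). Passing tests therefore
validate the estimator and statistics under their own model assumptions,
not the realism of any particular empirical dataset.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and 1-based in user-facing
reports. Sequences are uppercased on input; duplicate ids and ragged
alignments are rejected with the offending ids/lengths named. Metadata
morphs are validated against {A, I, O}; a morph on a non-female record
warns but is kept. Pipeline stages are pure functions of their inputs;
the summary report carries every parameter and an MD5 checksum of every
input file, and re-running a config reproduces the bundle byte for byte.
Test problem sizes (e.g. 200 replicates for estimator recovery, 50
random datasets for oracle agreement, ~790-codon loci) were chosen as
the smallest scales at which the asserted statistical properties are
stable; they run in seconds on one CPU.

## Known limitations

- The estimator inherits all star-genealogy caveats: incomplete sweeps,
  ongoing transmission leakage, or appreciable post-sweep coalescence
  bias t̂ in ways the package does not model.
- No confidence interval is computed for t̂ beyond propagating the
  divergence-time interval.
- Fu & Li significance stars, coalescent p-values and sliding-window
  scans are out of scope.
- The exact-test enumerator is exponential in table size; it is meant
  for the sparse tables where the chi-square approximation fails.
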