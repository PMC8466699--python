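import math

import numpy as np
import pytest

from mitosweep import (
    NotComputable,
    compare_groups,
    fu_li_tests,
    haplotype_diversity,
    nucleotide_diversity,
    summarize_polymorphism,
    tajimas_D,
)
from mitosweep.popgen import PolymorphismSummary

from . import oracles


def _rows(seqs):
    return [(f"s{i}", s) for i, s in enumerate(seqs)]


def _random_datasets(n_sets=50, seed=123):
    """Random small alignments with at least one segregating site."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_sets:
        n = int(rng.integers(4, 9))
        L = int(rng.integers(5, 31))
        # few distinct lineages so sites are not all singletons
        base = rng.choice(list("ACGT"), size=(3, L))
        picks = rng.integers(0, 3, size=n)
        seqs = ["".join(base[p]) for p in picks]
        # sprinkle point mutations
        for _ in range(int(rng.integers(1, 6))):
            i = int(rng.integers(0, n))
            j = int(rng.integers(0, L))
            s = list(seqs[i])
            s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
            seqs[i] = "".join(s)
        if oracles.site_counts(seqs)[0] >= 1:
            outg = "".join(rng.choice(list("ACGT"), size=L))
            out.append((seqs, outg))
    return out


class TestNucleotideDiversity:
    def test_single_difference_over_100_sites(self):
        a = "A" * 100
        b = "A" * 99 + "T"
        assert nucleotide_diversity(_rows([a, b])) == pytest.approx(0.01)

    def test_monomorphic_is_zero(self):
        assert nucleotide_diversity(_rows(["ACGT"] * 5)) == 0.0

    def test_hand_enumerated_four_sequences(self):
        # pairwise diffs {0,1,2,1,2,1}: k_bar = 7/6 over L = 3
        pi = nucleotide_diversity(_rows(["AAA", "AAA", "AAT", "ATT"]))
        assert pi == pytest.approx(7 / 18)

    def test_single_sequence_rejected(self):
        with pytest.raises(NotComputable):
            nucleotide_diversity(_rows(["AAA"]))

    def test_pi_never_exceeds_S_over_L(self):
        for seqs, _ in _random_datasets(10, seed=9):
            pi = nucleotide_diversity(_rows(seqs))
            S = oracles.site_counts(seqs)[0]
            assert pi <= S / len(seqs[0]) + 1e-12


class TestHaplotypeDiversity:
    def test_two_distinct_sequences(self):
        assert haplotype_diversity(_rows(["AAA", "AAT"])) == pytest.approx(1.0)

    def test_monomorphic_is_zero(self):
        assert haplotype_diversity(_rows(["AAA"] * 6)) == 0.0

    def test_two_plus_two(self):
        hd = haplotype_diversity(_rows(["AAA", "AAA", "AAT", "AAT"]))
        assert hd == pytest.approx(4 / 3 * 0.5)

    def test_bounds(self):
        for seqs, _ in _random_datasets(10, seed=21):
            hd = haplotype_diversity(_rows(seqs))
            assert 0.0 <= hd <= 1.0 + 1e-12


class TestTajimasD:
    def test_numerator_zero_gives_zero(self):
        # construct a summary with k_bar = S/a1 exactly
        n, S = 4, 2
        a1 = 1 + 1 / 2 + 1 / 3
        summary = PolymorphismSummary(n=n, L=10, S=S, eta=2, eta_s=1, k_bar=S / a1)
        assert tajimas_D(summary) == pytest.approx(0.0, abs=1e-12)

    def test_matches_fraction_oracle_on_small_example(self):
        seqs = ["AAAA", "AAAA", "AAAT", "AATT"]
        d = tajimas_D(summarize_polymorphism(_rows(seqs)))
        assert d == pytest.approx(oracles.tajima_d(seqs), abs=1e-12)

    def test_excess_singletons_drive_D_negative(self):
        # every mutation private to one of many sequences
        n, L = 12, 40
        seqs = ["A" * L for _ in range(n)]
        for i in range(6):
            s = list(seqs[i])
            s[i] = "T"
            seqs[i] = "".join(s)
        assert tajimas_D(summarize_polymorphism(_rows(seqs))) < 0

    def test_sign_matches_numerator(self):
        for seqs, _ in _random_datasets(15, seed=77):
            summary = summarize_polymorphism(_rows(seqs))
            d = tajimas_D(summary)
            a1 = sum(1 / i for i in range(1, summary.n))
            assert math.copysign(1, d) == math.copysign(1, summary.k_bar - summary.S / a1)

    def test_undefined_cases(self):
        with pytest.raises(NotComputable):
            tajimas_D(PolymorphismSummary(n=10, L=5, S=0, eta=0, eta_s=0, k_bar=0.0))
        with pytest.raises(NotComputable):
            tajimas_D(PolymorphismSummary(n=3, L=5, S=1, eta=1, eta_s=1, k_bar=0.5))

    def test_agrees_with_tskit_on_coalescent_simulation(self):
        """Independent oracle: tskit's site-mode Tajima's D on msprime data."""
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(
            samples=10, ploidy=1, sequence_length=1000, random_seed=17
        )
        ts = msprime.sim_mutations(ts, rate=2e-3, random_seed=17, discrete_genome=False)
        assert ts.num_sites > 5
        seqs = ["".join(v) for v in zip(*[
            [var.alleles[g] for g in var.genotypes] for var in ts.variants()
        ])]
        d = tajimas_D(summarize_polymorphism(_rows(seqs)))
        assert d == pytest.approx(float(ts.Tajimas_D()), abs=1e-10)


class TestFuLi:
    def test_matches_fraction_oracle_on_toy_dataset(self):
        seqs = ["AAAAA", "AAAAT", "AATAT", "ATAAA", "AAAAA"]
        outg = "AAAAA"
        summary = summarize_polymorphism(_rows(seqs), outgroup=outg)
        got = fu_li_tests(summary, with_outgroup=True)
        exp_D, exp_F = oracles.fu_li_d_f(seqs, outg)
        assert got["D"] == pytest.approx(exp_D, abs=1e-12)
        assert got["F"] == pytest.approx(exp_F, abs=1e-12)
        starred = fu_li_tests(summary, with_outgroup=False)
        exp_Ds, exp_Fs = oracles.fu_li_d_f_star(seqs)
        assert starred["D*"] == pytest.approx(exp_Ds, abs=1e-12)
        assert starred["F*"] == pytest.approx(exp_Fs, abs=1e-12)

    def test_all_external_mutations_drive_D_negative(self):
        n, L = 10, 30
        seqs = ["A" * L for _ in range(n)]
        for i in range(5):
            s = list(seqs[i])
            s[2 * i] = "G"
            seqs[i] = "".join(s)
        summary = summarize_polymorphism(_rows(seqs), outgroup="A" * L)
        assert summary.eta_e == summary.eta == 5
        assert fu_li_tests(summary, with_outgroup=True)["D"] < 0

    def test_outgroup_mode_requires_outgroup(self):
        summary = summarize_polymorphism(_rows(["AAT", "AAA", "ATA", "AAA"]))
        with pytest.raises(ValueError, match="outgroup"):
            fu_li_tests(summary, with_outgroup=True)

    def test_undefined_when_no_polymorphism(self):
        summary = summarize_polymorphism(_rows(["AAA"] * 4))
        with pytest.raises(NotComputable):
            fu_li_tests(summary)


class TestOracleAgreementBattery:
    def test_50_random_datasets_agree_with_independent_oracles(self):
        """D, F, D*, F* and Tajima's D match Fraction-arithmetic oracles to 1e-10."""
        for seqs, outg in _random_datasets(50):
            rows = _rows(seqs)
            summary = summarize_polymorphism(rows, outgroup=outg)
            assert tajimas_D(summary) == pytest.approx(
                oracles.tajima_d(seqs), abs=1e-10
            )
            got = fu_li_tests(summary, with_outgroup=True)
            exp_D, exp_F = oracles.fu_li_d_f(seqs, outg)
            assert got["D"] == pytest.approx(exp_D, abs=1e-10)
            assert got["F"] == pytest.approx(exp_F, abs=1e-10)
            starred = fu_li_tests(summary, with_outgroup=False)
            exp_Ds, exp_Fs = oracles.fu_li_d_f_star(seqs)
            assert starred["D*"] == pytest.approx(exp_Ds, abs=1e-10)
            assert starred["F*"] == pytest.approx(exp_Fs, abs=1e-10)


class TestCompareGroups:
    def test_sweep_dataset_orders_group_diversity(self, sweep_dataset):
        table = compare_groups(
            sweep_dataset.alignments, sweep_dataset.samples,
            outgroup=sweep_dataset.outgroup,
        ).set_index("group")
        assert table.loc["infected", "Hd"] < table.loc["uninfected", "Hd"]
        assert table.loc["infected", "pi"] < table.loc["uninfected", "pi"]
        assert {"fu_li_D", "fu_li_F"} <= set(table.columns)

    def test_single_group_input(self, sweep_dataset):
        infected = [r for r in sweep_dataset.samples if r.infected]
        table = compare_groups(sweep_dataset.alignments, infected)
        assert list(table["group"]) == ["infected"]

    def test_tiny_group_cells_not_computable(self, sweep_dataset):
        keep = [r for r in sweep_dataset.samples if r.infected][:1] + [
            r for r in sweep_dataset.samples if not r.infected
        ]
        table = compare_groups(sweep_dataset.alignments, keep).set_index("group")
        assert math.isnan(table.loc["infected", "Hd"])
        assert table.loc["infected", "n"] == 1
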