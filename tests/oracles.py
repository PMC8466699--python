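"""Independent from-scratch oracles used only by the test suite.

These deliberately re-derive each statistic by direct transcription of
the published formulas using exact Fraction arithmetic (converting to
float only at the final square root), and by brute-force enumeration
where possible, so they share no code with the implementation under
test.
"""

from fractions import Fraction
from itertools import combinations
from math import sqrt


def pairwise_pi(seqs):
    """Mean pairwise difference count by explicit pair enumeration."""
    pairs = list(combinations(seqs, 2))
    total = sum(sum(a != b for a, b in zip(x, y)) for x, y in pairs)
    return Fraction(total, len(pairs))


def site_counts(seqs, outgroup=None):
    """(S, eta, eta_s, eta_e) by direct per-column counting."""
    n_sites = len(seqs[0])
    S = eta = eta_s = 0
    eta_e = 0 if outgroup is not None else None
    for j in range(n_sites):
        col = [s[j] for s in seqs]
        states = sorted(set(col))
        if len(states) < 2:
            continue
        S += 1
        k = len(states)
        eta += k - 1
        # cap singleton mutations at the k-1 mutations the site carries
        ones = [b for b in states if col.count(b) == 1]
        eta_s += min(len(ones), k - 1)
        if outgroup is not None:
            eta_e += min(sum(1 for b in ones if b != outgroup[j]), k - 1)
    return S, eta, eta_s, eta_e


def tajima_d(seqs):
    """Tajima (1989), exact coefficients via Fractions."""
    n = len(seqs)
    S, _, _, _ = site_counts(seqs)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    k_bar = pairwise_pi(seqs)
    num = k_bar - Fraction(S) / a1
    var = e1 * S + e2 * S * (S - 1)
    return float(num) / sqrt(float(var))


def _fu_li_common(n):
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    an1 = a1 + Fraction(1, n)
    cn = 2 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2)) if n > 2 else Fraction(1)
    return a1, a2, an1, cn


def fu_li_d_f(seqs, outgroup):
    """Fu & Li (1993) D and F with outgroup, Simonsen et al. (1995) u/v."""
    n = len(seqs)
    S, eta, eta_s, eta_e = site_counts(seqs, outgroup)
    a1, a2, an1, cn = _fu_li_common(n)
    vD = 1 + (a1**2 / (a2 + a1**2)) * (cn - Fraction(n + 1, n - 1))
    uD = a1 - 1 - vD
    vF = (cn + Fraction(2 * (n * n + n + 3), 9 * n * (n - 1)) - Fraction(2, n - 1)) / (
        a1**2 + a2
    )
    uF = (
        1
        + Fraction(n + 1, 3 * (n - 1))
        - 4 * Fraction(n + 1, (n - 1) ** 2) * (an1 - Fraction(2 * n, n + 1))
    ) / a1 - vF
    k_bar = pairwise_pi(seqs)
    D = float(eta - a1 * eta_e) / sqrt(float(uD * eta + vD * eta**2))
    F = float(k_bar - eta_e) / sqrt(float(uF * eta + vF * eta**2))
    return D, F


def fu_li_d_f_star(seqs):
    """Fu & Li (1993) D* and F*, Simonsen et al. (1995) coefficients."""
    n = len(seqs)
    S, eta, eta_s, _ = site_counts(seqs)
    a1, a2, an1, cn = _fu_li_common(n)
    dn = (
        cn
        + Fraction(n - 2, (n - 1) ** 2)
        + Fraction(2, n - 1) * (Fraction(3, 2) - (2 * an1 - 3) / (n - 2) - Fraction(1, n))
    )
    vDs = (
        Fraction(n, n - 1) ** 2 * a2
        + a1**2 * dn
        - 2 * (n * a1 * (a1 + 1)) / Fraction((n - 1) ** 2)
    ) / (a1**2 + a2)
    uDs = Fraction(n, n - 1) * (a1 - Fraction(n, n - 1)) - vDs
    vFs = (
        dn
        + Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
        - Fraction(2, n - 1) * (4 * a2 - 6 + Fraction(8, n))
    ) / (a1**2 + a2)
    uFs = (
        Fraction(n, n - 1)
        + Fraction(n + 1, 3 * (n - 1))
        - Fraction(4, n * (n - 1))
        + 2 * Fraction(n + 1, (n - 1) ** 2) * (an1 - Fraction(2 * n, n + 1))
    ) / a1 - vFs
    k_bar = pairwise_pi(seqs)
    Ds = float(Fraction(n, n - 1) * eta - a1 * eta_s) / sqrt(float(uDs * eta + vDs * eta**2))
    Fs = float(k_bar - Fraction(n - 1, n) * eta_s) / sqrt(float(uFs * eta + vFs * eta**2))
    return Ds, Fs


def classify_third_position(prefix, code_table):
    """Degeneracy class by translating all four codons with Biopython."""
    from Bio.Seq import Seq

    aas = {}
    for b in "ACGT":
        aa = str(Seq(prefix + b).translate(table=code_table))
        aas.setdefault(aa, set()).add(b)
    if "*" in aas:
        return "other"
    if len(aas) == 1:
        return "fourfold"
    if len(aas) == 2:
        groups = {frozenset(v) for v in aas.values()}
        if groups == {frozenset("AG"), frozenset("CT")}:
            return "twofold"
    return "other"
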