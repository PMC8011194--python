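"""Independent brute-force oracles for the statistical estimators.

Everything here is written with explicit Python loops over individuals,
alleles and loci, straight from the defining formulas, and is deliberately
independent of the vectorized implementations in the package.
"""

import itertools
import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------- diversity


def bf_allele_freqs(geno_locus):
    """geno_locus: list of (a1, a2) tuples, MISSING for untyped."""
    copies = [int(a) for g in geno_locus for a in g if a != MISSING]
    n = len(copies)
    freqs = {}
    for a in copies:
        freqs[a] = freqs.get(a, 0) + 1
    return {a: c / n for a, c in freqs.items()}, n


def bf_expected_het(geno_locus):
    freqs, n = bf_allele_freqs(geno_locus)
    if n < 2:
        return np.nan
    return (n / (n - 1)) * (1.0 - sum(p * p for p in freqs.values()))


def bf_observed_het(geno_locus):
    typed = [g for g in geno_locus if g[0] != MISSING]
    if not typed:
        return np.nan
    return sum(1 for g in typed if g[0] != g[1]) / len(typed)


def bf_nae(geno_locus):
    freqs, n = bf_allele_freqs(geno_locus)
    if n == 0:
        return np.nan
    return 1.0 / sum(p * p for p in freqs.values())


def bf_allelic_richness(geno_locus, k):
    """Exact rarefaction by enumeration of allele counts."""
    copies = [a for g in geno_locus for a in g if a != MISSING]
    n = len(copies)
    counts = {}
    for a in copies:
        counts[a] = counts.get(a, 0) + 1
    total = 0.0
    for na in counts.values():
        total += 1.0 - math.comb(n - na, k) / math.comb(n, k) if n - na >= k else 1.0
    return total


def bf_fis(genotypes):
    """Weir & Cockerham within-population f via the published per-allele
    formulas (single population): f = 1 - sum(c) / sum(b + c)."""
    n_ind, L, _ = np.shape(genotypes)
    sum_b = 0.0
    sum_c = 0.0
    for l in range(L):
        col = [tuple(genotypes[i][l]) for i in range(n_ind)]
        typed = [g for g in col if g[0] != MISSING]
        n = len(typed)
        if n < 2:
            continue
        alleles = sorted({a for g in typed for a in g})
        if len(alleles) < 2:
            continue
        for a in alleles:
            p = sum(int(g[0] == a) + int(g[1] == a) for g in typed) / (2 * n)
            h = sum(1 for g in typed if (g[0] == a) != (g[1] == a)) / n
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2
            sum_b += b
            sum_c += c
    return sum_b / (sum_b + sum_c)


# ----------------------------------------------------------- differentiation


def bf_fst_wc(genotypes, labels):
    """Weir & Cockerham (1984) theta from the published per-allele a/b/c
    formulas, components summed over loci and alleles before the ratio."""
    labels = list(labels)
    pops = sorted(set(labels))
    r = len(pops)
    n_ind, L, _ = np.shape(genotypes)
    sum_a = sum_b = sum_c = 0.0
    for l in range(L):
        per_pop = {p: [] for p in pops}
        for i in range(n_ind):
            g = tuple(genotypes[i][l])
            if g[0] != MISSING:
                per_pop[labels[i]].append(g)
        ns = [len(per_pop[p]) for p in pops]
        if any(n < 1 for n in ns):
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({a for p in pops for g in per_pop[p] for a in g})
        if len(alleles) < 2:
            continue
        for al in alleles:
            p_i = []
            h_i = []
            for p in pops:
                gs = per_pop[p]
                p_i.append(sum(int(g[0] == al) + int(g[1] == al) for g in gs) / (2 * len(gs)))
                h_i.append(sum(1 for g in gs if (g[0] == al) != (g[1] == al)) / len(gs))
            pbar = sum(n * p for n, p in zip(ns, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, h_i)) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (1 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2
            sum_a += a
            sum_b += b
            sum_c += c
    return sum_a / (sum_a + sum_b + sum_c)


def bf_rst(genotypes, labels):
    """RST by direct enumeration of nested sums of squares on allele sizes."""
    labels = list(labels)
    pops = sorted(set(labels))
    r = len(pops)
    n_ind, L, _ = np.shape(genotypes)
    sum_a = sum_tot = 0.0
    for l in range(L):
        per_pop = {p: [] for p in pops}
        for i in range(n_ind):
            g = tuple(genotypes[i][l])
            if g[0] != MISSING:
                per_pop[labels[i]].append(g)
        ns = [len(per_pop[p]) for p in pops]
        if any(n < 2 for n in ns):
            continue
        N = sum(ns)
        all_copies = [a for p in pops for g in per_pop[p] for a in g]
        grand = sum(all_copies) / len(all_copies)
        ssw = ssb = ssa = 0.0
        for p in pops:
            gs = per_pop[p]
            pop_mean = sum(a for g in gs for a in g) / (2 * len(gs))
            ssa += 2 * len(gs) * (pop_mean - grand) ** 2
            for g in gs:
                ind_mean = (g[0] + g[1]) / 2
                ssb += 2 * (ind_mean - pop_mean) ** 2
                ssw += (g[0] - ind_mean) ** 2 + (g[1] - ind_mean) ** 2
        msw = ssw / N
        msb = ssb / (N - r)
        msa = ssa / (r - 1)
        nc = (N - sum(n * n for n in ns) / N) / (r - 1)
        s_w = msw
        s_b = (msb - msw) / 2
        s_a = (msa - msb) / (2 * nc)
        sum_a += s_a
        sum_tot += s_a + s_b + s_w
    return sum_a / sum_tot


# --------------------------------------------------------------- kinship


def bf_loiselle(genotypes, ref_freqs, ref_ncopies, i, j):
    """Loiselle Fij for one pair by direct triple loop.

    ``ref_freqs``: list per locus of {allele: freq}; ``ref_ncopies``: list of
    reference gene-copy counts n_l.
    """
    num = 0.0
    den = 0.0
    L = len(ref_freqs)
    for l in range(L):
        gi = genotypes[i][l]
        gj = genotypes[j][l]
        if gi[0] == MISSING or gj[0] == MISSING:
            continue
        f = ref_freqs[l]
        n_l = ref_ncopies[l]
        if not f or n_l < 2:
            continue
        if all(abs(p * (1 - p)) < 1e-300 for p in f.values()):
            continue
        for a, p in f.items():
            xi = (int(gi[0] == a) + int(gi[1] == a)) / 2.0
            xj = (int(gj[0] == a) + int(gj[1] == a)) / 2.0
            num += (xi - p) * (xj - p) + p * (1 - p) / (n_l - 1)
            den += p * (1 - p)
    return num / den


# ------------------------------------------------------------ mating system


def bf_g2(het):
    """g2 by direct double loops; ``het`` is an (n, L) array of 0/1/np.nan."""
    het = np.asarray(het, dtype=float)
    n, L = het.shape
    num = 0.0
    den = 0.0
    for k in range(L):
        for l in range(k + 1, L):
            ids = [
                i
                for i in range(n)
                if not (math.isnan(het[i, k]) or math.isnan(het[i, l]))
            ]
            n_kl = len(ids)
            if n_kl < 2:
                continue
            cross = sum(het[i, k] * het[i, l] for i in ids)
            pairs = sum(
                het[i, k] * het[j, l] for i in ids for j in ids if i != j
            )
            num += cross / n_kl
            den += pairs / (n_kl * (n_kl - 1))
    return num / den - 1.0


def mc_g2_of_s(s, n_draws=1_000_000, seed=12345):
    """Monte-Carlo oracle for g2(s).

    The number of consecutive selfing generations in an individual's ancestry
    is geometric, P(T=t) = (1-s) s^t, and heterozygosity halves per selfed
    generation, so a locus is heterozygous with probability h0 * 0.5^T (same T
    for all loci of the individual). g2 = E[0.25^T] / E[0.5^T]^2 - 1 with the
    Bernoulli heterozygosity draws marginalized out (h0 cancels).
    """
    rng = np.random.default_rng(seed)
    t = rng.geometric(1.0 - s, size=n_draws) - 1  # P(T=t) = (1-s) s^t
    return float(np.mean(0.25**t) / np.mean(0.5**t) ** 2 - 1.0)
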