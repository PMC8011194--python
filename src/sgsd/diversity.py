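"""Per-group genetic diversity statistics: He, Ho, NAe, rarefied allelic
richness and the multilocus inbreeding coefficient with permutation test."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln

from ._varcomp import copy_layout, two_level_components
from .genotype_io import MISSING, AlleleFrequencies, GenotypeTable, allele_frequencies


@dataclass
class LocusStat:
    """A per-locus statistic and its unweighted multilocus mean.

    ``per_locus`` is aligned with the locus list; loci excluded from the
    computation carry NaN and do not enter the mean.
    """

    loci: list
    per_locus: np.ndarray
    mean: float


@dataclass
class FiResult:
    fi: float
    p_two_sided: float
    p_one_sided: float
    n_perm: int
    per_locus: np.ndarray  # per-locus f (ratio within locus), for diagnostics


@dataclass
class DiversitySummary:
    group: Optional[str]
    n: int
    NAe: float
    AR_k: float
    He: float
    Ho: float
    Fi: float
    Fi_p: float


def expected_heterozygosity(freqs: AlleleFrequencies) -> LocusStat:
    """Unbiased expected heterozygosity He_l = n_l/(n_l-1) * (1 - sum p^2)."""
    vals = np.full(len(freqs.loci), np.nan)
    for l, f in enumerate(freqs.freqs):
        n = freqs.n_copies[l]
        if n < 2:
            if freqs.loci[l] not in freqs.untyped_loci:
                warnings.warn(f"locus {freqs.loci[l]!r} has n_l < 2; excluded from He")
            continue
        p2 = sum(p * p for p in f.values())
        vals[l] = (n / (n - 1.0)) * (1.0 - p2)
    return LocusStat(freqs.loci, vals, float(np.nanmean(vals)))


def observed_heterozygosity(table: GenotypeTable, group=None) -> LocusStat:
    """Fraction of typed genotypes with two distinct alleles, per locus."""
    t = table.select_group(group) if group is not None else table
    g = t.genotypes
    typed = g[:, :, 0] != MISSING
    het = (g[:, :, 0] != g[:, :, 1]) & typed
    n_typed = typed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        vals = np.where(n_typed > 0, het.sum(axis=0) / np.maximum(n_typed, 1), np.nan)
    return LocusStat(t.loci, vals, float(np.nanmean(vals)))


def effective_allele_number(freqs: AlleleFrequencies) -> LocusStat:
    """NAe_l = 1 / sum_a p_a^2 (reciprocal of expected homozygosity)."""
    vals = np.full(len(freqs.loci), np.nan)
    for l, f in enumerate(freqs.freqs):
        if f:
            vals[l] = 1.0 / sum(p * p for p in f.values())
    return LocusStat(freqs.loci, vals, float(np.nanmean(vals)))


def allelic_richness(freqs: AlleleFrequencies, k: int) -> LocusStat:
    """Rarefied allelic richness: expected allele count in k gene copies.

    AR_l(k) = sum_a [1 - C(n_l - n_a, k) / C(n_l, k)], binomial coefficients
    in log space.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = np.full(len(freqs.loci), np.nan)
    for l, counts in enumerate(freqs.counts):
        if not counts:
            continue
        n = int(freqs.n_copies[l])
        if k > n:
            raise ValueError(
                f"rarefaction k={k} exceeds gene-copy count n={n} at locus "
                f"{freqs.loci[l]!r}"
            )
        total = 0.0
        log_cnk = _log_comb(n, k)
        for na in counts.values():
            if n - na < k:
                total += 1.0
            else:
                total += 1.0 - np.exp(_log_comb(n - na, k) - log_cnk)
        vals[l] = total
    return LocusStat(freqs.loci, vals, float(np.nanmean(vals)))


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _fi_components(genotypes: np.ndarray):
    """Summed (b, c) components over loci and alleles for a genotype block."""
    n, L, _ = genotypes.shape
    num = 0.0
    den = 0.0
    per_locus = np.full(L, np.nan)
    for l in range(L):
        values, ind, typed_rows = copy_layout(genotypes[:, l, :], MISSING)
        m = typed_rows.size
        if m < 2:
            continue
        alleles = np.unique(values)
        if alleles.size < 2:
            # monomorphic: zero components, contributes nothing
            continue
        Y = (values[None, :] == alleles[:, None]).astype(float)
        comps = two_level_components(Y, ind, m)  # (A, 2): sigma_b, sigma_w
        b = comps[:, 0].sum()
        c = comps[:, 1].sum()
        num += b
        den += b + c
        if b + c != 0:
            per_locus[l] = b / (b + c)
    return num, den, per_locus


def inbreeding_coefficient(
    table: GenotypeTable,
    group=None,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> FiResult:
    """Multilocus within-group inbreeding coefficient f with permutation test.

    Weir & Cockerham-type f: per-locus, per-allele variance components among
    and within individuals are summed over loci and alleles before the ratio.
    Significance by ``n_perm`` permutations re-pairing gene copies among
    individuals within the group, independently at each locus; p-values use
    the (r+1)/(n_perm+1) correction. ``p_two_sided`` ranks |f|, ``p_one_sided``
    ranks f (excess homozygosity).
    """
    t = table.select_group(group) if group is not None else table
    if t.n_samples < 2:
        raise ValueError("inbreeding coefficient requires at least 2 individuals")
    num, den, per_locus = _fi_components(t.genotypes)
    if den == 0:
        raise ValueError("no polymorphic locus: Fi undefined")
    fi = num / den
    rng = np.random.default_rng(seed)
    count_two = 0
    count_one = 0
    g = t.genotypes
    for _ in range(n_perm):
        perm = np.empty_like(g)
        for l in range(t.n_loci):
            col = g[:, l, :]
            typed_rows = np.flatnonzero(col[:, 0] != MISSING)
            copies = col[typed_rows].reshape(-1)
            rng.shuffle(copies)
            newcol = np.full_like(col, MISSING)
            newcol[typed_rows] = copies.reshape(-1, 2)
            perm[:, l, :] = newcol
        pnum, pden, _ = _fi_components(perm)
        if pden == 0:
            continue
        fp = pnum / pden
        if abs(fp) >= abs(fi) - 1e-15:
            count_two += 1
        if fp >= fi - 1e-15:
            count_one += 1
    return FiResult(
        fi=float(fi),
        p_two_sided=(count_two + 1) / (n_perm + 1),
        p_one_sided=(count_one + 1) / (n_perm + 1),
        n_perm=n_perm,
        per_locus=per_locus,
    )


def diversity_summary(
    table: GenotypeTable,
    group=None,
    k: Optional[int] = None,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> DiversitySummary:
    """All Table-1-style statistics for one group (or the whole table)."""
    t = table.select_group(group) if group is not None else table
    freqs = allele_frequencies(t)
    if k is None:
        typed_counts = freqs.n_copies[freqs.n_copies > 0]
        k = int(typed_counts.min()) if typed_counts.size else 1
    fi = inbreeding_coefficient(t, n_perm=n_perm, seed=seed)
    return DiversitySummary(
        group=group,
        n=t.n_samples,
        NAe=effective_allele_number(freqs).mean,
        AR_k=allelic_richness(freqs, k).mean,
        He=expected_heterozygosity(freqs).mean,
        Ho=observed_heterozygosity(t).mean,
        Fi=fi.fi,
        Fi_p=fi.p_two_sided,
    )
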