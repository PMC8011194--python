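"""Pairwise FST/RST matrices and the allele-size permutation test.

FST is Weir & Cockerham (1984) theta computed through a three-level ANOVA on
allele-indicator responses; RST uses the same decomposition on allele sizes
(repeat units), so the two coincide exactly when allele sizes carry no
information beyond identity. Variance components are summed over loci (and
alleles) before the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._varcomp import copy_layout, three_level_components
from .genotype_io import MISSING, GenotypeTable


@dataclass
class DifferentiationResult:
    groups: list
    FST: np.ndarray
    RST: np.ndarray
    pRST_p: Optional[np.ndarray]
    n_perm: int


def _pair_layout(table: GenotypeTable, ga, gb, locus: int):
    """Copy-level layout for one locus restricted to two groups.

    Returns (values, ind_index, grp_of_ind) or None if either group has < 2
    typed individuals at the locus.
    """
    in_a = np.array([g == ga for g in table.groups])
    in_b = np.array([g == gb for g in table.groups])
    rows = np.flatnonzero(in_a | in_b)
    g = table.genotypes[rows, locus, :]
    values, ind, typed_rows = copy_layout(g, MISSING)
    if typed_rows.size == 0:
        return None
    grp_of_ind = in_b[rows][typed_rows].astype(int)  # 0 = group a, 1 = group b
    if (grp_of_ind == 0).sum() < 2 or (grp_of_ind == 1).sum() < 2:
        return None
    return values, ind, grp_of_ind


def _pair_fst(table: GenotypeTable, ga, gb) -> float:
    num = den = 0.0
    any_locus = False
    for l in range(table.n_loci):
        layout = _pair_layout(table, ga, gb, l)
        if layout is None:
            continue
        values, ind, grp_of_ind = layout
        alleles = np.unique(values)
        if alleles.size < 2:
            continue
        Y = (values[None, :] == alleles[:, None]).astype(float)
        comps = three_level_components(Y, ind, grp_of_ind, 2)
        if np.isnan(comps).any():
            continue
        any_locus = True
        num += comps[:, 0].sum()
        den += comps.sum()
    if not any_locus or den == 0:
        return np.nan
    return num / den


def _rst_components(table: GenotypeTable, ga, gb):
    """(sigma_a, total) summed over loci for allele-size responses."""
    num = den = 0.0
    any_locus = False
    for l in range(table.n_loci):
        layout = _pair_layout(table, ga, gb, l)
        if layout is None:
            continue
        values, ind, grp_of_ind = layout
        comps = three_level_components(values.astype(float), ind, grp_of_ind, 2)[0]
        if np.isnan(comps).any():
            continue
        any_locus = True
        num += comps[0]
        den += comps.sum()
    if not any_locus or den == 0:
        return np.nan
    return num / den


def pairwise_fst(table: GenotypeTable, groups: Optional[Sequence] = None) -> np.ndarray:
    """Pairwise Weir–Cockerham theta; negative estimates are not truncated."""
    groups = list(groups) if groups is not None else table.group_labels()
    if len(groups) < 2:
        raise ValueError("pairwise FST needs at least 2 groups")
    K = len(groups)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            v = _pair_fst(table, groups[i], groups[j])
            if np.isnan(v):
                warnings.warn(
                    f"FST undefined for pair ({groups[i]!r}, {groups[j]!r}); flagged NaN"
                )
            out[i, j] = out[j, i] = v
    return out


def pairwise_rst(table: GenotypeTable, groups: Optional[Sequence] = None) -> np.ndarray:
    """Pairwise RST from allele-size variance components (summed over loci)."""
    groups = list(groups) if groups is not None else table.group_labels()
    if len(groups) < 2:
        raise ValueError("pairwise RST needs at least 2 groups")
    K = len(groups)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            v = _rst_components(table, groups[i], groups[j])
            if np.isnan(v):
                warnings.warn(
                    f"RST undefined for pair ({groups[i]!r}, {groups[j]!r}); flagged NaN"
                )
            out[i, j] = out[j, i] = v
    return out


def allele_size_permutation_test(
    table: GenotypeTable,
    groups: Optional[Sequence] = None,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """One-sided test of whether allele sizes contribute to differentiation.

    For each permutation, the size values are reassigned at random among the
    distinct allele states within each locus (identities kept), and RST is
    recomputed; p = proportion of permuted RST >= observed, with the +1
    correction. A small p means stepwise mutations contribute to
    differentiation (RST exceeding its FST-like permutation distribution).
    """
    groups = list(groups) if groups is not None else table.group_labels()
    if len(groups) < 2:
        raise ValueError("test needs at least 2 groups")
    if all(
        np.unique(table.genotypes[:, l, :][table.genotypes[:, l, :] != MISSING]).size < 2
        for l in range(table.n_loci)
    ):
        raise ValueError("fewer than 2 distinct alleles at every locus: test undefined")
    K = len(groups)
    pmat = np.ones((K, K))
    np.fill_diagonal(pmat, 1.0)
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.spawn(K * (K - 1) // 2)
    idx = 0
    for i in range(K):
        for j in range(i + 1, K):
            pmat[i, j] = pmat[j, i] = _pair_size_perm_test(
                table, groups[i], groups[j], n_perm, pair_seeds[idx]
            )
            idx += 1
    return pmat


def _pair_size_perm_test(table, ga, gb, n_perm, seedseq) -> float:
    rng = np.random.default_rng(seedseq)
    # Per locus, precompute the copy layout and per-permutation responses.
    per_locus = []
    for l in range(table.n_loci):
        layout = _pair_layout(table, ga, gb, l)
        if layout is None:
            continue
        values, ind, grp_of_ind = layout
        states = np.unique(values)
        state_idx = np.searchsorted(states, values)
        per_locus.append((states.astype(float), state_idx, ind, grp_of_ind))
    if not per_locus:
        return np.nan

    def rst_from(sizes_rows):
        # sizes_rows: list over loci of (R, n_states) size assignments
        R = sizes_rows[0].shape[0]
        num = np.zeros(R)
        den = np.zeros(R)
        ok = np.zeros(R, dtype=bool)
        for (states, state_idx, ind, grp_of_ind), sizes in zip(per_locus, sizes_rows):
            Y = sizes[:, state_idx]
            comps = three_level_components(Y, ind, grp_of_ind, 2)
            good = ~np.isnan(comps).any(axis=1)
            num[good] += comps[good, 0]
            den[good] += comps[good].sum(axis=1)
            ok |= good
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(ok & (den != 0), num / den, np.nan)
        return out

    obs = rst_from([s[0][None, :] for s in per_locus])[0]
    if np.isnan(obs):
        return np.nan
    perm_sizes = []
    for states, state_idx, ind, grp in per_locus:
        tiled = np.tile(states, (n_perm, 1))
        perm_sizes.append(rng.permuted(tiled, axis=1))
    perm_vals = rst_from(perm_sizes)
    perm_vals = perm_vals[~np.isnan(perm_vals)]
    count = int((perm_vals >= obs - 1e-15).sum())
    return (count + 1) / (len(perm_vals) + 1)


def differentiation_result(
    table: GenotypeTable,
    groups: Optional[Sequence] = None,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    run_size_test: bool = True,
) -> DifferentiationResult:
    """FST, RST and (optionally) the allele-size permutation test in one call."""
    groups = list(groups) if groups is not None else table.group_labels()
    fst = pairwise_fst(table, groups)
    rst = pairwise_rst(table, groups)
    pmat = (
        allele_size_permutation_test(table, groups, n_perm=n_perm, seed=seed)
        if run_size_test
        else None
    )
    return DifferentiationResult(groups, fst, rst, pmat, n_perm if run_size_test else 0)
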