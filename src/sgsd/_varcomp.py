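"""Nested ANOVA variance components for diploid gene-copy data.

One engine backs the F-statistics: responses are per-gene-copy values
(allele indicators for identity-based statistics, allele sizes for
size-based ones) decomposed among groups / among individuals within
groups / within individuals. With allele-indicator responses the
three-level decomposition is exactly Weir & Cockerham's (1984) theta.
"""

from __future__ import annotations

import numpy as np


def three_level_components(Y, ind, grp_of_ind, n_groups):
    """Variance components for rows of copy-level responses.

    Parameters
    ----------
    Y : (R, 2m) array
        Each row is a response vector over the 2m gene copies of m typed
        individuals (copies of the same individual adjacent is not required).
    ind : (2m,) int array
        Individual index (0..m-1) of each copy; each individual has 2 copies.
    grp_of_ind : (m,) int array
        Group index (0..n_groups-1) per individual.
    n_groups : int

    Returns
    -------
    (R, 3) array of (sigma2_a, sigma2_b, sigma2_w): among groups, among
    individuals within groups, within individuals. NaN where degrees of
    freedom vanish.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ind = np.asarray(ind)
    grp_of_ind = np.asarray(grp_of_ind)
    m = grp_of_ind.size
    n_i = np.bincount(grp_of_ind, minlength=n_groups).astype(float)  # individuals/group
    present = n_i > 0
    r = int(present.sum())
    N = float(m)

    # per-individual and per-group copy sums
    ind_sum = np.zeros((Y.shape[0], m))
    np.add.at(ind_sum.T, ind, Y.T)  # scatter-add over copies
    grp_sum = np.zeros((Y.shape[0], n_groups))
    np.add.at(grp_sum.T, grp_of_ind, ind_sum.T)
    tot = Y.sum(axis=1)

    ss_total_raw = (Y**2).sum(axis=1)
    ss_ind = (ind_sum**2).sum(axis=1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_grp = np.where(n_i > 0, grp_sum**2 / (2.0 * n_i), 0.0).sum(axis=1)
    ss_mean = tot**2 / (2.0 * N)

    SSW = ss_total_raw - ss_ind          # df = N (one per individual)
    SSB = ss_ind - ss_grp                # df = N - r
    SSA = ss_grp - ss_mean               # df = r - 1

    out = np.full((Y.shape[0], 3), np.nan)
    MSW = SSW / N
    out[:, 2] = MSW
    if N - r > 0:
        MSB = SSB / (N - r)
        out[:, 1] = (MSB - MSW) / 2.0
    else:
        MSB = np.full(Y.shape[0], np.nan)
    if r > 1:
        n_c = (N - (n_i**2).sum() / N) / (r - 1)
        MSA = SSA / (r - 1)
        out[:, 0] = (MSA - MSB) / (2.0 * n_c)
    return out


def two_level_components(Y, ind, m):
    """Among-individual / within-individual components (single group).

    Same conventions as :func:`three_level_components`; returns (R, 2) array
    of (sigma2_b, sigma2_w).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ind = np.asarray(ind)
    N = float(m)
    ind_sum = np.zeros((Y.shape[0], m))
    np.add.at(ind_sum.T, ind, Y.T)
    tot = Y.sum(axis=1)
    ss_total_raw = (Y**2).sum(axis=1)
    ss_ind = (ind_sum**2).sum(axis=1) / 2.0
    ss_mean = tot**2 / (2.0 * N)
    SSW = ss_total_raw - ss_ind
    SSB = ss_ind - ss_mean
    out = np.full((Y.shape[0], 2), np.nan)
    out[:, 1] = SSW / N
    if N - 1 > 0:
        MSB = SSB / (N - 1)
        out[:, 0] = (MSB - out[:, 1]) / 2.0
    return out


def copy_layout(genotypes_locus, missing=-1):
    """Flatten one locus of ``(n, 2)`` genotypes into copy-level arrays.

    Returns ``(values, ind_index, typed_rows)`` where ``values`` holds the
    2m allele states of the m typed individuals, ``ind_index`` maps each copy
    to 0..m-1, and ``typed_rows`` are the original row indices retained.
    """
    g = np.asarray(genotypes_locus)
    typed_rows = np.flatnonzero(g[:, 0] != missing)
    m = typed_rows.size
    values = g[typed_rows].reshape(-1)
    ind_index = np.repeat(np.arange(m), 2)
    return values, ind_index, typed_rows
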