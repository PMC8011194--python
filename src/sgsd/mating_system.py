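"""Selfing-rate estimation from identity disequilibrium (g2).

The g2 moment estimator correlates heterozygosity across loci; under
partial selfing at inbreeding equilibrium g2(s) = s / ((1 - s)(4 - s)),
which is inverted to estimate s. Being based only on heterozygosity
indicators, the estimator is robust to null alleles that silence loci
independently of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .genotype_io import MISSING, GenotypeTable

_S_MAX = 1.0 - 1e-9


@dataclass
class MatingSystemEstimate:
    group: Optional[str]
    g2: float
    s_hat: float
    SE: Optional[float]
    n_loci: int
    significant: Optional[bool]  # 0 outside s_hat +- 1.96 SE
    saturated: bool = False


def _het_matrix(table: GenotypeTable, group=None) -> np.ndarray:
    t = table.select_group(group) if group is not None else table
    g = t.genotypes
    h = np.where(
        g[:, :, 0] == MISSING, np.nan, (g[:, :, 0] != g[:, :, 1]).astype(float)
    )
    return h


def _g2_from_h(h: np.ndarray) -> float:
    """g2 from an (n, L) heterozygosity-indicator matrix (NaN = untyped).

    Ratio of sums over locus pairs (k < l), each pair restricted to the
    individuals typed at both loci (n_kl of them):

        num += sum_i h_ik h_il / n_kl
        den += sum_{i != j} h_ik h_jl / (n_kl (n_kl - 1))

    g2 = num / den - 1. The i != j exclusion is the finite-sample correction;
    per-pair normalization handles missing data.
    """
    n, L = h.shape
    usable = 0
    num = 0.0
    den = 0.0
    defined = np.isfinite(h)
    for k in range(L):
        for l in range(k + 1, L):
            both = defined[:, k] & defined[:, l]
            n_kl = int(both.sum())
            if n_kl < 2:
                continue
            hk = h[both, k]
            hl = h[both, l]
            if hk.std() == 0 and hl.std() == 0 and hk.sum() == 0:
                continue
            cross = float(hk @ hl)  # sum_i h_ik h_il
            total = float(hk.sum() * hl.sum())
            num += cross / n_kl
            den += (total - cross) / (n_kl * (n_kl - 1))
            usable += 1
    if usable < 1 or den == 0:
        raise ValueError("identity disequilibrium undefined: "
                         "need >= 2 loci with heterozygosity variation")
    return num / den - 1.0


def identity_disequilibrium_g2(table: GenotypeTable, group=None) -> float:
    """Moment estimate of identity disequilibrium g2 for one group."""
    h = _het_matrix(table, group)
    if h.shape[1] < 2:
        raise ValueError("g2 requires at least 2 loci")
    return float(_g2_from_h(h))


def g2_expected(s: float) -> float:
    """Closed-form g2 under mixed mating at equilibrium: s / ((1-s)(4-s))."""
    if not 0 <= s < 1:
        raise ValueError("s must be in [0, 1)")
    return s / ((1.0 - s) * (4.0 - s))


def selfing_from_g2(g2: float):
    """Invert g2(s) for s in [0, 1) by bracketed root-finding.

    Negative g2 maps to s = 0. Returns ``(s_hat, saturated)``; ``saturated``
    is True when g2 exceeds g2(1 - eps) and s is clamped just below 1.
    """
    if not np.isfinite(g2):
        raise ValueError("g2 must be finite")
    if g2 <= 0:
        return 0.0, False
    if g2 >= g2_expected(_S_MAX):
        return _S_MAX, True
    s = brentq(lambda s: g2_expected(s) - g2, 0.0, _S_MAX, xtol=1e-12)
    return float(s), False


def selfing_with_jackknife(table: GenotypeTable, group=None) -> MatingSystemEstimate:
    """Selfing rate with delete-one-locus jackknife standard error.

    The point estimate uses all loci; each replicate drops one locus and
    re-estimates s. SE follows the standard jackknife variance formula over
    loci. The estimate is called significant when 0 lies outside
    s_hat +- 1.96 SE.
    """
    h = _het_matrix(table, group)
    L = h.shape[1]
    if L < 3:
        raise ValueError("jackknife over loci requires at least 3 loci")
    g2 = float(_g2_from_h(h))
    s_hat, saturated = selfing_from_g2(g2)
    reps = []
    for l in range(L):
        keep = np.ones(L, dtype=bool)
        keep[l] = False
        try:
            g2_l = _g2_from_h(h[:, keep])
        except ValueError:
            continue
        reps.append(selfing_from_g2(g2_l)[0])
    if len(reps) >= 2:
        reps = np.array(reps)
        m = len(reps)
        SE = float(np.sqrt((m - 1) / m * ((reps - reps.mean()) ** 2).sum()))
        significant = bool(s_hat - 1.96 * SE > 0)
    else:
        SE = None
        significant = None
    return MatingSystemEstimate(
        group=group, g2=g2, s_hat=s_hat, SE=SE, n_loci=L,
        significant=significant, saturated=saturated,
    )
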