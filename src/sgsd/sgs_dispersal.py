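"""Fine-scale spatial genetic structure and indirect gene-dispersal inference.

Implements the Loiselle pairwise kinship estimator, the kinship-on-ln(distance)
regression with its Sp statistic (permutation significance, jackknife-over-loci
SE), and the iterative isolation-by-distance estimator of the gene dispersal
parameter sigma_g and Wright's neighbourhood size Nb = 4*pi*De*sigma_g^2,
given a fixed effective density De.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeTable, allele_frequencies


@dataclass
class KinshipMatrix:
    """Pairwise Loiselle kinship with per-locus pieces kept for jackknifing.

    ``fij[i, j]`` = (sum over shared typed loci of ``num_per_locus[l, i, j]``)
    / (sum over the same loci of ``den_per_locus[l]``). NaN where a pair
    shares no typed locus.
    """

    sample_ids: list
    num_per_locus: np.ndarray  # (L, n, n)
    den_per_locus: np.ndarray  # (L,)
    typed: np.ndarray          # (n, L) bool
    loci: list

    def fij(self, drop_locus: Optional[int] = None) -> np.ndarray:
        keep = np.ones(len(self.loci), dtype=bool)
        if drop_locus is not None:
            keep[drop_locus] = False
        shared = (
            self.typed[:, keep][:, None, :] & self.typed[:, keep][None, :, :]
        )  # (n, n, L')
        num = np.where(shared.transpose(2, 0, 1), self.num_per_locus[keep], 0.0).sum(0)
        den = (shared * self.den_per_locus[keep][None, None, :]).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, np.nan)
        return out


@dataclass
class SGSResult:
    class_bounds: np.ndarray          # upper bounds of distance classes (m)
    class_mean_fij: np.ndarray
    class_mean_distance: np.ndarray
    class_pair_counts: np.ndarray
    b_log: float                      # OLS slope of Fij on ln(distance), over pairs
    F1: float                         # mean Fij in the first distance class
    Fn: float                         # mean Fij for pairs below fn_radius
    Sp: float
    Sp_SE: Optional[float]
    perm_p: Optional[float]
    n_perm: int


@dataclass
class DispersalEstimate:
    De: float                 # effective density, per m^2
    De_scenario: Optional[float]  # fraction of census density, if applicable
    sigma_g: float            # meters
    Nb: float                 # neighbourhood size 4*pi*De*sigma_g^2
    range_factor: float
    iterations: int
    converged: bool
    Fn: float
    b_final: float = np.nan
    history: list = field(default_factory=list)
    restricted_fallback: bool = False
    method: str = "iteration"  # iteration | bisection | bisection_nearest


# ------------------------------------------------------------------- kinship


def loiselle_kinship(
    table: GenotypeTable, ref_group=None, ref_freqs=None
) -> KinshipMatrix:
    """Loiselle et al. multilocus kinship coefficients between individuals.

    Reference allele frequencies come from ``ref_group`` (default: all samples
    in ``table``) or can be passed directly. Per locus l and allele a, with
    x_ia the frequency of a in individual i (0, 0.5 or 1) and p_a the reference
    frequency over n_l gene copies, the pair (i, j) accumulates

        numerator   += (x_ia - p_a)(x_ja - p_a) + p_a (1 - p_a) / (n_l - 1)
        denominator += p_a (1 - p_a)

    over alleles and loci typed in both individuals; Fij is the ratio of sums.
    """
    if ref_freqs is None:
        ref = table.select_group(ref_group) if ref_group is not None else table
        ref_freqs = allele_frequencies(ref)
    n = table.n_samples
    L = table.n_loci
    num = np.zeros((L, n, n))
    den = np.zeros(L)
    typed = table.typed()
    for l in range(L):
        f = ref_freqs.freqs[l]
        n_l = int(ref_freqs.n_copies[l])
        if not f or n_l < 2:
            den[l] = 0.0
            continue
        alleles = np.array(sorted(f), dtype=np.int64)
        p = np.array([f[a] for a in alleles])
        g = table.genotypes[:, l, :]
        x = (
            (g[:, 0][:, None] == alleles[None, :]).astype(float)
            + (g[:, 1][:, None] == alleles[None, :]).astype(float)
        ) / 2.0
        x[~typed[:, l]] = np.nan
        dev = x - p[None, :]
        dev0 = np.nan_to_num(dev)
        correction = float((p * (1 - p)).sum() / (n_l - 1))
        num[l] = dev0 @ dev0.T + correction
        den[l] = float((p * (1 - p)).sum())
    if (den == 0).all():
        raise ValueError("no locus with usable reference frequencies")
    # loci with zero denominator (monomorphic/untyped) must not contribute
    usable = den > 0
    typed_eff = typed & usable[None, :]
    km = KinshipMatrix(
        sample_ids=table.sample_ids,
        num_per_locus=num,
        den_per_locus=den,
        typed=typed_eff,
        loci=table.loci,
    )
    no_overlap = ~(typed_eff[:, None, :] & typed_eff[None, :, :]).any(axis=2)
    np.fill_diagonal(no_overlap, False)
    if no_overlap.any():
        warnings.warn("some pairs share no typed locus; their Fij is NaN")
    return km


# ---------------------------------------------------------------- regression


def log_distance_classes(
    d_max: float, first_bound: float = 100.0, n_classes: int = 8
) -> np.ndarray:
    """Upper bounds of log-spaced distance classes, first bound at 100 m."""
    if d_max <= first_bound:
        return np.array([d_max])
    ratio = (d_max / first_bound) ** (1.0 / (n_classes - 1))
    bounds = first_bound * ratio ** np.arange(n_classes)
    bounds[-1] = d_max
    return bounds


def _pair_arrays(fij: np.ndarray, dist: np.ndarray):
    iu = np.triu_indices(fij.shape[0], k=1)
    return fij[iu], dist[iu]


def _slope(lnd: np.ndarray, f: np.ndarray) -> float:
    lnd_c = lnd - lnd.mean()
    ss = (lnd_c**2).sum()
    if ss <= lnd.size * 1e-24:  # allow for rounding in the centering
        raise ValueError("all pairs at identical distance: slope undefined")
    return float((lnd_c * f).sum() / ss)


def kinship_distance_analysis(
    kin: KinshipMatrix,
    dist: np.ndarray,
    classes: Optional[Sequence[float]] = None,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    jackknife: bool = False,
    max_distance: Optional[float] = None,
    fn_radius: float = 100.0,
    min_pairs_per_class: int = 30,
) -> SGSResult:
    """Kinship-distance curve, regression slope, Sp and permutation test.

    The slope is the OLS regression of pairwise Fij on ln(distance) over all
    pairs with d > 0 (optionally restricted to d <= ``max_distance``).
    Sp = -b / (1 - F1), F1 being the mean Fij of the first distance class.
    The permutation test permutes spatial locations among individuals and
    ranks |b| (two-sided, +1 correction). With ``jackknife=True``, Sp is
    recomputed deleting one locus at a time and the delete-one jackknife SE
    over loci is reported.
    """
    fij = kin.fij()
    f_all, d_all = _pair_arrays(fij, np.asarray(dist, dtype=float))
    ok = np.isfinite(f_all)
    f_all, d_all = f_all[ok], d_all[ok]
    if f_all.size == 0:
        raise ValueError("no usable pairs")
    in_range = np.ones(d_all.size, dtype=bool)
    if max_distance is not None:
        in_range &= d_all <= max_distance
    d_used = d_all[in_range]
    f_used = f_all[in_range]

    if classes is None:
        classes = log_distance_classes(float(d_used.max()), first_bound=fn_radius)
    bounds = np.asarray(classes, dtype=float)
    lowers = np.concatenate([[0.0], bounds[:-1]])
    cls_mean = np.full(bounds.size, np.nan)
    cls_dist = np.full(bounds.size, np.nan)
    cls_n = np.zeros(bounds.size, dtype=int)
    for c, (lo, hi) in enumerate(zip(lowers, bounds)):
        sel = (d_used > lo) & (d_used <= hi) if c else (d_used <= hi)
        cls_n[c] = int(sel.sum())
        if cls_n[c]:
            cls_mean[c] = float(f_used[sel].mean())
            cls_dist[c] = float(d_used[sel].mean())
    if (cls_n < min_pairs_per_class).any():
        warnings.warn(
            f"distance class(es) with fewer than {min_pairs_per_class} pairs"
        )
    if bounds.size < 2:
        warnings.warn("fewer than 2 distance classes")

    reg = in_range & (d_all > 0)
    if reg.sum() < 2:
        raise ValueError("not enough positive-distance pairs for the regression")
    lnd = np.log(d_all[reg])
    b = _slope(lnd, f_all[reg])
    F1 = float(cls_mean[0])
    Fn = float(f_all[d_all < fn_radius].mean()) if (d_all < fn_radius).any() else np.nan
    Sp = -b / (1.0 - F1)

    perm_p = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        n = fij.shape[0]
        dist = np.asarray(dist, dtype=float)
        count = 0
        total = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            dp = dist[np.ix_(perm, perm)]
            fp, dpp = _pair_arrays(fij, dp)
            okp = np.isfinite(fp) & (dpp > 0)
            if max_distance is not None:
                okp &= dpp <= max_distance
            if okp.sum() < 2:
                continue
            try:
                bp = _slope(np.log(dpp[okp]), fp[okp])
            except ValueError:
                continue
            total += 1
            if abs(bp) >= abs(b) - 1e-15:
                count += 1
        perm_p = (count + 1) / (total + 1) if total else None

    Sp_SE = None
    if jackknife:
        L = len(kin.loci)
        if L >= 2:
            reps = []
            for l in range(L):
                fij_l = kin.fij(drop_locus=l)
                fl, dl = _pair_arrays(fij_l, np.asarray(dist, dtype=float))
                okl = np.isfinite(fl)
                if max_distance is not None:
                    okl &= dl <= max_distance
                regl = okl & (dl > 0)
                bl = _slope(np.log(dl[regl]), fl[regl])
                first = okl & (dl <= bounds[0])
                F1l = float(fl[first].mean()) if first.any() else F1
                reps.append(-bl / (1.0 - F1l))
            reps = np.array(reps)
            Sp_SE = float(np.sqrt((L - 1) / L * ((reps - reps.mean()) ** 2).sum()))

    return SGSResult(
        class_bounds=bounds,
        class_mean_fij=cls_mean,
        class_mean_distance=cls_dist,
        class_pair_counts=cls_n,
        b_log=b,
        F1=F1,
        Fn=Fn,
        Sp=float(Sp),
        Sp_SE=Sp_SE,
        perm_p=perm_p,
        n_perm=n_perm,
    )


# ----------------------------------------------------------------- dispersal


def wright_malecot_step(b: float, Fn: float, De: float):
    """One closed-form step: Nb = (1 - Fn) / (-b), sigma_g = sqrt(Nb/(4 pi De)).

    ``b`` must be negative; ``De`` is per m^2. Returns (Nb, sigma_g in m).
    """
    if b >= 0:
        raise ValueError("regression slope must be negative")
    if De <= 0:
        raise ValueError("De must be positive")
    Nb = (1.0 - Fn) / (-b)
    sigma_g = math.sqrt(Nb / (4.0 * math.pi * De))
    return Nb, sigma_g


def estimate_sigma_g(
    kin: KinshipMatrix,
    dist: np.ndarray,
    De: float,
    range_factor: float = 20.0,
    fn_radius: float = 100.0,
    tol: float = 1e-3,
    max_iter: int = 100,
    min_pairs: int = 30,
    mu: Optional[float] = None,
    De_scenario: Optional[float] = None,
) -> DispersalEstimate:
    """Iterative isolation-by-distance estimate of sigma_g at fixed De.

    Starting from the slope over the full distance range, iterate: restrict
    pairs to distances in (sigma_g, range_factor * sigma_g], regress Fij on
    ln(d), convert the slope to Nb = (1 - Fn)/(-b) and to
    sigma_g = sqrt(Nb / (4 pi De)), until relative change < ``tol``.

    The fixed point of that update defines the estimate; when plain iteration
    fails (oscillation near the fixed point, a non-negative windowed slope, or
    a thin window), a bracketed bisection on the same fixed-point equation is
    attempted over a log grid of sigma values (``method="bisection"``). If no
    sign change exists either, the grid point of closest approach is reported
    with ``converged=False`` (``method="bisection_nearest"``).

    Never raises on estimation failure: returns ``converged=False`` with
    diagnostics instead.
    """
    if De <= 0:
        raise ValueError("De must be positive")
    fij = kin.fij()
    f_all, d_all = _pair_arrays(fij, np.asarray(dist, dtype=float))
    ok = np.isfinite(f_all)
    f_all, d_all = f_all[ok], d_all[ok]
    near = d_all < fn_radius
    if not near.any():
        raise ValueError(f"no pair below fn_radius={fn_radius} m: Fn undefined")
    Fn = float(f_all[near].mean())

    result = DispersalEstimate(
        De=De, De_scenario=De_scenario, sigma_g=np.nan, Nb=np.nan,
        range_factor=range_factor, iterations=0, converged=False, Fn=Fn,
    )

    pos = d_all > 0
    f_pos = f_all[pos]
    d_pos = d_all[pos]

    def sigma_map(sig: float):
        """One update step: windowed slope -> new sigma (NaN on failure)."""
        sel = (d_pos > sig) & (d_pos <= range_factor * sig)
        if sel.sum() < min_pairs:
            return np.nan, np.nan
        try:
            b = _slope(np.log(d_pos[sel]), f_pos[sel])
        except ValueError:
            return np.nan, np.nan
        if b >= 0:
            return np.nan, b
        return wright_malecot_step(b, Fn, De)[1], b

    def finish(sigma, b, it, converged, method, fallback=False):
        result.sigma_g = sigma
        result.Nb = 4.0 * math.pi * De * sigma**2
        result.b_final = b
        result.iterations = it
        result.converged = converged
        result.method = method
        result.restricted_fallback = fallback
        if converged and mu is not None and mu > 0:
            limit = 0.56 * sigma / math.sqrt(2.0 * mu)
            if range_factor * sigma > limit:
                warnings.warn(
                    "regression window exceeds the isolation-by-distance "
                    f"validity limit 0.56*sigma_g/sqrt(2*mu) = {limit:.1f} m"
                )
        return result

    try:
        b0 = _slope(np.log(d_pos), f_pos)
    except ValueError:
        return result
    result.history.append(("init", b0, np.nan))
    sigma = np.nan
    iteration_failed = True
    if b0 < 0:
        _, sigma = wright_malecot_step(b0, Fn, De)
        result.history[-1] = ("init", b0, sigma)
        fallback = False
        for it in range(1, max_iter + 1):
            sel = (d_pos > sigma) & (d_pos <= range_factor * sigma)
            if sel.sum() < min_pairs and it == 1:
                # widen to the min_pairs pairs nearest the window center
                order = np.argsort(np.abs(np.log(d_pos / max(sigma, 1e-12))))
                sel = np.zeros_like(sel)
                sel[order[:min_pairs]] = True
                fallback = True
            if sel.sum() < min_pairs:
                break
            try:
                b = _slope(np.log(d_pos[sel]), f_pos[sel])
            except ValueError:
                break
            if b >= 0:
                result.b_final = b
                break
            _, sigma_new = wright_malecot_step(b, Fn, De)
            result.history.append((it, b, sigma_new))
            converged = abs(sigma_new - sigma) / sigma < tol
            sigma = sigma_new
            if converged:
                return finish(sigma, b, it, True, "iteration", fallback)
        result.iterations = min(it, max_iter)
        result.restricted_fallback = fallback
        iteration_failed = True

    # --- bracketed bisection on h(sig) = sigma_map(sig) - sig -------------
    d_max = float(d_pos.max())
    grid = np.exp(np.linspace(np.log(d_max / 200.0), np.log(0.7 * d_max), 25))
    maps = np.array([sigma_map(g)[0] for g in grid])
    h = maps - grid
    for i in range(grid.size - 1):
        if (
            np.isfinite(h[i]) and np.isfinite(h[i + 1])
            and h[i] > 0 >= h[i + 1]
        ):
            a, c = grid[i], grid[i + 1]
            n_bis = 0
            while (c - a) / a >= tol and n_bis < 60:
                m = math.sqrt(a * c)
                hm = sigma_map(m)[0] - m
                if not np.isfinite(hm):
                    break
                if hm > 0:
                    a = m
                else:
                    c = m
                n_bis += 1
            sig_star = math.sqrt(a * c)
            b_star = sigma_map(sig_star)[1]
            return finish(
                sig_star, b_star, result.iterations + n_bis, True, "bisection"
            )
    # no sign change: report the closest approach to the fixed point
    with np.errstate(invalid="ignore"):
        rel = np.abs(h) / grid
    if np.isfinite(rel).any():
        i = int(np.nanargmin(rel))
        sig_star = math.sqrt(grid[i] * maps[i])
        return finish(
            sig_star, sigma_map(sig_star)[1], result.iterations, False,
            "bisection_nearest",
        )
    # nothing informative: keep whatever the iteration left behind
    if np.isfinite(sigma):
        result.sigma_g = sigma
        result.Nb = 4.0 * math.pi * De * sigma**2
    return result


def density_scenarios(D_per_ha: float, fractions: Sequence[float] = (0.5, 0.25, 0.1)):
    """Effective-density scenarios De = fraction * D.

    Returns a list of dicts with the fraction and De in both individuals per
    hectare and per square meter (1 ha = 10,000 m^2).
    """
    if D_per_ha <= 0:
        raise ValueError("census density must be positive")
    return [
        {
            "fraction": float(f),
            "De_per_ha": float(f) * D_per_ha,
            "De_per_m2": float(f) * D_per_ha / 10_000.0,
        }
        for f in fractions
    ]
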