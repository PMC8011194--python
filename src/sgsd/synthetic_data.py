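"""Generators for genotype tables with known, recoverable parameters.

Two generators back the test suite and the parameter-recovery validation:

* :func:`simulate_ibd` — an individual-based, non-overlapping-generations
  forward simulation of diploid microsatellite genotypes on a torus, with
  Gaussian seed and pollen kernels, optional selfing, and strict stepwise
  (+-1) mutation reflected at the allele-range bounds. The composite gene
  dispersal parameter is sigma_g = sqrt(sigma_s^2 + sigma_p^2 / 2).
* :func:`simulate_demes` — Balding–Nichols island genotypes at a target
  drift level F, for differentiation and clustering recovery tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .genotype_io import MISSING, GenotypeTable


@dataclass
class IBDSimulationParams:
    """Parameters of the torus isolation-by-distance simulation."""

    side: float = 1000.0          # habitat side L (m), periodic boundary
    density: float = 0.002        # adults per m^2
    selfing: float = 0.0
    sigma_s: float = 50.0         # seed kernel (m)
    sigma_p: float = 200.0        # pollen kernel (m)
    loci: int = 10
    mu: float = 1e-3              # stepwise mutation rate per allele copy
    allele_range: Tuple[int, int] = (20, 60)
    generations: int = 500
    seed: Optional[int] = None
    init_allele_count: int = 8    # distinct starting states (centered in range)

    def __post_init__(self):
        N = self.density * self.side**2
        if N < 50:
            raise ValueError("D * L^2 must be at least 50 individuals")
        if not (0 <= self.selfing < 1):
            raise ValueError("selfing rate must be in [0, 1)")
        if not (0 <= self.mu <= 0.01):
            raise ValueError("mu must be in [0, 0.01]")
        if self.sigma_s <= 0 or self.sigma_p <= 0:
            raise ValueError("kernel widths must be positive")
        lo, hi = self.allele_range
        if not (0 < lo < hi):
            raise ValueError("allele_range must satisfy 0 < min < max")

    @property
    def n_individuals(self) -> int:
        return int(round(self.density * self.side**2))

    @property
    def sigma_g_true(self) -> float:
        return math.sqrt(self.sigma_s**2 + self.sigma_p**2 / 2.0)


@dataclass
class DemeSimulationParams:
    K: int = 2                    # deme count
    F: float = 0.2                # Balding–Nichols drift parameter
    ancestral_alleles: int = 5    # per locus
    samples_per_deme: int = 100
    loci: int = 20
    seed: Optional[int] = None
    allele_min: int = 10          # first allele size; states are consecutive
    deme_spacing: float = 2000.0  # planar spacing between deme centers (m)
    coord_scatter: float = 100.0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.F < 1):
            raise ValueError("F must be in (0, 1)")


@dataclass
class IBDSimulationResult:
    table: GenotypeTable
    sigma_g_true: float
    sigma_g_realized: float       # from parent-offspring gene displacements
    params: IBDSimulationParams
    sp_history: list = field(default_factory=list)


def _toroidal_delta(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    d = a - b
    return d - L * np.round(d / L)


def toroidal_distances(xy: np.ndarray, side: float) -> np.ndarray:
    """Pairwise toroidal distances for ``(n, 2)`` positions on a torus."""
    dx = _toroidal_delta(xy[:, 0][:, None], xy[:, 0][None, :], side)
    dy = _toroidal_delta(xy[:, 1][:, None], xy[:, 1][None, :], side)
    return np.hypot(dx, dy)


def _sample_fathers(pos, mothers, sigma_p, L, rng, max_rounds=200):
    """Kernel-weighted father index per offspring, excluding the mother.

    Vectorized rejection sampling against exp(-d^2 / (2 sigma_p^2)); offspring
    still unresolved after ``max_rounds`` fall back to exact kernel weights
    over all candidates (stabilized by the nearest candidate's distance, so
    arbitrarily narrow kernels resolve to the nearest non-mother neighbour).
    """
    N = pos.shape[0]
    n_off = mothers.size
    fathers = np.full(n_off, -1, dtype=np.int64)
    pending = np.arange(n_off)
    mother_pos = pos[mothers]
    two_sp2 = 2.0 * sigma_p**2
    for _ in range(max_rounds):
        if pending.size == 0:
            return fathers
        cand = rng.integers(0, N, size=pending.size)
        ok = cand != mothers[pending]
        d2 = (
            _toroidal_delta(pos[cand, 0], mother_pos[pending, 0], L) ** 2
            + _toroidal_delta(pos[cand, 1], mother_pos[pending, 1], L) ** 2
        )
        accept = ok & (rng.random(pending.size) < np.exp(-d2 / two_sp2))
        fathers[pending[accept]] = cand[accept]
        pending = pending[~accept]
    # exact fallback for the stragglers
    for i in pending:
        d2 = (
            _toroidal_delta(pos[:, 0], mother_pos[i, 0], L) ** 2
            + _toroidal_delta(pos[:, 1], mother_pos[i, 1], L) ** 2
        )
        d2[mothers[i]] = np.inf
        w = np.exp(-(d2 - d2.min()) / two_sp2)
        w[mothers[i]] = 0.0
        fathers[i] = rng.choice(N, p=w / w.sum())
    return fathers


def _mutate(alleles: np.ndarray, mu: float, lo: int, hi: int, rng) -> np.ndarray:
    if mu <= 0:
        return alleles
    hit = rng.random(alleles.shape) < mu
    step = np.where(rng.random(alleles.shape) < 0.5, -1, 1)
    out = np.where(hit, alleles + step, alleles)
    out = np.where(out < lo, 2 * lo - out, out)
    out = np.where(out > hi, 2 * hi - out, out)
    return out


def simulate_ibd(
    params: IBDSimulationParams,
    track_dispersal_generations: int = 10,
    sgs_history_every: int = 0,
) -> IBDSimulationResult:
    """Forward simulation of isolation by distance on a torus.

    Generation 0 places N = D * L^2 individuals uniformly at random. Each
    offspring draws a mother uniformly; with probability ``selfing`` the
    father is the mother (independent Mendelian segregation of both gametes),
    otherwise a father is drawn among the other individuals with probability
    proportional to a bivariate Gaussian of width sigma_p in toroidal distance
    from the mother. The offspring settles at the mother's position plus a
    wrapped Gaussian displacement of width sigma_s. Transmitted alleles mutate
    +-1 repeat unit with probability mu, reflected at the range bounds.

    Parent-offspring gene displacements over the last
    ``track_dispersal_generations`` generations give ``sigma_g_realized``,
    the internal check that sigma_g_true labels the composite dispersal
    correctly. With ``sgs_history_every`` > 0, a per-generation Sp diagnostic
    is recorded (list of ``(generation, Sp)``).
    """
    rng = np.random.default_rng(params.seed)
    N = params.n_individuals
    L = params.side
    lo, hi = params.allele_range
    pos = rng.uniform(0.0, L, size=(N, 2))
    mid = (lo + hi) // 2
    half = params.init_allele_count // 2
    init_states = np.arange(mid - half, mid - half + params.init_allele_count)
    init_states = init_states[(init_states >= lo) & (init_states <= hi)]
    geno = rng.choice(init_states, size=(N, params.loci, 2))

    disp_sq_sum = 0.0
    disp_n = 0
    track_from = params.generations - track_dispersal_generations
    sp_history = []

    for gen in range(params.generations):
        mothers = rng.integers(0, N, size=N)
        selfed = rng.random(N) < params.selfing
        fathers = mothers.copy()
        outcrossed = ~selfed
        if outcrossed.any():
            fathers[outcrossed] = _sample_fathers(
                pos, mothers[outcrossed], params.sigma_p, L, rng
            )
        # gametes: one random copy per parent per locus
        pick_m = rng.integers(0, 2, size=(N, params.loci))
        pick_f = rng.integers(0, 2, size=(N, params.loci))
        gm = np.take_along_axis(geno[mothers], pick_m[:, :, None], axis=2)[:, :, 0]
        gf = np.take_along_axis(geno[fathers], pick_f[:, :, None], axis=2)[:, :, 0]
        gm = _mutate(gm, params.mu, lo, hi, rng)
        gf = _mutate(gf, params.mu, lo, hi, rng)
        new_geno = np.stack([gm, gf], axis=2)
        disp = rng.normal(0.0, params.sigma_s, size=(N, 2))
        new_pos = (pos[mothers] + disp) % L

        if gen >= track_from:
            d2_m = (
                _toroidal_delta(new_pos[:, 0], pos[mothers, 0], L) ** 2
                + _toroidal_delta(new_pos[:, 1], pos[mothers, 1], L) ** 2
            )
            d2_f = (
                _toroidal_delta(new_pos[:, 0], pos[fathers, 0], L) ** 2
                + _toroidal_delta(new_pos[:, 1], pos[fathers, 1], L) ** 2
            )
            disp_sq_sum += float(d2_m.sum() + d2_f.sum())
            disp_n += 2 * N

        pos, geno = new_pos, new_geno

        if sgs_history_every and (gen + 1) % sgs_history_every == 0:
            sp_history.append((gen + 1, _quick_sp(pos, geno, L)))

    ids = [f"ind{i}" for i in range(N)]
    table = GenotypeTable(
        sample_ids=ids,
        x=pos[:, 0],
        y=pos[:, 1],
        groups=np.array([None] * N, dtype=object),
        loci=[f"L{l+1}" for l in range(params.loci)],
        genotypes=geno.astype(np.int64),
        coord_system="planar",
    )
    sigma_real = math.sqrt(disp_sq_sum / disp_n / 2.0) if disp_n else np.nan
    return IBDSimulationResult(
        table=table,
        sigma_g_true=params.sigma_g_true,
        sigma_g_realized=sigma_real,
        params=params,
        sp_history=sp_history,
    )


def _quick_sp(pos, geno, L, max_n=200):
    """Cheap Sp diagnostic on a subsample (no permutations)."""
    from .sgs_dispersal import kinship_distance_analysis, loiselle_kinship

    n = pos.shape[0]
    idx = np.arange(n) if n <= max_n else np.linspace(0, n - 1, max_n).astype(int)
    table = GenotypeTable(
        sample_ids=[f"i{i}" for i in idx],
        x=pos[idx, 0],
        y=pos[idx, 1],
        groups=np.array([None] * idx.size, dtype=object),
        loci=[f"L{l+1}" for l in range(geno.shape[1])],
        genotypes=geno[idx].astype(np.int64),
        coord_system="planar",
    )
    kin = loiselle_kinship(table)
    dist = toroidal_distances(pos[idx], L)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = kinship_distance_analysis(kin, dist, n_perm=0)
    return res.Sp


def simulate_demes(params: DemeSimulationParams) -> GenotypeTable:
    """Balding–Nichols deme genotypes with the true deme as group label.

    Ancestral frequencies are symmetric-Dirichlet per locus; each deme draws
    its frequencies from Dirichlet(p * (1 - F) / F) and individuals are
    sampled in Hardy–Weinberg proportions within demes.
    """
    rng = np.random.default_rng(params.seed)
    A = params.ancestral_alleles
    states = params.allele_min + np.arange(A)
    n = params.K * params.samples_per_deme
    geno = np.empty((n, params.loci, 2), dtype=np.int64)
    for l in range(params.loci):
        p_anc = rng.dirichlet(np.ones(A))
        for k in range(params.K):
            p_k = rng.dirichlet(p_anc * (1.0 - params.F) / params.F)
            rows = slice(k * params.samples_per_deme, (k + 1) * params.samples_per_deme)
            draws = rng.choice(states, size=(params.samples_per_deme, 2), p=p_k)
            geno[rows, l, :] = draws
    side = math.ceil(math.sqrt(params.K))
    xs = np.empty(n)
    ys = np.empty(n)
    groups = np.empty(n, dtype=object)
    for k in range(params.K):
        rows = slice(k * params.samples_per_deme, (k + 1) * params.samples_per_deme)
        cx = (k % side) * params.deme_spacing
        cy = (k // side) * params.deme_spacing
        xs[rows] = cx + rng.normal(0, params.coord_scatter, params.samples_per_deme)
        ys[rows] = cy + rng.normal(0, params.coord_scatter, params.samples_per_deme)
        groups[rows] = f"deme{k}"
    return GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n)],
        x=xs,
        y=ys,
        groups=groups,
        loci=[f"L{l+1}" for l in range(params.loci)],
        genotypes=geno,
        coord_system="planar",
    )


def inject_missingness(table: GenotypeTable, rate: float, seed: int) -> GenotypeTable:
    """Set each genotype missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    mask = rng.random((table.n_samples, table.n_loci)) < rate
    geno = table.genotypes.copy()
    geno[mask] = MISSING
    return replace(table, genotypes=geno)
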