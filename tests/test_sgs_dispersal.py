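import warnings

import numpy as np
import pytest

import sgsd
from sgsd.sgs_dispersal import (
    density_scenarios,
    estimate_sigma_g,
    kinship_distance_analysis,
    log_distance_classes,
    loiselle_kinship,
    wright_malecot_step,
)
from sgsd.synthetic_data import (
    IBDSimulationParams,
    simulate_ibd,
    toroidal_distances,
)
from sgsd.genotype_io import MISSING, pairwise_distances

import oracles
from conftest import make_table, to_pylists


# ------------------------------------------------------------------- kinship


def test_loiselle_matches_bruteforce():
    rng = np.random.default_rng(2)
    genos = [
        [tuple(rng.integers(1, 5, size=2)) for _ in range(2)] for _ in range(4)
    ]
    t = make_table(genos)
    freqs = sgsd.allele_frequencies(t)
    kin = loiselle_kinship(t)
    fij = kin.fij()
    geno = to_pylists(t)
    for i in range(4):
        for j in range(i + 1, 4):
            expect = oracles.bf_loiselle(
                geno, freqs.freqs, [int(v) for v in freqs.n_copies], i, j
            )
            assert fij[i, j] == pytest.approx(expect, abs=1e-12)


def test_loiselle_mean_near_zero(hwe_table):
    kin = loiselle_kinship(hwe_table)
    fij = kin.fij()
    iu = np.triu_indices(hwe_table.n_samples, 1)
    assert abs(np.nanmean(fij[iu])) < 0.02


def test_loiselle_symmetric_and_missing_pairs():
    genos = [
        [(1, 2), (MISSING, MISSING)],
        [(MISSING, MISSING), (3, 4)],
        [(1, 1), (3, 3)],
    ]
    t = make_table(genos)
    with pytest.warns(UserWarning, match="no typed locus"):
        kin = loiselle_kinship(t)
    fij = kin.fij()
    assert np.isnan(fij[0, 1])
    assert np.allclose(fij, fij.T, equal_nan=True)


def test_parent_offspring_kinship_quarter():
    """Mean Loiselle kinship of parent-offspring pairs ~ 0.25 against an
    unrelated reference population."""
    rng = np.random.default_rng(9)
    n_ref, L, A = 200, 10, 8
    # reference: random mating population with skewed frequencies
    p = rng.dirichlet(np.ones(A) * 2)
    ref = rng.choice(np.arange(1, A + 1), size=(n_ref, L, 2), p=p)
    # parents drawn from the same pool; offspring get one parental allele
    # and one random allele from the population
    parents = rng.choice(np.arange(1, A + 1), size=(40, L, 2), p=p)
    off = np.empty_like(parents)
    for i in range(40):
        for l in range(L):
            off[i, l, 0] = parents[i, l, rng.integers(2)]
            off[i, l, 1] = rng.choice(np.arange(1, A + 1), p=p)
    geno = np.concatenate([ref, parents, off])
    t = make_table(geno.tolist())
    kin = loiselle_kinship(t)
    fij = kin.fij()
    vals = [fij[n_ref + i, n_ref + 40 + i] for i in range(40)]
    assert np.mean(vals) == pytest.approx(0.25, abs=0.05)


# ---------------------------------------------------------------- regression


def test_sp_formula_direct():
    # Sp from b=-0.01, F1=0.1
    assert -(-0.01) / (1 - 0.1) == pytest.approx(0.011111, abs=1e-6)


def _sgs_inputs(seed=0, n=60, structured=True):
    rng = np.random.default_rng(seed)
    if structured:
        res = simulate_ibd(
            IBDSimulationParams(side=400, density=0.002, sigma_s=10, sigma_p=15,
                                loci=8, mu=1e-3, generations=80, seed=seed)
        )
        t = res.table
        idx = rng.choice(t.n_samples, n, replace=False)
        t = t.subset(idx)
        d = toroidal_distances(np.c_[t.x, t.y], 400.0)
    else:
        t = sgsd.simulate_demes(
            sgsd.DemeSimulationParams(K=1, F=0.2, samples_per_deme=n, loci=8,
                                      ancestral_alleles=5, seed=seed)
        )
        d = pairwise_distances(t)
    return t, d


def test_sgs_structured_positive_sp():
    t, d = _sgs_inputs(seed=3)
    kin = loiselle_kinship(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = kinship_distance_analysis(kin, d, n_perm=99, seed=1, fn_radius=50)
    assert res.b_log < 0
    assert res.Sp > 0
    assert res.perm_p < 0.05
    assert res.Sp == pytest.approx(-res.b_log / (1 - res.F1), abs=1e-12)
    assert res.class_pair_counts.sum() == (t.n_samples * (t.n_samples - 1)) // 2


def test_sp_invariant_to_distance_scaling():
    t, d = _sgs_inputs(seed=4)
    kin = loiselle_kinship(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = kinship_distance_analysis(kin, d, n_perm=0, fn_radius=50)
        b = kinship_distance_analysis(
            kin, d * 7.0,
            classes=a.class_bounds * 7.0,
            n_perm=0, fn_radius=50 * 7.0,
        )
    assert b.b_log == pytest.approx(a.b_log, rel=1e-9)
    assert b.Sp == pytest.approx(a.Sp, rel=1e-9)


def test_identical_distances_error():
    t, _ = _sgs_inputs(seed=5, n=20, structured=False)
    kin = loiselle_kinship(t)
    d = np.ones((20, 20)) * 5.0
    np.fill_diagonal(d, 0.0)
    with pytest.raises(ValueError, match="identical distance"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kinship_distance_analysis(kin, d, n_perm=0)


def test_jackknife_se_reported():
    t, d = _sgs_inputs(seed=6)
    kin = loiselle_kinship(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = kinship_distance_analysis(kin, d, n_perm=0, jackknife=True,
                                        fn_radius=50)
    assert res.Sp_SE is not None and res.Sp_SE >= 0


def test_permutation_null_uniform_p():
    # under no structure the permutation p should not be systematically small
    ps = []
    for seed in range(6):
        t, _ = _sgs_inputs(seed=seed, n=40, structured=False)
        rng = np.random.default_rng(100 + seed)
        t.x = rng.uniform(0, 1000, t.n_samples)
        t.y = rng.uniform(0, 1000, t.n_samples)
        kin = loiselle_kinship(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = kinship_distance_analysis(
                kin, pairwise_distances(t), n_perm=49, seed=seed, fn_radius=100
            )
        ps.append(res.perm_p)
    assert np.mean(ps) > 0.2


def test_log_distance_classes():
    b = log_distance_classes(10_000.0, first_bound=100.0, n_classes=8)
    assert b[0] == 100.0
    assert b[-1] == 10_000.0
    assert np.all(np.diff(b) > 0)
    assert log_distance_classes(50.0).tolist() == [50.0]


# ----------------------------------------------------------------- dispersal


def test_wright_malecot_closed_form():
    Nb, sigma = wright_malecot_step(-0.005, 0.05, 9e-4)
    assert Nb == pytest.approx(190.0, abs=1e-9)
    assert sigma == pytest.approx(129.6, abs=0.1)


def test_wright_malecot_rejects_bad_inputs():
    with pytest.raises(ValueError, match="negative"):
        wright_malecot_step(0.001, 0.05, 9e-4)
    with pytest.raises(ValueError, match="positive"):
        wright_malecot_step(-0.005, 0.05, 0.0)


def test_estimate_sigma_g_recovers_scale():
    res = simulate_ibd(
        IBDSimulationParams(side=700, density=0.004, sigma_s=25, sigma_p=35,
                            loci=10, mu=1e-3, generations=150, seed=2)
    )
    t = res.table
    rng = np.random.default_rng(0)
    sub = t.subset(rng.choice(t.n_samples, 250, replace=False))
    kin = loiselle_kinship(sub)
    d = toroidal_distances(np.c_[sub.x, sub.y], 700.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = estimate_sigma_g(kin, d, De=0.004, range_factor=20, fn_radius=50)
    # sigma_g_true = sqrt(25^2 + 35^2/2) ~ 35.2 m
    assert est.sigma_g == pytest.approx(res.sigma_g_true, rel=0.6)
    assert est.Nb == pytest.approx(4 * np.pi * 0.004 * est.sigma_g**2, abs=1e-9)


def test_estimate_sigma_g_no_structure_never_raises(hwe_table):
    rng = np.random.default_rng(1)
    t = hwe_table
    t.x = rng.uniform(0, 2000, t.n_samples)
    t.y = rng.uniform(0, 2000, t.n_samples)
    kin = loiselle_kinship(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = estimate_sigma_g(kin, pairwise_distances(t), De=0.001)
    assert isinstance(est.converged, bool)  # result, not an exception


def test_estimate_sigma_g_fn_requires_near_pairs(hwe_table):
    t = hwe_table
    t.x = np.arange(t.n_samples) * 10_000.0
    t.y = np.zeros(t.n_samples)
    kin = loiselle_kinship(t)
    with pytest.raises(ValueError, match="Fn undefined"):
        estimate_sigma_g(kin, pairwise_distances(t), De=0.001, fn_radius=100)


def test_validity_window_warning():
    res = simulate_ibd(
        IBDSimulationParams(side=700, density=0.004, sigma_s=25, sigma_p=35,
                            loci=10, mu=1e-3, generations=100, seed=3)
    )
    t = res.table
    rng = np.random.default_rng(0)
    sub = t.subset(rng.choice(t.n_samples, 200, replace=False))
    kin = loiselle_kinship(sub)
    d = toroidal_distances(np.c_[sub.x, sub.y], 700.0)
    with pytest.warns(UserWarning, match="validity limit"):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*fewer than.*")
            estimate_sigma_g(kin, d, De=0.004, fn_radius=50, mu=0.01)


def test_density_scenarios_standard_fractions():
    sc = density_scenarios(18.0)
    assert [s["De_per_ha"] for s in sc] == [9.0, 4.5, 1.8]
    assert sc[0]["De_per_m2"] == pytest.approx(9e-4)


def test_density_scenarios_identity_fraction():
    sc = density_scenarios(18.0, fractions=[1.0])
    assert sc[0]["De_per_ha"] == 18.0


def test_density_scenarios_rejects_nonpositive():
    with pytest.raises(ValueError):
        density_scenarios(0.0)
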