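"""Maximum-likelihood EM mixture clustering of multilocus genotypes.

The model assumes Hardy-Weinberg proportions within clusters and uniform
mixing weights: P(genotype | k) is a product over typed loci of p^2 (hom)
or 2pq (het). Missing loci drop out of the product. K is selected by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .genotype_io import MISSING, GenotypeTable


@dataclass
class ClusterAssignment:
    K: int
    sample_ids: list
    q: np.ndarray                # (n, K) posterior memberships
    hard_labels: np.ndarray      # argmax q
    log_likelihood: float
    aic: float
    cluster_freqs: list          # per locus: (K, A_l) frequency array
    locus_alleles: list          # per locus: sorted allele states
    n_iter: int
    loglik_path: np.ndarray      # per-iteration logL of the winning start

    def assigned(self, threshold: float = 0.8) -> np.ndarray:
        return self.q.max(axis=1) >= threshold


@dataclass
class KSelection:
    chosen_K: int
    ks: np.ndarray
    scores: np.ndarray           # AIC per K
    assignments: list            # ClusterAssignment per K


def _encode(table: GenotypeTable):
    """Per-locus allele codes: (a1, a2) index arrays with -1 for missing."""
    enc = []
    for l in range(table.n_loci):
        g = table.genotypes[:, l, :]
        typed = g[:, 0] != MISSING
        alleles = np.unique(g[typed]) if typed.any() else np.array([], dtype=np.int64)
        lut = {int(a): i for i, a in enumerate(alleles)}
        a1 = np.array([lut.get(int(v), -1) for v in g[:, 0]])
        a2 = np.array([lut.get(int(v), -1) for v in g[:, 1]])
        a1[~typed] = -1
        a2[~typed] = -1
        enc.append((alleles, a1, a2))
    return enc


def _loglik_matrix(enc, freqs):
    """(n, K) genotype log-likelihoods given per-cluster frequencies."""
    n = enc[0][1].size
    K = freqs[0].shape[0]
    ll = np.zeros((n, K))
    log2 = np.log(2.0)
    for (alleles, a1, a2), p in zip(enc, freqs):
        if alleles.size == 0:
            continue
        logp = np.log(p)  # (K, A)
        typed = a1 >= 0
        t1 = np.where(typed, a1, 0)
        t2 = np.where(typed, a2, 0)
        contrib = logp[:, t1].T + logp[:, t2].T  # (n, K)
        het = typed & (a1 != a2)
        contrib[het] += log2
        contrib[~typed] = 0.0
        ll += contrib
    return ll


def _m_step(enc, q, n_copies):
    """q-weighted allele frequencies with 1/(2 n_l) pseudo-counts."""
    K = q.shape[1]
    freqs = []
    for (alleles, a1, a2), n_l in zip(enc, n_copies):
        A = alleles.size
        if A == 0:
            freqs.append(np.ones((K, 1)))
            continue
        typed = a1 >= 0
        counts = np.zeros((K, A))
        w = q[typed]
        onehot1 = np.zeros((typed.sum(), A))
        onehot1[np.arange(typed.sum()), a1[typed]] = 1.0
        onehot2 = np.zeros((typed.sum(), A))
        onehot2[np.arange(typed.sum()), a2[typed]] = 1.0
        counts = w.T @ (onehot1 + onehot2)
        pseudo = 1.0 / (2.0 * max(n_l, 1))
        counts += pseudo
        freqs.append(counts / counts.sum(axis=1, keepdims=True))
    return freqs


def em_cluster(
    table: GenotypeTable,
    K: int,
    n_starts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
) -> ClusterAssignment:
    """Best-of-``n_starts`` EM fit of the K-cluster HWE mixture model.

    E-step: q_ik proportional to P(genotype_i | k) (uniform priors);
    M-step: frequencies from q-weighted allele counts with a pseudo-count of
    1/(2 n_l). Runs whose clusters empty out are restarted. Deterministic
    given ``seed``. AIC = -2 logL + 2 (K sum_l (A_l - 1) + (K - 1)).
    """
    n = table.n_samples
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > max(1, n // 2):
        raise ValueError("K must not exceed n/2")
    enc = _encode(table)
    typed = table.typed()
    n_copies = 2 * typed.sum(axis=0)
    rng = np.random.default_rng(seed)

    best = None
    attempts = 0
    max_attempts = n_starts * 5
    starts_done = 0
    while starts_done < n_starts and attempts < max_attempts:
        attempts += 1
        q = rng.dirichlet(np.ones(K), size=n)
        prev_ll = -np.inf
        path = []
        degenerate = False
        for it in range(max_iter):
            freqs = _m_step(enc, q, n_copies)
            ll_mat = _loglik_matrix(enc, freqs)
            ll = float(logsumexp(ll_mat - np.log(K), axis=1).sum())
            q = np.exp(ll_mat - logsumexp(ll_mat, axis=1, keepdims=True))
            path.append(ll)
            if q.sum(axis=0).min() < 1e-6:
                degenerate = True
                break
            if ll - prev_ll < tol and it > 0:
                break
            prev_ll = ll
        if degenerate and K > 1:
            continue
        starts_done += 1
        if best is None or path[-1] > best[0]:
            best = (path[-1], q, freqs, it + 1, np.array(path))
    if best is None:
        raise RuntimeError("all EM runs degenerated into empty clusters")

    ll, q, freqs, n_iter, path = best
    n_params = K * sum(max(e[0].size - 1, 0) for e in enc) + (K - 1)
    aic = -2.0 * ll + 2.0 * n_params
    return ClusterAssignment(
        K=K,
        sample_ids=table.sample_ids,
        q=q,
        hard_labels=q.argmax(axis=1),
        log_likelihood=ll,
        aic=aic,
        cluster_freqs=freqs,
        locus_alleles=[e[0] for e in enc],
        n_iter=n_iter,
        loglik_path=path,
    )


def select_k(
    table: GenotypeTable,
    k_max: int = 10,
    n_starts: int = 20,
    seed: Optional[int] = None,
    **em_kwargs,
) -> KSelection:
    """Fit K = 1..k_max and pick the AIC minimum (ties toward smaller K)."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, max(1, table.n_samples // 2))
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(k_max)
    ks, scores, fits = [], [], []
    for K in range(1, k_max + 1):
        fit = em_cluster(
            table, K, n_starts=n_starts,
            seed=int(child[K - 1].generate_state(1)[0]), **em_kwargs,
        )
        ks.append(K)
        scores.append(fit.aic)
        fits.append(fit)
    scores = np.array(scores)
    chosen = int(np.array(ks)[np.argmin(scores)])  # argmin takes first on ties
    return KSelection(chosen_K=chosen, ks=np.array(ks), scores=scores, assignments=fits)


def apply_admixture_threshold(
    table: GenotypeTable, assignment: ClusterAssignment, threshold: float = 0.8
):
    """Label samples by hard cluster where max q >= threshold.

    Returns ``(grouped_table, unassigned_ids)``: assigned samples get group
    ``"cluster<k>"``, admixed samples keep group ``None`` and their ids are
    listed separately (they are excluded from per-cluster statistics).
    """
    ok = assignment.assigned(threshold)
    groups = np.array(
        [
            f"cluster{assignment.hard_labels[i]}" if ok[i] else None
            for i in range(table.n_samples)
        ],
        dtype=object,
    )
    unassigned = [sid for sid, a in zip(table.sample_ids, ok) if not a]
    return table.with_groups(groups), unassigned


def match_accuracy(true_labels, assignment: ClusterAssignment) -> float:
    """Hard-assignment accuracy under the best label bipartite matching."""
    true_labels = np.asarray(true_labels)
    uniq = np.unique(true_labels)
    K = assignment.K
    cost = np.zeros((uniq.size, K))
    for i, t in enumerate(uniq):
        for k in range(K):
            cost[i, k] = -np.sum((true_labels == t) & (assignment.hard_labels == k))
    rows, cols = linear_sum_assignment(cost)
    return float(-cost[rows, cols].sum() / true_labels.size)
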