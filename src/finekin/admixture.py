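"""Bayesian admixture clustering of multilocus genotypes.

A Gibbs sampler for the admixture model: each allele copy of individual i
has a latent cluster of origin z drawn from the individual's ancestry
vector Q_i ~ Dirichlet(alpha, ..., alpha); cluster allele frequencies have
independent Dirichlet(lambda=1) priors; alpha is updated by a
Metropolis step with a uniform (0, 10] prior. Model order is selected by
the posterior log-probability estimate L(K) = mean(LL) - var(LL)/2 and by
the Evanno delta-K statistic; individuals are assigned to gene pools at
ancestry thresholds 0.5 and 0.875.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data_model import GenotypeMatrix

__all__ = [
    "AdmixtureResult",
    "KSelectionSummary",
    "run_admixture",
    "select_k",
    "assign_gene_pools",
    "align_replicates",
    "encode_alleles",
    "dirichlet_multinomial_loglik",
]


def encode_alleles(g: GenotypeMatrix) -> tuple[np.ndarray, list[int]]:
    """Integer-code alleles per locus: (n, L, 2) array, -1 for missing."""
    n, L = g.n_individuals, g.n_loci
    out = np.full((n, L, 2), -1, dtype=int)
    n_alleles = []
    for l in range(L):
        alleles = g.alleles_at(l)
        idx = {a: j for j, a in enumerate(alleles)}
        n_alleles.append(len(alleles))
        for i, row in enumerate(g.calls):
            c = row[l]
            if c is not None:
                out[i, l, 0] = idx[c[0]]
                out[i, l, 1] = idx[c[1]]
    return out, n_alleles


@dataclass
class AdmixtureResult:
    k: int
    q: np.ndarray  # (n, K) posterior-mean ancestry, rows on the simplex
    p: list[np.ndarray]  # per locus (K, A) posterior-mean allele freqs
    loglik_trace: np.ndarray
    alpha_trace: np.ndarray
    l_estimate: float  # mean - var/2 of the post-burn-in log-likelihood
    seed: int | None = None
    warning: str | None = None


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorised categorical draw along the last axis."""
    cum = probs.cumsum(axis=-1)
    cum /= cum[..., -1:]
    r = rng.random(probs.shape[:-1] + (1,))
    return (r > cum).sum(axis=-1)


def run_admixture(
    g: GenotypeMatrix,
    k: int,
    burnin: int = 20_000,
    iters: int = 80_000,
    n_reps: int = 1,
    seed: int | None = None,
    lambda_prior: float = 1.0,
    alpha_init: float = 1.0,
    alpha_sd: float = 0.025,
    alpha_max: float = 10.0,
) -> list[AdmixtureResult]:
    """Run the Gibbs sampler ``n_reps`` times; *iters* is the total chain
    length including *burnin* (matching common usage of the original
    program's run-length parameters)."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    alleles, n_alleles = encode_alleles(g)
    n, L, _ = alleles.shape
    valid = alleles >= 0  # (n, L, 2)
    ss = np.random.SeedSequence(seed)
    results = []
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        Q = rng.dirichlet(np.ones(k), size=n)
        P = [rng.dirichlet(np.ones(a), size=k) for a in n_alleles]
        alpha = alpha_init
        ll_trace = []
        alpha_trace = []
        q_sum = np.zeros((n, k))
        p_sum = [np.zeros((k, a)) for a in n_alleles]
        kept = 0
        z = [np.zeros((n, 2), dtype=int) for _ in range(L)]
        for it in range(iters):
            # z | Q, P
            nik = np.zeros((n, k))
            for l in range(L):
                a = alleles[:, l, :]
                am = np.where(valid[:, l, :], a, 0)
                pk = P[l][:, am]  # (k, n, 2)
                probs = Q[:, None, :] * np.moveaxis(pk, 0, -1)  # (n, 2, k)
                probs = np.where(valid[:, l, :, None], probs, 1.0)
                zl = _sample_categorical(rng, probs)
                z[l] = zl
                onehot = np.zeros((n, 2, k))
                idx0 = np.arange(n)[:, None], np.arange(2)[None, :]
                onehot[idx0[0], idx0[1], zl] = 1.0
                onehot *= valid[:, l, :, None]
                nik += onehot.sum(axis=1)
            # P | z
            for l in range(L):
                counts = np.zeros((k, n_alleles[l]))
                m = valid[:, l, :]
                np.add.at(counts, (z[l][m], alleles[:, l, :][m]), 1.0)
                gam = rng.standard_gamma(lambda_prior + counts)
                P[l] = gam / gam.sum(axis=1, keepdims=True)
            # Q | z
            gam = rng.standard_gamma(alpha + nik)
            Q = gam / gam.sum(axis=1, keepdims=True)
            # alpha | Q (Metropolis)
            if k > 1:
                prop = alpha + rng.normal(0.0, alpha_sd)
                if 0.0 < prop <= alpha_max:
                    lnq = float(np.log(np.clip(Q, 1e-300, None)).sum())

                    def _lp(a_: float) -> float:
                        return n * (gammaln(k * a_) - k * gammaln(a_)) + (a_ - 1) * lnq

                    if np.log(rng.random()) < _lp(prop) - _lp(alpha):
                        alpha = prop
            # log-likelihood of the data given (Q, P)
            ll = 0.0
            for l in range(L):
                a = alleles[:, l, :]
                am = np.where(valid[:, l, :], a, 0)
                pk = np.moveaxis(P[l][:, am], 0, -1)  # (n, 2, k)
                mix = np.einsum("nck,nk->nc", pk, Q)
                ll += float(np.log(mix[valid[:, l, :]]).sum())
            if it >= burnin:
                ll_trace.append(ll)
                alpha_trace.append(alpha)
                q_sum += Q
                for l in range(L):
                    p_sum[l] += P[l]
                kept += 1
        ll_arr = np.array(ll_trace)
        l_est = float(ll_arr.mean() - ll_arr.var() / 2.0)
        q_mean = q_sum / kept
        q_mean /= q_mean.sum(axis=1, keepdims=True)
        warning = None
        at = np.array(alpha_trace)
        if k > 1 and len(at) >= 20:
            half = len(at) // 2
            drift = abs(at[half:].mean() - at[:half].mean())
            if drift > 5 * (at.std() + 1e-12):
                warning = "alpha trace shows a trend: chain may not have converged"
        results.append(
            AdmixtureResult(
                k,
                q_mean,
                [ps / kept for ps in p_sum],
                ll_arr,
                at,
                l_est,
                seed,
                warning,
            )
        )
    return results


def dirichlet_multinomial_loglik(counts: np.ndarray, lam: float = 1.0) -> float:
    """Closed-form log marginal likelihood of gene-copy counts at one locus
    under a single population with a Dirichlet(lam) frequency prior —
    the exact L(1) for a one-cluster model, used as an oracle."""
    counts = np.asarray(counts, dtype=float)
    A = counts.size
    N = counts.sum()
    return float(
        gammaln(A * lam)
        - gammaln(A * lam + N)
        + np.sum(gammaln(lam + counts) - gammaln(lam))
    )


def align_replicates(results: list[AdmixtureResult]) -> list[AdmixtureResult]:
    """Resolve label switching by greedy matching of Q columns to the first
    replicate (maximal correlation); PI and L(K) are invariant under this."""
    if not results:
        return results
    ref = results[0].q
    k = results[0].k
    out = [results[0]]
    from scipy.optimize import linear_sum_assignment

    for r in results[1:]:
        C = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                sa, sb = ref[:, a], r.q[:, b]
                C[a, b] = np.dot(sa - sa.mean(), sb - sb.mean())
        _, perm = linear_sum_assignment(-C)
        q = r.q[:, perm]
        p = [pl[perm] for pl in r.p]
        out.append(
            AdmixtureResult(
                r.k, q, p, r.loglik_trace, r.alpha_trace, r.l_estimate, r.seed, r.warning
            )
        )
    return out


@dataclass
class KSelectionSummary:
    k_values: list[int]
    l_mean: dict[int, float]  # mean L(K) over replicates
    l_sd: dict[int, float]
    delta_k: dict[int, float] = field(default_factory=dict)
    best_by_l: int = 0
    best_by_delta: int | None = None
    conflict: bool = False


def select_k(results_by_k: dict[int, list[AdmixtureResult]]) -> KSelectionSummary:
    """Summarise model-order selection over a K grid.

    L(K) uses the mean over replicates; the Evanno statistic
    delta-K = |L(K-1) - 2 L(K) + L(K+1)| / sd(L(K)) is defined only for
    interior K with >= 2 replicates and non-zero sd. Disagreement between
    the two criteria is flagged, never resolved.
    """
    ks = sorted(results_by_k)
    l_mean = {k: float(np.mean([r.l_estimate for r in results_by_k[k]])) for k in ks}
    l_sd = {
        k: float(np.std([r.l_estimate for r in results_by_k[k]], ddof=1))
        if len(results_by_k[k]) >= 2
        else float("nan")
        for k in ks
    }
    delta = {}
    for k in ks[1:-1]:
        if k - 1 in l_mean and k + 1 in l_mean and len(results_by_k[k]) >= 2:
            sd = l_sd[k]
            if sd and np.isfinite(sd) and sd > 0:
                delta[k] = abs(l_mean[k - 1] - 2 * l_mean[k] + l_mean[k + 1]) / sd
    best_l = max(ks, key=lambda k: l_mean[k])
    best_d = max(delta, key=lambda k: delta[k]) if delta else None
    return KSelectionSummary(
        ks, l_mean, l_sd, delta, best_l, best_d, best_d is not None and best_d != best_l
    )


UNASSIGNED = "UNASSIGNED"


def assign_gene_pools(
    r: AdmixtureResult, threshold: float = 0.5
) -> tuple[list[str], float]:
    """Assign each individual to its argmax cluster when Q meets the
    threshold, else UNASSIGNED; returns (labels, percent assigned)."""
    if r.k < 2:
        raise ValueError("assignment needs K >= 2")
    labels = []
    for q in r.q:
        j = int(np.argmax(q))
        labels.append(f"GP{j + 1}" if q[j] >= threshold else UNASSIGNED)
    pct = 100.0 * np.mean([lab != UNASSIGNED for lab in labels])
    return labels, float(pct)
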