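"""Association tests on spatial genetic heterogeneity.

Weir-Cockerham F_ST among gene pools with a label-permutation test,
one-way ANOVA of sPCA scores against haplotype or altitude classes, Fisher
tests of haplotype x gene-pool (or morphotype) contingency tables (exact
for 2x2, fixed-margin Monte Carlo otherwise), partial Mantel tests of
pairwise similarity controlling for spatial distance, pooled-variance
one-tailed t-tests for continental contrasts, and an exact-enumeration
Spearman rank correlation for small population panels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .data_model import GenotypeMatrix

__all__ = [
    "DifferentiationResult",
    "AssociationTestResult",
    "weir_cockerham_fst",
    "fst_among_pools",
    "anova_scores",
    "fisher_association",
    "partial_mantel",
    "mantel",
    "continental_ttest",
    "spearman_exact",
]


@dataclass
class DifferentiationResult:
    fst: float
    p: float
    group_sizes: dict[str, int]
    n_perm: int


@dataclass
class AssociationTestResult:
    family: str  # anova | fisher | partial_mantel | mantel | ttest | spearman
    statistic: float
    p: float
    sidedness: str
    null_type: str  # analytic | exact | monte_carlo
    group_means: dict | None = None
    extra: dict | None = None


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_arrays(g: GenotypeMatrix) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-locus dosage matrices X (n, A) in {0, .5, 1} with NaN for missing,
    and heterozygote-carrier indicators H (n, A)."""
    Xs, Hs = [], []
    for l in range(g.n_loci):
        X, _ = g.dosage_matrix(l)
        H = np.where(np.isnan(X), np.nan, (X == 0.5).astype(float))
        Xs.append(X)
        Hs.append(H)
    return Xs, Hs


def _wc_theta(Xs: list[np.ndarray], Hs: list[np.ndarray], codes: np.ndarray) -> float:
    """Multilocus Weir-Cockerham (1984) theta: ratio of the a-component sum
    to the (a+b+c) sum over loci and alleles. ``codes`` are integer group
    labels per individual."""
    groups = np.unique(codes)
    num = den = 0.0
    for X, H in zip(Xs, Hs):
        typed = ~np.isnan(X[:, 0])
        ns = np.array([np.sum(typed & (codes == grp)) for grp in groups], float)
        keep = ns > 0
        if keep.sum() < 2:
            continue
        ns_arr = ns[keep]
        ps = np.stack(
            [np.nanmean(X[codes == grp], axis=0) for grp in groups[keep]]
        )  # (r, A)
        hs = np.stack([np.nanmean(H[codes == grp], axis=0) for grp in groups[keep]])
        r = len(ns_arr)
        nbar = ns_arr.mean()
        nc = (ns_arr.sum() - (ns_arr**2).sum() / ns_arr.sum()) / (r - 1)
        if nbar <= 1 or nc <= 0:
            continue
        w = ns_arr / ns_arr.sum()
        pbar = w @ ps  # (A,)
        s2 = (ns_arr[:, None] * (ps - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = w @ hs
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a.sum()
        den += (a + b + c).sum()
    if den == 0:
        return float("nan")
    return num / den


def weir_cockerham_fst(g: GenotypeMatrix, labels: list[str]) -> float:
    Xs, Hs = _wc_arrays(g)
    uniq = sorted(set(labels))
    codes = np.array([uniq.index(lab) for lab in labels])
    return float(_wc_theta(Xs, Hs, codes))


def fst_among_pools(
    g: GenotypeMatrix,
    labels: list[str],
    n_perm: int = 999,
    seed: int | None = None,
    unassigned: str = "UNASSIGNED",
) -> DifferentiationResult:
    """Multilocus Weir-Cockerham theta among gene pools; P from permuting
    labels over individuals. Individuals labelled *unassigned* are dropped;
    F_ST requires at least two groups with two members."""
    keep = [i for i, lab in enumerate(labels) if lab != unassigned]
    ids = [g.individual_ids[i] for i in keep]
    labs = [labels[i] for i in keep]
    sizes = {grp: labs.count(grp) for grp in sorted(set(labs))}
    if sum(v >= 2 for v in sizes.values()) < 2:
        raise ValueError("F_ST needs >= 2 groups with >= 2 members")
    gg = g.subset(ids)
    Xs, Hs = _wc_arrays(gg)
    uniq = sorted(set(labs))
    codes = np.array([uniq.index(lab) for lab in labs])
    obs = _wc_theta(Xs, Hs, codes)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        if _wc_theta(Xs, Hs, rng.permutation(codes)) >= obs:
            ge += 1
    return DifferentiationResult(float(obs), (ge + 1) / (n_perm + 1), sizes, n_perm)


# ---------------------------------------------------------------------------
# ANOVA of sPCA scores
# ---------------------------------------------------------------------------


def anova_scores(scores: np.ndarray, groups) -> AssociationTestResult:
    """One-way ANOVA of per-individual scores across categorical groups.

    Groups with fewer than 2 members are dropped with a note; the F
    statistic and analytic P follow the usual one-way decomposition.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    samples = []
    means = {}
    dropped = []
    for grp in np.unique(groups):
        vals = scores[(groups == grp) & np.isfinite(scores)]
        if len(vals) >= 2:
            samples.append(vals)
            means[str(grp)] = float(vals.mean())
        else:
            dropped.append(str(grp))
    if len(samples) < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 members")
    f, p = stats.f_oneway(*samples)
    return AssociationTestResult(
        "anova",
        float(f),
        float(p),
        "two-sided",
        "analytic",
        means,
        {"dropped_groups": dropped} if dropped else None,
    )


# ---------------------------------------------------------------------------
# Fisher association
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(N + 1)
        - gammaln(table + 1).sum()
    )


def fisher_association(
    table: np.ndarray,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> AssociationTestResult:
    """Fisher test of an r x c contingency table.

    2x2 tables get the exact two-sided hypergeometric P; larger tables a
    fixed-margin Monte-Carlo P (tables sampled by randomly pairing the
    two margins, the probability-based Freeman-Halton criterion).
    """
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValueError("table entries must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.sum(rows > 0) < 2 or np.sum(cols > 0) < 2:
        raise ValueError("both margins need >= 2 non-empty categories")
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return AssociationTestResult(
            "fisher", float(table[0, 0]), float(p), "two-sided", "exact"
        )
    obs_lp = _log_table_prob(table)
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(table.shape[0]), rows)
    col_labels = np.repeat(np.arange(table.shape[1]), cols)
    le = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        t = np.zeros_like(table)
        np.add.at(t, (row_labels, perm), 1)
        if _log_table_prob(t) <= obs_lp + 1e-9:
            le += 1
    return AssociationTestResult(
        "fisher", float(obs_lp), (le + 1) / (n_mc + 1), "two-sided", "monte_carlo"
    )


# ---------------------------------------------------------------------------
# (partial) Mantel
# ---------------------------------------------------------------------------


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], 1)
    return M[iu]


def _check_square(*Ms: np.ndarray) -> None:
    n = Ms[0].shape[0]
    for M in Ms:
        if M.shape != (n, n):
            raise ValueError("matrices must be square and matching")
        if not np.allclose(M, M.T, equal_nan=True):
            raise ValueError("matrices must be symmetric")


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    rab = np.corrcoef(a, b)[0, 1]
    rac = np.corrcoef(a, c)[0, 1]
    rbc = np.corrcoef(b, c)[0, 1]
    den = np.sqrt((1 - rac**2) * (1 - rbc**2))
    return float((rab - rac * rbc) / den)


def mantel(
    sim_a: np.ndarray,
    sim_b: np.ndarray,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> AssociationTestResult:
    """Simple Mantel test; one-sided P for positive association, permuting
    rows/columns of the first matrix jointly."""
    A, B = np.asarray(sim_a, float), np.asarray(sim_b, float)
    _check_square(A, B)
    a, b = _offdiag(A), _offdiag(B)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant matrix: Mantel statistic undefined")
    obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if np.corrcoef(_offdiag(A[np.ix_(perm, perm)]), b)[0, 1] >= obs:
            ge += 1
    return AssociationTestResult(
        "mantel", obs, (ge + 1) / (n_perm + 1), "one-sided", "monte_carlo"
    )


def partial_mantel(
    sim_a: np.ndarray,
    sim_b: np.ndarray,
    control: np.ndarray,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> AssociationTestResult:
    """Partial Mantel test: correlation of A and B off-diagonals controlling
    for the spatial distance matrix; the null permutes rows/columns of A
    jointly and recomputes the partial correlation. One-sided for positive
    association. A constant control matrix reduces this to the simple
    Mantel test."""
    A = np.asarray(sim_a, float)
    B = np.asarray(sim_b, float)
    C = np.asarray(control, float)
    _check_square(A, B, C)
    a, b, c = _offdiag(A), _offdiag(B), _offdiag(C)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant matrix: partial Mantel undefined")
    if c.std() == 0:
        res = mantel(sim_a, sim_b, n_perm=n_perm, seed=seed)
        return AssociationTestResult(
            "partial_mantel", res.statistic, res.p, "one-sided", "monte_carlo"
        )
    obs = _partial_r(a, b, c)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap = _offdiag(A[np.ix_(perm, perm)])
        if _partial_r(ap, b, c) >= obs:
            ge += 1
    return AssociationTestResult(
        "partial_mantel", obs, (ge + 1) / (n_perm + 1), "one-sided", "monte_carlo"
    )


# ---------------------------------------------------------------------------
# continental contrast and Spearman
# ---------------------------------------------------------------------------


def continental_ttest(group_a, group_b) -> AssociationTestResult:
    """Pooled-variance one-tailed Student t-test (H1: mean_a > mean_b),
    df = n_a + n_b - 2."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    if not np.isfinite(t):
        raise ValueError("zero pooled variance")
    return AssociationTestResult(
        "ttest",
        float(t),
        float(p),
        "one-sided",
        "analytic",
        {"mean_a": float(a.mean()), "mean_b": float(b.mean())},
        {"df": len(a) + len(b) - 2},
    )


def spearman_exact(x, y) -> AssociationTestResult:
    """Spearman rank correlation with midranks on ties.

    For n <= 10 the one-sided P is exact: the proportion of the n! rank
    permutations with rho at least as large as observed. Larger n falls
    back to the analytic approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector: Spearman undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= 10:
        count = 0
        total = 0
        rxc = rx - rx.mean()
        denom_x = np.sqrt(np.sum(rxc**2))
        for perm in itertools.permutations(ry):
            pv = np.asarray(perm)
            pc = pv - pv.mean()
            r = float(np.dot(rxc, pc) / (denom_x * np.sqrt(np.sum(pc**2))))
            if r >= obs - 1e-12:
                count += 1
            total += 1
        return AssociationTestResult(
            "spearman", obs, count / total, "one-sided", "exact", None, {"n_perm": total}
        )
    rho, p = stats.spearmanr(x, y, alternative="greater")
    return AssociationTestResult("spearman", float(rho), float(p), "one-sided", "analytic")
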