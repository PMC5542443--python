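"""Kinship correlograms and the Sp statistic.

Pairwise Loiselle kinship (multilocus ratio-of-sums, sample allele
frequencies as reference), distance-class construction with the standard
diagnostics (balanced pair counts, >50% of individuals per class,
coefficient of variation of per-individual representation < 1), the
regression of kinship on ln(distance) with a permutation test of the slope
and a delete-one-locus jackknife, and Sp = -b / (1 - F1) where F1 is the
mean kinship of the first distance class. The same machinery serves the
haploid (plastid) marker through a 0/1 dosage coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import GenotypeMatrix, HaplotypeSet, SpatialFrame

__all__ = [
    "KinshipMatrix",
    "DistanceClassScheme",
    "CorrelogramResult",
    "loiselle_kinship",
    "haploid_kinship",
    "build_distance_classes",
    "correlogram",
    "plastid_fsgs",
    "sp_statistic",
]


def sp_statistic(b: float, f1: float) -> float:
    """Sp = -b / (1 - F1): strength of fine-scale spatial genetic structure."""
    return -b / (1.0 - f1)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Pairwise kinship with per-locus components for the jackknife.

    ``numerator[l]`` and ``denominator[l]`` hold the locus-l contributions;
    ``valid[l]`` marks pairs co-typed at locus l. The multilocus value is
    the ratio of locus-summed numerators to denominators over valid loci.
    """

    individual_ids: list[str]
    numerator: np.ndarray  # (L, n, n)
    denominator: np.ndarray  # (L,)
    valid: np.ndarray  # (L, n, n) bool

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return self.numerator.shape[0]

    def multilocus(self, drop_locus: int | None = None) -> np.ndarray:
        """(n, n) multilocus F_ij; NaN where no co-typed locus remains."""
        keep = np.ones(self.n_loci, dtype=bool)
        if drop_locus is not None:
            keep[drop_locus] = False
        num = np.where(self.valid[keep], self.numerator[keep], 0.0).sum(axis=0)
        den = np.einsum("l,lij->ij", self.denominator[keep], self.valid[keep].astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            F = num / den
        F[den == 0] = np.nan
        return F


def _loiselle_locus(
    X: np.ndarray, ploidy: int = 2
) -> tuple[np.ndarray, float, np.ndarray]:
    """Single-locus Loiselle components from a dosage matrix X (n, A) with
    NaN rows for untyped individuals and rows summing to 1 (diploid: the
    two gene copies give dosages in {0, 1/2, 1}; haploid: {0, 1}).

    numerator_ij = sum_a (x_ia - p_a)(x_ja - p_a) + p_a (1-p_a) / (n_l - 1)
    denominator  = sum_a p_a (1 - p_a)
    with n_l the number of gene copies typed at the locus.
    """
    typed = ~np.isnan(X[:, 0])
    n_copies = typed.sum() * ploidy
    p = np.nanmean(X, axis=0)  # equals allele freq: dosages average to p
    D = X - p
    D0 = np.where(np.isnan(D), 0.0, D)
    num = D0 @ D0.T
    correction = float(np.sum(p * (1 - p))) / max(n_copies - 1, 1)
    num = num + correction
    den = float(np.sum(p * (1 - p)))
    valid = np.outer(typed, typed)
    return num, den, valid


def loiselle_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Loiselle et al. pairwise kinship for diploid data.

    Reference allele frequencies are the sample frequencies over all
    typed individuals; pairs with no co-typed locus get NaN downstream.
    """
    n = g.n_individuals
    nums = np.zeros((g.n_loci, n, n))
    dens = np.zeros(g.n_loci)
    valids = np.zeros((g.n_loci, n, n), dtype=bool)
    for l in range(g.n_loci):
        X, _ = g.dosage_matrix(l)
        if np.all(np.isnan(X)):
            continue
        num, den, valid = _loiselle_locus(X, ploidy=2)
        nums[l], dens[l], valids[l] = num, den, valid
    return KinshipMatrix(list(g.individual_ids), nums, dens, valids)


def haploid_kinship(h: HaplotypeSet) -> KinshipMatrix:
    """Single-locus Loiselle kinship for haploid haplotype data (dosage 0/1)."""
    labels = sorted({x for x in h.labels if x is not None})
    if len(labels) < 2:
        raise ValueError("monomorphic haplotypes: kinship undefined")
    idx = {a: j for j, a in enumerate(labels)}
    n = h.n_individuals
    X = np.full((n, len(labels)), np.nan)
    for i, lab in enumerate(h.labels):
        if lab is not None:
            X[i] = 0.0
            X[i, idx[lab]] = 1.0
    num, den, valid = _loiselle_locus(X, ploidy=1)
    return KinshipMatrix(
        list(h.individual_ids),
        num[None, :, :],
        np.array([den]),
        valid[None, :, :],
    )


# ---------------------------------------------------------------------------
# distance classes
# ---------------------------------------------------------------------------


@dataclass
class DistanceClassScheme:
    upper_bounds: np.ndarray  # ordered class upper bounds (metres)
    pair_class: np.ndarray  # (n, n) class index, -1 on diagonal
    pairs_per_class: np.ndarray
    pct_individuals: np.ndarray  # % of individuals represented in each class
    cv_participation: np.ndarray  # CV of per-individual pair counts per class
    accepted: bool
    report: str = ""

    @property
    def n_classes(self) -> int:
        return len(self.upper_bounds)


def build_distance_classes(s: SpatialFrame, n_classes: int) -> DistanceClassScheme:
    """Quantile-based distance classes with equal pair counts.

    Diagnostics follow the standard recommendations: similar pair counts
    per class, > 50% of individuals represented in each class, and a
    coefficient of variation < 1 of per-individual representation counts.
    A failing scheme is returned with ``accepted=False`` and a report,
    prompting a smaller ``n_classes``. Co-located pairs (distance 0) go to
    class 1.
    """
    n = s.n_individuals
    D = s.distances()
    iu = np.triu_indices(n, 1)
    d = D[iu]
    if n_classes > d.size:
        raise ValueError("more classes than pairs")
    if np.all(d == 0):
        scheme = DistanceClassScheme(
            np.array([0.0]),
            np.where(np.eye(n, dtype=bool), -1, 0),
            np.array([d.size]),
            np.array([100.0]),
            np.array([np.nan]),
            accepted=False,
            report="all locations identical: single degenerate class",
        )
        return scheme
    # rank-based split: order pairs by distance (stable on ties) and cut
    # into near-equal chunks, so pair counts balance even with tied distances
    order = np.argsort(d, kind="stable")
    edges = np.linspace(0, d.size, n_classes + 1).round().astype(int)
    cls_flat = np.empty(d.size, dtype=int)
    bounds = np.empty(n_classes)
    for c in range(n_classes):
        sel = order[edges[c] : edges[c + 1]]
        cls_flat[sel] = c
        bounds[c] = d[sel].max()
    pair_class = np.full((n, n), -1, dtype=int)
    pair_class[iu] = cls_flat
    pair_class[(iu[1], iu[0])] = cls_flat

    K = n_classes
    pairs_per_class = np.bincount(cls_flat, minlength=K)
    pct = np.zeros(K)
    cv = np.zeros(K)
    for k in range(K):
        part = np.zeros(n)
        mask = pair_class == k
        part = mask.sum(axis=1).astype(float)
        pct[k] = 100.0 * np.mean(part > 0)
        mu = part.mean()
        cv[k] = part.std() / mu if mu > 0 else np.nan

    problems = []
    if np.any(pct <= 50.0):
        problems.append("some class represents <= 50% of individuals")
    if np.any(cv >= 1.0):
        problems.append("per-individual representation CV >= 1 in some class")
    return DistanceClassScheme(
        bounds,
        pair_class,
        pairs_per_class,
        pct,
        cv,
        accepted=not problems,
        report="; ".join(problems),
    )


# ---------------------------------------------------------------------------
# correlogram / Sp
# ---------------------------------------------------------------------------


@dataclass
class CorrelogramResult:
    class_bounds: np.ndarray
    class_mean_f: np.ndarray
    class_jackknife_se: np.ndarray
    f1: float
    b: float  # jackknife mean of the slope (plain slope if 1 locus)
    b_obs: float  # slope from the full multilocus kinship
    b_se: float
    p_slope: float  # one-sided permutation P for b < 0
    sp: float
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    n_perm: int
    n_zero_distance_pairs: int = 0
    small_sample_warning: str | None = None
    per_locus_b: np.ndarray | None = None


def _slope(F: np.ndarray, lnD: np.ndarray, mask: np.ndarray) -> float:
    f = F[mask]
    x = lnD[mask]
    xc = x - x.mean()
    return float(np.sum(xc * (f - f.mean())) / np.sum(xc * xc))


def correlogram(
    k: KinshipMatrix,
    s: SpatialFrame,
    scheme: DistanceClassScheme,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> CorrelogramResult:
    """Kinship correlogram, slope on ln(distance), permutation test and Sp.

    The slope b is the OLS regression of pairwise F_ij on the natural log
    of distance over all pairs with d > 0 and a defined F_ij. Zero-distance
    pairs (e.g. clones) are excluded from the regression but included in
    the first class mean; their count is reported. The permutation test
    shuffles whole individuals over spatial positions and is one-sided for
    b < 0. The jackknife deletes one locus at a time.
    """
    if k.individual_ids != s.individual_ids:
        raise ValueError("kinship and spatial frame ids differ (join first)")
    n = k.n_individuals
    D = s.distances()
    F = k.multilocus()
    iu = np.triu_indices(n, 1)
    cls = scheme.pair_class[iu]
    if scheme.n_classes < 2:
        raise ValueError("fewer than 2 usable distance classes")

    d = D[iu]
    f = F[iu]
    defined = ~np.isnan(f)
    nz = d > 0
    reg_mask = defined & nz
    n_zero = int(np.sum(defined & ~nz))
    with np.errstate(divide="ignore"):
        lnd = np.where(nz, np.log(d), 0.0)

    b_obs = _slope(f, lnd, reg_mask)

    # class means (zero-distance pairs included)
    K = scheme.n_classes
    class_mean = np.array(
        [np.nanmean(f[cls == c]) if np.any(cls == c) else np.nan for c in range(K)]
    )
    f1 = float(class_mean[0])

    # jackknife over loci
    L = k.n_loci
    warn = None
    if L >= 2:
        b_del = np.empty(L)
        cm_del = np.empty((L, K))
        for l in range(L):
            Fl = k.multilocus(drop_locus=l)[iu]
            ml = reg_mask & ~np.isnan(Fl)
            b_del[l] = _slope(Fl, lnd, ml)
            for c in range(K):
                sel = (cls == c) & ~np.isnan(Fl)
                cm_del[l, c] = np.nanmean(Fl[sel]) if sel.any() else np.nan
        b_jack = float(L * b_obs - (L - 1) * b_del.mean())
        b_se = float(np.sqrt((L - 1) / L * np.sum((b_del - b_del.mean()) ** 2)))
        cm_se = np.sqrt((L - 1) / L * np.sum((cm_del - cm_del.mean(axis=0)) ** 2, axis=0))
        if L <= 3:
            warn = f"jackknife SE based on only {L} loci"
        per_locus_b = b_del
    else:
        b_jack, b_se = b_obs, float("nan")
        cm_se = np.full(K, np.nan)
        warn = "single locus: jackknife SE undefined"
        per_locus_b = None

    # permutation of individuals over positions
    rng = np.random.default_rng(seed)
    le = 0
    env = np.empty((n_perm, K))
    for p in range(n_perm):
        perm = rng.permutation(n)
        Dp = D[np.ix_(perm, perm)][iu]
        nzp = Dp > 0
        with np.errstate(divide="ignore"):
            lndp = np.where(nzp, np.log(Dp), 0.0)
        clsp = scheme.pair_class[np.ix_(perm, perm)][iu]
        mp = defined & nzp
        bp = _slope(f, lndp, mp)
        if bp <= b_obs:
            le += 1
        for c in range(K):
            sel = clsp == c
            env[p, c] = np.nanmean(f[sel]) if sel.any() else np.nan
    p_slope = (le + 1) / (n_perm + 1)
    env_low = np.nanpercentile(env, 2.5, axis=0) if n_perm else np.full(K, np.nan)
    env_high = np.nanpercentile(env, 97.5, axis=0) if n_perm else np.full(K, np.nan)

    b_rep = b_jack
    return CorrelogramResult(
        scheme.upper_bounds,
        class_mean,
        cm_se,
        f1,
        b_rep,
        b_obs,
        b_se,
        p_slope,
        sp_statistic(b_rep, f1),
        env_low,
        env_high,
        n_perm,
        n_zero,
        warn,
        per_locus_b,
    )


def plastid_fsgs(
    h: HaplotypeSet,
    s: SpatialFrame,
    scheme: DistanceClassScheme,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> CorrelogramResult:
    """FSGS analysis of the maternally inherited haploid marker.

    Raises ValueError on monomorphic haplotypes (reported as not
    calculable, as for a population fixed for one haplotype).
    """
    k = haploid_kinship(h)
    return correlogram(k, s, scheme, n_perm=n_perm, seed=seed)
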