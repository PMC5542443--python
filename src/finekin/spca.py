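"""Spatially weighted principal component analysis with G and L tests.

The decomposition diagonalises C = X' (W + W') X / (2n), where X is the
allele-frequency-centred dosage matrix and W a row-normalised spatial
weight matrix. Positive eigenvalues capture variance with positive spatial
autocorrelation ("global" structure: clines, patches); negative eigenvalues
capture local, anti-correlated structure. The G statistic is the positive
eigenvalue mass and the L statistic the absolute negative mass; both are
tested by permuting genotype rows over locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_model import GenotypeMatrix, SpatialFrame

__all__ = [
    "ConnectionNetwork",
    "SpcaResult",
    "GLTestResult",
    "build_network",
    "spca",
    "g_l_tests",
    "dosage_columns",
]


@dataclass
class ConnectionNetwork:
    weights: np.ndarray  # symmetric 0/1 adjacency, zero diagonal
    row_normalized: bool
    n_components: int
    rule: str

    @property
    def n_individuals(self) -> int:
        return self.weights.shape[0]

    def operator(self) -> np.ndarray:
        """Row-normalised weight matrix used in the Moran operator."""
        W = self.weights.astype(float)
        if self.row_normalized:
            rs = W.sum(axis=1, keepdims=True)
            rs[rs == 0] = 1.0
            W = W / rs
        return W


def build_network(
    s: SpatialFrame,
    rule: str = "knn",
    k: int = 10,
    threshold: float | None = None,
) -> ConnectionNetwork:
    """Build the spatial connection network.

    Rules: ``knn`` (k nearest neighbours, symmetrised by union; default
    k=10), ``distance`` (edges below *threshold* metres), ``gabriel``
    (no third point inside the diametral circle of the pair). A
    disconnected graph is allowed; the component count is reported.
    """
    n = s.n_individuals
    if n < 3:
        raise ValueError("need at least 3 individuals")
    D = s.distances()
    A = np.zeros((n, n), dtype=bool)
    if rule == "knn":
        k_eff = min(k, n - 1)
        order = np.argsort(D + np.where(np.eye(n, dtype=bool), np.inf, 0.0), axis=1)
        for i in range(n):
            A[i, order[i, :k_eff]] = True
        A = A | A.T
    elif rule == "distance":
        if threshold is None:
            raise ValueError("distance rule needs a threshold")
        A = (D <= threshold) & ~np.eye(n, dtype=bool)
    elif rule == "gabriel":
        D2 = D**2
        for i in range(n):
            for j in range(i + 1, n):
                if not np.any(np.delete(D2[i] + D2[j], [i, j]) < D2[i, j]):
                    A[i, j] = A[j, i] = True
    else:
        raise ValueError(f"unknown rule {rule!r}")
    np.fill_diagonal(A, False)
    ncomp = nx.number_connected_components(nx.from_numpy_array(A))
    return ConnectionNetwork(A.astype(float), True, ncomp, rule)


def dosage_columns(g: GenotypeMatrix) -> np.ndarray:
    """Stacked centred dosage matrix over all allele columns.

    Missing genotypes are mean-imputed per allele column before centring,
    so untyped individuals sit at the column mean (zero contribution).
    """
    cols = []
    for l in range(g.n_loci):
        X, _ = g.dosage_matrix(l)
        mu = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), mu, X)
        cols.append(X - mu)
    return np.hstack(cols)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray  # sorted descending (positive first)
    scores: np.ndarray  # (n, n_axes) individual scores X v
    axes: np.ndarray  # (A, n_axes) eigenvectors
    eig_spca: float  # leading positive eigenvalue

    @property
    def positive(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > 0]

    @property
    def negative(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def _spca_eigs(X: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    C = X.T @ (W + W.T) @ X / (2.0 * n)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def spca(
    g: GenotypeMatrix, w: ConnectionNetwork, s: SpatialFrame | None = None
) -> SpcaResult:
    """Spatial PCA of the centred dosage matrix.

    The sign of each axis is fixed by making the score's correlation with
    the x-coordinate non-negative when a SpatialFrame is supplied (scores
    are otherwise sign-arbitrary, as in any eigen decomposition).
    """
    X = dosage_columns(g)
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 allele columns")
    vals, vecs = _spca_eigs(X, w.operator())
    scores = X @ vecs
    if s is not None:
        xc = s.x - s.x.mean()
        for j in range(scores.shape[1]):
            if np.dot(scores[:, j], xc) < 0:
                scores[:, j] *= -1
                vecs[:, j] *= -1
    eig1 = float(vals[vals > 0][0]) if np.any(vals > 0) else 0.0
    return SpcaResult(vals, scores, vecs, eig1)


@dataclass
class GLTestResult:
    g_stat: float
    g_p: float
    l_stat: float
    l_p: float
    n_perm: int


def g_l_tests(
    g: GenotypeMatrix,
    w: ConnectionNetwork,
    n_perm: int = 999,
    seed: int | None = None,
) -> GLTestResult:
    """Monte-Carlo tests for global (G) and local (L) spatial structure.

    G = positive eigenvalue mass, L = absolute negative mass of the sPCA
    operator; the null permutes genotype rows over locations. One-sided
    P-values, (extreme+1)/(n_perm+1).
    """
    if n_perm < 99:
        import warnings

        warnings.warn("n_perm < 99 gives a coarse Monte-Carlo P", stacklevel=2)
    X = dosage_columns(g)
    W = w.operator()
    vals, _ = _spca_eigs(X, W)
    g_obs = float(vals[vals > 0].sum())
    l_obs = float(-vals[vals < 0].sum())
    rng = np.random.default_rng(seed)
    g_ge = l_ge = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(X.shape[0])]
        v, _ = _spca_eigs(Xp, W)
        if v[v > 0].sum() >= g_obs:
            g_ge += 1
        if -v[v < 0].sum() >= l_obs:
            l_ge += 1
    return GLTestResult(
        g_obs,
        (g_ge + 1) / (n_perm + 1),
        l_obs,
        (l_ge + 1) / (n_perm + 1),
        n_perm,
    )
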