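"""Cross-peak multivariate analyses per retention range.

Distances between samples (Bray-Curtis by default) feed two PERMANOVA
designs: Analysis I tests overall differences among lines; Analysis II,
run after excluding the domesticated line, partitions variation into
locality of origin and line nested within locality with sequential sums
of squares. Significant locality effects are visualised by reducing the
peak table with PCA (to fewer components than the smallest locality's
sample size) and running linear discriminant analysis on the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .peak_io import PeakTable


@dataclass
class DistanceMatrix:
    ids: list
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or len(self.ids) != m.shape[0]:
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m


def distance_matrix(table: PeakTable, metric: str = "braycurtis", log1p: bool = False) -> DistanceMatrix:
    """Pairwise sample dissimilarities over the table's peaks.

    Bray-Curtis (default, scale-invariant under common rescaling) or
    Euclidean; optionally log1p-transform areas first. Samples with zero
    total area are rejected.
    """
    X = table.areas.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (X.sum(axis=1) <= 0).any():
        bad = table.areas.index[X.sum(axis=1) <= 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    if log1p:
        X = np.log1p(X)
    metric_name = {"bray-curtis": "braycurtis", "bray_curtis": "braycurtis"}.get(metric, metric)
    d = squareform(pdist(X, metric=metric_name))
    return DistanceMatrix(list(table.areas.index), d, metric_name)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto col(x); x may be rank-deficient (redundant dummies)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > s[0] * 1e-10
    u = u[:, keep]
    return u @ u.T


def _design(levels) -> np.ndarray:
    levels = pd.Categorical(levels)
    return pd.get_dummies(levels).to_numpy(float)


@dataclass
class PermanovaTable:
    """Per-term pseudo-F decomposition with permutation p values."""

    terms: pd.DataFrame
    n_permutations: int
    seed: int | None


def _term_stats(g: np.ndarray, designs: list[np.ndarray], dfs: list[int]):
    """Sequential SS and pseudo-F per term from cumulative hat matrices."""
    n = g.shape[0]
    total_ss = float(np.trace(g))
    prev = np.ones((n, 1))
    h_prev = _hat(prev)
    ss_terms = []
    cum_cols = prev
    for x in designs:
        cum_cols = np.hstack([cum_cols, x])
        h = _hat(cum_cols)
        ss_terms.append(float(np.trace(h @ g)) - float(np.trace(h_prev @ g)))
        h_prev = h
    ss_res = total_ss - float(np.trace(h_prev @ g))
    df_res = n - int(np.linalg.matrix_rank(cum_cols))
    if df_res <= 0:
        raise ValueError("residual degrees of freedom is zero")
    fs = [
        (ss / df) / (ss_res / df_res) if df > 0 else np.nan
        for ss, df in zip(ss_terms, dfs)
    ]
    return ss_terms, ss_res, df_res, fs, total_ss


def permanova(
    dist: DistanceMatrix,
    factors: pd.DataFrame | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaTable:
    """PERMANOVA with sequential sums of squares.

    *factors* is a Series (one factor: differences among lines) or a
    DataFrame whose column order defines the sequential decomposition —
    for the nested locality design pass columns ``[locality, line]``:
    locality enters first and line-within-locality absorbs what remains.
    P values come from free permutation of sample rows, counting
    permuted pseudo-F >= observed with the +1 correction.
    """
    if isinstance(factors, pd.Series):
        factors = factors.to_frame()
    factors = factors.loc[dist.ids]
    d = dist.matrix
    n = d.shape[0]
    g = _gower_center(d)

    designs, dfs, names = [], [], []
    cum = np.ones((n, 1))
    for col in factors.columns:
        x = _design(factors[col])
        new = np.hstack([cum, x])
        dfs.append(int(np.linalg.matrix_rank(new)) - int(np.linalg.matrix_rank(cum)))
        designs.append(x)
        names.append(str(col))
        cum = new

    ss_terms, ss_res, df_res, fs, total_ss = _term_stats(g, designs, dfs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(designs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        g_perm = g[np.ix_(perm, perm)]
        _, _, _, fs_perm, _ = _term_stats(g_perm, designs, dfs)
        exceed += np.asarray(fs_perm) >= np.asarray(fs)
    p = (exceed + 1) / (n_perm + 1)

    terms = pd.DataFrame(
        {
            "term": names + ["residual"],
            "df": dfs + [df_res],
            "ss": ss_terms + [ss_res],
            "pseudo_F": fs + [np.nan],
            "p": list(p) + [np.nan],
        }
    )
    terms.attrs["total_ss"] = total_ss
    return PermanovaTable(terms, n_perm, seed)


def pca_reduce(table: PeakTable, k: int, log1p: bool = False):
    """Centered (unscaled) PCA scores on *k* components.

    With *log1p* the areas are log(1+x)-transformed first, putting the
    ordination on the scale where abundance effects are additive.
    Returns (scores DataFrame, explained-variance fractions).
    """
    X = table.areas.to_numpy(float)
    if log1p:
        X = np.log1p(X)
    if not 0 < k < min(X.shape):
        raise ValueError(f"k={k} must be in 1..{min(X.shape) - 1}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=table.areas.index, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class LdaSummary:
    """Group centroids with standard errors on the discriminant axes."""

    centroids: pd.DataFrame
    centroid_se: pd.DataFrame
    explained: np.ndarray
    scores: pd.DataFrame


def lda_localities(scores: pd.DataFrame, groups) -> LdaSummary:
    """Fisher LDA of PCA scores against locality.

    Returns per-locality centroids +/- standard errors on each
    discriminant axis and the per-axis share of between-group variance.
    """
    groups = pd.Series(np.asarray(groups), index=scores.index)
    counts = groups.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    lda = LinearDiscriminantAnalysis(solver="eigen")
    try:
        z = lda.fit_transform(scores.to_numpy(float), groups.to_numpy())
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular within-group scatter; reduce the number of PCs") from exc
    axes = [f"LD{i + 1}" for i in range(z.shape[1])]
    zdf = pd.DataFrame(z, index=scores.index, columns=axes)
    cent = zdf.groupby(groups).mean()
    se = zdf.groupby(groups).std(ddof=1).div(np.sqrt(counts), axis=0)
    explained = np.asarray(lda.explained_variance_ratio_[: len(axes)], dtype=float)
    explained = explained / explained.sum()
    return LdaSummary(cent, se, explained, zdf)
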