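"""Comparative statistics of gene-cluster-family presence/absence profiles.

Implements the beta-diversity partition of Sorensen dissimilarity into
turnover and nestedness components (pairwise and multiple-site forms),
Jaccard profile dissimilarity, principal coordinates analysis, patristic
(cophenetic) distances from a phylogeny, Mantel and PERMANOVA permutation
tests, and a partial F-test for nuisance covariates such as assembly N50.

All permutation procedures are seeded and deterministic; the Mantel test is
one-tailed for positive association, and p-values use the add-one rule
p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "BetaPartition",
    "DissimilarityMatrix",
    "MantelResult",
    "PcoaResult",
    "PermanovaResult",
    "PhyloPCs",
    "beta_pairwise",
    "beta_multisite",
    "jaccard_matrix",
    "pcoa",
    "cophenetic_distances",
    "mantel",
    "phylo_pcs",
    "permanova",
    "partial_f_test",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class BetaPartition:
    """Sorensen dissimilarity split into turnover and nestedness.

    beta_sor = beta_sim + beta_sne always holds; ``scope`` records whether the
    values are for one site pair or the multiple-site generalization.
    """

    beta_sor: float
    beta_sim: float
    beta_sne: float
    scope: str  # "pairwise" | "multisite"

    def __post_init__(self) -> None:
        for v in (self.beta_sor, self.beta_sim, self.beta_sne):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"beta component {v} outside [0, 1]")


class DissimilarityMatrix:
    """Symmetric zero-diagonal dissimilarity over labelled objects."""

    def __init__(self, data, labels=None, *, _validate: bool = True):
        if isinstance(data, pd.DataFrame):
            labels = list(data.index) if labels is None else list(labels)
            data = data.to_numpy(dtype=float)
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
        if len(labels) != arr.shape[0]:
            raise ValueError("label count does not match matrix size")
        if _validate:
            if not np.allclose(arr, arr.T, atol=1e-12, rtol=0.0):
                raise ValueError("matrix is not symmetric")
            if np.any(np.abs(np.diag(arr)) > 1e-12):
                raise ValueError("matrix diagonal is not zero")
            if np.any(arr < -1e-12):
                raise ValueError("negative dissimilarity")
        self.values = 0.5 * (arr + arr.T)
        np.fill_diagonal(self.values, 0.0)
        self.labels = [str(x) for x in labels]

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels) -> "DissimilarityMatrix":
        idx = [self.labels.index(str(x)) for x in labels]
        return DissimilarityMatrix(
            self.values[np.ix_(idx, idx)], labels, _validate=False
        )

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None = None


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


@dataclass(frozen=True)
class PermanovaResult:
    table: pd.DataFrame  # index: terms + Residual + Total; df, SS, R2, F, p
    n_perm: int
    seed: int | None = None

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


@dataclass(frozen=True)
class PhyloPCs:
    scores: pd.DataFrame  # taxa x PCs
    variance_fractions: np.ndarray
    k: int

    @property
    def selected(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.k]


# ---------------------------------------------------------------------------
# beta diversity


def beta_pairwise(site_a, site_b) -> BetaPartition:
    """Partition pairwise Sorensen dissimilarity into turnover + nestedness.

    With a = |A∩B|, b = |A\\B|, c = |B\\A|:
    beta_sor = (b+c)/(2a+b+c), beta_sim = min(b,c)/(a+min(b,c)),
    beta_sne = beta_sor - beta_sim.
    """
    A, B = set(site_a), set(site_b)
    if not A and not B:
        raise ValueError("both sites are empty")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    m = min(b, c)
    sor = (b + c) / (2 * a + b + c) if (b or c) else 0.0
    sim = m / (a + m) if m else 0.0
    return BetaPartition(sor, sim, sor - sim, scope="pairwise")


def _as_binary_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        arr = matrix.to_numpy()
    else:
        arr = np.asarray(matrix)
        labels = [str(i) for i in range(arr.shape[0])]
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("matrix is not binary (0/1)")
    return arr.astype(bool), labels


def beta_multisite(matrix) -> BetaPartition:
    """Multiple-site Sorensen partition over a sites x items binary matrix.

    beta_SIM = S_min / (richness_excess + S_min) and
    beta_SOR = (S_min + S_max) / (2 * richness_excess + S_min + S_max),
    where richness_excess = sum_i S_i - S_T, S_min = sum_{i<j} min(b_ij, b_ji)
    and S_max the corresponding sum of maxima of the asymmetric unique-item
    counts b_ij = |site_i \\ site_j|.
    """
    arr, _ = _as_binary_matrix(matrix)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("multisite partition needs at least 2 sites")
    if not arr.any():
        raise ValueError("all-zero presence-absence matrix")
    S_i = arr.sum(axis=1)
    S_T = arr.any(axis=0).sum()
    excess = int(S_i.sum() - S_T)
    s_min = 0
    s_max = 0
    for i, j in itertools.combinations(range(n), 2):
        b_ij = int((arr[i] & ~arr[j]).sum())
        b_ji = int((arr[j] & ~arr[i]).sum())
        s_min += min(b_ij, b_ji)
        s_max += max(b_ij, b_ji)
    if s_min + s_max == 0:
        return BetaPartition(0.0, 0.0, 0.0, scope="multisite")
    sim = s_min / (excess + s_min) if s_min else 0.0
    sor = (s_min + s_max) / (2 * excess + s_min + s_max)
    return BetaPartition(sor, sim, sor - sim, scope="multisite")


def jaccard_matrix(pa_matrix) -> DissimilarityMatrix:
    """Jaccard dissimilarity (1 - |∩|/|∪|) between the rows of a binary matrix."""
    arr, labels = _as_binary_matrix(pa_matrix)
    x = arr.astype(np.float64)
    inter = x @ x.T
    row = x.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    if np.any((union == 0) & ~np.eye(len(x), dtype=bool)):
        warnings.warn("two empty profiles: Jaccard dissimilarity set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, labels, _validate=False)


# ---------------------------------------------------------------------------
# ordination


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d * d
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def pcoa(D: DissimilarityMatrix) -> PcoaResult:
    """Principal coordinates analysis of a dissimilarity matrix.

    Gower-centers -d^2/2, eigendecomposes, and returns coordinates scaled by
    sqrt(eigenvalue) for positive eigenvalues only. Negative eigenvalues
    (non-Euclidean input) are reported unaltered, never corrected. Axis signs
    follow the convention that the first nonzero loading is positive.
    """
    if not isinstance(D, DissimilarityMatrix):
        D = DissimilarityMatrix(D)
    g = _gower_center(D.values)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals).max()) if evals.size else 0.0
    keep = evals > tol
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    for k in range(coords.shape[1]):
        nz = np.nonzero(np.abs(coords[:, k]) > 1e-12)[0]
        if nz.size and coords[nz[0], k] < 0:
            coords[:, k] *= -1.0
    frame = pd.DataFrame(
        coords,
        index=D.labels,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(coordinates=frame, eigenvalues=evals)


def cophenetic_distances(tree) -> DissimilarityMatrix:
    """Patristic distance matrix (path length between tips) from a newick tree.

    `tree` may be a newick string, a path to a newick file, or a dendropy Tree.
    Every non-root edge must carry a branch length.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if "(" not in text:  # treat as path
            with open(text) as fh:
                text = fh.read()
        t = dendropy.Tree.get(data=text, schema="newick")
    root = t.seed_node
    for edge in t.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else f"internal node {id(head)}"
            raise ValueError(f"missing branch length on edge above {name!r}")
    del root
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DissimilarityMatrix(d, [x.label for x in taxa], _validate=False)


# ---------------------------------------------------------------------------
# permutation tests


def _check_aligned(D1: DissimilarityMatrix, D2: DissimilarityMatrix) -> None:
    if D1.labels != D2.labels:
        raise ValueError("matrix labels differ or are ordered differently")


def mantel(
    D1,
    D2,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    exact: bool = False,
) -> MantelResult:
    """One-tailed Mantel test of positive matrix association.

    r is the Pearson correlation of the upper triangles; the null distribution
    jointly permutes rows and columns of ``D2``. ``exact=True`` enumerates all
    permutations instead of sampling (small n only).
    """
    if not isinstance(D1, DissimilarityMatrix):
        D1 = DissimilarityMatrix(D1)
    if not isinstance(D2, DissimilarityMatrix):
        D2 = DissimilarityMatrix(D2)
    _check_aligned(D1, D2)
    n = len(D1)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 objects")
    iu = np.triu_indices(n, k=1)
    x = D1.values[iu]

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        xs, ys = x - x.mean(), y - y.mean()
        denom = np.sqrt((xs @ xs) * (ys @ ys))
        if denom == 0:
            raise ValueError("constant distance matrix: correlation undefined")
        return float((xs @ ys) / denom)

    r_obs = corr(D2.values)
    if exact:
        perms = [p for p in itertools.permutations(range(n)) if p != tuple(range(n))]
        n_perm = len(perms)
        hits = sum(
            corr(D2.values[np.ix_(p, p)]) >= r_obs - 1e-12 for p in perms
        )
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            if corr(D2.values[np.ix_(p, p)]) >= r_obs - 1e-12:
                hits += 1
    return MantelResult(r=r_obs, p=(1 + hits) / (1 + n_perm), n_perm=n_perm, seed=seed)


def phylo_pcs(
    D_phylo, var_threshold: float = 0.8, *, double_center: bool = False
) -> PhyloPCs:
    """PCA of a phylogenetic distance matrix, rows treated as observations.

    Retains the smallest k principal components whose cumulative variance
    fraction reaches ``var_threshold``. With ``double_center=True`` the matrix
    is Gower-centered first (PCoA-equivalent geometry) instead of treating
    distance-matrix rows as raw feature vectors.
    """
    if not isinstance(D_phylo, DissimilarityMatrix):
        D_phylo = DissimilarityMatrix(D_phylo)
    if double_center:
        X = _gower_center(D_phylo.values)
    else:
        X = D_phylo.values - D_phylo.values.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = u * s
    for k in range(scores.shape[1]):
        nz = np.nonzero(np.abs(scores[:, k]) > 1e-12)[0]
        if nz.size and scores[nz[0], k] < 0:
            scores[:, k] *= -1.0
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k = max(1, min(k, len(frac)))
    frame = pd.DataFrame(
        scores, index=D_phylo.labels, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    return PhyloPCs(scores=frame, variance_fractions=frac, k=k)


def _hat(X: np.ndarray) -> np.ndarray:
    # pinv-based hat matrix; X has full column rank (checked by caller)
    return X @ np.linalg.pinv(X)


def permanova(
    D,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    exact: bool = False,
) -> PermanovaResult:
    """Distance-based PERMANOVA with sequential (Type-I) sums of squares.

    Mirrors `adonis2`-style models D ~ x1 + x2 + ...: the distance matrix is
    Gower-centered to G, each term's SS is tr(H_k G) - tr(H_{k-1} G) for the
    nested hat matrices of the design grown one covariate at a time, and
    pseudo-F values are referred to a permutation distribution obtained by
    jointly permuting rows and columns of D.
    """
    if not isinstance(D, DissimilarityMatrix):
        D = DissimilarityMatrix(D)
    cov = pd.DataFrame(covariates)
    if list(map(str, cov.index)) != D.labels:
        raise ValueError("covariate rows do not match distance-matrix labels")
    n = len(D)
    terms = list(cov.columns)
    X = np.column_stack([np.ones(n)] + [cov[t].to_numpy(dtype=float) for t in terms])
    for k in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : k + 1]) <= np.linalg.matrix_rank(X[:, :k]):
            raise ValueError(f"covariate {terms[k - 1]!r} is collinear with earlier terms")

    hats = [_hat(X[:, : k + 1]) for k in range(len(terms) + 1)]  # hats[0] = intercept
    df_res = n - 1 - len(terms)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def decompose(g: np.ndarray) -> tuple[np.ndarray, float, float]:
        tr = np.array([float(np.sum(h * g.T)) for h in hats])  # tr(H G)
        ss_terms = np.diff(tr)
        ss_total = float(np.trace(g))
        ss_res = ss_total - tr[-1]
        return ss_terms, ss_res, ss_total

    g_obs = _gower_center(D.values)
    ss_terms, ss_res, ss_total = decompose(g_obs)
    f_obs = (ss_terms / 1.0) / (ss_res / df_res)

    def perm_f(p) -> np.ndarray:
        gp = g_obs[np.ix_(p, p)]
        st, sr, _ = decompose(gp)
        return (st / 1.0) / (sr / df_res)

    if exact:
        perms = [p for p in itertools.permutations(range(n)) if p != tuple(range(n))]
        n_perm = len(perms)
        hits = np.zeros(len(terms))
        for p in perms:
            hits += perm_f(np.array(p)) >= f_obs - 1e-12
    else:
        rng = np.random.default_rng(seed)
        hits = np.zeros(len(terms))
        for _ in range(n_perm):
            hits += perm_f(rng.permutation(n)) >= f_obs - 1e-12
    pvals = (1 + hits) / (1 + n_perm)

    rows = []
    for i, t in enumerate(terms):
        rows.append((t, 1, ss_terms[i], ss_terms[i] / ss_total, f_obs[i], pvals[i]))
    rows.append(("Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "R2", "F", "p"]
    ).set_index("term")
    return PermanovaResult(table=table, n_perm=n_perm, seed=seed)


def partial_f_test(response, predictor, covariates=None):
    """Partial F-test for a predictor on top of nuisance covariates.

    Fits nested least-squares models (intercept + covariates, then + predictor)
    and returns (F, p, (df_num, df_den)). Used e.g. to test whether assembly
    fragmentation (N50) affects the number of detected gene clusters.
    """
    y = np.asarray(response, dtype=float).ravel()
    n = y.size
    pred = np.atleast_2d(np.asarray(predictor, dtype=float))
    if pred.shape[0] != n:
        pred = pred.T
    parts = [np.ones((n, 1))]
    if covariates is not None:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        parts.append(c)
    X0 = np.column_stack(parts)
    X1 = np.column_stack([X0, pred])
    q = pred.shape[1]
    p1 = X1.shape[1]
    if n <= p1:
        raise ValueError("too few observations for the requested model")
    if np.linalg.matrix_rank(X1) < p1:
        raise ValueError("singular design matrix")

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss0, rss1 = rss(X0), rss(X1)
    df_den = n - p1
    if rss1 <= max(1e-300, 1e-14 * rss0):
        return float("inf"), 0.0, (q, df_den)
    F = ((rss0 - rss1) / q) / (rss1 / df_den)
    F = max(F, 0.0)
    p = float(_sps.f.sf(F, q, df_den))
    return F, p, (q, df_den)
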