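"""Distance matrices, ordination, and permutation statistics.

This module holds the shared machinery used by every analysis stage:
a labelled :class:`DistanceMatrix` container, principal coordinates
analysis (PCoA), UPGMA clustering, the Mantel test, congruence among
distance matrices (CADM, Kendall's W), Benjamini–Hochberg adjustment,
and a seeded permutation engine with optional strata.

Permutation p-values everywhere follow the convention
``p = (1 + b) / (1 + n_perm)`` where ``b`` counts permuted statistics at
least as extreme as the observed one, so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DistanceMatrix",
    "EigenvectorSet",
    "MantelResult",
    "CadmResult",
    "PermutationResult",
    "UpgmaTree",
    "pcoa",
    "upgma",
    "mantel",
    "cadm",
    "bh_adjust",
    "permuted_indices",
    "permutation_test",
    "permutation_pvalue",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """A symmetric, hollow, nonnegative dissimilarity matrix with labels.

    Parameters
    ----------
    labels : sequence of str
        Object identifiers, one per row/column.
    values : (n, n) ndarray
        Dissimilarities. Must be symmetric with a zero diagonal and no
        negative entries. Infinite entries are rejected unless
        ``allow_infinite=True`` (used e.g. for Nei distances between
        populations fixed for different alleles).
    """

    labels: list[str]
    values: np.ndarray
    allow_infinite: bool = False

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if np.any(np.isnan(self.values)):
            raise ValueError("distance matrix contains NaN")
        if not self.allow_infinite and np.any(np.isinf(self.values)):
            i, j = np.argwhere(np.isinf(self.values))[0]
            raise ValueError(
                f"infinite distance between {self.labels[i]!r} and {self.labels[j]!r}"
            )
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T],
            self.values.T[finite & finite.T],
            rtol=1e-10,
            atol=1e-12,
        ) or np.any(np.isinf(self.values) != np.isinf(self.values.T)):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values[finite] < 0):
            raise ValueError("distance matrix has negative entries")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries, row-major (the order of ``pdist``)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(str(l)) for l in labels]
        return DistanceMatrix(
            [self.labels[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            allow_infinite=self.allow_infinite,
        )

    def capped(self, cap: float) -> "DistanceMatrix":
        """Replace infinite entries by ``cap`` (for downstream ordination)."""
        vals = np.where(np.isinf(self.values), cap, self.values)
        return DistanceMatrix(self.labels, vals)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, allow_infinite: bool = False) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), allow_infinite)


@dataclass
class EigenvectorSet:
    """Positive-eigenvalue ordination axes (PCoA scores).

    ``vectors`` columns are mutually orthogonal and scaled so column *i*
    has norm ``sqrt(eigenvalues[i])``; eigenvalues are strictly positive
    and descending.
    """

    labels: list[str]
    vectors: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if not self.names:
            self.names = [f"Axis{i + 1}" for i in range(self.vectors.shape[1])]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def renamed(self, prefix: str) -> "EigenvectorSet":
        return EigenvectorSet(
            self.labels,
            self.vectors,
            self.eigenvalues,
            [f"{prefix}{i + 1}" for i in range(self.k)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=self.labels, columns=self.names)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass
class CadmResult:
    W: float
    chi2: float
    p: float
    n_perm: int


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def _gower_center(d2: np.ndarray) -> np.ndarray:
    """Gower-center -0.5 * D^2: B = -1/2 J D^2 J with J = I - 11'/n."""
    a = -0.5 * d2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(D: DistanceMatrix, neg_policy: str = "drop") -> EigenvectorSet:
    """Principal coordinates analysis of a distance matrix.

    Retains only positive-eigenvalue axes; axis *i* is scaled to norm
    ``sqrt(lambda_i)`` and its sign fixed so the largest-magnitude
    loading is positive.

    Parameters
    ----------
    neg_policy : {"drop", "error"}
        ``"drop"`` silently discards negative-eigenvalue axes (the
        default; no Lingoes/Cailliez correction). ``"error"`` raises if
        the matrix is non-Euclidean beyond numerical noise.
    """
    if neg_policy not in ("drop", "error"):
        raise ValueError(f"unknown neg_policy {neg_policy!r}")
    if np.any(np.isinf(D.values)):
        i, j = np.argwhere(np.isinf(D.values))[0]
        raise ValueError(
            f"cannot ordinate: infinite distance between "
            f"{D.labels[i]!r} and {D.labels[j]!r}"
        )
    b = _gower_center(D.values**2)
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = max(abs(lam[0]), abs(lam[-1]), 1.0) * 1e-10
    if neg_policy == "error" and lam[-1] < -tol:
        raise ValueError(
            f"non-Euclidean distance matrix: smallest eigenvalue {lam[-1]:.3g}"
        )
    keep = lam > tol
    lam, vec = lam[keep], vec[:, keep]
    scores = vec * np.sqrt(lam)
    # sign convention: largest |loading| positive, first index on ties
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return EigenvectorSet(list(D.labels), scores, lam)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


class UpgmaTree:
    """Result of UPGMA (average-linkage) agglomeration.

    ``merges`` is the ordered list of ``(cluster_a, cluster_b, height)``
    tuples where clusters are frozensets of leaf labels and the height is
    half the between-cluster average distance (so an ultrametric input is
    reproduced exactly by the cophenetic distances, which equal twice the
    merge height of the pair's lowest common ancestor).
    """

    def __init__(self, labels: list[str], merges: list[tuple[frozenset, frozenset, float]]):
        self.labels = labels
        self.merges = merges

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def cophenetic(self) -> DistanceMatrix:
        n = len(self.labels)
        idx = {l: i for i, l in enumerate(self.labels)}
        out = np.zeros((n, n))
        for a, b, h in self.merges:
            for x in a:
                for y in b:
                    out[idx[x], idx[y]] = out[idx[y], idx[x]] = 2.0 * h
        return DistanceMatrix(self.labels, out)

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        node_repr: dict[frozenset, tuple[str, float]] = {
            frozenset([l]): (l, 0.0) for l in self.labels
        }
        for a, b, h in self.merges:
            ra, ha = node_repr.pop(a)
            rb, hb = node_repr.pop(b)
            parts = sorted([f"{ra}:{h - ha:.10g}", f"{rb}:{h - hb:.10g}"])
            node_repr[a | b] = ("(" + ",".join(parts) + ")", h)
        (rep, _), = node_repr.values()
        return rep + ";"


def upgma(D: DistanceMatrix) -> UpgmaTree:
    """Average-linkage agglomerative clustering of a distance matrix.

    Merge height equals the between-cluster average distance divided by
    two. Ties are broken deterministically: among equally close pairs the
    one whose (lexicographically smallest member of each side) pair sorts
    first is merged.
    """
    if D.n < 2:
        raise ValueError("UPGMA needs at least two objects")
    if np.any(np.isinf(D.values)):
        raise ValueError("UPGMA requires finite distances")
    labels = list(D.labels)
    idx = {l: i for i, l in enumerate(labels)}
    clusters: list[frozenset] = [frozenset([l]) for l in labels]
    cluster_heights: dict[frozenset, float] = {c: 0.0 for c in clusters}
    merges: list[tuple[frozenset, frozenset, float]] = []

    def avg_dist(a: frozenset, b: frozenset) -> float:
        rows = [idx[x] for x in a]
        cols = [idx[y] for y in b]
        return float(D.values[np.ix_(rows, cols)].mean())

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                d = avg_dist(a, b)
                ka, kb = min(a), min(b)
                key = (d, *sorted((ka, kb)))
                if best is None or key < best[0]:
                    best = (key, a, b, d)
        _, a, b, d = best
        clusters = [c for c in clusters if c is not a and c is not b]
        merged = a | b
        clusters.append(merged)
        h = d / 2.0
        merges.append((a, b, h))
        cluster_heights[merged] = h
    return UpgmaTree(labels, merges)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


def permuted_indices(
    n: int, rng: np.random.Generator, strata: Sequence | None = None
) -> np.ndarray:
    """One random permutation of ``range(n)``, optionally within strata."""
    if strata is None:
        return rng.permutation(n)
    strata = np.asarray(strata)
    if strata.size == 0 or strata.size != n:
        raise ValueError("strata must label every observation")
    out = np.arange(n)
    for s in pd.unique(strata):
        pos = np.flatnonzero(strata == s)
        out[pos] = pos[rng.permutation(pos.size)]
    return out


def permutation_pvalue(
    observed: float, null: np.ndarray, alternative: str = "greater"
) -> float:
    null = np.asarray(null, dtype=float)
    if alternative == "greater":
        b = int(np.sum(null >= observed))
    elif alternative == "less":
        b = int(np.sum(null <= observed))
    elif alternative == "two-sided":
        b = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + b) / (1 + null.size)


def permutation_test(
    statistic_fn: Callable[[np.ndarray], float],
    n: int,
    n_perm: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    strata: Sequence | None = None,
    alternative: str = "greater",
) -> PermutationResult:
    """Generic permutation test.

    ``statistic_fn`` receives an index permutation of ``range(n)`` and
    returns the statistic under that relabelling; the identity
    permutation gives the observed value. The same seed always yields
    the same permutation stream.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = float(statistic_fn(np.arange(n)))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic_fn(permuted_indices(n, rng, strata))
    return PermutationResult(observed, null, permutation_pvalue(observed, null, alternative))


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _lower(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    The correlation (Pearson by default, Spearman on ranks otherwise) is
    computed on the off-diagonal lower triangles; the null distribution
    permutes object order of the second matrix. One-sided ("greater") by
    default, the common ecological convention.
    """
    if D1.labels != D2.labels:
        raise ValueError("Mantel requires identically labelled and ordered matrices")
    if D1.n < 3:
        raise ValueError("Mantel requires at least 3 objects")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    v1 = D1.values.astype(float)
    v2 = D2.values.astype(float)
    if method == "spearman":
        # rank the full off-diagonal sets, then correlate as Pearson
        def ranked(v):
            out = np.zeros_like(v)
            iu = np.triu_indices(v.shape[0], 1)
            r = rankdata(v[iu])
            out[iu] = r
            out = out + out.T
            return out

        v1, v2 = ranked(v1), ranked(v2)
    x = _lower(v1)
    x = (x - x.mean()) / x.std()

    def corr(perm: np.ndarray) -> float:
        y = _lower(v2[np.ix_(perm, perm)])
        sy = y.std()
        if sy == 0:
            return 0.0
        return float(np.mean(x * (y - y.mean()) / sy))

    rng = np.random.default_rng(seed)
    res = permutation_test(corr, D1.n, n_perm, rng=rng, alternative=alternative)
    return MantelResult(res.observed, res.p, n_perm)


# ---------------------------------------------------------------------------
# CADM (Kendall's W over distance matrices)
# ---------------------------------------------------------------------------


def _kendall_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``ranks``: (m, N) midranks per judge (matrix) over N objects.
    """
    m, N = ranks.shape
    r_sum = ranks.sum(axis=0)
    s = float(np.sum((r_sum - r_sum.mean()) ** 2))
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = m**2 * (N**3 - N) - m * ties
    if denom <= 0:
        return 1.0  # all entries tied in every matrix: perfect concordance
    return 12.0 * s / denom


def cadm(
    matrices: Sequence[DistanceMatrix],
    n_perm: int = 999,
    seed: int | None = None,
) -> CadmResult:
    """Congruence among distance matrices (global test).

    Each matrix's lower triangle is midranked; Kendall's W measures
    concordance across matrices, with the Friedman chi-square
    ``m (N - 1) W``. The global p-value permutes the object order of all
    matrices except the first (reference).
    """
    if len(matrices) < 2:
        raise ValueError("CADM needs at least two matrices")
    labels = matrices[0].labels
    for d in matrices[1:]:
        if d.labels != labels:
            raise ValueError("CADM matrices must share labels and order")
    n = matrices[0].n
    if n < 3:
        raise ValueError("CADM requires at least 3 objects")
    vals = [d.values for d in matrices]
    m, N = len(vals), n * (n - 1) // 2

    def ranks_of(v: np.ndarray) -> np.ndarray:
        return rankdata(_lower(v))

    base = np.vstack([ranks_of(v) for v in vals])
    W_obs = _kendall_w(base)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    rows = np.empty_like(base)
    rows[0] = base[0]
    for b in range(n_perm):
        for j in range(1, m):
            perm = rng.permutation(n)
            rows[j] = ranks_of(vals[j][np.ix_(perm, perm)])
        null[b] = _kendall_w(rows)
    p = permutation_pvalue(W_obs, null, "greater")
    return CadmResult(W_obs, m * (N - 1) * W_obs, p, n_perm)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR).

    Monotone in the sorted order, capped at 1, returned in the original
    order.
    """
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
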