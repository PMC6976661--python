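"""OTU-table processing and community-composition statistics.

Covers the whole composition stage: count filtering and taxonomy
truncation, rarefaction (random and analytic), Hellinger transform and
Bray–Curtis dissimilarity, ANOSIM, multi-term PERMANOVA with optional
permutation strata, forward selection of eigenvector predictors,
Wilcoxon rank-sum comparisons, richness~diversity regression, and a
two-class indicator-feature screen with a logarithmic effect-size
threshold (an LEfSe-style procedure).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import kruskal, linregress, mannwhitneyu, rankdata

from .distmat import (
    DistanceMatrix,
    EigenvectorSet,
    bh_adjust,
    permutation_pvalue,
    permuted_indices,
)

__all__ = [
    "OtuTable",
    "AnosimResult",
    "PermanovaResult",
    "RarefactionCurve",
    "RegressionResult",
    "filter_otus",
    "rarefy",
    "rarefaction_curve",
    "hellinger",
    "bray_curtis",
    "anosim",
    "permanova",
    "forward_select",
    "wilcoxon_rank_sum",
    "richness_diversity_regression",
    "indicator_features",
    "assign_rank_by_identity",
    "read_taxonomy_tsv",
]

TAXONOMIC_RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Samples x OTUs integer count table with optional sample metadata.

    ``counts`` rows are samples, columns are OTUs. ``state`` tracks the
    processing stage: raw -> filtered -> rarefied; a rarefied table has
    equal row sums.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(int)
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate OTU ids")
        if self.state == "rarefied":
            sums = self.counts.sum(axis=1)
            if sums.nunique() > 1:
                raise ValueError("rarefied table must have equal sample totals")
        if self.metadata is not None:
            missing = set(self.counts.index) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index.astype(str))

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns.astype(str))

    def richness(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def to_tsv(self, path) -> None:
        # conventional dialect: rows are OTUs, columns are samples
        self.counts.T.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path, metadata: pd.DataFrame | None = None, state: str = "raw"):
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.T.rename_axis(index=None, columns=None)
        return cls(counts, metadata=metadata, state=state)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int


@dataclass
class PermanovaResult:
    """Sequential (Type I) decomposition table.

    ``table`` rows: one per term plus Residual and Total, with columns
    SS, df, R2, F, p.
    """

    table: pd.DataFrame

    @property
    def total_ss(self) -> float:
        return float(self.table.loc["Total", "SS"])


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    expected_richness: pd.DataFrame  # samples x depths


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float


# ---------------------------------------------------------------------------
# filtering and taxonomy
# ---------------------------------------------------------------------------


def read_taxonomy_tsv(path) -> pd.DataFrame:
    """Taxonomy table: otu_id, identity, evalue, kingdom..genus[, guild]."""
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    return df.set_index("otu_id")


def filter_otus(
    table: OtuTable,
    min_reads: int = 10,
    taxonomy: pd.DataFrame | None = None,
    exclude_guilds: Sequence[str] = (),
) -> tuple[OtuTable, dict]:
    """Remove low-count OTUs and excluded guilds.

    OTUs whose total reads across all samples are below ``min_reads``
    are removed (the printed rule: fewer than 10 reads); OTUs whose
    taxonomy ``guild`` annotation matches ``exclude_guilds`` (e.g.
    mycorrhizal fungi, animal pathogens) are removed as putative
    contaminants. Returns the filtered table and a removal report.
    """
    totals = table.counts.sum(axis=0)
    low = set(totals.index[totals < min_reads])
    guild: set = set()
    if exclude_guilds and taxonomy is not None and "guild" in taxonomy.columns:
        excluded = set(exclude_guilds)
        guild = {
            o
            for o in table.otus
            if o in taxonomy.index and taxonomy.loc[o, "guild"] in excluded
        }
    drop = low | guild
    kept = [o for o in table.otus if o not in drop]
    report = {
        "removed_low_count": sorted(low),
        "removed_guild": sorted(guild),
        "n_kept": len(kept),
    }
    return (
        OtuTable(table.counts[kept], metadata=table.metadata, state="filtered"),
        report,
    )


def assign_rank_by_identity(
    identity: float, evalue: float, full_lineage: Mapping[str, str | None]
) -> dict[str, str | None] | None:
    """Truncate a best-hit lineage by the identity/e-value criteria.

    Records with e-value above 1e-50 are rejected entirely (returns
    ``None``). Identity >= 90 keeps genus, >= 85 family, >= 80 order,
    >= 75 class; below that only the kingdom is retained.
    """
    if not 0 <= identity <= 100:
        raise ValueError("identity must be a percentage in [0, 100]")
    missing = [r for r in TAXONOMIC_RANKS if r not in full_lineage]
    if missing:
        raise ValueError(f"malformed lineage, missing ranks: {missing}")
    if evalue > 1e-50:
        return None
    if identity >= 90:
        deepest = "genus"
    elif identity >= 85:
        deepest = "family"
    elif identity >= 80:
        deepest = "order"
    elif identity >= 75:
        deepest = "class"
    else:
        deepest = "kingdom"
    cut = TAXONOMIC_RANKS.index(deepest)
    return {
        r: (full_lineage[r] if i <= cut else None)
        for i, r in enumerate(TAXONOMIC_RANKS)
    }


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream keyed by (global seed, crc32 of the id) so results
    # do not depend on sample order
    return np.random.default_rng([seed, zlib.crc32(str(sample_id).encode())])


def rarefy(table: OtuTable, depth: int = 5415, seed: int = 0) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads
    (multivariate hypergeometric). Samples below ``depth`` raise."""
    totals = table.counts.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"samples below rarefaction depth {depth}: {list(short.index)}"
        )
    out = np.empty_like(table.counts.to_numpy())
    for i, sid in enumerate(table.samples):
        row = table.counts.iloc[i].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            rng = _sample_rng(seed, sid)
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(counts, metadata=table.metadata, state="rarefied")


def rarefaction_curve(table: OtuTable, depths: Sequence[int]) -> RarefactionCurve:
    """Analytic expected richness ``E[S_m]`` per sample.

    ``E[S_m] = sum_i [ 1 - C(N - N_i, m) / C(N, m) ]`` evaluated with
    log-gamma arithmetic; nondecreasing in m and equal to the observed
    richness at m = N.
    """
    depths = np.asarray(depths, dtype=int)
    totals = table.counts.sum(axis=1)
    if np.any(depths > totals.min()):
        bad = int(depths.max())
        raise ValueError(
            f"depth {bad} exceeds the smallest sample total {int(totals.min())}"
        )
    if np.any(depths < 0):
        raise ValueError("depths must be nonnegative")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rows = {}
    for sid in table.samples:
        counts = table.counts.loc[sid].to_numpy()
        counts = counts[counts > 0]
        N = counts.sum()
        es = np.empty(depths.size)
        for d, m in enumerate(depths):
            keep = (N - counts) >= m
            frac = np.zeros(counts.size)
            if np.any(keep):
                frac[keep] = np.exp(log_choose(N - counts[keep], m) - log_choose(N, m))
            es[d] = float(np.sum(1.0 - frac))
        rows[sid] = es
    return RarefactionCurve(
        depths, pd.DataFrame.from_dict(rows, orient="index", columns=depths)
    )


# ---------------------------------------------------------------------------
# transforms and dissimilarity
# ---------------------------------------------------------------------------


def hellinger(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of relative abundance per sample."""
    counts = table.counts if isinstance(table, OtuTable) else table
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    return np.sqrt(counts.div(totals, axis=0))


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between rows:
    ``BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``."""
    arr = matrix.to_numpy(float)
    if np.any(arr < 0):
        raise ValueError("Bray-Curtis requires nonnegative data")
    sums = arr.sum(axis=1)
    if np.sum(sums == 0) >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero rows")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(list(matrix.index.astype(str)), d)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def anosim(
    D: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities.

    ``R = (mean between-group rank - mean within-group rank) / (M / 2)``
    over the ranked condensed distances, ``M = n(n-1)/2``; p-value by
    permuting group labels.
    """
    groups = np.asarray(groups, dtype=object)
    if groups.size != D.n:
        raise ValueError("group labels must align with the distance matrix")
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    ranks = rankdata(D.condensed())
    iu, ju = np.triu_indices(D.n, k=1)
    M = ranks.size

    def stat(perm: np.ndarray) -> float:
        g = groups[perm]
        within = g[iu] == g[ju]
        rw = ranks[within].mean()
        rb = ranks[~within].mean()
        return float((rb - rw) / (M / 2.0))

    rng = np.random.default_rng(seed)
    observed = stat(np.arange(D.n))
    null = np.array([stat(rng.permutation(D.n)) for _ in range(n_perm)])
    return AnosimResult(observed, permutation_pvalue(observed, null, "greater"), n_perm)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def _projector(design: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space and its rank."""
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > max(design.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def permanova(
    D: DistanceMatrix,
    terms: Mapping[str, np.ndarray],
    strata: Sequence | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Multi-term sequential PERMANOVA on a distance matrix.

    The Gower-centered matrix ``G = -1/2 J D^2 J`` is decomposed
    sequentially (Type I) over the ordered predictor blocks in
    ``terms``; each term's pseudo-F uses the full-model residual. The
    permutation test shuffles sample identities of ``G``, restricted
    within ``strata`` when given (e.g. population as a random effect).
    Rank-deficient terms (no new dimensions beyond the previous design)
    are skipped with a warning.
    """
    n = D.n
    a = -0.5 * D.values**2
    g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
    ss_total = float(np.trace(g))

    design = np.ones((n, 1))
    p_prev, rank_prev = _projector(design)
    kept_terms: list[str] = []
    projectors: list[tuple[np.ndarray, np.ndarray]] = []
    dfs: list[int] = []
    for name, x in terms.items():
        x = _as_matrix(x)
        if x.shape[0] != n:
            raise ValueError(f"term {name!r} is not aligned with the distance matrix")
        new_design = np.hstack([design, x])
        p_new, rank_new = _projector(new_design)
        df = rank_new - rank_prev
        if df == 0:
            warnings.warn(f"term {name!r} is rank-deficient given earlier terms; skipped")
            continue
        kept_terms.append(name)
        projectors.append((p_prev.copy(), p_new.copy()))
        dfs.append(df)
        design, p_prev, rank_prev = new_design, p_new, rank_new

    df_res = n - rank_prev
    p_full = p_prev

    def term_ss(gmat: np.ndarray) -> np.ndarray:
        return np.array(
            [float(np.vdot(pn, gmat) - np.vdot(pp, gmat)) for pp, pn in projectors]
        )

    def resid_ss(gmat: np.ndarray) -> float:
        return float(np.trace(gmat) - np.vdot(p_full, gmat))

    ss_obs = term_ss(g)
    ss_res = resid_ss(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res / df_res) if df_res > 0 else np.full(len(dfs), np.nan)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept_terms))
    for _ in range(n_perm):
        perm = permuted_indices(n, rng, strata)
        gp = g[np.ix_(perm, perm)]
        ssb = term_ss(gp)
        srb = resid_ss(gp)
        fb = (ssb / np.array(dfs)) / (srb / df_res) if df_res > 0 else np.full(len(dfs), np.nan)
        exceed += fb >= f_obs
    pvals = (1 + exceed) / (1 + n_perm)

    rows = []
    for i, name in enumerate(kept_terms):
        rows.append(
            dict(term=name, SS=ss_obs[i], df=dfs[i], R2=ss_obs[i] / ss_total,
                 F=f_obs[i], p=pvals[i])
        )
    rows.append(dict(term="Residual", SS=ss_res, df=df_res,
                     R2=ss_res / ss_total, F=np.nan, p=np.nan))
    rows.append(dict(term="Total", SS=ss_total, df=n - 1, R2=1.0, F=np.nan, p=np.nan))
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------


def forward_select(
    D: DistanceMatrix,
    candidates: EigenvectorSet | pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Greedy forward selection of predictor axes against a distance matrix.

    At each step the candidate with the largest sum-of-squares gain is
    considered; its permutation p-value compares the observed best gain
    with the null distribution of the *maximum* gain over all remaining
    candidates (so under pure noise the familywise admission rate is
    alpha). Selection stops when the best candidate fails ``p <= alpha``.

    Returns a table of admitted axes (order, ss_gain, p).
    """
    frame = candidates.to_frame() if isinstance(candidates, EigenvectorSet) else candidates
    if frame.shape[1] < 1:
        raise ValueError("need at least one candidate axis")
    n = D.n
    x_all = frame.to_numpy(float)
    a = -0.5 * D.values**2
    g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    rows = []
    design = np.ones((n, 1))
    proj, _ = _projector(design)
    remaining = list(frame.columns)
    while remaining:
        resid = x_all[:, [frame.columns.get_loc(c) for c in remaining]]
        resid = resid - proj @ resid
        norms = (resid**2).sum(axis=0)
        usable = norms > 1e-12
        if not np.any(usable):
            break
        resid_u = resid[:, usable] / np.sqrt(norms[usable])
        names_u = [c for c, u in zip(remaining, usable) if u]

        def gains(gmat: np.ndarray) -> np.ndarray:
            return np.einsum("ij,jk,ki->i", resid_u.T, gmat, resid_u)

        obs = gains(g)
        best = int(np.argmax(obs))
        null_max = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            null_max[b] = gains(g[np.ix_(perm, perm)]).max()
        p = permutation_pvalue(float(obs[best]), null_max, "greater")
        if p > alpha:
            break
        name = names_u[best]
        selected.append(name)
        rows.append(dict(axis=name, ss_gain=float(obs[best]), p=p))
        remaining.remove(name)
        design = np.hstack([design, x_all[:, [frame.columns.get_loc(name)]]])
        proj, _ = _projector(design)
    return pd.DataFrame(rows, columns=["axis", "ss_gain", "p"])


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Wilcoxon (Mann–Whitney) rank-sum test.

    Exact enumeration when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections. Returns ``(U, p)`` with U counted for x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12:
        if not has_ties:
            res = mannwhitneyu(x, y, alternative=alternative, method="exact")
            return float(res.statistic), float(res.pvalue)
        return _wilcoxon_exact_with_ties(x, y, alternative)
    res = mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _wilcoxon_exact_with_ties(
    x: np.ndarray, y: np.ndarray, alternative: str
) -> tuple[float, float]:
    """Exact rank-sum p by enumerating all label arrangements of the pooled
    sample (ties receive half credit in U), feasible for n <= 12."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    gt = (pooled[:, None] > pooled[None, :]).astype(float)
    gt += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(gt, 0.0)

    def u_of(ix):
        ix = list(ix)
        iy = [k for k in range(n) if k not in set(ix)]
        return gt[np.ix_(ix, iy)].sum()

    obs = u_of(range(nx))
    us = np.array([u_of(c) for c in combinations(range(n), nx)])
    mean_u = nx * (n - nx) / 2.0
    if alternative == "two-sided":
        p = np.mean(np.abs(us - mean_u) >= abs(obs - mean_u) - 1e-12)
    elif alternative == "greater":
        p = np.mean(us >= obs - 1e-12)
    elif alternative == "less":
        p = np.mean(us <= obs + 1e-12)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(obs), float(p)


def richness_diversity_regression(
    richness: Sequence[float], diversity: Sequence[float]
) -> RegressionResult:
    """OLS of fungal OTU richness on host genetic diversity (Ho).

    Returns slope, intercept, R^2 and the F-test p-value (equal to the
    slope t-test for simple regression).
    """
    x = np.asarray(diversity, dtype=float)
    y = np.asarray(richness, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue**2), float(fit.pvalue))


# ---------------------------------------------------------------------------
# indicator features (LEfSe-style two-class screen)
# ---------------------------------------------------------------------------


def indicator_features(
    table: OtuTable,
    classes: Mapping[str, str] | pd.Series,
    kw_alpha: float = 0.05,
    effect_threshold: float = 3.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-class indicator OTU screen with a logarithmic effect size.

    Counts are normalized to one million per sample; OTUs passing a
    Kruskal–Wallis screen at ``kw_alpha`` receive an effect size: the
    mean over ``n_boot`` bootstrap rounds (two-thirds subsampling per
    class) of ``log10 |difference of class means|`` on the per-million
    scale, clamped below at zero. OTUs with effect at or above
    ``effect_threshold`` (the conventional logarithmic score cutoff of
    3.0) are reported, labelled by the enriched class.
    """
    classes = pd.Series(classes)
    classes = classes.loc[table.samples]
    levels = sorted(classes.unique())
    if len(levels) != 2:
        raise ValueError("indicator screen requires exactly 2 classes")
    norm = table.counts.div(table.counts.sum(axis=1), axis=0) * 1e6
    ia = np.flatnonzero((classes == levels[0]).to_numpy())
    ib = np.flatnonzero((classes == levels[1]).to_numpy())
    rng = np.random.default_rng(seed)
    rows = []
    arr = norm.to_numpy()
    for j, otu in enumerate(table.otus):
        va, vb = arr[ia, j], arr[ib, j]
        if np.ptp(np.concatenate([va, vb])) == 0:
            continue  # identical across classes: never an indicator
        stat_p = kruskal(va, vb).pvalue
        if not stat_p < kw_alpha:
            continue
        effects = np.empty(n_boot)
        na = max(1, round(2 * va.size / 3))
        nb = max(1, round(2 * vb.size / 3))
        for b in range(n_boot):
            sa = va[rng.choice(va.size, na, replace=False)]
            sb = vb[rng.choice(vb.size, nb, replace=False)]
            diff = abs(sa.mean() - sb.mean())
            effects[b] = max(0.0, np.log10(diff)) if diff > 0 else 0.0
        effect = float(effects.mean())
        if effect >= effect_threshold:
            enriched = levels[0] if va.mean() > vb.mean() else levels[1]
            rows.append(dict(feature=otu, **{"class": enriched},
                             effect=effect, p=float(stat_p)))
    out = pd.DataFrame(rows, columns=["feature", "class", "effect", "p"])
    return out.sort_values("effect", ascending=False).reset_index(drop=True)
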