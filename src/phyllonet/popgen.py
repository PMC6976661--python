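"""Microsatellite population genetics.

Diploid codominant genotypes (integer allele codes, 0 = missing) for
individuals nested in populations nested in regions. Provides allele
frequencies, observed heterozygosity (Ho), Nei's genetic distance
between populations, hierarchical AMOVA with permutation tests of the
among-region fixation index F_CT, plant genetic eigenvectors (PGE, PCoA
axes of individual-level genetic distances used as predictors of the
phyllosphere community), and the isolation-by-distance Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .distmat import (
    DistanceMatrix,
    EigenvectorSet,
    MantelResult,
    mantel,
    pcoa,
    permutation_pvalue,
)

__all__ = [
    "GenotypeMatrix",
    "GeneticDiversityResult",
    "AmovaResult",
    "allele_frequencies",
    "observed_heterozygosity",
    "nei_distance",
    "allele_sharing_distance",
    "amova",
    "pge_vectors",
    "ibd_test",
]

MISSING = 0


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for individuals with population/region labels.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; allele code 0
    marks a missing call (a call is missing if either allele is 0).
    """

    ids: list[str]
    population: np.ndarray
    region: np.ndarray
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(x) for x in self.ids]
        self.population = np.asarray(self.population, dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        self.calls = np.asarray(self.calls, dtype=int)
        n = len(self.ids)
        if self.calls.shape != (n, len(self.loci), 2):
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        if len(self.loci) < 1:
            raise ValueError("at least one locus required")
        if self.population.shape != (n,) or self.region.shape != (n,):
            raise ValueError("population/region labels must match individuals")
        # each population must belong to exactly one region
        mapping: dict = {}
        for p, r in zip(self.population, self.region):
            if p in mapping and mapping[p] != r:
                raise ValueError(f"population {p!r} assigned to multiple regions")
            mapping[p] = r
        self._pop_region = mapping

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def populations(self) -> list:
        return list(pd.unique(self.population))

    @property
    def regions(self) -> list:
        return list(pd.unique(self.region))

    def population_region_map(self) -> dict:
        return dict(self._pop_region)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the call is missing."""
        return np.any(self.calls == MISSING, axis=2)

    # -- I/O: two-column codominant CSV dialect ---------------------------

    def to_csv(self, path) -> None:
        cols: dict = {
            "id": self.ids,
            "population": self.population,
            "region": self.region,
        }
        for j, locus in enumerate(self.loci):
            cols[f"{locus}_a"] = self.calls[:, j, 0]
            cols[f"{locus}_b"] = self.calls[:, j, 1]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path)
        fixed = ["id", "population", "region"]
        allele_cols = [c for c in df.columns if c not in fixed]
        if len(allele_cols) % 2:
            raise ValueError("expected two allele columns per locus")
        loci = []
        for i in range(0, len(allele_cols), 2):
            a, b = allele_cols[i], allele_cols[i + 1]
            if a[:-2] != b[:-2]:
                raise ValueError(f"allele columns {a!r}/{b!r} do not pair")
            loci.append(a[:-2])
        calls = np.stack(
            [df[[f"{l}_a", f"{l}_b"]].to_numpy(int) for l in loci], axis=1
        )
        return cls(
            list(df["id"].astype(str)),
            df["population"].to_numpy(object),
            df["region"].to_numpy(object),
            loci,
            calls,
        )


@dataclass
class GeneticDiversityResult:
    """Observed heterozygosity per locus and its unweighted mean."""

    ho_per_locus: dict[str, float]
    ho_overall: float


@dataclass
class AmovaResult:
    sigma2_among_groups: float
    sigma2_among_pops_within: float
    sigma2_within_pops: float
    F_CT: float
    F_SC: float
    F_ST: float
    p_FCT: float
    n_perm: int


# ---------------------------------------------------------------------------
# grouping helpers
# ---------------------------------------------------------------------------


def _group_labels(G: GenotypeMatrix, grouping: str) -> np.ndarray:
    if grouping == "population":
        return G.population
    if grouping == "region":
        return G.region
    if grouping == "all":
        return np.array(["all"] * G.n, dtype=object)
    raise ValueError(f"unknown grouping {grouping!r}")


def allele_frequencies(
    G: GenotypeMatrix, grouping: str = "population"
) -> dict[tuple, dict[int, float]]:
    """Allele frequency tables per (group, locus).

    Missing calls are excluded from the denominators; frequencies sum to
    one within each table. A group x locus combination with no data at
    all raises, naming the offending combinations.
    """
    labels = _group_labels(G, grouping)
    missing = G.missing_mask()
    out: dict[tuple, dict[int, float]] = {}
    empty = []
    for g in pd.unique(labels):
        rows = np.flatnonzero(labels == g)
        for j, locus in enumerate(G.loci):
            ok = rows[~missing[rows, j]]
            if ok.size == 0:
                empty.append((g, locus))
                continue
            alleles = G.calls[ok, j, :].ravel()
            vals, counts = np.unique(alleles, return_counts=True)
            total = counts.sum()
            out[(g, locus)] = {int(v): c / total for v, c in zip(vals, counts)}
    if empty:
        raise ValueError(f"no genotype data for group x locus: {empty}")
    return out


def observed_heterozygosity(
    G: GenotypeMatrix, grouping: str = "all"
) -> dict[object, GeneticDiversityResult]:
    """Observed heterozygosity Ho per group.

    Per locus, Ho is the fraction of heterozygous individuals among
    those with a non-missing call; the overall value is the unweighted
    mean across loci with data (loci without data in a group are dropped
    from that group's mean).
    """
    labels = _group_labels(G, grouping)
    missing = G.missing_mask()
    het = G.calls[:, :, 0] != G.calls[:, :, 1]
    out = {}
    for g in pd.unique(labels):
        rows = np.flatnonzero(labels == g)
        per_locus: dict[str, float] = {}
        for j, locus in enumerate(G.loci):
            ok = rows[~missing[rows, j]]
            if ok.size:
                per_locus[locus] = float(het[ok, j].mean())
        if not per_locus:
            raise ValueError(f"group {g!r} has no genotype data")
        out[g] = GeneticDiversityResult(per_locus, float(np.mean(list(per_locus.values()))))
    return out


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------


def nei_distance(
    G: GenotypeMatrix, estimator: str = "nei1972", inf_cap: float | None = None
) -> DistanceMatrix:
    """Nei's standard genetic distance between populations.

    Per pair of populations, the gene identities ``Jx = sum(x^2)``,
    ``Jy = sum(y^2)`` and ``Jxy = sum(x*y)`` are averaged arithmetically
    across loci; ``D = -ln( Jxy_bar / sqrt(Jx_bar * Jy_bar) )``. The
    1978 unbiased estimator corrects ``Jx``/``Jy`` for sample size.
    Populations sharing no alleles have infinite distance, which is
    flagged (or capped at ``inf_cap`` when given).
    """
    if estimator not in ("nei1972", "nei1978"):
        raise ValueError(f"unknown estimator {estimator!r}")
    pops = G.populations
    if len(pops) < 2:
        raise ValueError("Nei distance needs at least two populations")
    freqs = allele_frequencies(G, "population")
    missing = G.missing_mask()
    # per (pop, locus) sample sizes (diploid individuals with data)
    sizes = {
        (p, l): int(np.sum((G.population == p) & ~missing[:, j]))
        for p in pops
        for j, l in enumerate(G.loci)
    }
    n = len(pops)
    vals = np.zeros((n, n))
    has_inf = False
    for a in range(n):
        for b in range(a + 1, n):
            jx = jy = jxy = 0.0
            for l in G.loci:
                fx = freqs[(pops[a], l)]
                fy = freqs[(pops[b], l)]
                sx = sum(v * v for v in fx.values())
                sy = sum(v * v for v in fy.values())
                if estimator == "nei1978":
                    nx, ny = 2 * sizes[(pops[a], l)], 2 * sizes[(pops[b], l)]
                    sx = (nx * sx - 1) / (nx - 1) if nx > 1 else sx
                    sy = (ny * sy - 1) / (ny - 1) if ny > 1 else sy
                jx += sx
                jy += sy
                jxy += sum(fx.get(k, 0.0) * fy.get(k, 0.0) for k in fx)
            L = len(G.loci)
            identity = (jxy / L) / np.sqrt((jx / L) * (jy / L))
            if identity <= 0:
                vals[a, b] = vals[b, a] = np.inf
                has_inf = True
            else:
                vals[a, b] = vals[b, a] = max(0.0, -np.log(identity))
    labels = [str(p) for p in pops]
    if has_inf and inf_cap is not None:
        vals = np.where(np.isinf(vals), inf_cap, vals)
        has_inf = False
    return DistanceMatrix(labels, vals, allow_infinite=has_inf)


def _shared_alleles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Multiset intersection size (0/1/2) of sorted diploid genotype rows."""
    eq = (a == b).sum(axis=1)
    cross = (a[:, 0] == b[:, 1]) | (a[:, 1] == b[:, 0])
    return np.where(eq == 2, 2, np.where((eq >= 1) | cross, 1, 0))


def allele_sharing_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Individual-level allele-sharing distance.

    Per locus where both calls are present, ``d = 1 - shared/2`` where
    ``shared`` is the size of the multiset intersection of the two
    diploid genotypes (0, 1 or 2); the distance is the mean over
    pairwise-complete loci. Used to build PGE axes, since Nei's formula
    degenerates for single-individual "populations".
    """
    n, L = G.n, len(G.loci)
    missing = G.missing_mask()
    calls = np.sort(G.calls, axis=2)  # unordered genotypes
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~missing[i] & ~missing[j]
            if not np.any(ok):
                raise ValueError(
                    f"individuals {G.ids[i]!r} and {G.ids[j]!r} share no typed loci"
                )
            shared = _shared_alleles(calls[i, ok], calls[j, ok])
            d = 1.0 - shared / 2.0
            vals[i, j] = vals[j, i] = float(d.mean())
    return DistanceMatrix(G.ids, vals)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _allele_diff_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Squared inter-individual distance: allele-count differences.

    Per pairwise-complete locus the contribution is ``2 - shared``
    (0, 1 or 2 allele differences); loci with a missing call in either
    individual are dropped for that pair.
    """
    n = G.n
    missing = G.missing_mask()
    calls = np.sort(G.calls, axis=2)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~missing[i] & ~missing[j]
            if not np.any(ok):
                raise ValueError(
                    f"individuals {G.ids[i]!r} and {G.ids[j]!r} share no typed loci"
                )
            shared = _shared_alleles(calls[i, ok], calls[j, ok])
            out[i, j] = out[j, i] = float((2 - shared).sum())
    return out


def _ssd(d2: np.ndarray, rows: np.ndarray) -> float:
    """Sum of squared deviations for a set: (1/n) * sum_{i<j} d2_ij."""
    sub = d2[np.ix_(rows, rows)]
    return float(np.triu(sub, 1).sum() / rows.size)


def _amova_components(
    d2: np.ndarray, pop_of: np.ndarray, group_of_pop: Mapping
) -> tuple[float, float, float]:
    """Method-of-moments variance components of two-level AMOVA."""
    pops = list(pd.unique(pop_of))
    groups: dict = {}
    for p in pops:
        groups.setdefault(group_of_pop[p], []).append(p)
    N = pop_of.size
    P, Gn = len(pops), len(groups)
    all_rows = np.arange(N)
    ssd_total = _ssd(d2, all_rows)
    ssd_wp = sum(_ssd(d2, np.flatnonzero(pop_of == p)) for p in pops)
    ssd_groups = {
        g: _ssd(d2, np.flatnonzero(np.isin(pop_of, members)))
        for g, members in groups.items()
    }
    ssd_ap_wg = sum(ssd_groups.values()) - ssd_wp
    ssd_ag = ssd_total - sum(ssd_groups.values())

    n_p = {p: int(np.sum(pop_of == p)) for p in pops}
    n_g = {g: sum(n_p[p] for p in m) for g, m in groups.items()}
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in m) / n_g[g] for g, m in groups.items()
    )
    sum_np2_over_n = sum(n_p[p] ** 2 for p in pops) / N
    sum_ng2_over_n = sum(v**2 for v in n_g.values()) / N

    df_ag, df_ap, df_wp = Gn - 1, P - Gn, N - P
    ms_wp = ssd_wp / df_wp if df_wp else 0.0
    sigma_c = ms_wp
    if df_ap > 0:
        n1 = (N - sum_np2_over_ng) / df_ap
        ms_ap = ssd_ap_wg / df_ap
        sigma_b = (ms_ap - sigma_c) / n1 if n1 else 0.0
    else:
        sigma_b = 0.0
    n2 = (sum_np2_over_ng - sum_np2_over_n) / df_ag if df_ag else 0.0
    n3 = (N - sum_ng2_over_n) / df_ag if df_ag else 0.0
    ms_ag = ssd_ag / df_ag if df_ag else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 else 0.0
    return sigma_a, sigma_b, sigma_c


def amova(
    G: GenotypeMatrix,
    groups: Mapping | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    permute: str = "populations",
) -> AmovaResult:
    """Two-level hierarchical AMOVA (regions / populations / individuals).

    Works on squared inter-individual distances counted as allele
    differences (0/1/2 per locus). Variance components follow the
    standard method of moments; the among-group index
    ``F_CT = sigma_a / (sigma_a + sigma_b + sigma_c)`` is tested by
    permutation.

    Parameters
    ----------
    groups : mapping population -> group, optional
        Defaults to the region assignment carried by ``G``.
    permute : {"populations", "individuals"}
        Permutation unit for the F_CT test. ``"populations"`` shuffles
        whole populations among groups (the classical scheme; note its
        resolution is coarse for few populations: with 6 populations in
        two groups of three only 10 distinct assignments exist, so the
        smallest attainable p is 0.1). ``"individuals"`` shuffles
        individuals among groups keeping population sizes, which has
        full resolution.
    """
    if groups is None:
        groups = G.population_region_map()
    pops = G.populations
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least two populations")
    group_ids = sorted(set(groups[p] for p in pops), key=str)
    if len(group_ids) < 2:
        raise ValueError("AMOVA needs at least two groups")
    d2 = _allele_diff_matrix(G)
    pop_of = np.asarray(G.population, dtype=object)

    one_level = len(pops) == len(group_ids) and all(
        len([p for p in pops if groups[p] == g]) == 1 for g in group_ids
    )

    if one_level:
        # degenerate case groups == populations: one-level decomposition
        N, P = G.n, len(pops)
        all_rows = np.arange(N)
        ssd_total = _ssd(d2, all_rows)
        ssd_wp = sum(_ssd(d2, np.flatnonzero(pop_of == p)) for p in pops)
        ssd_ap = ssd_total - ssd_wp
        df_ap, df_wp = P - 1, N - P
        ms_wp = ssd_wp / df_wp if df_wp else 0.0
        n_p = {p: int(np.sum(pop_of == p)) for p in pops}
        n0 = (N - sum(v**2 for v in n_p.values()) / N) / df_ap
        sigma_a = ((ssd_ap / df_ap) - ms_wp) / n0 if n0 else 0.0
        sigma_b, sigma_c = 0.0, ms_wp

        def fct(pop_labels: np.ndarray) -> float:
            ssd_w = sum(
                _ssd(d2, np.flatnonzero(pop_labels == p)) for p in pops
            )
            ssd_a = ssd_total - ssd_w
            msw = ssd_w / df_wp if df_wp else 0.0
            sa = ((ssd_a / df_ap) - msw) / n0 if n0 else 0.0
            tot = sa + msw
            return sa / tot if tot > 0 else 0.0

        total = sigma_a + sigma_c
        f_ct = sigma_a / total if total > 0 else 0.0
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = fct(pop_of[rng.permutation(N)])
        p = permutation_pvalue(f_ct, null, "greater")
        return AmovaResult(sigma_a, 0.0, sigma_c, f_ct, 0.0, f_ct, p, n_perm)

    def fstats(group_of_pop: Mapping, pop_labels: np.ndarray):
        sa, sb, sc = _amova_components(d2, pop_labels, group_of_pop)
        total = sa + sb + sc
        f_ct = sa / total if total > 0 else 0.0
        f_sc = sb / (sb + sc) if (sb + sc) > 0 else 0.0
        f_st = (sa + sb) / total if total > 0 else 0.0
        return f_ct, f_sc, f_st, sa, sb, sc

    f_ct, f_sc, f_st, sa, sb, sc = fstats(groups, pop_of)
    rng = np.random.default_rng(seed)
    if permute == "populations":
        pop_list = list(pops)
        assigned = tuple(groups[p] for p in pop_list)
        if len(pop_list) <= 8:
            # few populations: enumerate every distinct assignment exactly
            # (the sampled test cannot resolve below ~2/K for K assignments)
            import itertools as _it

            assignments = sorted(set(_it.permutations(assigned)), key=str)
            stats = np.array(
                [fstats(dict(zip(pop_list, a)), pop_of)[0] for a in assignments]
            )
            p = float(np.mean(stats >= f_ct - 1e-12))
            return AmovaResult(sa, sb, sc, f_ct, f_sc, f_st, p, len(assignments))
        null = np.empty(n_perm)
        for b in range(n_perm):
            shuffled = dict(
                zip(pop_list, [assigned[i] for i in rng.permutation(len(pop_list))])
            )
            null[b] = fstats(shuffled, pop_of)[0]
    elif permute == "individuals":
        null = np.empty(n_perm)
        # relabel individuals across groups, keeping population sizes:
        # permute individual rows, keep population/group structure fixed
        for b in range(n_perm):
            perm = rng.permutation(G.n)
            null[b] = fstats(groups, pop_of[perm])[0]
    else:
        raise ValueError(f"unknown permute scheme {permute!r}")
    p = permutation_pvalue(f_ct, null, "greater")
    return AmovaResult(sa, sb, sc, f_ct, f_sc, f_st, p, n_perm)


# ---------------------------------------------------------------------------
# PGE and isolation by distance
# ---------------------------------------------------------------------------


def pge_vectors(D: DistanceMatrix) -> EigenvectorSet:
    """Plant genetic eigenvectors: PCoA axes of a genetic distance matrix,
    renamed PGE1..PGEk. Only positive-eigenvalue axes are retained."""
    return pcoa(D).renamed("PGE")


def ibd_test(
    D_genetic: DistanceMatrix,
    D_geographic: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Isolation by distance: Mantel test between population genetic and
    geographic distance matrices."""
    if D_genetic.n < 3:
        raise ValueError("IBD Mantel test needs at least 3 populations")
    return mantel(D_genetic, D_geographic, n_perm=n_perm, seed=seed)
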