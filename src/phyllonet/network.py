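"""Fungal co-occurrence network inference and topology.

Edges are significant Spearman rank correlations between OTU abundance
profiles (|rho| above a cutoff, Benjamini–Hochberg adjusted p below
alpha). The module provides per-plant induced subnetworks, Louvain
module detection, the six topological metrics reported for such
networks (nodes, edges, average degree, degree centralization,
closeness centralization, modularity), Erdős–Rényi baselines with
matched nodes and edges, within/among-module connectivity (Zi/Pi) with
the standard keystone role classification, region-wise Wilcoxon
comparisons of per-sample metrics, and the degree distribution with a
log-log power-law slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import linregress, spearmanr

from .community import OtuTable, wilcoxon_rank_sum
from .distmat import bh_adjust

__all__ = [
    "CooccurrenceNetwork",
    "NetworkMetrics",
    "abundance_filter",
    "spearman_matrix",
    "build_network",
    "induced_subnetwork",
    "detect_modules",
    "topology_metrics",
    "erdos_renyi_baseline",
    "zi_pi",
    "classify_roles",
    "compare_region_topologies",
    "degree_distribution",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class CooccurrenceNetwork:
    """Undirected signed correlation graph over OTU nodes.

    Edge attributes: ``rho`` (Spearman), ``p_raw``, ``q`` (BH-adjusted),
    ``sign``. Node attribute ``abundance`` holds overall relative
    abundance when known. ``modules`` maps node -> module id once
    detection has run, with the achieved ``modularity``.
    """

    graph: nx.Graph
    modules: dict | None = None
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_edge_fraction(self) -> float:
        if self.n_edges == 0:
            return float("nan")
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d.get("rho", 0) > 0)
        return pos / self.n_edges

    def edge_table(self) -> pd.DataFrame:
        rows = [
            dict(otu_a=a, otu_b=b, **d) for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p_raw", "q", "sign"])

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.modules:
            nx.set_node_attributes(g, {k: int(v) for k, v in self.modules.items()}, "module")
        nx.write_graphml(g, path)


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    avg_degree: float
    degree_centralization: float
    closeness_centralization: float
    modularity: float

    def as_dict(self) -> dict:
        return dict(
            n_nodes=self.n_nodes,
            n_edges=self.n_edges,
            avg_degree=self.avg_degree,
            degree_centralization=self.degree_centralization,
            closeness_centralization=self.closeness_centralization,
            modularity=self.modularity,
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def abundance_filter(table: OtuTable, min_rel_abundance: float = 1e-4) -> OtuTable:
    """Drop OTUs whose overall relative abundance (total reads of the OTU
    over total reads of the table) is below the threshold (0.01% by
    default)."""
    totals = table.counts.sum(axis=0)
    rel = totals / totals.sum()
    kept = list(rel.index[rel >= min_rel_abundance])
    # dropping OTUs breaks the equal-row-sum invariant of a rarefied table
    return OtuTable(table.counts[kept], metadata=table.metadata, state="filtered")


def spearman_matrix(table: OtuTable | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlation of OTU abundance profiles.

    Midrank ties; p-values from the t approximation. A constant OTU has
    undefined correlation: recorded as rho = 0 with p = 1 (the pair can
    never become an edge). Diagonal rho is 1.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    if counts.shape[0] < 4:
        raise ValueError("need at least 4 samples for correlation inference")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = spearmanr(counts.to_numpy(float), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    const = counts.nunique(axis=0).to_numpy() == 1
    rho[np.isnan(rho)] = 0.0
    p[np.isnan(p)] = 1.0
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    p[const, :] = 1.0
    p[:, const] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    cols = counts.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    table: OtuTable | None = None,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    drop_isolated: bool = True,
) -> CooccurrenceNetwork:
    """Assemble the co-occurrence graph from correlation matrices.

    All upper-triangle p-values are Benjamini–Hochberg adjusted; an edge
    is retained when ``|rho| > rho_min`` and the (adjusted, by default)
    p-value is below ``alpha``. Isolated nodes are dropped unless
    ``drop_isolated=False``.
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices are not aligned")
    otus = list(rho.index)
    n = len(otus)
    iu, ju = np.triu_indices(n, k=1)
    p_flat = p.to_numpy()[iu, ju]
    q_flat = bh_adjust(p_flat)
    rho_flat = rho.to_numpy()[iu, ju]
    crit = q_flat if use_adjusted else p_flat
    keep = (np.abs(rho_flat) > rho_min) & (crit < alpha)

    g = nx.Graph()
    g.add_nodes_from(otus)
    for k in np.flatnonzero(keep):
        a, b = otus[iu[k]], otus[ju[k]]
        g.add_edge(
            a,
            b,
            rho=float(rho_flat[k]),
            p_raw=float(p_flat[k]),
            q=float(q_flat[k]),
            sign="positive" if rho_flat[k] > 0 else "negative",
        )
    if table is not None:
        totals = table.counts.sum(axis=0)
        rel = totals / totals.sum()
        nx.set_node_attributes(
            g, {o: float(rel.get(o, 0.0)) for o in g.nodes}, "abundance"
        )
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return CooccurrenceNetwork(g)


def induced_subnetwork(
    net: CooccurrenceNetwork, present_otus: Sequence[str]
) -> CooccurrenceNetwork:
    """Node-induced subgraph on the OTUs present in one plant.

    OTUs outside the parent node universe are ignored with a warning;
    module labels are inherited from the parent (no re-detection), so
    node role identities stay comparable across plants.
    """
    present = set(present_otus)
    unknown = present - set(net.graph.nodes)
    if unknown:
        warnings.warn(f"{len(unknown)} OTUs not in the network were ignored")
    nodes = present & set(net.graph.nodes)
    sub = net.graph.subgraph(nodes).copy()
    modules = (
        {n: net.modules[n] for n in sub.nodes if n in net.modules}
        if net.modules
        else None
    )
    return CooccurrenceNetwork(sub, modules=modules, modularity=None)


# ---------------------------------------------------------------------------
# modules and metrics
# ---------------------------------------------------------------------------


def detect_modules(
    net: CooccurrenceNetwork, seed: int = 0, n_restarts: int = 10
) -> tuple[dict, float]:
    """Louvain community detection on the unweighted graph.

    Runs ``n_restarts`` seeded restarts and keeps the partition with the
    highest Newman–Girvan modularity (first found wins ties). An
    edgeless graph gets singleton modules and Q = 0. The assignment and
    Q are stored on the network and returned.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        modules = {n: i for i, n in enumerate(g.nodes)}
        net.modules, net.modularity = modules, 0.0
        return modules, 0.0
    best_q, best_parts = -np.inf, None
    for r in range(n_restarts):
        parts = nx.community.louvain_communities(g, weight=None, seed=seed + r)
        q = nx.community.modularity(g, parts, weight=None)
        if q > best_q:
            best_q, best_parts = q, parts
    modules = {}
    for i, part in enumerate(best_parts):
        for node in part:
            modules[node] = i
    net.modules, net.modularity = modules, float(best_q)
    return modules, float(best_q)


def _closeness_within_components(g: nx.Graph) -> dict:
    """Closeness centrality computed inside each connected component
    (on the component's induced subgraph), 0 for isolated nodes."""
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        for node, val in nx.closeness_centrality(sub).items():
            out[node] = val
    return out


def topology_metrics(net: CooccurrenceNetwork, seed: int = 0) -> NetworkMetrics:
    """The six topological descriptors of a network.

    Degree centralization follows Freeman:
    ``sum(dmax - d_i) / ((n-1)(n-2))``; closeness centralization uses
    within-component closeness and the Freeman normalization
    ``(n-1)(n-2)/(2n-3)``. Both are defined as 0 for n < 3. Modularity
    comes from the stored Louvain partition (detected here if absent).
    """
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        return NetworkMetrics(0, 0, 0.0, 0.0, 0.0, 0.0)
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    avg_degree = 2.0 * m / n
    if n < 3:
        deg_cent = clo_cent = 0.0
    else:
        deg_cent = float(np.sum(degrees.max() - degrees) / ((n - 1) * (n - 2)))
        clo = np.array(list(_closeness_within_components(g).values()))
        clo_cent = float(np.sum(clo.max() - clo) / ((n - 1) * (n - 2) / (2 * n - 3)))
    if net.modularity is None:
        detect_modules(net, seed=seed)
    return NetworkMetrics(n, m, avg_degree, deg_cent, clo_cent, float(net.modularity))


def erdos_renyi_baseline(
    n_nodes: int, n_edges: int, n_reps: int = 100, seed: int = 0
) -> tuple[list[NetworkMetrics], pd.DataFrame]:
    """Random G(n, m) baselines with the observed node and edge counts.

    Returns per-replicate metrics and a mean +/- sd summary table.
    """
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("more edges than a simple graph allows")
    reps = []
    for r in range(n_reps):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed + r)
        reps.append(topology_metrics(CooccurrenceNetwork(g), seed=seed + r))
    frame = pd.DataFrame([m.as_dict() for m in reps])
    summary = pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})
    return reps, summary


# ---------------------------------------------------------------------------
# node roles
# ---------------------------------------------------------------------------


def zi_pi(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    ``Zi = (k_is - mean(k_.s)) / sd(k_.s)`` over the nodes of module s
    (population sd; Zi = 0 when the sd is 0), where ``k_is`` is the
    node's number of links inside its own module.
    ``Pi = 1 - sum_s (k_is / k_i)^2``; an isolated node has Pi = 0.
    """
    if net.modules is None:
        raise ValueError("run detect_modules before zi_pi")
    g = net.graph
    modules = net.modules
    nodes = list(g.nodes)
    within = {}
    per_module_links: dict[str, dict] = {}
    for node in nodes:
        counts: dict = {}
        for nb in g.neighbors(node):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        per_module_links[node] = counts
        within[node] = counts.get(modules[node], 0)
    # module-wise stats of within-degree
    by_module: dict = {}
    for node in nodes:
        by_module.setdefault(modules[node], []).append(within[node])
    stats = {
        s: (np.mean(v), np.std(v)) for s, v in by_module.items()
    }
    rows = []
    for node in nodes:
        k = g.degree(node)
        mu, sd = stats[modules[node]]
        zi = (within[node] - mu) / sd if sd > 0 else 0.0
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        rows.append(dict(otu=node, module=modules[node], degree=k,
                         zi=float(zi), pi=float(pi)))
    return pd.DataFrame(rows).set_index("otu")


def classify_roles(topology: pd.DataFrame) -> pd.DataFrame:
    """Assign keystone roles from Zi/Pi.

    Strict thresholds as conventionally printed: module hub
    (Zi > 2.5, Pi <= 0.62), connector (Pi > 0.62, Zi <= 2.5), network
    hub (both exceeded), peripheral otherwise — a node exactly at a
    threshold falls to the non-exceeding side. Keystones are all
    non-peripheral nodes.
    """
    out = topology.copy()
    zi = out["zi"].to_numpy()
    pi = out["pi"].to_numpy()
    role = np.where(
        (zi > ZI_THRESHOLD) & (pi > PI_THRESHOLD),
        "network hub",
        np.where(
            zi > ZI_THRESHOLD,
            "module hub",
            np.where(pi > PI_THRESHOLD, "connector", "peripheral"),
        ),
    )
    out["role"] = role
    out["keystone"] = out["role"] != "peripheral"
    return out


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------


def compare_region_topologies(
    per_sample_metrics: pd.DataFrame, regions: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests of per-sample network metrics
    between two regions. ``per_sample_metrics`` is indexed by sample with
    one column per metric. Returns per metric: the regional medians, U
    and p."""
    regions = pd.Series(regions).loc[per_sample_metrics.index]
    levels = sorted(regions.unique())
    if len(levels) != 2:
        raise ValueError("exactly two regions required")
    counts = regions.value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per region")
    rows = []
    for metric in per_sample_metrics.columns:
        va = per_sample_metrics.loc[regions == levels[0], metric].to_numpy(float)
        vb = per_sample_metrics.loc[regions == levels[1], metric].to_numpy(float)
        u, p = wilcoxon_rank_sum(va, vb, alternative="two-sided")
        rows.append(
            {
                "metric": metric,
                f"median_{levels[0]}": float(np.median(va)),
                f"median_{levels[1]}": float(np.median(vb)),
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def degree_distribution(net: CooccurrenceNetwork) -> dict:
    """Degree histogram and log-log OLS fit.

    Returns the histogram over positive degrees and, when at least two
    distinct degrees occur, the OLS slope and R^2 of log10 frequency on
    log10 degree (a scale-free network shows a negative slope); slope
    and r2 are None for a single distinct degree.
    """
    if net.n_edges == 0:
        raise ValueError("degree distribution needs at least one edge")
    degrees = np.array([d for _, d in net.graph.degree() if d > 0])
    values, counts = np.unique(degrees, return_counts=True)
    hist = pd.Series(counts, index=values, name="frequency")
    if values.size < 2:
        return dict(histogram=hist, slope=None, r2=None)
    fit = linregress(np.log10(values), np.log10(counts))
    return dict(histogram=hist, slope=float(fit.slope), r2=float(fit.rvalue**2))
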