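"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes filter -> rarefy -> (population genetics,
spatial predictors) -> community statistics -> co-occurrence network ->
driver attribution on one input bundle, writing TSV/JSON/GraphML/Newick
outputs plus a manifest (config hash, seed, stage timings, content
hashes) so a rerun with the same config and inputs is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import drivers as drv
from . import network as net
from . import popgen, spatial
from .distmat import cadm, mantel, upgma

logger = logging.getLogger("phyllonet")

__all__ = ["PipelineConfig", "ValidationReport", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the pipeline.

    Defaults are the conventional printed constants of this analysis:
    count filter 10 reads, rarefaction depth 5415, network abundance
    filter 0.01%, |rho| cutoff 0.6 at alpha 0.05, indicator effect
    threshold 3.0, and keystone thresholds Zi 2.5 / Pi 0.62.
    """

    otu_table: str | None = None
    metadata: str | None = None
    genotypes: str | None = None
    taxonomy: str | None = None
    out_dir: str = "results"

    min_reads: int = 10
    rarefaction_depth: int = 5415
    min_rel_abundance: float = 0.0001
    rho_min: float = 0.6
    alpha: float = 0.05
    lda_threshold: float = 3.0
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62

    n_perm: int = 999
    glm_n_perm: int = 99
    glm_top_otus: int = 40
    rf_n_perm: int = 99
    rf_n_trees: int = 100
    er_reps: int = 100
    seed: int = 0
    exclude_guilds: tuple = ("ectomycorrhizal", "animal_pathogen")
    stages: tuple = ("popgen", "community", "network", "drivers")

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 <= self.min_rel_abundance < 1
                and 0 < self.rho_min < 1):
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exclude_guilds", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    warnings: list[str] = field(default_factory=list)
    fatal: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(
    table: comm.OtuTable,
    metadata: pd.DataFrame,
    genotypes: popgen.GenotypeMatrix | None = None,
) -> ValidationReport:
    """Check sample-id alignment across the OTU table, metadata and
    genotypes. Orphan metadata rows are warnings; OTU-table samples
    without metadata are fatal; samples without genotypes are fatal for
    the genetics stage only (reported as warnings here)."""
    report = ValidationReport()
    samples = set(table.samples)
    meta = set(metadata.index.astype(str))
    missing_meta = samples - meta
    if missing_meta:
        report.fatal.append(f"samples without metadata: {sorted(missing_meta)}")
    orphans = meta - samples
    if orphans:
        report.warnings.append(f"metadata rows without samples: {sorted(orphans)}")
    if genotypes is not None:
        geno = set(genotypes.ids)
        missing_geno = samples - geno
        if missing_geno:
            report.warnings.append(
                "samples without genotypes (genetics stage will fail for them): "
                f"{sorted(missing_geno)}"
            )
    return report


def _seed_for(stage: str, seed: int) -> int:
    """Stable per-stage substream: toggling one stage never changes
    another stage's randomness."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    bundle=None,
) -> dict:
    """Run the configured stages and write a results directory.

    When ``bundle`` is None the inputs are read from the paths in the
    config; passing a :class:`~phyllonet.simulate.SyntheticBundle`
    (or any object with the same attributes) skips file input. Returns a
    summary dict of the headline numbers; all full outputs land in
    ``config.out_dir``.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {}

    if bundle is None:
        if not (config.otu_table and config.metadata):
            raise ValueError("otu_table and metadata paths (or a bundle) required")
        metadata = spatial.read_metadata_tsv(config.metadata)
        table = comm.OtuTable.from_tsv(config.otu_table, metadata=metadata)
        genotypes = (
            popgen.GenotypeMatrix.from_csv(config.genotypes)
            if config.genotypes
            else None
        )
        taxonomy = (
            comm.read_taxonomy_tsv(config.taxonomy) if config.taxonomy else None
        )
    else:
        metadata = bundle.metadata
        table = bundle.otu_table
        genotypes = bundle.genotypes
        taxonomy = bundle.taxonomy

    report = validate_inputs(table, metadata, genotypes)
    for w in report.warnings:
        logger.warning(w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.fatal))

    # ------------------------------------------------------------------ filter
    t0 = time.time()
    filtered, filt_report = comm.filter_otus(
        table, min_reads=config.min_reads, taxonomy=taxonomy,
        exclude_guilds=config.exclude_guilds,
    )
    rarefied = comm.rarefy(
        filtered, depth=config.rarefaction_depth, seed=_seed_for("rarefy", config.seed)
    )
    rarefied.to_tsv(out / "otu_table.rarefied.tsv")
    summary["n_otus_filtered"] = len(filtered.otus)
    summary["n_samples"] = len(rarefied.samples)
    timings["filter_rarefy"] = time.time() - t0

    region = metadata.loc[rarefied.samples, "region"]
    population = metadata.loc[rarefied.samples, "population"]

    # ------------------------------------------------------------------ popgen
    d_ind = None
    pge = None
    if "popgen" in config.stages and genotypes is not None:
        t0 = time.time()
        seed = _seed_for("popgen", config.seed)
        ho = popgen.observed_heterozygosity(genotypes, "region")
        d_nei = popgen.nei_distance(genotypes, inf_cap=10.0)
        tree = upgma(d_nei)
        (out / "nei_upgma.nwk").write_text(tree.to_newick() + "\n")
        d_nei.to_tsv(out / "nei_distance.tsv")
        am = popgen.amova(genotypes, n_perm=config.n_perm, seed=seed)
        d_ind = popgen.allele_sharing_distance(genotypes)
        pge = popgen.pge_vectors(d_ind)
        pops = genotypes.populations
        pop_coord = spatial.GeoCoordinates(
            [str(p) for p in pops],
            np.array([metadata.loc[population == p, "latitude"].iloc[0] for p in pops]),
            np.array([metadata.loc[population == p, "longitude"].iloc[0] for p in pops]),
        )
        ibd = popgen.ibd_test(
            d_nei.capped(10.0) if np.any(np.isinf(d_nei.values)) else d_nei,
            spatial.haversine_matrix(pop_coord),
            n_perm=config.n_perm, seed=seed,
        )
        popgen_results = {
            "ho_per_region": {str(k): v.ho_overall for k, v in ho.items()},
            "amova": {
                "F_CT": am.F_CT, "F_SC": am.F_SC, "F_ST": am.F_ST,
                "p_FCT": am.p_FCT,
                "sigma2": [am.sigma2_among_groups, am.sigma2_among_pops_within,
                           am.sigma2_within_pops],
            },
            "ibd": {"r": ibd.r, "p": ibd.p},
            "n_pge_axes": pge.k,
        }
        (out / "popgen.json").write_text(json.dumps(popgen_results, indent=1))
        summary.update(
            amova_fct=am.F_CT, amova_p=am.p_FCT,
            ho_per_region=popgen_results["ho_per_region"],
            ibd_r=ibd.r, ibd_p=ibd.p,
        )
        timings["popgen"] = time.time() - t0

    # ------------------------------------------------------------- community
    bc = None
    if "community" in config.stages:
        t0 = time.time()
        seed = _seed_for("community", config.seed)
        hel = comm.hellinger(rarefied)
        bc = comm.bray_curtis(hel)
        bc.to_tsv(out / "bray_curtis.tsv")
        groups = region.to_numpy(object)
        an = comm.anosim(bc, groups, n_perm=config.n_perm, seed=seed)
        summary.update(anosim_r=an.R, anosim_p=an.p)

        richness = rarefied.richness()
        levels = list(pd.unique(groups))
        u, p_rich = comm.wilcoxon_rank_sum(
            richness[groups == levels[0]], richness[groups == levels[1]]
        )
        indicators = comm.indicator_features(
            rarefied, region, effect_threshold=config.lda_threshold,
            seed=seed,
        )
        indicators.to_csv(out / "indicator_otus.tsv", sep="\t", index=False)
        summary["n_indicator_otus"] = len(indicators)

        depths = np.unique(
            np.linspace(1, config.rarefaction_depth, 8).astype(int)
        )
        curve = comm.rarefaction_curve(rarefied, depths)
        curve.expected_richness.to_csv(out / "rarefaction_curves.tsv", sep="\t")

        if genotypes is not None:
            # per-population OTU richness against host genetic diversity
            ho_pop = popgen.observed_heterozygosity(genotypes, "population")
            pop_richness = richness.groupby(population).mean()
            ho_vals = [ho_pop[p].ho_overall for p in pop_richness.index]
            reg = comm.richness_diversity_regression(
                pop_richness.to_numpy(float), ho_vals
            )
            summary.update(
                richness_ho_r2=reg.r2, richness_ho_p=reg.p,
                richness_ho_slope=reg.slope,
            )

        terms: dict[str, np.ndarray] = {}
        if pge is not None and d_ind is not None:
            sel_pge = comm.forward_select(
                bc, pge, alpha=config.alpha, n_perm=config.n_perm, seed=seed
            )
            pge_frame = pge.to_frame()
            terms["host_genetic_eigenvectors"] = (
                pge_frame[sel_pge["axis"]].to_numpy()
                if len(sel_pge)
                else pge_frame.iloc[:, :3].to_numpy()
            )
        coords = spatial.GeoCoordinates(
            rarefied.samples,
            metadata.loc[rarefied.samples, "latitude"].to_numpy(),
            metadata.loc[rarefied.samples, "longitude"].to_numpy(),
        )
        d_geo = spatial.haversine_matrix(coords)
        pcnm = spatial.pcnm_vectors(d_geo)
        sel_pcnm = comm.forward_select(
            bc, pcnm, alpha=config.alpha, n_perm=config.n_perm, seed=seed + 1
        )
        pcnm_frame = pcnm.to_frame()
        terms["geographic_distance"] = (
            pcnm_frame[sel_pcnm["axis"]].to_numpy()
            if len(sel_pcnm)
            else pcnm_frame.iloc[:, :2].to_numpy()
        )
        for climate_var in ("MAP", "MAT", "elevation"):
            if climate_var in metadata.columns:
                terms[climate_var] = metadata.loc[
                    rarefied.samples, climate_var
                ].to_numpy(float)
        perm = comm.permanova(
            bc, terms, strata=population.to_numpy(object),
            n_perm=config.n_perm, seed=seed,
        )
        perm.table.to_csv(out / "permanova.tsv", sep="\t")
        first = perm.table.index[0]
        summary.update(
            permanova_r2_host=float(perm.table.loc[first, "R2"]),
            permanova_p_host=float(perm.table.loc[first, "p"]),
            richness_wilcoxon_p=p_rich,
        )

        if d_ind is not None:
            mt = mantel(
                d_ind.reorder(bc.labels), bc, n_perm=config.n_perm, seed=seed
            )
            cd = cadm([d_ind.reorder(bc.labels), bc], n_perm=config.n_perm, seed=seed)
            summary.update(
                mantel_r=mt.r, mantel_p=mt.p, cadm_w=cd.W, cadm_p=cd.p
            )
        timings["community"] = time.time() - t0

    # --------------------------------------------------------------- network
    per_sample_metrics = None
    if "network" in config.stages:
        t0 = time.time()
        seed = _seed_for("network", config.seed)
        dense = net.abundance_filter(rarefied, config.min_rel_abundance)
        rho, pmat = net.spearman_matrix(dense)
        graph = net.build_network(
            rho, pmat, table=dense, rho_min=config.rho_min, alpha=config.alpha
        )
        net.detect_modules(graph, seed=seed)
        graph.to_graphml(out / "network.graphml")
        graph.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        topo = net.classify_roles(net.zi_pi(graph))
        topo.to_csv(out / "node_topology.tsv", sep="\t")
        metrics = net.topology_metrics(graph, seed=seed)
        _, er_summary = net.erdos_renyi_baseline(
            metrics.n_nodes, metrics.n_edges, n_reps=config.er_reps, seed=seed
        )
        er_summary.to_csv(out / "erdos_renyi_baseline.tsv", sep="\t")

        rows = {}
        node_set = set(graph.graph.nodes)
        for sid in rarefied.samples:
            present = rarefied.counts.columns[rarefied.counts.loc[sid] > 0]
            # restrict to the node universe up front: absence of unconnected
            # OTUs from the parent network is expected here, not a concern
            sub = net.induced_subnetwork(graph, [o for o in present if o in node_set])
            rows[sid] = net.topology_metrics(sub, seed=seed).as_dict()
        per_sample_metrics = pd.DataFrame.from_dict(rows, orient="index")
        per_sample_metrics.to_csv(out / "per_sample_metrics.tsv", sep="\t")
        region_cmp = net.compare_region_topologies(per_sample_metrics, region)
        region_cmp.to_csv(out / "region_topology_wilcoxon.tsv", sep="\t")

        summary.update(
            network_nodes=metrics.n_nodes, network_edges=metrics.n_edges,
            network_modularity=metrics.modularity,
            positive_edge_fraction=graph.positive_edge_fraction(),
            n_keystone=int(topo["keystone"].sum()),
            region_edges_p=float(region_cmp.loc["n_edges", "p"]),
        )
        timings["network"] = time.time() - t0

    # --------------------------------------------------------------- drivers
    if "drivers" in config.stages and per_sample_metrics is not None:
        t0 = time.time()
        seed = _seed_for("drivers", config.seed)
        predictors = {}
        if pge is not None:
            pf = pge.to_frame()
            predictors.update({c: pf[c] for c in pf.columns[: min(5, pf.shape[1])]})
        for climate_var in ("MAP", "MAT", "elevation"):
            if climate_var in metadata.columns:
                predictors[climate_var] = metadata.loc[rarefied.samples, climate_var]
        xmat = pd.DataFrame(predictors, index=rarefied.samples)
        rf_rows = []
        for metric in ("n_nodes", "n_edges", "avg_degree",
                       "degree_centralization", "closeness_centralization",
                       "modularity"):
            res = drv.rf_importance(
                xmat, per_sample_metrics[metric], n_trees=config.rf_n_trees,
                n_perm=config.rf_n_perm, seed=seed,
            )
            for pred, row in res.table.iterrows():
                rf_rows.append(dict(metric=metric, predictor=pred,
                                    importance=row["importance"], p=row["p"]))
        rf_table = pd.DataFrame(rf_rows)
        rf_table.to_csv(out / "rf_importance.tsv", sep="\t", index=False)

        # model the most informative taxa: variance of log relative
        # abundance, not total reads (abundant-but-flat OTUs carry no signal)
        logrel = np.log1p(
            rarefied.counts.div(rarefied.counts.sum(axis=1), axis=0) * 1e4
        )
        top = logrel.var(axis=0).nlargest(config.glm_top_otus).index
        glm_terms = {}
        if pge is not None:
            glm_terms["host_genetic_eigenvectors"] = pge.to_frame().iloc[:, :3].to_numpy()
        if "MAP" in metadata.columns:
            glm_terms["MAP"] = metadata.loc[rarefied.samples, "MAP"].to_numpy(float)
        glm = drv.multispecies_glm(
            rarefied.counts[top], glm_terms, n_perm=config.glm_n_perm, seed=seed
        )
        glm.table.to_csv(out / "multispecies_glm.tsv", sep="\t")
        summary["glm_p_host"] = float(glm.table["p"].iloc[0])
        timings["drivers"] = time.time() - t0

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            p.name: _hash_file(p) for p in sorted(out.iterdir()) if p.is_file()
            and p.name != "manifest.json"
        },
        "total_s": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
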