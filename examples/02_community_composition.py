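"""Community composition: rarefaction, Bray-Curtis, ANOSIM, PERMANOVA,
Mantel/CADM congruence with host genetic structure, indicator OTUs."""

from phyllonet import community as comm
from phyllonet import popgen, spatial
from phyllonet.distmat import cadm, mantel
from phyllonet.simulate import SimulationConfig, simulate_all

bundle = simulate_all(SimulationConfig(seed=1))
filtered, report = comm.filter_otus(
    bundle.otu_table, taxonomy=bundle.taxonomy,
    exclude_guilds=("ectomycorrhizal", "animal_pathogen"),
)
print(f"{report['n_kept']} OTUs kept "
      f"({len(report['removed_low_count'])} below 10 reads, "
      f"{len(report['removed_guild'])} excluded guilds)")
rarefied = comm.rarefy(filtered, depth=5415, seed=0)

bc = comm.bray_curtis(comm.hellinger(rarefied))
region = bundle.metadata["region"]

an = comm.anosim(bc, region.to_numpy(object), n_perm=999, seed=11)
print(f"ANOSIM R = {an.R:.3f} (p = {an.p:.3f})")
# R > 0: between-region community dissimilarities outrank within-region ones

pge = popgen.pge_vectors(popgen.allele_sharing_distance(bundle.genotypes))
coords = spatial.GeoCoordinates(
    rarefied.samples,
    bundle.metadata["latitude"].to_numpy(),
    bundle.metadata["longitude"].to_numpy(),
)
pcnm = spatial.pcnm_vectors(spatial.haversine_matrix(coords))
sel = comm.forward_select(bc, pge, alpha=0.05, n_perm=499, seed=3)
print(f"forward-selected PGE axes: {list(sel['axis'])}")

terms = {
    "host_genetic_eigenvectors": pge.to_frame()[sel["axis"]].to_numpy(),
    "geographic_distance": pcnm.to_frame().iloc[:, :3].to_numpy(),
    "MAP": bundle.metadata["MAP"].to_numpy(float),
}
res = comm.permanova(bc, terms, strata=bundle.metadata["population"].to_numpy(object),
                     n_perm=999, seed=5)
print(res.table.round(3))
# sequential R^2 per predictor block; permutations restricted within population

d_ind = popgen.allele_sharing_distance(bundle.genotypes).reorder(bc.labels)
mt = mantel(d_ind, bc, n_perm=999, seed=21)
cd = cadm([d_ind, bc], n_perm=499, seed=22)
print(f"Mantel host-genetic vs community: r = {mt.r:.3f} (p = {mt.p:.3f})")
print(f"CADM concordance: W = {cd.W:.3f} (p = {cd.p:.3f})")
# both significant: plants with similar genotypes carry similar fungi

ind = comm.indicator_features(rarefied, region, seed=9)
print(f"{len(ind)} indicator OTUs at effect >= 3.0; top rows:")
print(ind.head(5).to_string(index=False))
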