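"""Synthetic genotypes, geography, climate and OTU tables.

The generator emulates the sampling design the analyses assume: two
regions (a mainland and an island group), three populations per region,
ten plants per population, eleven polymorphic microsatellite loci with
hierarchical Balding–Nichols divergence, and a phyllosphere OTU count
table with planted co-occurrence modules, a multi-module hub OTU, a
host-genotype effect on composition, and a mainland-enriched OTU block
that produces both the regional composition shift and the denser
mainland co-occurrence networks.

Ground truth (module memberships, hub identity, effect sizes) is
emitted alongside the data for recovery tests; analysis modules never
read it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .community import OtuTable
from .distmat import pcoa
from .popgen import GenotypeMatrix, allele_sharing_distance
from .spatial import GeoCoordinates

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticBundle",
           "simulate_genotypes", "simulate_geography_climate",
           "simulate_otu_table", "simulate_taxonomy", "simulate_all"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    The defaults reproduce the study conditions: 2 regions x 3
    populations x 10 plants, 11 diploid loci, regional Fst ~ 0.1, and a
    rarefaction-scale OTU table (depth 5415, ~770 OTUs).
    """

    # genotypes
    n_regions: int = 2
    n_pops_per_region: int = 3
    n_plants_per_pop: int = 10
    n_loci: int = 11
    alleles_per_locus: int = 8
    fst_between_regions: float = 0.10
    fst_within_region: float = 0.05
    # OTU table
    n_otus: int = 772
    n_rare_otus: int = 40          # sub-10-read OTUs destined for the count filter
    depth: int = 5415
    depth_margin: int = 2000       # raw per-sample extra reads above depth
    n_modules: int = 6
    module_size: int = 15
    within_module_rho: float = 0.75
    host_effect_beta: float = 1.0
    n_host_otus: int = 40
    region_effect: float = 4.0     # log-scale mainland boost of the region module
    n_region_modules: int = 1
    n_hub_modules: int = 5
    hub_loading: float = 0.84
    module_log_abundance: float = 2.5
    host_log_abundance: float = 1.5
    hub_log_abundance: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst_between_regions < 1 or not 0 < self.fst_within_region < 1:
            raise ValueError("fst parameters must lie in (0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if self.n_modules * self.module_size + 1 + self.n_host_otus > self.n_otus:
            raise ValueError("module sizes exceed the OTU budget")
        if not 0 < self.within_module_rho < 1:
            raise ValueError("within_module_rho must lie in (0, 1)")
        if self.n_hub_modules > self.n_modules:
            raise ValueError("hub cannot span more modules than exist")
        if self.n_region_modules > self.n_modules:
            raise ValueError("more region modules than modules")

    @classmethod
    def small(cls, **overrides) -> "SimulationConfig":
        """A reduced configuration for quick tests and examples."""
        defaults = dict(
            n_otus=160, n_rare_otus=10, depth=2000, depth_margin=800,
            n_modules=4, module_size=10, n_host_otus=20, n_hub_modules=3,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to the synthetic data."""

    region_of_sample: dict[str, str]
    module_of_otu: dict[str, int]
    hub_otu: str
    host_otus: list[str]
    region_module_otus: list[str]
    host_effect_beta: float
    region_effect: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticBundle:
    genotypes: GenotypeMatrix
    coords: GeoCoordinates
    metadata: pd.DataFrame
    otu_table: OtuTable
    taxonomy: pd.DataFrame
    truth: SyntheticTruth

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_csv(d / "genotypes.csv")
        self.metadata.to_csv(d / "metadata.tsv", sep="\t", index_label="sample_id")
        self.otu_table.to_tsv(d / "otu_table.tsv")
        self.taxonomy.to_csv(d / "taxonomy.tsv", sep="\t", index_label="otu_id")
        self.truth.to_json(d / "truth.json")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _bn_frequencies(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols (Dirichlet) draw of derived allele frequencies
    around ancestral frequencies ``p`` at divergence ``fst``."""
    conc = p * (1.0 - fst) / fst
    return rng.dirichlet(np.maximum(conc, 1e-8))


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Hierarchical Balding–Nichols microsatellite genotypes.

    Ancestral allele frequencies per locus are symmetric-Dirichlet;
    regional frequencies diverge at ``fst_between_regions`` and
    population frequencies within regions at ``fst_within_region``;
    diploid individuals draw two independent alleles per locus.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    regions = [f"R{r + 1}" for r in range(cfg.n_regions)]
    region_names = (
        ["mainland", "island"] if cfg.n_regions == 2 else regions
    )
    ids, pops, regs = [], [], []
    allele_codes = np.arange(1, cfg.alleles_per_locus + 1) * 2 + 100  # sizes
    calls = []
    pop_freqs: dict[tuple[int, int], list[np.ndarray]] = {}
    for l in range(cfg.n_loci):
        anc = rng.dirichlet(np.ones(cfg.alleles_per_locus))
        for r in range(cfg.n_regions):
            reg_f = _bn_frequencies(anc, cfg.fst_between_regions, rng)
            for p in range(cfg.n_pops_per_region):
                pop_freqs.setdefault((r, p), []).append(
                    _bn_frequencies(reg_f, cfg.fst_within_region, rng)
                )
    for r in range(cfg.n_regions):
        for p in range(cfg.n_pops_per_region):
            pop_name = f"{region_names[r][:2].upper()}{p + 1}"
            for i in range(cfg.n_plants_per_pop):
                ids.append(f"{pop_name}_{i + 1:02d}")
                pops.append(pop_name)
                regs.append(region_names[r])
                geno = np.empty((cfg.n_loci, 2), dtype=int)
                for l in range(cfg.n_loci):
                    f = pop_freqs[(r, p)][l]
                    geno[l] = allele_codes[rng.choice(cfg.alleles_per_locus, 2, p=f)]
                calls.append(geno)
    loci = [f"L{l + 1:02d}" for l in range(cfg.n_loci)]
    return GenotypeMatrix(ids, np.array(pops, dtype=object),
                          np.array(regs, dtype=object), loci, np.stack(calls))


# ---------------------------------------------------------------------------
# geography and climate
# ---------------------------------------------------------------------------


def simulate_geography_climate(
    cfg: SimulationConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[GeoCoordinates, pd.DataFrame]:
    """Site coordinates, elevation and climate per plant.

    Two regional coordinate clusters roughly 100 km apart along a
    subtropical coast; plants inherit their site's coordinates. Climate
    (MAT degC, MAP mm) carries a regional offset plus site noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    region_centers = {
        reg: (22.0 + 0.9 * k, 112.5 + 0.9 * k)
        for k, reg in enumerate(pd.unique(genotypes.region))
    }
    site_rows = {}
    for pop in genotypes.populations:
        reg = genotypes.population_region_map()[pop]
        clat, clon = region_centers[reg]
        lat = clat + rng.uniform(-0.12, 0.12)
        lon = clon + rng.uniform(-0.12, 0.12)
        elev = (
            rng.uniform(200, 400) if reg == pd.unique(genotypes.region)[0]
            else rng.uniform(40, 160)
        )
        mat = 21.5 + (0.6 if reg == pd.unique(genotypes.region)[0] else -0.4) + rng.normal(0, 0.2)
        map_ = 1750 + (120 if reg == pd.unique(genotypes.region)[0] else -130) + rng.normal(0, 40)
        site_rows[pop] = (lat, lon, elev, mat, map_)
    lat = np.array([site_rows[p][0] for p in genotypes.population])
    lon = np.array([site_rows[p][1] for p in genotypes.population])
    elev = np.array([site_rows[p][2] for p in genotypes.population])
    coords = GeoCoordinates(genotypes.ids, lat, lon, elev)
    meta = pd.DataFrame(
        {
            "population": genotypes.population,
            "region": genotypes.region,
            "latitude": lat,
            "longitude": lon,
            "elevation": elev,
            "MAT": [site_rows[p][3] for p in genotypes.population],
            "MAP": [site_rows[p][4] for p in genotypes.population],
        },
        index=pd.Index(genotypes.ids, name="sample_id"),
    )
    return coords, meta


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------


def _host_axis(genotypes: GenotypeMatrix) -> np.ndarray:
    """Standardized first PCoA axis of the allele-sharing distances."""
    axes = pcoa(allele_sharing_distance(genotypes))
    g = axes.vectors[:, 0]
    return (g - g.mean()) / g.std()


def simulate_otu_table(
    cfg: SimulationConfig,
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """Latent Gaussian factor model for the phyllosphere OTU counts.

    Per module one standard-normal latent factor per sample induces
    within-block correlation ``within_module_rho`` (Gaussian copula:
    ranks survive the exponential mapping). The hub OTU is coupled to
    the first ``n_hub_modules`` module factors through a shared latent
    variable. Host-responsive OTUs shift along the first genotype PCoA
    axis by ``host_effect_beta`` (half positively, half negatively);
    members of the region module carry a mainland abundance boost of
    ``region_effect`` log units, making them largely island-absent. The
    latent values map through ``exp`` to log-normal-like relative
    abundances sampled multinomially at the raw per-sample depth.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n = genotypes.n
    samples = genotypes.ids
    regions = np.asarray(genotypes.region, dtype=object)
    mainland = regions == pd.unique(regions)[0]
    g_axis = _host_axis(genotypes)
    if g_axis[mainland].mean() < 0:
        g_axis = -g_axis  # orient the (sign-arbitrary) axis toward the mainland

    n_module_otus = cfg.n_modules * cfg.module_size
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(cfg.n_otus + cfg.n_rare_otus)]
    module_of: dict[str, int] = {}
    base = np.zeros(cfg.n_otus)

    # latent factors
    hub_latent = rng.normal(size=n)
    factors = np.empty((n, cfg.n_modules))
    for m in range(cfg.n_modules):
        if m < cfg.n_hub_modules:
            factors[:, m] = (
                cfg.hub_loading * hub_latent
                + np.sqrt(1 - cfg.hub_loading**2) * rng.normal(size=n)
            )
        else:
            factors[:, m] = rng.normal(size=n)

    z = np.empty((n, cfg.n_otus))
    rho = cfg.within_module_rho
    col = 0
    region_modules = list(range(cfg.n_modules - cfg.n_region_modules, cfg.n_modules))
    region_otus: list[str] = []
    for m in range(cfg.n_modules):
        for _ in range(cfg.module_size):
            otu = otu_ids[col]
            module_of[otu] = m
            base[col] = cfg.module_log_abundance
            z[:, col] = np.sqrt(rho) * factors[:, m] + np.sqrt(1 - rho) * rng.normal(size=n)
            if m in region_modules:
                z[:, col] += np.where(mainland, cfg.region_effect, 0.0)
                base[col] -= cfg.region_effect  # mainland ~ module level, island depressed
                region_otus.append(otu)
            col += 1
    hub_otu = otu_ids[col]
    base[col] = cfg.hub_log_abundance
    z[:, col] = hub_latent
    col += 1
    host_otus = otu_ids[col : col + cfg.n_host_otus]
    for k in range(cfg.n_host_otus):
        base[col] = cfg.host_log_abundance
        z[:, col] = cfg.host_effect_beta * g_axis + rng.normal(size=n)
        col += 1
    # remaining OTUs: independent noise carrying most of the read mass, so
    # the planted blocks do not dominate the compositional denominator
    n_noise = cfg.n_otus - col
    z[:, col:] = rng.normal(size=(n, n_noise))
    base[col:] = rng.normal(1.0, 1.2, size=n_noise)

    weights = np.exp(base[None, :] + z)
    raw_depths = cfg.depth + 415 + rng.integers(0, cfg.depth_margin, size=n)
    counts = np.zeros((n, cfg.n_otus + cfg.n_rare_otus), dtype=int)
    for i in range(n):
        p = weights[i] / weights[i].sum()
        counts[i, : cfg.n_otus] = rng.multinomial(int(raw_depths[i]), p)
    # rare OTUs: a handful of reads in total, below the count filter
    for k in range(cfg.n_rare_otus):
        n_reads = int(rng.integers(1, 10))
        for _ in range(n_reads):
            counts[rng.integers(0, n), cfg.n_otus + k] += 1

    table = OtuTable(
        pd.DataFrame(counts, index=pd.Index(samples), columns=otu_ids),
        metadata=metadata,
        state="raw",
    )
    truth = SyntheticTruth(
        region_of_sample={s: str(r) for s, r in zip(samples, regions)},
        module_of_otu=module_of,
        hub_otu=hub_otu,
        host_otus=list(host_otus),
        region_module_otus=region_otus,
        host_effect_beta=cfg.host_effect_beta,
        region_effect=cfg.region_effect,
    )
    return table, truth


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_CLASSES = {
    "Dothideomycetes": ["Capnodiales", "Pleosporales", "Botryosphaeriales"],
    "Sordariomycetes": ["Hypocreales", "Xylariales", "Diaporthales"],
    "Eurotiomycetes": ["Eurotiales", "Chaetothyriales"],
    "Tremellomycetes": ["Tremellales"],
}
_GENERA = [
    "Nigrospora", "Phoma", "Acremonium", "Stagonospora", "Phomopsis",
    "Hortaea", "Preussia", "Sphaceloma", "Trichomerium", "Curvularia",
    "Myrothecium", "Glomerella", "Fusidium", "Paraconiothyrium", "Cladosporium",
]


def simulate_taxonomy(
    otu_ids: list[str], rng: np.random.Generator, guild_fraction: float = 0.03
) -> pd.DataFrame:
    """Synthetic best-hit taxonomy with identity/e-value annotations.

    Identities are drawn over 70–100% so all truncation rules are
    exercised; a small fraction of records carry unreliable e-values
    (above 1e-50) or excluded guilds (mycorrhizal / animal-pathogen).
    """
    rows = []
    classes = list(_CLASSES)
    for otu in otu_ids:
        cls = classes[rng.integers(len(classes))]
        order = _CLASSES[cls][rng.integers(len(_CLASSES[cls]))]
        genus = _GENERA[rng.integers(len(_GENERA))]
        identity = float(np.round(rng.uniform(70, 100), 1))
        evalue = float(10.0 ** rng.uniform(-180, -30))
        u = rng.random()
        guild = (
            "ectomycorrhizal" if u < guild_fraction / 2
            else "animal_pathogen" if u < guild_fraction
            else "undefined"
        )
        rows.append(
            dict(
                otu_id=otu, identity=identity, evalue=evalue,
                kingdom="Fungi", phylum="Ascomycota",
                **{"class": cls}, order=order, family=f"{order}_fam",
                genus=genus, guild=guild,
            )
        )
    return pd.DataFrame(rows).set_index("otu_id")


# ---------------------------------------------------------------------------
# everything at once
# ---------------------------------------------------------------------------


def simulate_all(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate a complete coherent input bundle from one config/seed."""
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(2**31, size=4)
    genotypes = simulate_genotypes(cfg, np.random.default_rng(int(seeds[0])))
    coords, metadata = simulate_geography_climate(
        cfg, genotypes, np.random.default_rng(int(seeds[1]))
    )
    table, truth = simulate_otu_table(
        cfg, genotypes, metadata, np.random.default_rng(int(seeds[2]))
    )
    taxonomy = simulate_taxonomy(table.otus, np.random.default_rng(int(seeds[3])))
    return SyntheticBundle(genotypes, coords, metadata, table, taxonomy, truth)
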