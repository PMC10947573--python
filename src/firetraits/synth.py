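"""Synthetic fire-gradient community generator with known ground truth.

The generator emulates the statistical structure of a long-term
fire-frequency experiment along a savanna-forest ecotone: 12 plots holding
9 realized fire frequencies spanning 0-0.77 fires/year, ~89 herbaceous
species in 6 functional groups, cover turnover along the gradient, species
trait means carrying phylogenetic signal, within-species linear trait
responses to fire, and individual-level measurement noise.

Community structure follows a Gaussian coenocline: each species has a fire
optimum and its expected cover is a Gaussian niche kernel around that
optimum times multiplicative log-normal sampling noise. Optima are drawn
uniformly over the fire range extended by a margin on both sides; a species
pool truncated exactly at the sampled gradient would attenuate the
community-weighted mean optimum near the gradient ends and bias the
interspecific slope recovery, whereas the extended pool keeps the
cover-weighted mean optimum tracking plot fire frequency almost one-to-one
(see docs/methods.md for the design calculation).

Species mean traits are a linear function of the fire optimum
(the interspecific component beta) plus a lambda-scaled Brownian deviation
on the simulated phylogeny (phylogenetic signal with known lambda).
Individuals add the intraspecific component delta times plot fire frequency
plus i.i.d. noise. Every stochastic component draws from an independent
substream of one master seed, so regeneration is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .community import CoverTable
from .cwm import derive_traits
from .phylo import Phylogeny, covariance_matrix, lambda_transform

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "assign_taxonomy",
    "simulate_optima",
    "simulate_species_traits",
    "simulate_cover",
    "simulate_individuals",
    "simulate_environment",
    "make_dataset",
]

#: Realized fire frequencies (fires/year) of the 12 plots: three unburned,
#: two burned about once per decade, two about every third year, two in
#: alternate years, and three burned about three years in four.
DEFAULT_FIRE_LEVELS = (
    0.0, 0.0, 0.0, 0.10, 0.12, 0.31, 0.33, 0.48, 0.52, 0.72, 0.75, 0.77
)

FUNCTIONAL_GROUPS = (
    "C4_grass", "C3_grass", "forb", "N_fixing_forb", "shrub", "woody",
)


@dataclass
class SimulationConfig:
    """Generating parameters; defaults are the emulated study's conditions."""

    n_plots: int = 12
    fire_levels: tuple = DEFAULT_FIRE_LEVELS
    n_species: int = 89
    n_functional_groups: int = 6
    niche_breadth: float = 0.33            # fires/yr
    optima_margin: float = 0.6             # fires/yr beyond the gradient ends
    peak_cover: float = 80.0               # percent cover at a species' optimum
    cover_lognormal_sd: float = 0.6        # multiplicative cover noise (log scale)
    sampling_threshold: float = 0.5        # percent cover; survey/trait floor
    interspecific_slope_n: float = -7.0    # (mg/g) per (fires/yr)
    intraspecific_slope_n: float = -3.6
    interspecific_slope_sla: float = -190.0  # (cm^2/g) per (fires/yr)
    intraspecific_slope_sla: float = -78.0
    baseline_n_mass: float = 24.5          # mg/g at a fire optimum of 0
    baseline_sla: float = 380.0            # cm^2/g at a fire optimum of 0
    baseline_percent_c: float = 45.0
    trait_signal_lambda: float = 0.75
    bm_sd: dict = field(default_factory=lambda: {"n_mass": 3.0, "sla": 60.0})
    individual_noise_sd: dict = field(
        default_factory=lambda: {"n_mass": 2.0, "sla": 40.0, "percent_c": 1.5}
    )
    individuals_per_species_plot: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_plots < 2:
            raise ValueError("n_plots must be >= 2")
        if len(self.fire_levels) != self.n_plots:
            raise ValueError("fire_levels must have one entry per plot")
        if any(f < 0 for f in self.fire_levels):
            raise ValueError("fire frequencies must be >= 0")
        if not 0 <= self.trait_signal_lambda <= 1:
            raise ValueError("trait_signal_lambda must be in [0, 1]")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be > 0")
        if any(v < 0 for v in self.individual_noise_sd.values()):
            raise ValueError("individual noise sd must be >= 0")
        if self.individuals_per_species_plot < 1:
            raise ValueError("individuals_per_species_plot must be >= 1")

    @property
    def plots(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_plots)]

    def fire_by_plot(self) -> pd.Series:
        return pd.Series(list(self.fire_levels), index=self.plots,
                         name="fire_freq")


@dataclass
class SyntheticDataset:
    """Generated tables plus the generating truth."""

    cover: CoverTable
    traits: pd.DataFrame       # derived individual-level trait table
    environment: pd.DataFrame
    tree: Phylogeny
    taxonomy: pd.DataFrame
    truth: dict


def _substreams(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def _yule_tree(n_species: int, rng) -> dendropy.Tree:
    """Pure-birth (Yule) tree, run past the n-th speciation so every
    terminal branch has positive length (an exact cut at the last split
    would leave zero-length cherries and a singular covariance matrix)."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    for c in (c1, c2):
        root.add_child(c)
        c.birth_time = 0.0
    active = [c1, c2]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.split_time = t
        a, b = dendropy.Node(), dendropy.Node()
        for c in (a, b):
            node.add_child(c)
            c.birth_time = t
        active.extend([a, b])
    t += rng.exponential(1.0 / len(active))
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = 0.0
        elif node.is_leaf():
            node.edge.length = t - node.birth_time
        else:
            node.edge.length = node.split_time - node.birth_time
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.require_taxon(label=f"T{i}")
    return tree


def simulate_tree(n_species: int, seed: int) -> Phylogeny:
    """Random pure-birth ultrametric tree with genus-structured tip labels.

    Tips are labelled ``Genus##_sp##`` where genera are clades cut at a
    fixed relative depth, so congeners cluster. Depth is scaled to 1.
    Deterministic for a given (n_species, seed).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    tree = _yule_tree(n_species, np.random.default_rng(int(seed)))
    # scale maximum root-to-tip depth to 1
    depths = {}
    maxd = 0.0
    for node in tree.preorder_node_iter():
        d = (depths[node.parent_node] if node.parent_node else 0.0) + float(
            node.edge.length or 0.0
        )
        depths[node] = d
        maxd = max(maxd, d)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / maxd
    for node in tree.preorder_node_iter():
        depths[node] /= maxd

    # genera: maximal clades whose stem crosses relative depth 0.75
    cut = 0.75
    genus_id = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        pd_depth = depths[parent] if parent else 0.0
        if depths[node] >= cut and pd_depth < cut:
            genus_id += 1
            leaves = [node] if node.is_leaf() else list(node.leaf_iter())
            for j, leaf in enumerate(leaves, start=1):
                leaf.taxon.label = f"Genus{genus_id:02d}_sp{j:02d}"
    return Phylogeny(tree)


def _clade_blocks(tree: Phylogeny, cut: float) -> list[list[str]]:
    dtree = tree.tree
    depths = tree._node_depths()
    maxd = max(depths[lf] for lf in dtree.leaf_node_iter())
    blocks = []
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        pdepth = depths[parent] if parent else 0.0
        if depths[node] >= cut * maxd and pdepth < cut * maxd:
            leaves = [node] if node.is_leaf() else list(node.leaf_iter())
            blocks.append(sorted(lf.taxon.label for lf in leaves))
    return blocks


def assign_taxonomy(tree: Phylogeny, n_functional_groups: int = 6) -> pd.DataFrame:
    """Species -> genus / family / functional group from clade structure.

    Genera come from the tip labels; families are clades cut at relative
    depth 0.5; functional groups are deeper clade blocks (relative depth
    0.3) cycled through the group names, so group membership is
    phylogenetically structured.
    """
    species = tree.tip_labels
    genus = {sp: sp.split("_", 1)[0] for sp in species}
    fam_blocks = _clade_blocks(tree, 0.5)
    family = {}
    for i, block in enumerate(fam_blocks, start=1):
        for sp in block:
            family[sp] = f"Family{i:02d}"
    # shallowest cut yielding at least n_functional_groups clade blocks
    grp_blocks = _clade_blocks(tree, 0.05)
    for cut in np.arange(0.05, 1.0, 0.05):
        blocks = _clade_blocks(tree, cut)
        if len(blocks) >= n_functional_groups:
            grp_blocks = blocks
            break
    names = [FUNCTIONAL_GROUPS[i % len(FUNCTIONAL_GROUPS)]
             for i in range(max(n_functional_groups, 1))]
    group = {}
    for i, block in enumerate(grp_blocks):
        for sp in block:
            group[sp] = names[i % len(names)]
    return pd.DataFrame(
        {
            "species": species,
            "genus": [genus[s] for s in species],
            "family": [family[s] for s in species],
            "functional_group": [group[s] for s in species],
        }
    ).set_index("species")


def simulate_optima(cfg: SimulationConfig, rng) -> pd.Series:
    """Species fire optima: uniform over the gradient extended by the margin."""
    lo = min(cfg.fire_levels) - cfg.optima_margin
    hi = max(cfg.fire_levels) + cfg.optima_margin
    return pd.Series(rng.uniform(lo, hi, cfg.n_species), name="optimum")


def simulate_species_traits(
    tree: Phylogeny,
    cfg: SimulationConfig,
    optima: pd.Series,
    rng,
) -> pd.DataFrame:
    """Species mean traits: linear in the fire optimum plus lambda-BM deviation.

    The Brownian deviation for each trait is multivariate normal with
    covariance bm_sd^2 times the lambda transform of the unit-depth tree's
    shared path-length matrix, so the realized phylogenetic signal is known.
    """
    species = tree.tip_labels
    if len(optima) != len(species):
        raise ValueError("need one optimum per species")
    optima = pd.Series(np.asarray(optima, float), index=species)
    C = covariance_matrix(tree)
    V = np.asarray(lambda_transform(C, cfg.trait_signal_lambda), dtype=float)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(len(V)))
    out = pd.DataFrame(index=pd.Index(species, name="species"))
    slopes = {"n_mass": cfg.interspecific_slope_n,
              "sla": cfg.interspecific_slope_sla}
    baselines = {"n_mass": cfg.baseline_n_mass, "sla": cfg.baseline_sla}
    for trait in ("n_mass", "sla"):
        dev = cfg.bm_sd.get(trait, 0.0) * (L @ rng.standard_normal(len(species)))
        out[trait] = baselines[trait] + slopes[trait] * optima.values + dev
    out["optimum"] = optima.values
    return out


def simulate_cover(cfg: SimulationConfig, optima: pd.Series, rng,
                   taxonomy: pd.DataFrame | None = None,
                   species: list | None = None) -> CoverTable:
    """Plot x species percent cover from the Gaussian niche kernel.

    cover(plot, sp) = peak_cover * exp(-(f_plot - o_sp)^2 / (2 b^2)) times
    log-normal noise; covers below the survey detection floor
    (``sampling_threshold``) are recorded as absent, mirroring the minimum
    cover class of the field protocol. Raw covers are kept (the Domin
    design has no upper limit on total cover).
    """
    if cfg.niche_breadth <= 0:
        raise ValueError("niche_breadth must be > 0")
    fire = np.asarray(cfg.fire_levels, dtype=float)
    opt = np.asarray(optima, dtype=float)
    if species is None:
        species = [f"sp{i + 1:03d}" for i in range(len(opt))]
    kernel = np.exp(-((fire[:, None] - opt[None, :]) ** 2)
                    / (2.0 * cfg.niche_breadth ** 2))
    noise = (
        np.exp(rng.normal(0.0, cfg.cover_lognormal_sd, kernel.shape))
        if cfg.cover_lognormal_sd > 0
        else 1.0
    )
    cover = cfg.peak_cover * kernel * noise
    cover[cover < cfg.sampling_threshold] = 0.0
    mat = pd.DataFrame(cover, index=cfg.plots, columns=list(species))
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {
                "genus": [s.split("_", 1)[0] for s in species],
                "family": [s.split("_", 1)[0] for s in species],
                "functional_group": "unknown",
            },
            index=pd.Index(list(species), name="species"),
        )
    return CoverTable(matrix=mat, taxonomy=taxonomy)


def simulate_individuals(
    cover: CoverTable,
    species_traits: pd.DataFrame,
    cfg: SimulationConfig,
    rng,
) -> pd.DataFrame:
    """Raw individual-level measurements for every present (plot, species).

    trait = species mean + intraspecific slope * plot fire + N(0, noise_sd),
    for each of ``individuals_per_species_plot`` individuals. %C is drawn
    around its baseline so C:N is computable. Traits are floored at small
    positive physiological minima (SLA 20 cm^2/g, N 1 mg/g) to keep derived
    ratios defined; with the default noise levels the floor is rarely hit.
    """
    fire = cfg.fire_by_plot()
    rows = []
    k = cfg.individuals_per_species_plot
    sd = cfg.individual_noise_sd
    for plot in cover.matrix.index:
        f = fire[plot]
        present = cover.matrix.loc[plot]
        present = present[present >= cfg.sampling_threshold]
        for sp in present.index:
            base_n = species_traits.loc[sp, "n_mass"] + cfg.intraspecific_slope_n * f
            base_sla = species_traits.loc[sp, "sla"] + cfg.intraspecific_slope_sla * f
            for i in range(k):
                n_mass = base_n + rng.normal(0.0, sd.get("n_mass", 0.0))
                sla = base_sla + rng.normal(0.0, sd.get("sla", 0.0))
                pc = cfg.baseline_percent_c + rng.normal(0.0, sd.get("percent_c", 0.0))
                rows.append(
                    (plot, sp, i + 1, max(n_mass, 1.0) / 10.0,
                     float(np.clip(pc, 30.0, 60.0)), max(sla, 20.0))
                )
    return pd.DataFrame(
        rows,
        columns=["plot", "species", "individual", "percent_n", "percent_c", "sla"],
    )


def simulate_environment(cfg: SimulationConfig, rng,
                         years=(2001, 2002, 2003, 2004, 2005)) -> pd.DataFrame:
    """Plot environment with repeated soil measurements across years.

    Light penetration rises linearly with fire frequency (≈12% under fire
    exclusion to ≈76% under near-annual burning); net N mineralisation and
    standing inorganic N decline quadratically (5.15 -> 1.15 and
    0.51 -> 0.24 kg N/ha); total soil N declines linearly (2.75 -> 1.68
    Mg N/ha). Soil variables carry a plot-level random intercept plus
    year-to-year noise, the structure the random-intercept mixed model
    targets.
    """
    fire = cfg.fire_by_plot()
    f = fire.values
    light_mu = 12.0 + (76.0 - 12.0) / 0.77 * f
    nmin_mu = 5.15 - 7.5 * f + 3.0 * f ** 2
    inorg_mu = 0.51 - 0.582 * f + 0.3 * f ** 2
    totn_mu = 2.75 - 1.39 * f
    light = light_mu + rng.normal(0, 4.0, len(f))
    totn = totn_mu + rng.normal(0, 0.15, len(f))
    re_nmin = rng.normal(0, 0.5, len(f))
    re_inorg = rng.normal(0, 0.04, len(f))
    rows = []
    for yi, year in enumerate(years):
        nmin = nmin_mu + re_nmin + rng.normal(0, 0.45, len(f))
        inorg = inorg_mu + re_inorg + rng.normal(0, 0.05, len(f))
        for i, plot in enumerate(fire.index):
            rows.append(
                (plot, year, f[i], float(np.clip(light[i], 0, 100)),
                 max(nmin[i], 0.05), max(inorg[i], 0.01), max(totn[i], 0.1))
            )
    return pd.DataFrame(
        rows,
        columns=["plot", "year", "fire_freq", "light_penetration",
                 "n_mineralisation", "inorganic_n", "total_soil_n"],
    )


def make_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full dataset from one master seed.

    One seed governs tree, optima, species traits, cover, individuals and
    environment through independent substreams, so components can be
    regenerated independently yet the whole dataset is reproducible
    byte-for-byte.
    """
    cfg = cfg or SimulationConfig()
    streams = _substreams(cfg.rng_seed, 6)
    tree_seed = int(streams[0].generate_state(1)[0] % (2 ** 31))
    tree = simulate_tree(cfg.n_species, tree_seed)
    taxonomy = assign_taxonomy(tree, cfg.n_functional_groups)
    species = tree.tip_labels

    rng_opt = np.random.default_rng(streams[1])
    optima = simulate_optima(cfg, rng_opt)
    optima.index = species

    rng_traits = np.random.default_rng(streams[2])
    sp_traits = simulate_species_traits(tree, cfg, optima, rng_traits)

    rng_cover = np.random.default_rng(streams[3])
    cover = simulate_cover(cfg, optima, rng_cover, taxonomy=taxonomy,
                           species=species)

    rng_ind = np.random.default_rng(streams[4])
    raw = simulate_individuals(cover, sp_traits, cfg, rng_ind)
    traits = derive_traits(raw)

    rng_env = np.random.default_rng(streams[5])
    env = simulate_environment(cfg, rng_env)

    # dataset invariant: every species with cover appears in the trait table
    covered = set(cover.matrix.columns[(cover.matrix > 0).any(axis=0)])
    sampled = set(traits["species"])
    assert covered <= sampled, "cover/trait invariant violated"

    truth = {
        "config": asdict(cfg),
        "optima": optima.to_dict(),
        "species_means": sp_traits[["n_mass", "sla"]].to_dict(orient="index"),
        "true_slopes": {
            "n_mass": {
                "interspecific": cfg.interspecific_slope_n,
                "intraspecific": cfg.intraspecific_slope_n,
                "full": cfg.interspecific_slope_n + cfg.intraspecific_slope_n,
            },
            "sla": {
                "interspecific": cfg.interspecific_slope_sla,
                "intraspecific": cfg.intraspecific_slope_sla,
                "full": cfg.interspecific_slope_sla + cfg.intraspecific_slope_sla,
            },
        },
        "trait_signal_lambda": cfg.trait_signal_lambda,
    }
    return SyntheticDataset(
        cover=cover, traits=traits, environment=env, tree=tree,
        taxonomy=taxonomy, truth=truth,
    )
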