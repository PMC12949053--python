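"""Synthetic phylogenies, trait tables, plot inventories and rasters.

The generators emulate the statistical structure the downstream analyses
assume, so the whole chain — signal detection, taxonomy-based comparison,
community-weighted means, clustering and interpolation — is testable without
any field data:

* pure-birth (Yule) genus trees with positive branch lengths, tips ending at
  the present;
* Brownian-motion trait evolution with a tunable signal fraction
  ``signal_lambda`` mixing the BM realisation with white noise of matched
  marginal variance (``1`` gives pure BM, K near 1; ``0`` gives pure noise,
  K near 0);
* a species-by-site psi50 table (MPa, negative) with monophyletic families
  and orders cut from the tree, and site dry-season-length classes;
* stem-level plot inventories on a planar km domain whose designated
  "resistant family" share of basal area climbs west to east with strength
  ``gradient_strength``, with log-normal stem basal areas;
* smooth (Gaussian-filtered) environmental rasters standing in for drought
  intensity (MCWD-like, negative mm) and water-table depth (WTD-like, m).

Every generator takes an explicit integer seed; a bundle seed deterministically
derives per-stage seeds through :class:`numpy.random.SeedSequence`, so a fixed
``SimConfig`` reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError, InvalidTreeError
from .gridio import AsciiGrid
from .phylosignal import Phylogeny

__all__ = [
    "SimConfig",
    "SyntheticBundle",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_trait_table",
    "simulate_inventories",
    "simulate_env_rasters",
    "simulate_bundle",
]

FOREST_TYPES = ("long_DSL", "intermediate_DSL", "everwet")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the defaults the tests assume.

    Core fields: random ``seed``; ``n_tips`` genera in the Yule tree grown at
    ``birth_rate`` per unit time; BM rate ``bm_sigma2`` (trait variance per
    unit branch length); ``signal_lambda`` in [0, 1]; ``n_plots`` inventory
    plots of ``stems_per_plot`` stems on a ``domain_extent`` (km) box; and
    ``gradient_strength``, the dimensionless log-odds swing of the resistant
    family's share across the domain's x axis.
    """

    seed: int = 0
    n_tips: int = 100
    birth_rate: float = 1.0
    bm_sigma2: float = 0.25
    signal_lambda: float = 1.0
    n_plots: int = 150
    stems_per_plot: int = 150
    domain_extent: tuple[float, float, float, float] = (0.0, 0.0, 2000.0, 1500.0)
    gradient_strength: float = 4.0
    # secondary knobs (sensible field-like defaults)
    root_psi50: float = -2.0
    n_sites: int = 11
    species_per_genus_rate: float = 0.5  # 1 + Poisson(rate) species per genus
    sites_per_species_rate: float = 0.7  # 1 + Poisson(rate) site records
    species_sd: float = 0.25  # within-genus species deviation, MPa
    site_sd: float = 0.15  # site-to-site replicate deviation, MPa
    family_cut: float = 0.35  # depth fraction at which families are cut
    order_cut: float = 0.15  # depth fraction at which orders are cut
    resistant_shift: float = -0.8  # MPa shift planted on the resistant family
    monocot_fraction: float = 0.05
    unmatched_fraction: float = 0.03
    basal_area_log_mean: float = -3.0  # log m^2; exp(-3) ~ 0.05 m^2
    basal_area_log_sd: float = 0.8
    patch_strength: float = 0.8  # log-odds amplitude of regional patchiness
    patch_length_km: float = 700.0  # correlation length of the patches
    cell_size: float = 25.0  # km, for the environmental rasters

    def __post_init__(self):
        if not 0.0 <= self.signal_lambda <= 1.0:
            raise InvalidArgumentError("signal_lambda must lie in [0, 1]")
        for name in ("n_tips", "n_plots", "stems_per_plot", "n_sites"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")
        x0, y0, x1, y1 = self.domain_extent
        if x1 <= x0 or y1 <= y0:
            raise InvalidArgumentError("domain_extent must have positive area")


@dataclass
class SyntheticBundle:
    """A complete synthetic study: tree, traits, inventories, rasters."""

    config: SimConfig
    tree: Phylogeny
    traits: pd.DataFrame
    inventories: pd.DataFrame
    rasters: dict[str, AsciiGrid]
    genus_values: dict[str, float]
    resistant_family: str

    def write(self, outdir) -> None:
        """Emit the bundle as plain-text files under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.traits.to_csv(out / "traits.csv", index=False)
        self.inventories.to_csv(out / "inventories.csv", index=False)
        for name, grid in self.rasters.items():
            grid.write(out / f"{name}.asc")


# ---------------------------------------------------------------------------
# tree and traits


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | None = None
) -> Phylogeny:
    """Pure-birth ultrametric tree with ``n_tips`` labelled tips.

    The process starts from the root split (two lineages at time 0); while
    fewer than ``n_tips`` lineages exist, an exponential waiting time with
    rate ``k * birth_rate`` elapses and a uniformly chosen lineage splits.
    After the last split one further exponential interval passes, so terminal
    branches are strictly positive. Tips are labelled ``G001 ...`` in
    birth order. Tree depth is therefore a sum of independent exponentials
    with mean ``(H_n - 1) / birth_rate`` (``H_n`` the n-th harmonic number).
    """
    if n_tips < 2:
        raise InvalidArgumentError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    root = tree.seed_node
    root_time = {id(root): 0.0}
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [c1, c2]
    born = {id(c1): 0.0, id(c2): 0.0}
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node = active.pop(i)
        node.edge.length = t - born[id(node)]
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        born[id(a)] = born[id(b)] = t
        active.extend([a, b])
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    width = max(3, len(str(n_tips)))
    order = sorted(active, key=lambda nd: born[id(nd)])
    for j, node in enumerate(order):
        node.edge.length = t - born[id(node)]
        node.taxon = taxa.new_taxon(label=f"G{j + 1:0{width}d}")
    del root_time
    return Phylogeny(tree)


def simulate_bm_traits(
    tree: Phylogeny,
    sigma2: float,
    signal_lambda: float = 1.0,
    root_value: float = 0.0,
    seed: int | None = None,
) -> dict[str, float]:
    """Tip trait values from a BM/white-noise mixture.

    A Brownian walk with rate ``sigma2`` runs down the tree from
    ``root_value``; the returned tip value is

    ``root + signal_lambda * (BM_tip - root) + (1 - signal_lambda) * eps``

    with ``eps`` i.i.d. normal with the BM marginal tip variance
    ``sigma2 * depth(tip)``, so the mean stays at ``root_value`` for every
    ``signal_lambda`` and the two anchors are pure BM (K near 1) and pure
    noise (K near 0).
    """
    if sigma2 < 0:
        raise InvalidArgumentError("sigma2 must be >= 0")
    if not 0.0 <= signal_lambda <= 1.0:
        raise InvalidArgumentError("signal_lambda must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dtree = tree._tree
    value = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            value[id(node)] = root_value
            continue
        bl = node.edge.length
        if bl is None:
            raise InvalidTreeError("tree has edges without branch lengths")
        value[id(node)] = value[id(node.parent_node)] + rng.normal(
            0.0, np.sqrt(sigma2 * bl)
        )
    depths = tree.tip_depths()
    out = {}
    for lab, tip, depth in zip(tree.tip_labels, tree._tips, depths):
        eps = rng.normal(0.0, np.sqrt(sigma2 * depth))
        bm_dev = value[id(tip)] - root_value
        out[lab] = float(
            root_value + signal_lambda * bm_dev + (1.0 - signal_lambda) * eps
        )
    return out


def _cut_clades(tree: Phylogeny, depth_fraction: float, prefix: str) -> dict[str, str]:
    """Assign each tip the monophyletic group hanging from the edge crossing
    ``depth_fraction`` of the maximum tree depth. Returns tip -> group name."""
    T = float(tree.tip_depths().max())
    cut = depth_fraction * T
    groups: dict[str, str] = {}
    counter = [0]

    def walk(node, parent_depth):
        d = tree._depth[node]
        if parent_depth <= cut < d or (node.is_leaf() and d <= cut):
            counter[0] += 1
            name = f"{prefix}{counter[0]:02d}"
            if node.is_leaf():
                lab = node.taxon.label if node.taxon is not None else node.label
                groups[str(lab)] = name
            else:
                for leaf in node.leaf_iter():
                    lab = leaf.taxon.label if leaf.taxon is not None else leaf.label
                    groups[str(lab)] = name
            return
        for child in node.child_nodes():
            walk(child, d)

    root = tree._tree.seed_node
    walk(root, -np.inf)
    return groups


def simulate_trait_table(
    tree: Phylogeny, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, float], str]:
    """Species-by-site psi50 table with tree-consistent taxonomy.

    Families and orders are monophyletic clades cut from the tree at fixed
    depth fractions; genus mean values come from the BM mixture, the largest
    family is shifted by ``resistant_shift`` MPa (the planted Fabaceae-like
    contrast), and species/site records scatter around the genus mean. psi50
    is clipped to stay strictly negative. Returns the table, the genus-mean
    map used for it, and the resistant family's name.
    """
    rng = np.random.default_rng(seed)
    s_tree, s_noise = map(int, rng.integers(0, 2**31 - 1, size=2))
    genus_vals = simulate_bm_traits(
        tree,
        sigma2=config.bm_sigma2,
        signal_lambda=config.signal_lambda,
        root_value=config.root_psi50,
        seed=s_tree,
    )
    family = _cut_clades(tree, config.family_cut, "Fam")
    order = _cut_clades(tree, config.order_cut, "Ord")
    fam_sizes = pd.Series(family).value_counts()
    resistant_family = str(fam_sizes.index[0])
    # plant the family contrast exactly: recentre the resistant family's genus
    # means to (mean of the others) + resistant_shift, keeping their spread
    res = [g for g in genus_vals if family[g] == resistant_family]
    oth = [g for g in genus_vals if family[g] != resistant_family]
    if res and oth:
        target = float(np.mean([genus_vals[g] for g in oth])) + config.resistant_shift
        offset = target - float(np.mean([genus_vals[g] for g in res]))
        for g in res:
            genus_vals[g] += offset
    genus_vals = {g: min(v, -0.05) for g, v in genus_vals.items()}

    site_ids = [f"S{j + 1:02d}" for j in range(config.n_sites)]
    site_types = [FOREST_TYPES[j % len(FOREST_TYPES)] for j in range(config.n_sites)]
    rng2 = np.random.default_rng(s_noise)
    rows = []
    for genus in tree.tip_labels:
        n_sp = 1 + rng2.poisson(config.species_per_genus_rate)
        for s in range(n_sp):
            species = f"{genus}_sp{s + 1}"
            sp_val = genus_vals[genus] + rng2.normal(0.0, config.species_sd)
            n_site = 1 + rng2.poisson(config.sites_per_species_rate)
            picks = rng2.choice(config.n_sites, size=min(n_site, config.n_sites),
                                replace=False)
            for si in picks:
                psi = min(sp_val + rng2.normal(0.0, config.site_sd), -0.05)
                rows.append(
                    {
                        "species": species,
                        "genus": genus,
                        "family": family[genus],
                        "order": order[genus],
                        "site": site_ids[si],
                        "forest_type": site_types[si],
                        "psi50": psi,
                    }
                )
    return pd.DataFrame(rows), genus_vals, resistant_family


# ---------------------------------------------------------------------------
# inventories and rasters


def simulate_inventories(
    tree: Phylogeny,
    traits: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    resistant_family: str | None = None,
) -> pd.DataFrame:
    """Stem-level plot inventories on the planar domain.

    Plot locations are uniform over ``domain_extent``. Stems pick a family
    with probability proportional to its genus count, tilted in log-odds for
    the resistant family by a linear west-east gradient of strength
    ``gradient_strength`` plus a smooth regional patchiness field of
    amplitude ``patch_strength`` and correlation length ``patch_length_km``
    (floristic regions, not just a single cline); a genus within the family
    and a species within the genus are drawn uniformly. Basal areas are
    log-normal. A small fraction of stems are monocots (palm-like, no trait
    coverage) and another small fraction are dicots of an unmatched family,
    to exercise the coverage filter and the plot-mean gap-fill fallback.
    """
    if traits.empty:
        raise InvalidArgumentError("traits table is empty")
    rng = np.random.default_rng(seed)
    fam_genera = traits.groupby("family")["genus"].unique().to_dict()
    families = sorted(fam_genera)
    if resistant_family is None:
        resistant_family = max(families, key=lambda f: len(fam_genera[f]))
    base = np.array([len(fam_genera[f]) for f in families], dtype=float)
    res_idx = families.index(resistant_family)
    species_of = traits.groupby("genus")["species"].unique().to_dict()
    x0, y0, x1, y1 = config.domain_extent
    # smooth patchiness field on a coarse grid, unit variance
    cell = config.patch_length_km / 3.0
    pnx = max(4, int(np.ceil((x1 - x0) / cell)))
    pny = max(4, int(np.ceil((y1 - y0) / cell)))
    patch = ndimage.gaussian_filter(
        rng.normal(size=(pny, pnx)), 3.0, mode="nearest"
    )
    sd = patch.std()
    patch = patch / sd if sd > 0 else patch
    rows = []
    for p in range(config.n_plots):
        px = rng.uniform(x0, x1)
        py = rng.uniform(y0, y1)
        xnorm = (px - x0) / (x1 - x0)  # 0 at west edge, 1 at east
        ix = min(pnx - 1, int((px - x0) / cell))
        iy = min(pny - 1, int((py - y0) / cell))
        w = base.copy()
        w[res_idx] *= np.exp(
            config.gradient_strength * (xnorm - 0.5)
            + config.patch_strength * patch[iy, ix]
        )
        w /= w.sum()
        plot_id = f"P{p + 1:04d}"
        for _ in range(config.stems_per_plot):
            ba = float(
                np.exp(rng.normal(config.basal_area_log_mean, config.basal_area_log_sd))
            )
            u = rng.uniform()
            if u < config.monocot_fraction:
                rows.append(
                    dict(plot_id=plot_id, x_km=px, y_km=py, species="Palmus_indet",
                         genus="Palmus", family="Palmaceae", basal_area=ba,
                         dicot=False)
                )
                continue
            if u < config.monocot_fraction + config.unmatched_fraction:
                rows.append(
                    dict(plot_id=plot_id, x_km=px, y_km=py, species="Ignotus_indet",
                         genus="Ignotus", family="FamUnknown", basal_area=ba,
                         dicot=True)
                )
                continue
            fam = families[int(rng.choice(len(families), p=w))]
            genus = str(rng.choice(fam_genera[fam]))
            species = str(rng.choice(species_of[genus]))
            rows.append(
                dict(plot_id=plot_id, x_km=px, y_km=py, species=species,
                     genus=genus, family=fam, basal_area=ba, dicot=True)
            )
    return pd.DataFrame(rows)


def simulate_env_rasters(
    domain_extent: tuple[float, float, float, float],
    cell_size: float,
    seed: int | None = None,
    smooth_cells: float = 3.0,
    constant: dict[str, float] | None = None,
) -> dict[str, AsciiGrid]:
    """Smooth MCWD-like and WTD-like grids covering the extent.

    Each field is Gaussian-filtered white noise (correlation length
    ``smooth_cells`` cells) plus a west-east trend, rescaled to field-like
    units: MCWD in negative mm (drought intensity), WTD in positive metres.
    ``constant`` maps layer name to a constant value for the degenerate mode
    used in extrapolation-diagnostic edge cases.
    """
    if cell_size <= 0:
        raise InvalidArgumentError("cell_size must be > 0")
    x0, y0, x1, y1 = domain_extent
    nx = max(2, int(np.ceil((x1 - x0) / cell_size)))
    ny = max(2, int(np.ceil((y1 - y0) / cell_size)))
    rng = np.random.default_rng(seed)
    xnorm = (np.arange(nx) + 0.5) / nx

    def smooth_field():
        z = rng.normal(size=(ny, nx))
        z = ndimage.gaussian_filter(z, smooth_cells, mode="nearest")
        sd = z.std()
        return z / sd if sd > 0 else z

    grids = {}
    specs = {
        "mcwd": lambda z: -(250.0 + 180.0 * xnorm[None, :] + 60.0 * z),
        "wtd": lambda z: np.maximum(1.0, 12.0 + 6.0 * z - 4.0 * xnorm[None, :]),
    }
    for name, make in specs.items():
        if constant is not None and name in constant:
            data = np.full((ny, nx), float(constant[name]))
        else:
            data = make(smooth_field())
        grids[name] = AsciiGrid(
            values=np.asarray(data, dtype=float), xll=x0, yll=y0, cell_size=cell_size
        )
    return grids


# ---------------------------------------------------------------------------
# bundle


def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """Generate a full, internally consistent synthetic study.

    Stage seeds derive deterministically from ``config.seed`` via
    ``SeedSequence.spawn``, so the bundle is bit-reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_inv, s_env = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    ]
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, seed=s_tree)
    traits, genus_vals, resistant = simulate_trait_table(tree, config, seed=s_traits)
    inventories = simulate_inventories(
        tree, traits, config, seed=s_inv, resistant_family=resistant
    )
    rasters = simulate_env_rasters(
        config.domain_extent, config.cell_size, seed=s_env
    )
    return SyntheticBundle(
        config=config,
        tree=tree,
        traits=traits,
        inventories=inventories,
        rasters=rasters,
        genus_values=genus_vals,
        resistant_family=resistant,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
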