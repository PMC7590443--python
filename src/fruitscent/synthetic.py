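"""Synthetic fruit-scent data with the structure the analyses assume.

Generators for (i) pure-birth phylogenies, (ii) Brownian-motion traits with
the covariance implied by a tree, (iii) zero-inflated compositional scent
tables with species replicates and biochemical-class structure, and (iv)
paired ripe/unripe profiles whose class-level rank correlation is calibrated
to a target.  These emulate the statistical shape of headspace GC-MS
surveys — strictly positive right-skewed amounts, many absences, few
dominant classes — not the underlying biosynthesis.

Everything is bit-reproducible under (config, seed).
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from fruitscent.physignal import phylo_cov
from fruitscent.voctable import CLASS_ORDER, ClassMap, ScentTable, SpeciesProfile

__all__ = [
    "SimConfig", "PairedSimulation", "simulate_tree", "simulate_bm_traits",
    "simulate_scent_table", "simulate_paired_ripe_unripe",
]

#: Compound-count mix over the seven classes: aliphatics, aromatics and
#: terpenoids dominate fruit headspace, C5-branched / N-S / misc-cyclic are
#: minor, and a sliver of peaks stays unidentified.
DEFAULT_CLASS_PROPORTIONS: tuple[float, ...] = (
    0.32, 0.20, 0.05, 0.30, 0.05, 0.05, 0.03
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generators.

    Defaults mirror a single-site survey: 30 species, 3 sampled individuals
    per species, ~120 detected volatiles, strongly zero-inflated profiles.
    """

    n_species: int = 30
    n_individuals_per_species: int = 3
    n_compounds: int = 120
    class_proportions: tuple[float, ...] = DEFAULT_CLASS_PROPORTIONS
    zero_inflation: float = 0.7
    bm_sigma2: float = 1.0
    target_class_rho: float = 0.7
    compound_turnover: float = 0.8
    #: log-scale SD of species-level class weights (right-skewed dominance)
    class_dispersion: float = 1.0
    #: log-scale SD of individual-level multiplicative noise
    individual_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if len(self.class_proportions) != len(CLASS_ORDER):
            raise ValueError(f"class_proportions needs {len(CLASS_ORDER)} entries")
        props = np.asarray(self.class_proportions, dtype=float)
        if (props < 0).any() or not np.isclose(props.sum(), 1.0):
            raise ValueError("class_proportions must be non-negative and sum to 1")
        if props.max() == 0:
            raise ValueError("all-zero class proportions")
        for name in ("zero_inflation", "compound_turnover"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 <= self.target_class_rho <= 1:
            raise ValueError("target_class_rho must lie in [-1, 1]")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be >= 0")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def species_names(n: int) -> list[str]:
    return [f"sp{i + 1:03d}" for i in range(n)]


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree on ``n_species`` tips, scaled to unit depth."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    from dendropy.model import birthdeath

    rng = _random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tree.seed_node.edge.length = 0.0
    # the simulator stops exactly at the n-th speciation, leaving zero-length
    # sister tips; run the clock to the next event so tips are distinct
    extra = rng.expovariate(n_species * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= depth
    for name, leaf in zip(species_names(n_species),
                          sorted(tree.leaf_node_iter(),
                                 key=lambda l: l.taxon.label)):
        leaf.taxon.label = name
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree, p_axes: int, bm_sigma2: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Draw ``p_axes`` independent Brownian-motion traits on a tree.

    Each column is multivariate normal with covariance ``bm_sigma2 * C``,
    where C is the phylogenetic covariance; ``bm_sigma2 = 0`` degenerates to
    constant (zero) columns.
    """
    if bm_sigma2 < 0:
        raise ValueError("bm_sigma2 must be >= 0")
    cov = phylo_cov(tree)
    n = len(cov.labels)
    if bm_sigma2 == 0:
        return pd.DataFrame(np.zeros((n, p_axes)), index=cov.labels)
    # tiny jitter: polytomy-born zero branches keep C PSD but cholesky fussy
    L = np.linalg.cholesky(cov.C + 1e-12 * np.trace(cov.C) / n * np.eye(n))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p_axes))
    X = np.sqrt(bm_sigma2) * (L @ Z)
    return pd.DataFrame(X, index=cov.labels)


def _assign_classes(rng: np.random.Generator, config: SimConfig) -> ClassMap:
    props = np.asarray(config.class_proportions, dtype=float)
    draws = rng.choice(len(CLASS_ORDER), size=config.n_compounds, p=props)
    compounds = [f"c{i + 1:04d}" for i in range(config.n_compounds)]
    return ClassMap({c: CLASS_ORDER[k] for c, k in zip(compounds, draws)})


def simulate_scent_table(
    config: SimConfig,
    tree: dendropy.Tree | None = None,
    phylo_signal: float = 0.0,
    ripeness: str = "ripe",
) -> tuple[ScentTable, ClassMap]:
    """Zero-inflated species x compound amounts with individual replicates.

    Per species and compound, presence is Bernoulli(1 - zero_inflation) and
    positive amounts are log-normal.  Individuals multiply the species
    profile by log-normal noise.  With a ``tree`` and ``phylo_signal > 0``,
    per-compound Brownian-motion effects (variance ``bm_sigma2``) enter both
    the log amounts and the presence pattern (a latent-threshold model kept
    at the same expected sparsity), so related species share scent
    structure — the knob used to inject genuine phylogenetic signal.
    """
    rng = np.random.default_rng(config.seed)
    classmap = _assign_classes(rng, config)
    compounds = sorted(classmap.class_of)
    names = species_names(config.n_species)
    if tree is not None:
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        if len(tips) != config.n_species:
            raise ValueError("tree tip count must equal n_species")
        names = tips

    shape = (config.n_species, config.n_compounds)
    log_amount = rng.normal(0.0, 1.0, size=shape)
    if tree is not None and phylo_signal > 0:
        seeds = rng.integers(2**31, size=2)
        bm = simulate_bm_traits(tree, config.n_compounds, config.bm_sigma2,
                                seed=int(seeds[0])).loc[names].to_numpy()
        log_amount = log_amount + phylo_signal * bm
        bm_presence = simulate_bm_traits(tree, config.n_compounds,
                                         config.bm_sigma2,
                                         seed=int(seeds[1])).loc[names].to_numpy()
        latent = rng.standard_normal(shape) + phylo_signal * bm_presence
        cutoff = np.quantile(latent, config.zero_inflation, axis=0)
        present = latent >= cutoff
    else:
        present = rng.random(shape) >= config.zero_inflation
    base = np.where(present, np.exp(log_amount), 0.0)
    if not present.any():
        warnings.warn("zero_inflation produced an all-zero table", stacklevel=2)

    rows, meta_rows, index = [], [], []
    for i, sp in enumerate(names):
        for j in range(config.n_individuals_per_species):
            noise = np.exp(rng.normal(0.0, config.individual_noise,
                                      size=config.n_compounds))
            rows.append(base[i] * noise)
            sample = f"{sp}_{ripeness[0]}{j + 1}"
            index.append(sample)
            meta_rows.append({"species": sp, "individual": f"{sp}_ind{j + 1}",
                              "ripeness": ripeness, "site": "SIM"})
    amounts = pd.DataFrame(rows, index=index, columns=compounds)
    meta = pd.DataFrame(meta_rows, index=index)
    return ScentTable(amounts, meta), classmap


# ---------------------------------------------------------------------------
# paired ripe / unripe generator
# ---------------------------------------------------------------------------

def _pearson_for_spearman(rho_s: float) -> float:
    """Gaussian-copula latent correlation giving a target Spearman's rho.

    For bivariate normals rho_s = (6 / pi) * arcsin(r / 2); this inverts it.
    """
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass
class PairedSimulation:
    """Output of :func:`simulate_paired_ripe_unripe`."""

    ripe_classes: SpeciesProfile
    unripe_classes: SpeciesProfile
    ripe_table: ScentTable
    unripe_table: ScentTable
    classmap: ClassMap
    latent_correlation: float = 0.0


def simulate_paired_ripe_unripe(config: SimConfig) -> PairedSimulation:
    """Ripe and unripe profiles with a controlled class-level correlation.

    Class weights for each stage come from a Gaussian copula: the latent
    normals of ripe and unripe share Pearson correlation r chosen so the
    implied Spearman correlation is ``target_class_rho``; log-normal
    transformation then yields right-skewed class weights that are closed
    (normalised) into compositions.  Within each class, the ripe stage keeps
    an unripe compound with probability ``1 - compound_turnover`` and
    otherwise swaps in a different class member — so a high-turnover,
    high-rho configuration reproduces the signature pattern: similar class
    budgets built from different molecules.
    """
    rng = np.random.default_rng(config.seed)
    classmap = _assign_classes(rng, config)
    compounds = sorted(classmap.class_of)
    by_class: dict[str, list[str]] = {c: [] for c in CLASS_ORDER}
    for cmp_id in compounds:
        by_class[classmap[cmp_id]].append(cmp_id)
    names = species_names(config.n_species)
    n, k = config.n_species, len(CLASS_ORDER)

    r = _pearson_for_spearman(config.target_class_rho)
    z_u = rng.standard_normal((n, k))
    eps = rng.standard_normal((n, k))
    z_r = r * z_u + np.sqrt(max(0.0, 1.0 - r * r)) * eps
    if config.target_class_rho == 1.0:
        z_r = z_u.copy()
    mu = np.log(np.asarray(config.class_proportions, dtype=float) + 1e-12)
    w_u = np.exp(mu + config.class_dispersion * z_u)
    w_r = np.exp(mu + config.class_dispersion * z_r)
    # empty classes (no member compounds) cannot carry weight
    empty = np.array([len(by_class[c]) == 0 for c in CLASS_ORDER])
    w_u[:, empty] = 0.0
    w_r[:, empty] = 0.0
    comp_u = w_u / w_u.sum(axis=1, keepdims=True)
    comp_r = w_r / w_r.sum(axis=1, keepdims=True)
    cols = list(CLASS_ORDER)
    unripe_classes = SpeciesProfile(
        pd.DataFrame(comp_u, index=names, columns=cols), level="class")
    ripe_classes = SpeciesProfile(
        pd.DataFrame(comp_r, index=names, columns=cols), level="class")

    # compound level: distribute each class budget over member compounds
    def _empty_amounts() -> pd.DataFrame:
        return pd.DataFrame(0.0, index=names, columns=compounds)

    amounts_u, amounts_r = _empty_amounts(), _empty_amounts()
    totals = np.exp(rng.normal(2.0, 0.5, size=n))  # per-species total emission
    for i, sp in enumerate(names):
        for ci, cls in enumerate(CLASS_ORDER):
            members = by_class[cls]
            if not members:
                continue
            n_sup = max(1, int(round((1 - config.zero_inflation) * len(members))))
            support_u = list(rng.choice(members, size=min(n_sup, len(members)),
                                        replace=False))
            support_r = []
            pool = [m for m in members if m not in support_u]
            rng.shuffle(pool)
            for m in support_u:
                if rng.random() < config.compound_turnover and pool:
                    support_r.append(pool.pop())
                else:
                    support_r.append(m)
            for table, support, comp in (
                (amounts_u, support_u, comp_u), (amounts_r, support_r, comp_r)
            ):
                shares = rng.dirichlet(np.ones(len(support)))
                budget = totals[i] * comp[i, ci]
                for m, sh in zip(support, shares):
                    table.loc[sp, m] += budget * sh

    def _table(amounts: pd.DataFrame, stage: str) -> ScentTable:
        idx = [f"{sp}_{stage[0]}1" for sp in names]
        df = amounts.copy()
        df.index = idx
        meta = pd.DataFrame(
            {"species": names, "individual": [f"{sp}_ind1" for sp in names],
             "ripeness": stage, "site": "SIM"}, index=idx)
        return ScentTable(df, meta)

    return PairedSimulation(
        ripe_classes, unripe_classes,
        _table(amounts_r, "ripe"), _table(amounts_u, "unripe"),
        classmap, latent_correlation=r,
    )
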