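"""Synthetic communities with known assembly regimes.

Generates a pure-birth phylogeny, a lognormal metacommunity, Brownian niche
optima, per-sample environments, communities assembled neutrally or under
Gaussian environmental filtering, and metabolite matrices with a planted
subset of environment-coupled compounds — so that every inference stage of
the pipeline can be tested against ground truth.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .community_data import (
    AsvTable,
    MetaboliteTable,
    Phylogeny,
    TaxonomyTable,
    write_asv_table,
)

__all__ = [
    "SyntheticScenario",
    "simulate_tree",
    "evolve_optima",
    "simulate_metacommunity",
    "simulate_neutral",
    "simulate_selected",
    "simulate_clade_filtered",
    "simulate_homogenizing",
    "simulate_metabolites",
    "assign_genera",
    "make_keystone_scenario",
    "make_scenario",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = (
    "neutral",
    "variable",
    "homogeneous",
    "homogenizing",
    "keystone",
    "drivers",
)


# ---------------------------------------------------------------------------
# tree and traits
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self) -> None:
        self.children: tuple["_Node", "_Node"] | None = None
        self.length = 0.0
        self.label: str | None = None

    def newick(self) -> str:
        if self.children is None:
            return f"{self.label}:{self.length:.10f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10f}"


def simulate_tree(n_tips: int, seed: int, height: float = 1.0) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with unit birth rate.

    Tip labels are T0001... in a deterministic traversal order; the tree is
    rescaled so every root-to-tip path equals ``height``.
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = np.random.default_rng(seed)
    root = _Node()
    active: list[tuple[_Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, start = active.pop(i)
        node.length = t - start
        left, right = _Node(), _Node()
        node.children = (left, right)
        active.append((left, t))
        active.append((right, t))
    present = t + rng.exponential(1.0 / n_tips)
    for node, start in active:
        node.length = present - start

    # rescale to the requested height and label leaves preorder
    scale = height / present

    def walk(node: _Node) -> None:
        node.length *= scale
        if node.children:
            for c in node.children:
                walk(c)

    walk(root)
    counter = [0]
    width = max(4, len(str(n_tips)))

    def label(node: _Node) -> None:
        if node.children is None:
            counter[0] += 1
            node.label = f"T{counter[0]:0{width}d}"
        else:
            for c in node.children:
                label(c)

    label(root)
    return Phylogeny.from_newick(root.newick() + ";")


def evolve_optima(tree: Phylogeny, sigma_bm: float, seed: int) -> pd.Series:
    """Brownian-motion niche optima on the tree, root value 0.

    Tip values are jointly normal with covariance sigma_bm^2 times the
    shared root-to-MRCA path length.
    """
    if sigma_bm <= 0:
        raise ValueError("sigma_bm must be positive")
    rng = np.random.default_rng(seed)
    dtree = tree.tree
    vals: dict[object, float] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            vals[node] = 0.0
        else:
            edge = node.edge.length or 0.0
            vals[node] = vals[node.parent_node] + rng.normal(
                0.0, sigma_bm * np.sqrt(edge)
            )
    tips = {
        leaf.taxon.label: vals[leaf] for leaf in dtree.leaf_node_iter()
    }
    return pd.Series(
        [tips[l] for l in tree.leaf_labels], index=tree.leaf_labels,
        name="optimum",
    )


def simulate_metacommunity(
    n_taxa: int, lognormal_sigma: float, seed: int
) -> np.ndarray:
    """Lognormal metacommunity relative abundances summing to 1."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=n_taxa))
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# community assembly regimes
# ---------------------------------------------------------------------------

def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{j + 1:03d}" for j in range(n)]


def simulate_neutral(
    meta: np.ndarray,
    N: int,
    m: float,
    n_samples: int,
    seed: int,
    taxon_ids=None,
) -> AsvTable:
    """Communities from the neutral model's stationary beta marginals.

    Per sample and taxon a latent frequency is drawn from
    Beta(N*m*p_i, N*m*(1-p_i)) and the latent vector renormalised. Taxa
    whose latent frequency exceeds the detection limit 1/N form the sample's
    community: each receives one seed read and the remaining reads are
    distributed multinomially in proportion to the latent frequencies. This
    makes detection coincide exactly with the fitted model's threshold rule
    (frequency > 1/N) — a plain multinomial read layer would add a second
    detection process the model does not describe and biases migration-rate
    recovery upward by ~30%.
    """
    if N < 100:
        raise ValueError("N must be at least 100")
    if not 0 < m <= 1:
        raise ValueError("m must lie in (0, 1]")
    meta = np.asarray(meta, dtype=float)
    p = np.clip(meta, 1e-12, 1 - 1e-12)
    rng = np.random.default_rng(seed)
    nm = N * m
    counts = np.zeros((meta.size, n_samples))
    for j in range(n_samples):
        latent = rng.beta(nm * p, nm * (1.0 - p))
        latent /= latent.sum()
        present = latent > 1.0 / N
        k = int(present.sum())
        if k == 0:  # pathological; keep the single largest taxon
            present = latent == latent.max()
            k = int(present.sum())
        if k > N:
            raise ValueError("more detected taxa than reads; increase N")
        sub = latent[present]
        counts[present, j] = 1 + rng.multinomial(N - k, sub / sub.sum())
    ids = list(taxon_ids) if taxon_ids is not None else [
        f"T{i + 1:04d}" for i in range(meta.size)
    ]
    return AsvTable(ids, _sample_ids(n_samples), counts, mode="counts")


def simulate_selected(
    meta: np.ndarray,
    optima: np.ndarray,
    env: np.ndarray,
    sigma_sel: float,
    N: int,
    seed: int,
    taxon_ids=None,
    drift_sigma: float = 2.0,
) -> AsvTable:
    """Communities under Gaussian environmental filtering with drift.

    Sample s draws N reads multinomially with weights
    w_i(s) proportional to meta_i * exp(-(optima_i - env_s)^2 / (2*sigma_sel^2)).
    ``drift_sigma`` adds iid per-sample lognormal noise to the weights so
    that samples sharing an environment still turn over taxa *within* the
    favoured clades — without it, replicate communities are compositionally
    identical and convergent selection leaves no nearest-taxon signal.
    """
    if sigma_sel <= 0:
        raise ValueError("sigma_sel must be positive")
    if drift_sigma < 0:
        raise ValueError("drift_sigma must be non-negative")
    meta = np.asarray(meta, dtype=float)
    optima = np.asarray(optima, dtype=float)
    env = np.asarray(env, dtype=float)
    if optima.shape != meta.shape:
        raise ValueError("optima and metacommunity lengths differ")
    rng = np.random.default_rng(seed)
    counts = np.empty((meta.size, env.size))
    for s, e in enumerate(env):
        w = meta * np.exp(-((optima - e) ** 2) / (2.0 * sigma_sel**2))
        if drift_sigma > 0:
            w = w * np.exp(rng.normal(0.0, drift_sigma, size=meta.size))
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError(
                "selection weights underflowed to zero; increase sigma_sel"
            )
        counts[:, s] = rng.multinomial(N, w / total)
    ids = list(taxon_ids) if taxon_ids is not None else [
        f"T{i + 1:04d}" for i in range(meta.size)
    ]
    return AsvTable(ids, _sample_ids(env.size), counts, mode="counts")


def simulate_clade_filtered(
    meta: np.ndarray,
    clade_mask: np.ndarray,
    N: int,
    n_samples: int,
    seed: int,
    retention: float = 0.6,
    background_eps: float = 0.01,
    background_retention: float = 0.1,
    taxon_ids=None,
) -> AsvTable:
    """Convergent (homogeneous) selection: every sample assembles from one
    favoured clade.

    ``background_eps`` and ``background_retention`` leave non-clade taxa a
    small, per-sample-thinned residual presence, so the *observed* regional
    pool (which defines the betaNTI null) still spans the whole tree while
    each single sample stays dominated by the clade; with a hard filter the
    pool would collapse onto the clade and the null would lose its frame of
    reference, while an un-thinned background pads every sample's support
    with tree-wide taxa and dilutes the nearest-taxon signal.

    This is the perfectly-conserved-niche limit of Gaussian environmental
    filtering: the niche axis is clade membership, every sample sits at the
    clade's optimum, and the filter width tends to zero. Bernoulli
    ``retention`` thins the clade independently per sample so replicate
    communities still turn over taxa *within* the clade (ecological drift);
    without turnover there is no nearest-taxon signal to detect. Gaussian
    filtering on a scalar Brownian trait cannot express this regime at desk
    scale (~200 taxa): unrelated clades converge on any scalar trait value,
    which caps the betaNTI signal well above the -2 threshold.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    meta = np.asarray(meta, dtype=float)
    clade_mask = np.asarray(clade_mask, dtype=bool)
    if clade_mask.shape != meta.shape:
        raise ValueError("clade mask and metacommunity lengths differ")
    if not clade_mask.any():
        raise ValueError("empty favoured clade")
    rng = np.random.default_rng(seed)
    base = np.where(clade_mask, meta, background_eps * meta)
    counts = np.empty((meta.size, n_samples))
    for j in range(n_samples):

        def draw_keep():
            u = rng.random(meta.size)
            return np.where(
                clade_mask, u < retention, u < background_retention
            )

        keep = draw_keep()
        while (base * keep)[clade_mask].sum() <= 0:
            keep = draw_keep()
        w = base * keep
        counts[:, j] = rng.multinomial(N, w / w.sum())
    ids = list(taxon_ids) if taxon_ids is not None else [
        f"T{i + 1:04d}" for i in range(meta.size)
    ]
    return AsvTable(ids, _sample_ids(n_samples), counts, mode="counts")


def simulate_homogenizing(
    meta: np.ndarray,
    N: int,
    n_samples: int,
    seed: int,
    taxon_ids=None,
) -> AsvTable:
    """Near-identical communities: every sample is a multinomial draw from
    one shared composition, so observed dissimilarity sits far below the
    richness-matched null (a phenomenological stand-in for very high
    dispersal, not a mechanistic model)."""
    meta = np.asarray(meta, dtype=float)
    rng = np.random.default_rng(seed)
    shared = meta / meta.sum()
    counts = np.empty((meta.size, n_samples))
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(N, shared)
    ids = list(taxon_ids) if taxon_ids is not None else [
        f"T{i + 1:04d}" for i in range(meta.size)
    ]
    return AsvTable(ids, _sample_ids(n_samples), counts, mode="counts")


# ---------------------------------------------------------------------------
# metabolites and taxonomy
# ---------------------------------------------------------------------------

def simulate_metabolites(
    env: np.ndarray,
    n_compounds: int,
    n_informative: int,
    coupling: float,
    noise_sd: float,
    seed: int,
    sample_ids=None,
    noise_sigma: float = 1.0,
    n_classes: int = 11,
) -> tuple[MetaboliteTable, list[str]]:
    """Metabolite intensities with ``n_informative`` environment-coupled
    compounds among lognormal noise.

    Informative compounds have log-intensity coupling*env + N(0, noise_sd);
    the rest are pure lognormal noise with log-sd ``noise_sigma``. Returns
    the table and the list of informative compound ids (the ground truth).
    """
    if n_informative > n_compounds:
        raise ValueError("n_informative exceeds n_compounds")
    env = np.asarray(env, dtype=float)
    rng = np.random.default_rng(seed)
    ids = [f"MET{i + 1:03d}" for i in range(n_compounds)]
    informative_idx = set(
        rng.choice(n_compounds, size=n_informative, replace=False).tolist()
    )
    informative = sorted(ids[i] for i in informative_idx)
    x = np.empty((n_compounds, env.size))
    for i in range(n_compounds):
        if i in informative_idx:
            x[i] = np.exp(coupling * env + rng.normal(0, noise_sd, env.size))
        else:
            x[i] = np.exp(rng.normal(0.0, noise_sigma, env.size))
    classes = {
        cid: f"G{(i % n_classes) + 1:02d}" for i, cid in enumerate(ids)
    }
    samples = (
        list(sample_ids) if sample_ids is not None else _sample_ids(env.size)
    )
    table = MetaboliteTable(ids, samples, x, classes=classes)
    return table, informative


def assign_genera(
    tree: Phylogeny,
    n_genera: int = 8,
    keystone_labels=None,
    keystone_genus: str = "Keystone",
    seed: int = 0,
) -> TaxonomyTable:
    """Genus labels from patristic clustering of the tree's leaves.

    Leaves in ``keystone_labels`` get the ``keystone_genus`` label; the
    remainder are cut into ``n_genera`` patristic clusters G01..Gnn. Higher
    ranks are filled with placeholder values.
    """
    labels = tree.leaf_labels
    keystone = set(keystone_labels or [])
    others = [l for l in labels if l not in keystone]
    d = tree.patristic_matrix(order=others)
    z = linkage(squareform(d, checks=False), method="average")
    clusters = fcluster(z, t=n_genera, criterion="maxclust")
    lineage = {}
    for label in labels:
        if label in keystone:
            genus = keystone_genus
        else:
            genus = f"G{clusters[others.index(label)]:02d}"
        lineage[label] = (
            f"k__Bacteria;p__SimPhylum;c__SimClass;o__SimOrder;"
            f"f__SimFamily;g__{genus};s__"
        )
    return TaxonomyTable.from_lineage_strings(lineage)


def _find_clade(tree: Phylogeny, size: int, tolerance: int = 0) -> list[str]:
    """Leaf labels of an internal clade whose tip count is closest to
    ``size`` (within ``tolerance``); raises listing available sizes."""
    best = None
    sizes = set()
    for node in tree.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        leaves = [l.taxon.label for l in node.leaf_iter()]
        sizes.add(len(leaves))
        gap = abs(len(leaves) - size)
        if gap <= tolerance and (best is None or gap < best[0]):
            best = (gap, leaves)
    if best is None:
        raise ValueError(
            f"no clade of size {size} (+/-{tolerance}); available sizes: "
            f"{sorted(sizes)}"
        )
    return best[1]


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """A complete simulated data set with ground-truth labels."""

    tree: Phylogeny
    metacommunity: np.ndarray
    optima: pd.Series | None
    env: np.ndarray
    groups: np.ndarray
    communities: AsvTable
    metabolites: MetaboliteTable | None
    taxonomy: TaxonomyTable | None
    truth: dict
    seed: int

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"env": self.env, "group": self.groups},
            index=self.communities.sample_ids,
        )

    def write(self, outdir: str | Path, biom: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_asv_table(self.communities, outdir / "table.tsv", "tsv")
        if biom:
            write_asv_table(self.communities, outdir / "table.biom", "biom")
        self.tree.write(outdir / "tree.nwk")
        self.metadata_frame().to_csv(
            outdir / "metadata.tsv", sep="\t", index_label="sample_id"
        )
        if self.taxonomy is not None:
            self.taxonomy.write_tsv(outdir / "taxonomy.tsv")
        if self.metabolites is not None:
            self.metabolites.write_tsv(outdir / "metabolites.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n"
        )


def _two_group_env(n_samples: int, lo: float, hi: float):
    half = n_samples // 2
    env = np.array([lo] * half + [hi] * (n_samples - half), dtype=float)
    groups = np.array(
        ["low"] * half + ["high"] * (n_samples - half), dtype=object
    )
    return env, groups


def make_keystone_scenario(
    seed: int,
    n_taxa: int = 200,
    n_samples: int = 12,
    N: int = 2000,
    clade_size: int = 20,
    clade_size_tolerance: int = 10,
    clade_mass: float = 0.45,
    clade_optimum: float = 2.0,
    sigma_keystone: float = 1.0,
    env_lo: float = -2.0,
    env_hi: float = 2.0,
    lognormal_sigma: float = 1.0,
    n_other_genera: int = 8,
    coupling_enabled: bool = True,
) -> SyntheticScenario:
    """Scenario in which one clade (a 'genus') carries the whole selection
    response: clade taxa are filtered by the environment while everything
    else assembles neutrally from the metacommunity.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
    labels = tree.leaf_labels
    meta = simulate_metacommunity(
        n_taxa, lognormal_sigma, seed=int(rng.integers(2**31))
    )
    clade = _find_clade(tree, clade_size, clade_size_tolerance)
    clade_mask = np.isin(labels, clade)
    # reweight the metacommunity so the clade carries a fixed mass
    meta = meta.copy()
    meta[clade_mask] *= clade_mass / meta[clade_mask].sum()
    meta[~clade_mask] *= (1 - clade_mass) / meta[~clade_mask].sum()

    env, groups = _two_group_env(n_samples, env_lo, env_hi)
    counts = np.empty((n_taxa, n_samples))
    draw_rng = np.random.default_rng(int(rng.integers(2**31)))
    for s, e in enumerate(env):
        w = meta.copy()
        if coupling_enabled:
            w[clade_mask] *= np.exp(
                -((clade_optimum - e) ** 2) / (2.0 * sigma_keystone**2)
            )
        counts[:, s] = draw_rng.multinomial(N, w / w.sum())
    communities = AsvTable(labels, _sample_ids(n_samples), counts)
    taxonomy = assign_genera(
        tree, n_genera=n_other_genera, keystone_labels=clade,
        seed=int(rng.integers(2**31)),
    )
    truth = {
        "regime": "variable_selection" if coupling_enabled else "neutral",
        "keystone_genus": "Keystone",
        "keystone_clade": sorted(clade),
        "informative_compounds": [],
    }
    return SyntheticScenario(
        tree=tree,
        metacommunity=meta,
        optima=None,
        env=env,
        groups=groups,
        communities=communities,
        metabolites=None,
        taxonomy=taxonomy,
        truth=truth,
        seed=seed,
    )


def make_scenario(
    name: str,
    seed: int,
    n_taxa: int = 200,
    n_samples: int = 12,
    N: int = 2000,
    m: float = 0.3,
    lognormal_sigma: float | None = None,
    sigma_bm: float = 2.0,
    sigma_sel: float = 0.5,
    env_lo: float = -2.0,
    env_hi: float = 2.0,
    n_compounds: int = 100,
    n_informative: int = 5,
    coupling: float = 1.0,
    noise_sd: float = 0.3,
    **keystone_kwargs,
) -> SyntheticScenario:
    """Build one of the named ground-truth scenarios.

    ``neutral``: all samples drawn from the neutral model (m, N).
    ``variable``: two environment groups with Gaussian filtering on
    Brownian niche optima — divergent (variable) selection.
    ``homogeneous``: one shared environment with the same filtering —
    convergent (homogeneous) selection.
    ``homogenizing``: all samples near-copies of one composition (this
    regime defaults to a more skewed metacommunity, lognormal_sigma = 1.5:
    with an even pool every taxon occurs in every sample, the richness-
    matched null saturates and the RC signal vanishes).
    ``keystone``: see :func:`make_keystone_scenario`.
    ``drivers``: the variable scenario plus a metabolite matrix with
    ``n_informative`` environment-coupled compounds.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; one of {SCENARIO_NAMES}")
    if name == "keystone":
        return make_keystone_scenario(
            seed, n_taxa=n_taxa, n_samples=n_samples, N=N,
            lognormal_sigma=(
                1.0 if lognormal_sigma is None else lognormal_sigma
            ),
            env_lo=env_lo, env_hi=env_hi, **keystone_kwargs,
        )
    if lognormal_sigma is None:
        # regime-appropriate skew: homogenizing needs rare taxa so the
        # richness-matched null does not saturate, homogeneous needs an
        # even clade so the nearest-taxon average is stable
        lognormal_sigma = {"homogenizing": 1.5, "homogeneous": 0.5}.get(
            name, 1.0
        )
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
    labels = tree.leaf_labels
    meta = simulate_metacommunity(
        n_taxa, lognormal_sigma, seed=int(rng.integers(2**31))
    )
    optima = evolve_optima(tree, sigma_bm, seed=int(rng.integers(2**31)))
    metabolites = None
    informative: list[str] = []
    regime = name

    if name == "neutral":
        env = np.zeros(n_samples)
        groups = np.array(["all"] * n_samples, dtype=object)
        communities = simulate_neutral(
            meta, N=N, m=m, n_samples=n_samples,
            seed=int(rng.integers(2**31)), taxon_ids=labels,
        )
    elif name in ("variable", "drivers"):
        env, groups = _two_group_env(n_samples, env_lo, env_hi)
        communities = simulate_selected(
            meta, optima.to_numpy(), env, sigma_sel=sigma_sel, N=N,
            seed=int(rng.integers(2**31)), taxon_ids=labels,
        )
        regime = "variable_selection"
        if name == "drivers":
            metabolites, informative = simulate_metabolites(
                env, n_compounds=n_compounds, n_informative=n_informative,
                coupling=coupling, noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
                sample_ids=communities.sample_ids,
            )
    elif name == "homogeneous":
        # every sample filtered to one favoured clade (see
        # simulate_clade_filtered for why a scalar Brownian trait is not
        # used for this regime)
        env = np.full(n_samples, env_hi)
        groups = np.array(["all"] * n_samples, dtype=object)
        clade = _find_clade(tree, 30, tolerance=10)
        clade_mask = np.isin(labels, clade)
        communities = simulate_clade_filtered(
            meta, clade_mask, N=N, n_samples=n_samples,
            seed=int(rng.integers(2**31)), retention=0.7, taxon_ids=labels,
        )
        regime = "homogeneous_selection"
    elif name == "homogenizing":
        env = np.zeros(n_samples)
        groups = np.array(["all"] * n_samples, dtype=object)
        communities = simulate_homogenizing(
            meta, N=N, n_samples=n_samples,
            seed=int(rng.integers(2**31)), taxon_ids=labels,
        )
        regime = "homogenizing_dispersal"

    truth = {
        "regime": regime,
        "keystone_genus": None,
        "keystone_clade": [],
        "informative_compounds": informative,
    }
    return SyntheticScenario(
        tree=tree,
        metacommunity=meta,
        optima=optima,
        env=env,
        groups=groups,
        communities=communities,
        metabolites=metabolites,
        taxonomy=None,
        truth=truth,
        seed=seed,
    )
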