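"""Phylogenetic turnover null models: abundance-weighted betaMNTD, the
tip-shuffling null, betaNTI z-scores, and the phylogenetic-signal
correlogram that justifies them.

betaMNTD(j,k) is the abundance-weighted mean distance from each taxon
present in one sample to its nearest relative present in the other. The
null shuffles taxon labels across all tips of the regional pool and
recomputes betaMNTD for every pair per shuffle; betaNTI is the z-score of
the observed value against that null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .community_data import AsvTable, Phylogeny, align_to_tree, to_relative
from .community_stats import DistanceMatrix

__all__ = [
    "TurnoverMatrices",
    "SignalCorrelogram",
    "beta_mntd",
    "beta_nti",
    "niche_values",
    "phylo_signal_correlogram",
]


@dataclass
class TurnoverMatrices:
    """Observed betaMNTD, null summaries, and betaNTI for all sample pairs."""

    ids: list[str]
    beta_mntd_obs: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    beta_nti: np.ndarray  # NaN on the diagonal and where null_sd == 0
    n_null: int
    seed: int | None

    def beta_nti_matrix(self) -> DistanceMatrix:
        """betaNTI with a zeroed diagonal, as a DistanceMatrix for Mantel use.

        betaNTI is a signed z-score, not a metric; this container is only a
        convenience for distance-matrix machinery that ignores the diagonal.
        """
        vals = np.array(self.beta_nti)
        np.fill_diagonal(vals, 0.0)
        return DistanceMatrix(list(self.ids), vals)

    def mean_beta_nti(self, mask: np.ndarray | None = None) -> float:
        """Mean betaNTI over the upper-triangle pairs (optionally masked)."""
        n = len(self.ids)
        iu = np.triu_indices(n, 1)
        vals = self.beta_nti[iu]
        if mask is not None:
            vals = vals[np.asarray(mask, dtype=bool)[iu]]
        return float(np.nanmean(vals))

    def to_long_frame(self) -> pd.DataFrame:
        n = len(self.ids)
        iu, ju = np.triu_indices(n, 1)
        return pd.DataFrame(
            {
                "sample_a": [self.ids[i] for i in iu],
                "sample_b": [self.ids[j] for j in ju],
                "beta_mntd": self.beta_mntd_obs[iu, ju],
                "null_mean": self.null_mean[iu, ju],
                "null_sd": self.null_sd[iu, ju],
                "beta_nti": self.beta_nti[iu, ju],
            }
        )


def group_masks(ids, groups) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and between-group boolean pair masks (n x n)."""
    g = np.asarray(groups)
    if g.shape[0] != len(ids):
        raise ValueError("one group label per sample required")
    same = g[:, None] == g[None, :]
    off = ~np.eye(len(ids), dtype=bool)
    return same & off, (~same) & off


def _prepare(table: AsvTable, tree: Phylogeny):
    table, tree = align_to_tree(table, tree)
    # the regional pool for the null is the set of taxa *detected* in at
    # least one sample; all-zero rows carry no abundance and must not
    # perturb the shuffle (removing a never-observed taxon is an exact
    # no-op, RNG stream included)
    observed = table.counts.sum(axis=1) > 0
    if not observed.all():
        if table.mode == "relative":
            keep = [t for t, ok in zip(table.taxon_ids, observed) if ok]
            table = AsvTable(
                keep, list(table.sample_ids), table.counts[observed, :],
                mode="relative",
            )
        else:
            table = table.select_taxa(
                [t for t, ok in zip(table.taxon_ids, observed) if ok]
            )
        tree = tree.prune_to(table.taxon_ids)
    if table.mode == "counts":
        table = to_relative(table)
    f = table.counts
    present = f > 0
    if np.any(~present.any(axis=0)):
        empty = [
            s for s, ok in zip(table.sample_ids, present.any(axis=0)) if not ok
        ]
        raise ValueError(f"samples with no taxa on the tree: {empty}")
    d = tree.patristic_matrix(order=table.taxon_ids)
    return table, f, present, d


def _bmntd_from_distance(
    f: np.ndarray, present: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """betaMNTD for all sample pairs given relative abundances and a
    patristic matrix. A taxon present in both samples contributes distance 0
    (the diagonal of ``d`` is zero and the taxon is its own nearest
    relative)."""
    n_taxa, n_samples = f.shape
    # nearest-taxon distance from every taxon to each sample's support
    m = np.empty((n_taxa, n_samples))
    for k in range(n_samples):
        m[:, k] = d[:, present[:, k]].min(axis=1)
    w = f.T @ m  # w[j,k] = sum_i f_ij * min-dist(i -> support of k)
    return 0.5 * (w + w.T)


def beta_mntd(table: AsvTable, tree: Phylogeny) -> DistanceMatrix:
    """Observed abundance-weighted betaMNTD for all sample pairs."""
    table, f, present, d = _prepare(table, tree)
    return DistanceMatrix(
        list(table.sample_ids), _bmntd_from_distance(f, present, d)
    )


def beta_nti(
    table: AsvTable,
    tree: Phylogeny,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> TurnoverMatrices:
    """betaNTI z-scores from the tip-shuffling null.

    Each null iteration shuffles taxon labels across all tips of the aligned
    tree — implemented as one permutation of the cached patristic matrix,
    which is exactly equivalent to relabelling tips — and recomputes
    betaMNTD for every sample pair. Pairs whose null has zero spread get a
    NaN betaNTI with a warning.
    """
    if n_null < 99:
        warnings.warn(f"n_null={n_null} is small; 999 is conventional")
    table, f, present, d = _prepare(table, tree)
    if not weighted:
        f = present / present.sum(axis=0)
    obs = _bmntd_from_distance(f, present, d)

    rng = np.random.default_rng(seed)
    n_taxa = f.shape[0]
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _bmntd_from_distance(f, present, d[np.ix_(perm, perm)])
        total += null
        total_sq += null * null
    mean = total / n_null
    var = np.maximum(total_sq / n_null - mean * mean, 0.0)
    sd = np.sqrt(var)

    with np.errstate(divide="ignore", invalid="ignore"):
        nti = (obs - mean) / sd
    n = len(table.sample_ids)
    off = ~np.eye(n, dtype=bool)
    degenerate = (sd == 0) & off
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum() // 2)} sample pair(s) have a degenerate "
            "null (sd = 0); betaNTI reported as missing"
        )
    nti[sd == 0] = np.nan
    np.fill_diagonal(nti, np.nan)
    return TurnoverMatrices(
        ids=list(table.sample_ids),
        beta_mntd_obs=obs,
        null_mean=mean,
        null_sd=sd,
        beta_nti=nti,
        n_null=n_null,
        seed=seed,
    )


def niche_values(table: AsvTable, variable: np.ndarray) -> pd.Series:
    """Abundance-weighted mean of a per-sample variable, per taxon.

    niche_i = sum_s f_is * v_s / sum_s f_is. Taxa absent everywhere get NaN.
    """
    v = np.asarray(variable, dtype=float)
    if v.shape[0] != table.n_samples:
        raise ValueError("variable length must equal number of samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("variable contains non-finite values")
    f = table.relative_matrix()
    weight = f.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        niche = (f @ v) / weight
    niche[weight == 0] = np.nan
    return pd.Series(niche, index=table.taxon_ids, name="niche")


@dataclass
class SignalCorrelogram:
    """Per-distance-class correlation between phylogenetic distance and
    niche difference."""

    class_edges: np.ndarray  # length n_classes + 1
    r: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_lo": self.class_edges[:-1],
                "class_hi": self.class_edges[1:],
                "n_pairs": self.n_pairs,
                "r": self.r,
                "p": self.p,
            }
        )


def phylo_signal_correlogram(
    tree: Phylogeny,
    niche: pd.Series,
    n_classes: int = 4,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalCorrelogram:
    """Distance-class correlogram of phylogenetic vs. niche distance.

    Taxon pairs are binned into ``n_classes`` equal-count phylogenetic
    distance classes. Within each class the statistic is the Pearson
    correlation between phylogenetic distance and |niche_i - niche_j|;
    significance comes from permuting niche values across taxa (one-tailed,
    greater, +1 correction). Classes with zero variance in either margin
    report NaN.
    """
    niche = niche.dropna()
    labels = [l for l in tree.leaf_labels if l in set(niche.index)]
    if len(labels) < 20:
        raise ValueError("need at least 20 taxa with niche values")
    v = niche.loc[labels].to_numpy(dtype=float)
    d = tree.patristic_matrix(order=labels)
    n = len(labels)
    iu, ju = np.triu_indices(n, 1)
    pd_pairs = d[iu, ju]

    # equal-count classes on ranked distances
    ranks = rankdata(pd_pairs, method="ordinal") - 1
    cls = np.minimum((ranks * n_classes) // pd_pairs.size, n_classes - 1)
    edges = np.empty(n_classes + 1)
    edges[0] = pd_pairs.min()
    edges[-1] = pd_pairs.max()
    for c in range(1, n_classes):
        edges[c] = pd_pairs[cls == c].min()

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    nd_pairs = np.abs(v[iu] - v[ju])
    nd_perm = np.abs(v[perms[:, iu]] - v[perms[:, ju]])  # (n_perm, m)

    r = np.full(n_classes, np.nan)
    p = np.full(n_classes, np.nan)
    n_pairs = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        mask = cls == c
        n_pairs[c] = int(mask.sum())
        x = pd_pairs[mask]
        y = nd_pairs[mask]
        if x.std() == 0 or y.std() == 0:
            continue
        xs = (x - x.mean()) / x.std()
        r_obs = float(xs @ (y - y.mean()) / (y.std() * x.size))
        yp = nd_perm[:, mask]
        mu = yp.mean(axis=1, keepdims=True)
        sd = yp.std(axis=1)
        ok = sd > 0
        r_star = np.full(n_perm, -np.inf)
        r_star[ok] = ((yp[ok] - mu[ok]) @ xs) / (sd[ok] * x.size)
        r[c] = r_obs
        p[c] = (1 + int(np.sum(r_star >= r_obs))) / (1 + n_perm)
    return SignalCorrelogram(edges, r, p, n_pairs)
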