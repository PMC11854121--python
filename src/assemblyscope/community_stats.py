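"""Shared descriptive statistics: alpha diversity, Bray-Curtis, Mantel test,
and the Spearman co-occurrence network."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr

__all__ = [
    "DistanceMatrix",
    "Network",
    "AlphaDiversity",
    "alpha_diversity",
    "bray_curtis",
    "mantel_test",
    "cooccurrence_network",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with a zero diagonal over ordered ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        idx = [index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_long_frame(self, value_name: str = "distance") -> pd.DataFrame:
        iu, ju = np.triu_indices(self.n, 1)
        return pd.DataFrame(
            {
                "id_a": [self.ids[i] for i in iu],
                "id_b": [self.ids[j] for j in ju],
                value_name: self.values[iu, ju],
            }
        )


class AlphaDiversity(NamedTuple):
    richness: int
    shannon: float
    pielou: float  # NaN when richness == 1


def alpha_diversity(column: np.ndarray) -> AlphaDiversity:
    """Richness, Shannon entropy (nats) and Pielou evenness of one sample.

    Shannon uses within-sample relative abundances over present taxa;
    Pielou is H / ln(richness) and is reported as NaN for a single-taxon
    sample, where evenness is undefined.
    """
    x = np.asarray(column, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("sample has zero total abundance")
    q = x[x > 0] / total
    richness = int(q.size)
    shannon = float(-(q * np.log(q)).sum())
    pielou = shannon / np.log(richness) if richness > 1 else float("nan")
    return AlphaDiversity(richness, shannon, pielou)


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(j,k) = 1 - 2 * sum_i min(x_ij, x_ik) / sum_i (x_ij + x_ik).
    """
    x = np.asarray(table.counts, dtype=float)
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"empty samples: {empty}")
    d = _bray_curtis_matrix(x)
    return DistanceMatrix(list(table.sample_ids), d)


def _bray_curtis_matrix(x: np.ndarray) -> np.ndarray:
    """Bray-Curtis over columns of a taxa x samples matrix."""
    from scipy.spatial.distance import pdist

    return squareform(pdist(x.T, metric="braycurtis"))


class MantelResult(NamedTuple):
    r: float
    p: float
    n_perm: int


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    method: str = "pearson",
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson (or Spearman, via triangle ranks)
    correlation of the upper-triangle entries. The permutation null permutes
    the ids of ``d2``; the reported p-value is one-tailed (greater) with the
    +1 correction: p = (1 + #{r* >= r}) / (1 + n_perm).
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices must share identical id sets")
        d2 = d2.reorder(d1.ids)
    n = d1.n
    if n < 4:
        raise ValueError("mantel test needs at least 4 objects")
    iu, ju = np.triu_indices(n, 1)
    x = d1.values[iu, ju]
    m2 = np.array(d2.values, dtype=float)
    y = m2[iu, ju]
    if method == "spearman":
        x = rankdata(x)
        yr = rankdata(y)
        # place triangle ranks back into matrix form so that permuting ids
        # permutes the rank values (pairs map to pairs, multiset unchanged)
        m2 = np.zeros_like(m2)
        m2[iu, ju] = yr
        m2 = m2 + m2.T
        y = m2[iu, ju]
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a distance-matrix triangle")

    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    m = x.size
    r = float(xs @ ys / m)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # gather permuted triangles in one shot: row q holds d2 with ids permuted
    yp = m2[perms[:, iu], perms[:, ju]]  # (n_perm, m)
    yp = yp - yp.mean(axis=1, keepdims=True)
    sd = yp.std(axis=1)
    sd[sd == 0] = np.inf
    r_star = (yp @ xs) / (m * sd)
    p = (1 + int(np.sum(r_star >= r))) / (1 + n_perm)
    return MantelResult(r, float(p), n_perm)


@dataclass
class Network:
    """Thresholded Spearman co-occurrence network over abundant taxa."""

    nodes: list[str]
    edges: list[tuple[str, str, float, float, int]]  # (i, j, rho, p, sign)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_positive(self) -> int:
        return sum(1 for e in self.edges if e[4] > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self.edges if e[4] < 0)

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["source", "target", "rho", "p", "sign"]
        )

    def write_edge_tsv(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, rho, p, sign in self.edges:
            g.add_edge(a, b, rho=rho, p=p, sign=sign)
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


def cooccurrence_network(
    table,
    top_n: int = 150,
    rho_threshold: float = 0.8,
    alpha: float = 0.05,
) -> Network:
    """Spearman co-occurrence network among the most abundant taxa.

    Taxa are ranked by mean within-sample relative abundance and the top
    ``top_n`` retained; edges keep pairs with |rho| > ``rho_threshold`` and
    p < ``alpha`` (t-approximation, uncorrected).
    """
    if table.n_samples < 4:
        raise ValueError("network construction needs at least 4 samples")
    rel = table.relative_matrix()
    mean_ab = rel.mean(axis=1)
    if top_n > table.n_taxa:
        warnings.warn(
            f"top_n={top_n} exceeds available taxa ({table.n_taxa}); using all"
        )
        top_n = table.n_taxa
    order = np.argsort(-mean_ab, kind="stable")[:top_n]
    nodes = [table.taxon_ids[i] for i in order]
    sub = rel[order, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows yield NaN rho
        rho, p = spearmanr(sub.T)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2x2 case
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            rij, pij = rho[i, j], p[i, j]
            if np.isnan(rij):
                continue
            if abs(rij) > rho_threshold and pij < alpha:
                edges.append(
                    (nodes[i], nodes[j], float(rij), float(pij),
                     1 if rij > 0 else -1)
                )
    return Network(nodes, edges)
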