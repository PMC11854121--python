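"""Abundance-weighted Raup-Crick null model on Bray-Curtis dissimilarity.

For each sample pair, null communities of identical richness and read total
are drawn from the regional pool: taxa are picked without replacement with
probability proportional to their occupancy frequency across all samples,
seeded with one read each, and the remaining reads distributed by a
multinomial proportional to metacommunity relative abundance. The observed
Bray-Curtis dissimilarity is located within the null distribution.

Sign convention: under ``standard`` the numerator counts null values BELOW
the observed one, so RC -> -1 for communities more similar than expected by
drift (homogenizing dispersal) and +1 for less similar (dispersal
limitation). The literal wording of some methods texts inverts the
numerator; that variant is available as ``paper_literal`` for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_data import AsvTable

__all__ = ["RcResult", "null_community_pair", "rc_bray"]

_TIE_TOL = 1e-10


@dataclass
class RcResult:
    ids: list[str]
    rc_scaled: np.ndarray  # in [-1, 1], NaN diagonal
    rc_raw: np.ndarray  # in [0, 1], NaN diagonal
    bc_obs: np.ndarray
    n_null: int
    seed: int | None
    convention: str

    def rc_matrix(self):
        """rc_scaled with a zeroed diagonal, for distance-matrix machinery."""
        from .community_stats import DistanceMatrix

        vals = np.array(self.rc_scaled)
        np.fill_diagonal(vals, 0.0)
        return DistanceMatrix(list(self.ids), vals)

    def mean_rc(self) -> float:
        iu = np.triu_indices(len(self.ids), 1)
        return float(np.nanmean(self.rc_scaled[iu]))

    def to_long_frame(self) -> pd.DataFrame:
        n = len(self.ids)
        iu, ju = np.triu_indices(n, 1)
        return pd.DataFrame(
            {
                "sample_a": [self.ids[i] for i in iu],
                "sample_b": [self.ids[j] for j in ju],
                "bc_obs": self.bc_obs[iu, ju],
                "rc_raw": self.rc_raw[iu, ju],
                "rc_scaled": self.rc_scaled[iu, ju],
            }
        )


def _universe(table: AsvTable) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy frequency and metacommunity mean relative abundance."""
    occupancy = (table.counts > 0).sum(axis=1).astype(float)
    meta = table.relative_matrix().mean(axis=1)
    return occupancy, meta


def _draw_communities(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    meta: np.ndarray,
    richness: int,
    total: int,
    n: int,
) -> np.ndarray:
    """Draw ``n`` null communities as an (n, n_taxa) relative-abundance
    matrix, each with exactly ``richness`` taxa and ``total`` reads.

    Weighted sampling without replacement uses the Gumbel top-k trick:
    adding iid Gumbel noise to log-weights and taking the top ``richness``
    keys draws taxa with probability proportional to occupancy.
    """
    n_taxa = occupancy.size
    available = int(np.sum(occupancy > 0))
    if richness > available:
        raise ValueError(
            f"requested richness {richness} exceeds the {available} taxa "
            "with nonzero occupancy"
        )
    if total < richness:
        raise ValueError("read total smaller than requested richness")
    with np.errstate(divide="ignore"):
        log_w = np.log(occupancy)
    keys = rng.gumbel(size=(n, n_taxa)) + log_w
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]

    out = np.zeros((n, n_taxa))
    extra = total - richness
    for row in range(n):
        idx = chosen[row]
        p = meta[idx]
        s = p.sum()
        p = np.full(idx.size, 1.0 / idx.size) if s <= 0 else p / s
        counts = np.ones(idx.size)
        if extra > 0:
            counts += rng.multinomial(extra, p)
        out[row, idx] = counts / total
    return out


def null_community_pair(
    universe: tuple[np.ndarray, np.ndarray],
    richness_a: int,
    richness_b: int,
    total_a: int,
    total_b: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One null community per sample of a pair, as relative-abundance
    vectors over the universe's taxa.

    ``universe`` is the (occupancy_frequency, metacommunity_rel_abundance)
    pair over all taxa. Each community independently has exactly the
    requested richness and read total.
    """
    occupancy, meta = universe
    rng = np.random.default_rng(seed)
    a = _draw_communities(rng, occupancy, meta, richness_a, total_a, 1)[0]
    b = _draw_communities(rng, occupancy, meta, richness_b, total_b, 1)[0]
    return a, b


def _bc_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Bray-Curtis between two (n, taxa) relative matrices."""
    num = np.minimum(a, b).sum(axis=1)
    den = (a + b).sum(axis=1)
    return 1.0 - 2.0 * num / den


def rc_bray(
    table: AsvTable,
    n_null: int = 999,
    seed: int | None = None,
    convention: str = "standard",
) -> RcResult:
    """Raup-Crick (Bray-Curtis) null-model deviation for all sample pairs.

    rc_raw(standard) = (N_below + 0.5 * N_ties) / n_null and
    rc_raw(paper_literal) = (N_above + 0.5 * N_ties) / n_null, with ties
    judged at 1e-10; rc_scaled = 2 * rc_raw - 1.
    """
    if convention not in ("standard", "paper_literal"):
        raise ValueError(f"unknown convention {convention!r}")
    if table.mode != "counts":
        raise ValueError("rc_bray expects a counts-mode table")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_null < 99:
        warnings.warn(f"n_null={n_null} is small; 999 is conventional")
    totals = table.sample_totals()
    if np.any(totals <= 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"empty samples: {empty}")

    occupancy, meta = _universe(table)
    rel = table.relative_matrix()
    richness = (table.counts > 0).sum(axis=0).astype(int)
    totals = np.round(totals).astype(int)
    n = table.n_samples

    rng = np.random.default_rng(seed)
    bc_obs = np.zeros((n, n))
    rc_raw = np.full((n, n), np.nan)
    for j in range(n):
        for k in range(j + 1, n):
            obs = float(_bc_rows(rel[:, j][None, :], rel[:, k][None, :])[0])
            bc_obs[j, k] = bc_obs[k, j] = obs
            null_a = _draw_communities(
                rng, occupancy, meta, richness[j], totals[j], n_null
            )
            null_b = _draw_communities(
                rng, occupancy, meta, richness[k], totals[k], n_null
            )
            bc_null = _bc_rows(null_a, null_b)
            ties = np.abs(bc_null - obs) <= _TIE_TOL
            below = np.sum((bc_null < obs) & ~ties)
            above = np.sum((bc_null > obs) & ~ties)
            num = below if convention == "standard" else above
            raw = (num + 0.5 * ties.sum()) / n_null
            rc_raw[j, k] = rc_raw[k, j] = raw
    rc_scaled = 2.0 * rc_raw - 1.0
    return RcResult(
        ids=list(table.sample_ids),
        rc_scaled=rc_scaled,
        rc_raw=rc_raw,
        bc_obs=bc_obs,
        n_null=n_null,
        seed=seed,
        convention=convention,
    )
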