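"""Five-way ecological process classification from betaNTI and RCbray, group
summaries, and the leave-one-genus-out keystone screen.

Classification rule per sample pair (strict inequalities at every
threshold): betaNTI > 2 -> variable selection; betaNTI < -2 -> homogeneous
selection; otherwise RC > 0.95 -> dispersal limitation; RC < -0.95 ->
homogenizing dispersal; otherwise drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_data import (
    AsvTable,
    Phylogeny,
    TaxonomyTable,
    align_to_tree,
    to_relative,
)
from .community_stats import DistanceMatrix, mantel_test
from .phylo_null import TurnoverMatrices, beta_nti
from .raup_crick import rc_bray

__all__ = [
    "PROCESS_LABELS",
    "SELECTION_LABELS",
    "STOCHASTIC_LABELS",
    "classify_pair",
    "classify_matrix",
    "PartitionSummary",
    "partition_fractions",
    "KeystoneScreenResult",
    "keystone_loo_screen",
]

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)
SELECTION_LABELS = ("variable_selection", "homogeneous_selection")
STOCHASTIC_LABELS = (
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def classify_pair(bnti: float, rc_scaled: float) -> str | None:
    """Process label for one sample pair; None when either input is missing."""
    if bnti is None or rc_scaled is None:
        return None
    if np.isnan(bnti) or np.isnan(rc_scaled):
        return None
    if bnti > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_scaled > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_scaled < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def classify_matrix(
    bnti: np.ndarray, rc_scaled: np.ndarray
) -> np.ndarray:
    """Elementwise labels (object array, None where undefined)."""
    bnti = np.asarray(bnti, dtype=float)
    rc = np.asarray(rc_scaled, dtype=float)
    if bnti.shape != rc.shape:
        raise ValueError("matrix shapes differ")
    out = np.empty(bnti.shape, dtype=object)
    it = np.nditer(bnti, flags=["multi_index"])
    for val in it:
        idx = it.multi_index
        out[idx] = classify_pair(float(val), float(rc[idx]))
    return out


@dataclass
class PartitionSummary:
    """Per-group process counts, fractions and mean betaNTI."""

    frame: pd.DataFrame  # index = group; columns = labels + derived stats

    def fractions(self, group: str) -> dict[str, float]:
        row = self.frame.loc[group]
        return {k: float(row[f"frac_{k}"]) for k in PROCESS_LABELS}


def partition_fractions(
    bnti: TurnoverMatrices | np.ndarray,
    rc: "np.ndarray | object",
    groups=None,
    scope: str = "within_group",
    ids=None,
) -> PartitionSummary:
    """Process fractions per group of sample pairs.

    ``scope`` is ``within_group`` (pairs whose two samples share a label),
    ``between_group`` (pairs with different labels, summarised under one
    "between" group), or ``all_pairs`` (everything pooled as "all").
    Groups with fewer than 2 samples are skipped with a warning.
    """
    if isinstance(bnti, TurnoverMatrices):
        ids = list(bnti.ids)
        bnti_m = bnti.beta_nti
    else:
        bnti_m = np.asarray(bnti, dtype=float)
        if ids is None:
            ids = [f"S{i}" for i in range(bnti_m.shape[0])]
    rc_m = rc.rc_scaled if hasattr(rc, "rc_scaled") else np.asarray(rc, dtype=float)
    n = len(ids)
    if bnti_m.shape != (n, n) or rc_m.shape != (n, n):
        raise ValueError("matrices must share the sample id set")

    iu, ju = np.triu_indices(n, 1)
    labels = np.array(
        [classify_pair(bnti_m[i, j], rc_m[i, j]) for i, j in zip(iu, ju)],
        dtype=object,
    )
    bvals = bnti_m[iu, ju]

    if groups is None:
        pair_groups = np.array(["all"] * len(labels), dtype=object)
    else:
        g = np.asarray(groups)
        if g.shape[0] != n:
            raise ValueError("one group label per sample required")
        counts = pd.Series(g).value_counts()
        for name, c in counts.items():
            if c < 2:
                warnings.warn(f"group {name!r} has < 2 samples; skipped")
        if scope == "within_group":
            pair_groups = np.array(
                [g[i] if g[i] == g[j] else None for i, j in zip(iu, ju)],
                dtype=object,
            )
        elif scope == "between_group":
            pair_groups = np.array(
                ["between" if g[i] != g[j] else None for i, j in zip(iu, ju)],
                dtype=object,
            )
        elif scope == "all_pairs":
            pair_groups = np.array(["all"] * len(labels), dtype=object)
        else:
            raise ValueError(f"unknown scope {scope!r}")

    rows = {}
    for name in pd.unique(pair_groups):
        if name is None:
            continue
        sel = pair_groups == name
        lab = labels[sel]
        defined = np.array([l is not None for l in lab])
        lab = lab[defined]
        total = len(lab)
        if total == 0:
            warnings.warn(f"group {name!r} has no classified pairs; skipped")
            continue
        row = {}
        for k in PROCESS_LABELS:
            c = int(np.sum(lab == k))
            row[f"count_{k}"] = c
            row[f"frac_{k}"] = c / total
        row["n_pairs"] = total
        row["deterministic_fraction"] = sum(
            row[f"frac_{k}"] for k in SELECTION_LABELS
        )
        row["stochastic_fraction"] = sum(
            row[f"frac_{k}"] for k in STOCHASTIC_LABELS
        )
        row["mean_bnti"] = float(np.nanmean(bvals[sel]))
        rows[name] = row
    return PartitionSummary(pd.DataFrame(rows).T)


@dataclass
class KeystoneScreenResult:
    """Per-genus leave-one-out screen output."""

    frame: pd.DataFrame
    """Columns: genus, mean_rel_abund, mantel_r, mantel_p, mean_bnti_removed,
    flip (bool)."""
    full_mean_bnti: float
    min_rel_abund: float

    def flip_genera(self) -> list[str]:
        return list(self.frame.loc[self.frame["flip"], "genus"])


def keystone_loo_screen(
    table: AsvTable,
    tree: Phylogeny,
    taxonomy: TaxonomyTable,
    min_rel_abund: float = 0.01,
    n_null: int = 999,
    seed: int | None = None,
    n_perm: int = 999,
    include_rc: bool = False,
) -> KeystoneScreenResult:
    """Leave-one-genus-out screen for taxa carrying the selection signal.

    Genera are filtered at mean within-sample relative abundance >
    ``min_rel_abund``. For each passing genus the screen reports (a) a
    Mantel test between the pairwise |delta genus relative abundance| matrix
    and the full-community betaNTI matrix, and (b) the mean betaNTI after
    removing every ASV of the genus, pruning the tree, renormalising per
    sample and recomputing betaNTI with the same seed. The flip flag marks
    genera whose removal pulls a full-community mean betaNTI from above the
    +2 selection threshold to below it.

    ``include_rc`` additionally recomputes RCbray per removal (slow; the
    flip decision only needs betaNTI).
    """
    table, tree = align_to_tree(table, tree)
    if table.mode != "counts":
        raise ValueError("keystone screen expects a counts-mode table")
    full = beta_nti(table, tree, n_null=n_null, seed=seed)
    full_mean = full.mean_beta_nti()
    bnti_dm = full.beta_nti_matrix()

    rel = table.relative_matrix()
    genus_of = {t: taxonomy.value(t, "genus") for t in table.taxon_ids}
    genera = pd.unique(np.array([genus_of[t] for t in table.taxon_ids]))

    rows = []
    for genus in genera:
        members = [t for t in table.taxon_ids if genus_of[t] == genus]
        rows_idx = [table.taxon_ids.index(t) for t in members]
        genus_rel = rel[rows_idx, :].sum(axis=0)
        mean_ab = float(genus_rel.mean())
        if mean_ab <= min_rel_abund:
            continue

        # genus-abundance-difference matrix vs full-community betaNTI
        diff = np.abs(genus_rel[:, None] - genus_rel[None, :])
        if diff[np.triu_indices(table.n_samples, 1)].std() > 0:
            mt = mantel_test(
                DistanceMatrix(list(table.sample_ids), diff),
                bnti_dm,
                n_perm=n_perm,
                seed=seed,
            )
            mantel_r, mantel_p = mt.r, mt.p
        else:
            mantel_r, mantel_p = float("nan"), float("nan")

        reduced = table.drop_taxa(members)
        keep_samples = [
            s
            for s, tot in zip(reduced.sample_ids, reduced.sample_totals())
            if tot > 0
        ]
        if len(keep_samples) < reduced.n_samples:
            dropped = set(reduced.sample_ids) - set(keep_samples)
            warnings.warn(
                f"removing genus {genus!r} emptied samples {sorted(dropped)}; "
                "they are dropped from the recomputation"
            )
            reduced = reduced.select_samples(keep_samples)
        if len(keep_samples) < 2:
            warnings.warn(
                f"genus {genus!r} removal leaves < 2 samples; skipped"
            )
            continue
        reduced_rel = to_relative(reduced)
        red_tree = tree.prune_to(reduced.taxon_ids)
        removed = beta_nti(reduced_rel, red_tree, n_null=n_null, seed=seed)
        mean_removed = removed.mean_beta_nti()
        row = {
            "genus": genus,
            "mean_rel_abund": mean_ab,
            "mantel_r": mantel_r,
            "mantel_p": mantel_p,
            "mean_bnti_removed": mean_removed,
            "flip": bool(
                full_mean > BNTI_THRESHOLD and mean_removed < BNTI_THRESHOLD
            ),
        }
        if include_rc:
            rc = rc_bray(reduced, n_null=n_null, seed=seed)
            row["mean_rc_removed"] = rc.mean_rc()
        rows.append(row)
    frame = pd.DataFrame(
        rows,
        columns=[
            "genus",
            "mean_rel_abund",
            "mantel_r",
            "mantel_p",
            "mean_bnti_removed",
            "flip",
        ]
        + (["mean_rc_removed"] if include_rc and rows else []),
    )
    return KeystoneScreenResult(
        frame=frame, full_mean_bnti=full_mean, min_rel_abund=min_rel_abund
    )
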