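"""Metabolite / variable driver screen against betaNTI.

Compounds pass a coefficient-of-variation prefilter, their pairwise
intensity-difference matrices are correlated with the betaNTI matrix by
Mantel permutation, and compounds with r above a threshold (and a
significant p, unless disabled) are flagged as candidate regulators of the
assembly process. Compound classes are screened as multi-compound blocks
with Euclidean distance on z-scored members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_data import MetaboliteTable
from .community_stats import DistanceMatrix, mantel_test

__all__ = [
    "cv_filter",
    "variable_distance",
    "DriverResult",
    "bnti_driver_screen",
]


def cv_filter(
    metabolites: MetaboliteTable, cv_threshold: float = 0.5
) -> pd.DataFrame:
    """Coefficient of variation (sample sd / mean) per compound.

    Compounds with zero mean intensity get a missing CV and never pass.
    """
    x = metabolites.intensities
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    passed = np.where(np.isnan(cv), False, cv > cv_threshold)
    return pd.DataFrame(
        {
            "compound_id": metabolites.compound_ids,
            "cv": cv,
            "passed_cv": passed.astype(bool),
        }
    )


def variable_distance(values, sample_ids=None) -> DistanceMatrix:
    """Pairwise distance matrix from per-sample variables.

    A 1-D vector gives |v_j - v_k|; a 2-D block (samples x variables) gives
    Euclidean distance on per-column z-scores. Constant columns are a zero-
    variance error.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    if v.ndim == 1:
        if v.std() == 0:
            raise ValueError("constant variable (zero variance)")
        d = np.abs(v[:, None] - v[None, :])
        n = v.shape[0]
    elif v.ndim == 2:
        sd = v.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant column(s) in variable block")
        z = (v - v.mean(axis=0)) / sd
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(z, metric="euclidean"))
        n = v.shape[0]
    else:
        raise ValueError("values must be 1-D or 2-D")
    ids = sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]
    return DistanceMatrix(list(ids), d)


@dataclass
class DriverResult:
    """Per-compound and per-class screen output."""

    compounds: pd.DataFrame
    """Columns: compound_id, cv, passed_cv, mantel_r, mantel_p, selected."""
    classes: pd.DataFrame
    """Columns: class, n_members, mantel_r, mantel_p, selected."""
    r_threshold: float
    alpha: float | None

    def selected_compounds(self) -> list[str]:
        return list(
            self.compounds.loc[self.compounds["selected"], "compound_id"]
        )


def bnti_driver_screen(
    bnti_matrix: DistanceMatrix,
    metabolites: MetaboliteTable,
    cv_threshold: float = 0.5,
    r_threshold: float = 0.2,
    alpha: float | None = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> DriverResult:
    """Screen compounds (and compound classes) whose pairwise differences
    track betaNTI.

    Per compound passing the CV prefilter, a Mantel test is run between the
    |delta intensity| matrix and betaNTI; ``selected`` requires
    r > ``r_threshold`` and, when ``alpha`` is not None, p < ``alpha``.
    Classes (from the table's class labels) are screened the same way with
    Euclidean block distances. Results are sorted by r, descending.
    """
    if metabolites.n_compounds == 0:
        raise ValueError("empty metabolite table")
    ids = list(bnti_matrix.ids)
    if set(ids) != set(metabolites.sample_ids):
        raise ValueError("betaNTI and metabolite sample ids differ")
    if len(ids) < 6:
        raise ValueError("driver screen needs at least 6 samples")
    col = {s: j for j, s in enumerate(metabolites.sample_ids)}
    order = [col[s] for s in ids]
    x = metabolites.intensities[:, order]

    cv = cv_filter(metabolites, cv_threshold)
    rng = np.random.default_rng(seed)

    rows = []
    for i, cid in enumerate(metabolites.compound_ids):
        crow = cv.iloc[i]
        r = p = np.nan
        selected = False
        if crow["passed_cv"] and x[i].std() > 0:
            dm = variable_distance(x[i], sample_ids=ids)
            mt = mantel_test(
                dm, bnti_matrix, n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            r, p = mt.r, mt.p
            selected = r > r_threshold and (alpha is None or p < alpha)
        rows.append(
            {
                "compound_id": cid,
                "cv": crow["cv"],
                "passed_cv": bool(crow["passed_cv"]),
                "mantel_r": r,
                "mantel_p": p,
                "selected": bool(selected),
            }
        )
    compounds = (
        pd.DataFrame(rows)
        .sort_values("mantel_r", ascending=False, na_position="last")
        .reset_index(drop=True)
    )

    class_rows = []
    class_names = sorted(set(metabolites.classes.values()))
    for cname in class_names:
        members = [
            i
            for i, cid in enumerate(metabolites.compound_ids)
            if metabolites.classes.get(cid) == cname
        ]
        if not members:
            warnings.warn(f"class {cname!r} has no member compounds; skipped")
            continue
        block = x[members, :].T  # samples x members
        keep = block.std(axis=0) > 0
        if not np.any(keep):
            warnings.warn(f"class {cname!r} has only constant compounds")
            continue
        dm = variable_distance(block[:, keep], sample_ids=ids)
        mt = mantel_test(
            dm, bnti_matrix, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        class_rows.append(
            {
                "class": cname,
                "n_members": len(members),
                "mantel_r": mt.r,
                "mantel_p": mt.p,
                "selected": bool(
                    mt.r > r_threshold and (alpha is None or mt.p < alpha)
                ),
            }
        )
    classes = pd.DataFrame(
        class_rows,
        columns=["class", "n_members", "mantel_r", "mantel_p", "selected"],
    )
    if len(classes):
        classes = classes.sort_values(
            "mantel_r", ascending=False
        ).reset_index(drop=True)
    return DriverResult(
        compounds=compounds,
        classes=classes,
        r_threshold=r_threshold,
        alpha=alpha,
    )
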