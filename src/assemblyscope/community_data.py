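"""Core data structures and I/O for amplicon community analysis.

Holds the taxa-by-samples abundance table, the rooted phylogeny, the ranked
taxonomy, sample metadata and metabolite intensity tables, together with the
normalisation utilities every downstream stage shares (relative-abundance
conversion, rarefaction to minimum depth, tree alignment, rank aggregation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "Phylogeny",
    "TaxonomyTable",
    "SampleMetadata",
    "MetaboliteTable",
    "read_asv_table",
    "write_asv_table",
    "to_relative",
    "subsample_to_min_depth",
    "align_to_tree",
    "aggregate_by_rank",
    "RANKS",
]

#: Seven-rank lineage scheme used by QIIME-style taxonomy strings.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIXES = ("k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__")

UNASSIGNED = "Unassigned"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AsvTable:
    """Taxa x samples abundance matrix.

    ``mode`` is an explicit flag (``"counts"`` or ``"relative"``) rather than
    being inferred from the values, so that accidental double normalisation is
    a detectable error.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    mode: str = "counts"

    def __post_init__(self) -> None:
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (taxa x samples)")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("abundance matrix contains non-finite entries")
        if np.any(self.counts < 0):
            t, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {self.taxon_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.mode == "counts":
            if not np.allclose(self.counts, np.round(self.counts)):
                t, s = np.argwhere(
                    ~np.isclose(self.counts, np.round(self.counts))
                )[0]
                raise ValueError(
                    f"counts-mode entry is not integral at taxon "
                    f"{self.taxon_ids[t]!r}, sample {self.sample_ids[s]!r}"
                )
        elif self.mode == "relative":
            sums = self.counts.sum(axis=0)
            bad = np.abs(sums - 1.0) > 1e-9
            if np.any(bad):
                j = int(np.argmax(bad))
                raise ValueError(
                    f"relative-mode column {self.sample_ids[j]!r} sums to "
                    f"{sums[j]!r}, expected 1"
                )
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- basic queries ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxon_ids, columns=self.sample_ids
        )

    def relative_matrix(self) -> np.ndarray:
        """Per-sample relative abundances regardless of mode."""
        if self.mode == "relative":
            return self.counts.copy()
        totals = self.sample_totals()
        if np.any(totals <= 0):
            empty = [
                s for s, t in zip(self.sample_ids, totals) if t <= 0
            ]
            raise ValueError(f"samples with zero total reads: {empty}")
        return self.counts / totals

    def select_taxa(self, taxon_ids: Sequence[str]) -> "AsvTable":
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        if self.mode == "relative" and set(taxon_ids) != set(self.taxon_ids):
            # dropping rows would break relative-mode column sums; subset the
            # counts table first, then renormalise
            raise ValueError("cannot subset taxa of a relative-mode table")
        rows = [index[t] for t in taxon_ids]
        sub = self.counts[rows, :]
        return AsvTable(list(taxon_ids), list(self.sample_ids), sub, mode=self.mode)

    def drop_taxa(self, taxon_ids: Iterable[str]) -> "AsvTable":
        drop = set(taxon_ids)
        keep = [t for t in self.taxon_ids if t not in drop]
        return self.select_taxa(keep)

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return AsvTable(
            list(self.taxon_ids), list(sample_ids),
            self.counts[:, cols], mode=self.mode,
        )


class Phylogeny:
    """Rooted phylogeny over taxon identifiers, backed by a dendropy tree.

    Supplies patristic (cophenetic) leaf-to-leaf distances and pruning;
    branch lengths must be present and non-negative.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        _check_unique(labels, "leaf")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
            if edge.length < 0:
                raise ValueError("negative branch length in tree")
        self._labels = labels

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- queries ----------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def patristic_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Dense symmetric leaf-to-leaf path-length matrix.

        ``order`` fixes the row/column ordering; defaults to ``leaf_labels``.
        """
        order = list(order) if order is not None else self.leaf_labels
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace
                if t.label in set(order)}
        missing = [l for l in order if l not in taxa]
        if missing:
            raise KeyError(f"labels not on tree: {missing[:5]}")
        n = len(order)
        d = np.zeros((n, n))
        tx = [taxa[l] for l in order]
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(tx[i], tx[j])
        return d

    def prune_to(self, labels: Sequence[str]) -> "Phylogeny":
        keep = set(labels)
        missing = keep - set(self._labels)
        if missing:
            raise KeyError(f"labels not on tree: {sorted(missing)[:5]}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return Phylogeny(clone)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))


@dataclass
class TaxonomyTable:
    """taxon_id -> ranked lineage mapping; missing ranks are None."""

    lineages: dict[str, dict[str, str | None]]

    @classmethod
    def from_lineage_strings(
        cls, strings: Mapping[str, str]
    ) -> "TaxonomyTable":
        """Parse QIIME/SILVA-style ``k__A; p__B; ...`` lineage strings.

        Rank prefixes are stripped; empty or unparsable fields become
        missing ranks.
        """
        lineages: dict[str, dict[str, str | None]] = {}
        for taxon, text in strings.items():
            fields = [f.strip() for f in str(text).split(";")]
            lin: dict[str, str | None] = {r: None for r in RANKS}
            for rank, value in zip(RANKS, fields):
                for pref in _RANK_PREFIXES:
                    if value.startswith(pref):
                        value = value[len(pref):]
                        break
                value = value.strip()
                lin[rank] = value if value else None
            lineages[str(taxon)] = lin
        return cls(lineages)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        col = df.columns[0]
        return cls.from_lineage_strings(df[col].to_dict())

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for taxon, lin in self.lineages.items():
            parts = [lin[r] if lin[r] is not None else "" for r in RANKS]
            rows.append((taxon, ";".join(parts)))
        pd.DataFrame(rows, columns=["taxon_id", "lineage"]).to_csv(
            path, sep="\t", index=False
        )

    def value(self, taxon_id: str, rank: str) -> str:
        """Rank value for a taxon, pooling missing entries as Unassigned."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lin = self.lineages.get(taxon_id)
        if lin is None:
            return UNASSIGNED
        v = lin.get(rank)
        return v if v else UNASSIGNED


@dataclass
class SampleMetadata:
    """Per-sample numeric variables and categorical group labels."""

    frame: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        _check_unique(list(self.frame.index.astype(str)), "sample")
        num = self.frame.select_dtypes(include=[np.number])
        if num.size and not np.all(np.isfinite(num.to_numpy(dtype=float))):
            raise ValueError("non-finite numeric metadata values")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = set(map(str, sample_ids)) - set(self.frame.index.astype(str))
        if missing:
            raise KeyError(f"samples without metadata: {sorted(missing)[:5]}")

    def numeric(self, name: str, sample_ids: Sequence[str]) -> np.ndarray:
        return self.frame.loc[list(sample_ids), name].to_numpy(dtype=float)

    def groups(self, name: str, sample_ids: Sequence[str]) -> np.ndarray:
        return self.frame.loc[list(sample_ids), name].astype(str).to_numpy()


@dataclass
class MetaboliteTable:
    """Compounds x samples intensity matrix with optional class labels."""

    compound_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    names: dict[str, str] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.compound_ids = list(map(str, self.compound_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.intensities = np.asarray(self.intensities, dtype=float)
        _check_unique(self.compound_ids, "compound")
        _check_unique(self.sample_ids, "sample")
        if self.intensities.shape != (
            len(self.compound_ids), len(self.sample_ids)
        ):
            raise ValueError("intensity matrix shape mismatch")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite metabolite intensities")
        if np.any(self.intensities < 0):
            raise ValueError("negative metabolite intensities")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=self.compound_ids, columns=self.sample_ids
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MetaboliteTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta_cols = [c for c in ("name", "class") if c in df.columns]
        names = df["name"].to_dict() if "name" in df.columns else {}
        classes = df["class"].to_dict() if "class" in df.columns else {}
        data = df.drop(columns=meta_cols)
        return cls(
            list(data.index.astype(str)),
            list(data.columns.astype(str)),
            data.to_numpy(dtype=float),
            names={str(k): str(v) for k, v in names.items()},
            classes={str(k): str(v) for k, v in classes.items()},
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        if self.classes:
            df.insert(0, "class", [self.classes.get(c, "") for c in self.compound_ids])
        if self.names:
            df.insert(0, "name", [self.names.get(c, "") for c in self.compound_ids])
        df.to_csv(path, sep="\t", index_label="compound_id")


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_asv_table(
    path: str | Path, format: str = "tsv", transpose: bool = False
) -> AsvTable:
    """Read a counts-mode table from TSV (taxa as rows) or BIOM 2.1 HDF5.

    Parameters
    ----------
    path
        File to read. For TSV, the first column holds taxon ids and the
        header row holds sample ids.
    format
        ``"tsv"`` or ``"biom"``.
    transpose
        TSV only: set when the file stores samples as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if transpose:
            df = df.T
        taxa = list(df.index.astype(str))
        samples = list(df.columns.astype(str))
        try:
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
        if np.any(mat < 0):
            t, s = np.argwhere(mat < 0)[0]
            raise ValueError(
                f"negative entry at taxon {taxa[t]!r}, sample {samples[s]!r}"
            )
        return AsvTable(taxa, samples, mat, mode="counts")
    if format == "biom":
        import biom

        bt = biom.load_table(str(path))
        mat = np.asarray(bt.matrix_data.todense())
        return AsvTable(
            [str(i) for i in bt.ids("observation")],
            [str(i) for i in bt.ids("sample")],
            mat,
            mode="counts",
        )
    raise ValueError(f"unknown format {format!r}")


def write_asv_table(
    table: AsvTable, path: str | Path, format: str = "tsv"
) -> None:
    """Write a table to TSV (taxa as rows) or BIOM 2.1 HDF5."""
    path = Path(path)
    if format == "tsv":
        df = table.to_dataframe()
        if table.mode == "counts":
            df = df.astype(int)
        df.to_csv(path, sep="\t", index_label="taxon_id")
        return
    if format == "biom":
        import biom
        import h5py

        bt = biom.Table(
            table.counts, observation_ids=table.taxon_ids,
            sample_ids=table.sample_ids,
        )
        with h5py.File(path, "w") as fh:
            bt.to_hdf5(fh, generated_by="assemblyscope")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# normalisation utilities
# ---------------------------------------------------------------------------

def to_relative(table: AsvTable) -> AsvTable:
    """Convert counts to within-sample relative abundances.

    Raises on relative-mode input (double normalisation) and on all-zero
    samples.
    """
    if table.mode != "counts":
        raise ValueError("table is already in relative mode")
    rel = table.relative_matrix()
    return AsvTable(table.taxon_ids, table.sample_ids, rel, mode="relative")


def subsample_to_min_depth(table: AsvTable, seed: int) -> AsvTable:
    """Rarefy every sample to the minimum observed sample total.

    Sampling is without replacement within each sample (multivariate
    hypergeometric), reproducible given ``seed``. A sample already at the
    minimum depth is returned unchanged.
    """
    if table.mode != "counts":
        raise ValueError("subsampling requires a counts-mode table")
    totals = table.sample_totals().astype(int)
    depth = int(totals.min())
    if depth <= 0:
        empty = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"minimum depth is zero (empty samples: {empty})")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts, dtype=float)
    counts = np.round(table.counts).astype(np.int64)
    for j in range(table.n_samples):
        col = counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return AsvTable(table.taxon_ids, table.sample_ids, out, mode="counts")


def align_to_tree(
    table: AsvTable, tree: Phylogeny
) -> tuple[AsvTable, Phylogeny]:
    """Restrict table and tree to their shared taxa, in table row order."""
    leaves = set(tree.leaf_labels)
    shared = [t for t in table.taxon_ids if t in leaves]
    if not shared:
        raise ValueError("table and tree share no taxon identifiers")
    sub = table if len(shared) == table.n_taxa else table.select_taxa(shared)
    pruned = tree if len(shared) == tree.n_leaves else tree.prune_to(shared)
    return sub, pruned


def aggregate_by_rank(
    table: AsvTable, taxonomy: TaxonomyTable, rank: str
) -> AsvTable:
    """Sum member rows by taxonomy rank value; unassigned taxa pool together.

    Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, taxon in enumerate(table.taxon_ids):
        value = taxonomy.value(taxon, rank)
        if value not in groups:
            groups[value] = []
            order.append(value)
        groups[value].append(i)
    mat = np.vstack(
        [table.counts[groups[g], :].sum(axis=0) for g in order]
    )
    return AsvTable(order, list(table.sample_ids), mat, mode=table.mode)
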