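"""Domain containers and readers/writers for every on-disk format the pipeline touches.

All cross-file gene matching is by ``gene_id``; symbols are display-only
(symbols are not unique). The dense matrix dialect is: first column
``gene_id``, header row holding cell ids, tab-separated, ``.`` decimal.
Sparse input is MatrixMarket coordinate format (1-based indices) with two
one-column sidecar files listing gene and cell ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

BIOTYPES = ("coding", "lncRNA", "pcRNA")
UNITS = ("counts", "fpkm", "log2fpkm")

COMPARTMENTS = (
    "ventricle",
    "atrium",
    "left ventricle",
    "right ventricle",
    "left atrium",
)
STAGES = ("E9.5", "E11.5", "E14.5", "E18.5", "P0", "P3", "P7", "P21")


class FormatError(ValueError):
    """A file violates the format or an invariant of its domain type."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with a unit tag.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Non-negative expression values.
    gene_ids, cell_ids : list of str
        Ordered unique identifiers for rows and columns.
    unit : {"counts", "fpkm", "log2fpkm"}
    meta : dict
        Per-dataset labels, e.g. ``compartment`` and ``stage``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    unit: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.unit not in UNITS:
            raise FormatError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if np.any(self.values < 0):
            g, c = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative expression value at gene {self.gene_ids[g]!r}, "
                f"cell {self.cell_ids[c]!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[idx], list(gene_ids), self.cell_ids, self.unit, dict(self.meta)
        )

    def subset_cells(self, cell_ids: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.cell_ids).get_indexer(cell_ids)
        if (idx < 0).any():
            missing = [c for c, i in zip(cell_ids, idx) if i < 0]
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[:, idx], self.gene_ids, list(cell_ids), self.unit, dict(self.meta)
        )


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id {i!r}")
        seen.add(i)


@dataclass
class MarkerDatabase:
    """Cell type -> marker gene set, with per-gene provenance tags."""

    entries: dict[str, set[str]]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell_type, genes in self.entries.items():
            if not genes:
                raise FormatError(f"empty marker set for cell type {cell_type!r}")
            self.entries[cell_type] = set(genes)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.entries)

    def markers(self, cell_type: str) -> set[str]:
        return self.entries[cell_type]


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT contents)."""

    sets: dict[str, tuple[str, set[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"empty gene set {name!r}")

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> set[str]:
        return self.sets[name][1]

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping sets that empty out."""
        kept = {}
        for name, (desc, genes) in self.sets.items():
            inter = genes & universe
            if inter:
                kept[name] = (desc, inter)
        return GeneSetCollection(kept)


@dataclass
class InteractionNetwork:
    """Undirected gene-gene interaction edges with optional weights."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen: set[frozenset] = set()
        for a, b, _ in self.edges:
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise FormatError(f"duplicate undirected edge {a!r}-{b!r}")
            seen.add(key)

    def edges_within(self, genes: set[str]) -> list[tuple[str, str, float]]:
        return [(a, b, w) for a, b, w in self.edges if a in genes and b in genes]


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_matrix(path: str | Path, fmt: str = "tsv", unit: str = "counts",
                           meta: dict | None = None) -> ExpressionMatrix:
    """Read a genes x cells matrix from dense TSV or MatrixMarket triplets.

    For ``fmt="mtx-triplet"`` the matrix file must sit next to ``genes.txt``
    and ``cells.txt`` sidecars (one id per line, ordered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    elif fmt == "mtx-triplet":
        gene_ids = _read_id_file(path.parent / "genes.txt")
        cell_ids = _read_id_file(path.parent / "cells.txt")
        mat = scipy.io.mmread(path)
        values = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"MTX shape {values.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx-triplet'")
    return ExpressionMatrix(values, gene_ids, cell_ids, unit=unit, meta=meta or {})


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        m.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx-triplet":
        sparse = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(str(path), sparse)
        _write_id_file(path.parent / "genes.txt", m.gene_ids)
        _write_id_file(path.parent / "cells.txt", m.cell_ids)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_id_file(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar id file {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def _write_id_file(path: Path, ids: list[str]) -> None:
    path.write_text("\n".join(ids) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation TSV (gene_id, symbol, biotype, length_bp).

    Biotype must be one of coding / lncRNA / pcRNA; lengths are positive
    integers. Returns a DataFrame indexed by gene_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "biotype": str})
    required = {"gene_id", "symbol", "biotype", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing columns {sorted(missing)}")
    bad = sorted(set(df["biotype"]) - set(BIOTYPES))
    if bad:
        raise FormatError(
            f"unknown biotype(s) {bad}; allowed classes are {list(BIOTYPES)}"
        )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r} in annotation")
    if (df["length_bp"] < 1).any():
        bad_id = df.loc[df["length_bp"] < 1, "gene_id"].iloc[0]
        raise FormatError(f"non-positive length for gene {bad_id!r}")
    df = df.set_index("gene_id")
    df["length_bp"] = df["length_bp"].astype(int)
    return df


def write_gene_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Marker database (TSV: cell_type <TAB> gene_id <TAB> source)


def read_marker_db(path: str | Path) -> MarkerDatabase:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_type", "gene_id"}
    if missing := required - set(df.columns):
        raise FormatError(f"marker DB missing columns {sorted(missing)}")
    entries: dict[str, set[str]] = {}
    source: dict[str, str] = {}
    for row in df.itertuples(index=False):
        entries.setdefault(row.cell_type, set()).add(row.gene_id)
        if hasattr(row, "source") and isinstance(row.source, str):
            source[row.gene_id] = row.source
    return MarkerDatabase(entries, source)


def write_marker_db(db: MarkerDatabase, path: str | Path) -> None:
    rows = []
    for cell_type in sorted(db.entries):
        for gene in sorted(db.entries[cell_type]):
            rows.append((cell_type, gene, db.source.get(gene, "")))
    pd.DataFrame(rows, columns=["cell_type", "gene_id", "source"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: ``name <TAB> description <TAB> gene1 <TAB> gene2 ...``.

    Sets reduced below one member after optional intersection with
    ``universe`` are dropped with a warning.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
        name, desc = parts[0], parts[1]
        if name in sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        genes = {g for g in parts[2:] if g}
        if universe is not None:
            genes &= universe
        if not genes:
            logger.warning("dropping gene set %r: no members after filtering", name)
            continue
        sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, (desc, genes) in gsc.sets.items():
        lines.append("\t".join([name, desc] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Interaction network (edge-list TSV: gene_a <TAB> gene_b [<TAB> weight])


def read_interaction_network(path: str | Path) -> InteractionNetwork:
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"edge list line {lineno} has fewer than 2 fields")
        w = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
        edges.append((parts[0], parts[1], w))
    return InteractionNetwork(edges)


def write_interaction_network(net: InteractionNetwork, path: str | Path) -> None:
    lines = [f"{a}\t{b}\t{w:g}" for a, b, w in net.edges]
    Path(path).write_text("\n".join(lines) + "\n")
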