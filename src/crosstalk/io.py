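"""Core data model and plain-text I/O.

In-memory containers for sparse gene-by-cell count data, per-cell
annotation tables, ligand-receptor pair tables and interaction edges,
plus readers/writers for the formats the pipeline exchanges on disk:
CellRanger-style MatrixMarket triplets (``matrix.mtx`` + ``features.tsv``
+ ``barcodes.tsv``), tab-separated tables, GraphML and DOT.

All tabular files are UTF-8, tab-delimited, with a header row.  Gene
symbols are matched case-sensitively throughout: zebrafish symbols are
lowercase and case distinguishes orthologs across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

# status -> edge colour, matching the usual rendering of differential
# interaction maps (unchanged black, lost cyan, gained magenta).
STATUS_COLORS = {"unchanged": "black", "lost": "cyan", "gained": "magenta"}

EDGE_TSV_COLUMNS = [
    "source_cluster",
    "ligand",
    "receptor",
    "target_cluster",
    "status",
    "treatment",
    "control",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} identifiers: {sorted(set(dup))[:5]} ...")


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell count matrix.

    Rows are genes, columns are cells.  ``counts`` is stored CSC so that
    per-cell (column) operations and cell subsetting are cheap; iteration
    over nonzeros never densifies.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csc_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entries")
            if not np.all(data == np.floor(data)):
                raise FormatError("non-integer count entries")
        self.counts = self.counts.astype(np.int64)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    # -- shape ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    # -- lookups -------------------------------------------------------
    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def cell_indices(self, cell_ids: Iterable[str]) -> np.ndarray:
        idx = []
        missing = []
        for c in cell_ids:
            i = self._cell_index.get(c)
            if i is None:
                missing.append(c)
            else:
                idx.append(i)
        if missing:
            raise KeyError(f"cells absent from matrix: {missing[:5]} ...")
        return np.asarray(idx, dtype=int)

    # -- summaries -----------------------------------------------------
    def cell_totals(self) -> np.ndarray:
        """Per-cell UMI totals (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (count > 0) genes per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells in which each gene is detected."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    # -- subsetting ----------------------------------------------------
    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            list(self.gene_ids),
            [self.cell_ids[i] for i in keep],
            self.counts[:, keep],
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            [self.gene_ids[i] for i in keep],
            list(self.cell_ids),
            self.counts[keep, :],
        )

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense count vector for one gene across all cells."""
        return np.asarray(self.counts[self.gene_index(gene), :].todense()).ravel()


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the same axes and sparsity as the
    source :class:`CountMatrix`.

    ``value(g, c) = ln(1 + scale_factor * count(g, c) / total(c))``; zero
    exactly where the count is zero.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: sp.csc_matrix
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values).astype(np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("normalized matrix shape mismatch")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def cell_indices(self, cell_ids: Iterable[str]) -> np.ndarray:
        idx = []
        missing = []
        for c in cell_ids:
            i = self._cell_index.get(c)
            if i is None:
                missing.append(c)
            else:
                idx.append(i)
        if missing:
            raise KeyError(f"cells absent from matrix: {missing[:5]} ...")
        return np.asarray(idx, dtype=int)

    def dense_cells_by_genes(self, cell_idx: np.ndarray, gene_idx: np.ndarray | None = None) -> np.ndarray:
        """Dense (cells x genes) block for group-wise statistics."""
        sub = self.values[:, cell_idx]
        if gene_idx is not None:
            sub = sub[gene_idx, :]
        return np.asarray(sub.todense()).T


# ---------------------------------------------------------------------------
# interaction edges
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class InteractionEdge:
    """A potential ligand->receptor interaction between two clusters,
    asserted for a single experimental condition."""

    source_cluster: str
    ligand: str
    receptor: str
    target_cluster: str
    condition: str = ""

    def key(self) -> tuple[str, str, str, str]:
        """Condition-free identity used for differential comparison."""
        return (self.source_cluster, self.ligand, self.receptor, self.target_cluster)


@dataclass(frozen=True, order=True)
class DifferentialEdge:
    """An interaction edge with its fate in a treatment-vs-control
    comparison: unchanged (both), lost (control only), gained (treatment
    only)."""

    source_cluster: str
    ligand: str
    receptor: str
    target_cluster: str
    status: str
    treatment: str
    control: str

    def __post_init__(self) -> None:
        if self.status not in STATUS_COLORS:
            raise ValueError(f"unknown status {self.status!r}")
        if self.treatment == self.control:
            raise ValueError("treatment and control conditions must differ")

    def key(self) -> tuple[str, str, str, str]:
        return (self.source_cluster, self.ligand, self.receptor, self.target_cluster)

    @property
    def color(self) -> str:
        return STATUS_COLORS[self.status]


# ---------------------------------------------------------------------------
# MatrixMarket triplet
# ---------------------------------------------------------------------------


def _read_id_column(path: Path, use_second: bool) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 0 or df.empty:
        return []
    col = 1 if (use_second and df.shape[1] >= 2) else 0
    ids = df.iloc[:, col].tolist()
    if any(pd.isna(i) or str(i) == "" for i in ids):
        raise FormatError(f"empty identifier in {path}")
    return [str(i) for i in ids]


def read_mtx_triplet(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a CellRanger-convention MatrixMarket triplet.

    The features file may have one column (symbol) or two or more
    (id, symbol, ...); the second column is used as the working symbol
    when present.  Gene order follows the features file, cell order the
    barcodes file.
    """
    matrix_path, features_path, barcodes_path = map(Path, (matrix_path, features_path, barcodes_path))
    for p in (matrix_path, features_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    genes = _read_id_column(features_path, use_second=True)
    cells = _read_id_column(barcodes_path, use_second=False)
    try:
        mat = scipy.io.mmread(matrix_path)
    except ValueError as e:
        raise FormatError(f"cannot parse {matrix_path}: {e}") from e
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix header declares {mat.shape[0]} x {mat.shape[1]} but features/barcodes "
            f"list {len(genes)} genes and {len(cells)} cells"
        )
    return CountMatrix(genes, cells, sp.csc_matrix(mat))


def write_mtx_triplet(m: CountMatrix, outdir) -> dict[str, Path]:
    """Write ``matrix.mtx``, ``features.tsv`` and ``barcodes.tsv``.

    Round-trip through :func:`read_mtx_triplet` is lossless.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(m.counts), field="integer")
    paths["features"].write_text("".join(f"{g}\n" for g in m.gene_ids))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in m.cell_ids))
    return paths


# ---------------------------------------------------------------------------
# cell annotation table
# ---------------------------------------------------------------------------

MANDATORY_CELL_COLUMNS = ("cell_id", "sample_id", "condition")


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell annotation TSV.

    Requires columns ``cell_id``, ``sample_id``, ``condition``;
    ``cluster`` and any further columns are preserved untouched.  The
    result is indexed by ``cell_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    missing = [c for c in MANDATORY_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table {path} lacks mandatory column(s): {missing}")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise FormatError(f"duplicate cell_id in {path}: {dups[:5]} ...")
    return df.set_index("cell_id")


def write_cell_table(annotation: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    annotation.rename_axis("cell_id").reset_index().to_csv(path, sep="\t", index=False)
    return path


def join_annotation(m: CountMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Align an annotation table to a matrix's cells, in matrix order.

    Every matrix cell must be annotated; a missing cell is an explicit
    error rather than a silent drop.
    """
    missing = [c for c in m.cell_ids if c not in annotation.index]
    if missing:
        raise KeyError(f"cells in matrix but absent from annotation: {missing[:5]} ...")
    return annotation.loc[m.cell_ids]


# ---------------------------------------------------------------------------
# ligand-receptor pair table
# ---------------------------------------------------------------------------


def builtin_lr_table() -> pd.DataFrame:
    """Small built-in zebrafish demo ligand-receptor table.

    bdnf signals through its two receptors ntrk2 (mostly neuronal) and
    ngfra (mostly glial); il4 signals through il4r.1 on glia and immune
    cells.
    """
    return pd.DataFrame(
        [
            ("bdnf", "ntrk2"),
            ("bdnf", "ngfra"),
            ("il4", "il4r.1"),
        ],
        columns=["ligand", "receptor"],
    )


def validate_lr_table(lr: pd.DataFrame) -> pd.DataFrame:
    if not {"ligand", "receptor"}.issubset(lr.columns):
        raise FormatError("ligand-receptor table needs 'ligand' and 'receptor' columns")
    lr = lr[["ligand", "receptor"]].astype(str)
    if (lr["ligand"].str.len() == 0).any() or (lr["receptor"].str.len() == 0).any():
        raise FormatError("empty gene symbol in ligand-receptor table")
    if lr.duplicated().any():
        raise FormatError("duplicate (ligand, receptor) rows")
    return lr.reset_index(drop=True)


def read_lr_table(path) -> pd.DataFrame:
    return validate_lr_table(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# edge graph output
# ---------------------------------------------------------------------------


def edges_to_frame(edges: Sequence[DifferentialEdge]) -> pd.DataFrame:
    rows = [
        (e.source_cluster, e.ligand, e.receptor, e.target_cluster, e.status, e.treatment, e.control)
        for e in edges
    ]
    return pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS)


def frame_to_edges(df: pd.DataFrame) -> list[DifferentialEdge]:
    return [
        DifferentialEdge(
            r.source_cluster, r.ligand, r.receptor, r.target_cluster, r.status, r.treatment, r.control
        )
        for r in df.itertuples(index=False)
    ]


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def write_edge_graph(edges: Sequence[DifferentialEdge], path, format: str = "tsv") -> Path:
    """Write a differential interaction graph.

    ``tsv`` round-trips exactly through :func:`read_edge_tsv`; ``graphml``
    and ``dot`` carry the status as an edge color attribute (unchanged =
    black, lost = cyan, gained = magenta).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        edges_to_frame(edges).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        for e in edges:
            g.add_node(e.source_cluster)
            g.add_node(e.target_cluster)
            g.add_edge(
                e.source_cluster,
                e.target_cluster,
                ligand=e.ligand,
                receptor=e.receptor,
                status=e.status,
                color=e.color,
                treatment=e.treatment,
                control=e.control,
            )
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["digraph interactions {"]
        nodes = sorted({e.source_cluster for e in edges} | {e.target_cluster for e in edges})
        for n in nodes:
            lines.append(f"  {_dot_quote(n)};")
        for e in sorted(edges):
            label = f"{e.ligand}->{e.receptor}"
            lines.append(
                f"  {_dot_quote(e.source_cluster)} -> {_dot_quote(e.target_cluster)} "
                f'[label={_dot_quote(label)}, color={e.color}];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown edge graph format {format!r}")
    return path


def read_edge_tsv(path) -> list[DifferentialEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EDGE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"edge TSV lacks column(s): {missing}")
    return frame_to_edges(df)
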