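"""Core data containers and plain-text readers/writers.

Counts are exchanged either as a Matrix Market triplet (``matrix.mtx`` plus
``barcodes.tsv`` / ``features.tsv`` sidecars, CellRanger style) or as a dense
delimited table (header row = feature ids, first column = cell ids).
Partitions are two-column TSV files mapping ``cell_id`` to ``metacell_id``;
an empty or ``NA`` metacell id marks an unassigned cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("mcrigor")

#: Sentinel label for cells excluded from every metacell.
UNASSIGNED = ""

_NA_TOKENS = {"", "NA", "NaN", "nan", "None"}


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, cells in rows, features in columns."""

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.feature_ids)} feature ids"
            )
        if np.any(self.values < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts must be integral")
            self.values = self.values.astype(np.int64)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total count per cell (``y_{i+}``)."""
        return self.values.sum(axis=1)


@dataclass
class MetacellPartition:
    """Assignment of cells to metacells; unassigned cells are permitted.

    ``assignment`` maps every cell id to a metacell label or :data:`UNASSIGNED`.
    ``metacell_ids`` fixes a deterministic label order (first appearance by
    default) used by every downstream table.
    """

    assignment: dict[str, str]
    metacell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for label in self.assignment.values():
            if label != UNASSIGNED and label not in seen:
                seen.append(label)
        if not self.metacell_ids:
            self.metacell_ids = seen
        else:
            missing = set(seen) - set(self.metacell_ids)
            if missing:
                raise ValueError(f"labels missing from metacell_ids: {sorted(missing)}")
        if len(set(self.metacell_ids)) != len(self.metacell_ids):
            raise ValueError("duplicate metacell ids")

    @property
    def n_metacells(self) -> int:
        return len(self.metacell_ids)

    def members(self, metacell_id: str) -> list[str]:
        return [c for c, m in self.assignment.items() if m == metacell_id]

    def sizes(self) -> dict[str, int]:
        out = {m: 0 for m in self.metacell_ids}
        for label in self.assignment.values():
            if label != UNASSIGNED:
                out[label] += 1
        return out

    def n_unassigned(self) -> int:
        return sum(1 for v in self.assignment.values() if v == UNASSIGNED)

    def member_indices(self, cell_ids: list[str]) -> dict[str, np.ndarray]:
        """Row indices into ``cell_ids`` for each metacell, in label order."""
        pos = {c: i for i, c in enumerate(cell_ids)}
        groups: dict[str, list[int]] = {m: [] for m in self.metacell_ids}
        for cell, label in self.assignment.items():
            if label != UNASSIGNED:
                if cell not in pos:
                    raise KeyError(f"cell {cell!r} not present in the count matrix")
                groups[label].append(pos[cell])
        return {m: np.array(sorted(idx), dtype=np.intp) for m, idx in groups.items()}


# ---------------------------------------------------------------------------
# counts I/O


def _read_ids(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    cells_in: str | None = None,
) -> CountMatrix:
    """Read a Matrix Market triplet, normalizing orientation to cells-in-rows.

    Orientation is auto-detected from the sidecar lengths; for square
    matrices it must be disambiguated with ``cells_in`` ("rows" or
    "columns").  CellRanger convention (features x cells) is transposed.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    barcodes = _read_ids(Path(barcodes_path))
    features = _read_ids(Path(features_path))
    n_rows, n_cols = mat.shape
    if n_rows == n_cols and len(barcodes) == len(features):
        if cells_in == "rows":
            pass
        elif cells_in == "columns":
            mat = mat.T
        else:
            raise ValueError(
                "square matrix with equal sidecar lengths: pass cells_in="
                "'rows' or 'columns'"
            )
    elif (n_rows, n_cols) == (len(barcodes), len(features)):
        pass
    elif (n_rows, n_cols) == (len(features), len(barcodes)):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(barcodes)} barcodes "
            f"x {len(features)} features nor its transpose"
        )
    cm = CountMatrix(mat, barcodes, features)
    logger.info("read counts: %d cells x %d features", cm.n_cells, cm.n_features)
    return cm


def read_counts_dense(path: str | Path, sep: str | None = None) -> CountMatrix:
    """Read a dense delimited table (header = feature ids, column 0 = cell ids)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        df.to_numpy(), [str(c) for c in df.index], [str(f) for f in df.columns]
    )


def read_counts(
    path: str | Path,
    fmt: str = "auto",
    barcodes_path: str | Path | None = None,
    features_path: str | Path | None = None,
    cells_in: str | None = None,
) -> CountMatrix:
    """Dispatch on format: ``mtx_triplet`` or ``dense_table``.

    For MTX input, sidecars default to ``barcodes.tsv`` / ``features.tsv``
    next to the matrix file.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx_triplet" if path.suffix == ".mtx" else "dense_table"
    if fmt == "mtx_triplet":
        barcodes = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        features = Path(features_path) if features_path else path.parent / "features.tsv"
        return read_counts_mtx(path, barcodes, features, cells_in=cells_in)
    if fmt == "dense_table":
        return read_counts_dense(path)
    raise ValueError(f"unknown counts format {fmt!r}")


def write_counts_mtx(counts: CountMatrix, directory: str | Path) -> None:
    """Write counts as ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    (directory / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    (directory / "features.tsv").write_text("\n".join(counts.feature_ids) + "\n")


def write_counts_dense(counts: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(counts.values, index=counts.cell_ids, columns=counts.feature_ids)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# partition I/O


def read_partition(path: str | Path, cell_ids: list[str]) -> MetacellPartition:
    """Read a two-column TSV (``cell_id``, ``metacell_id``).

    The returned partition covers exactly ``cell_ids``; cells absent from the
    file, or with an empty/NA metacell id, are unassigned.  Cells in the file
    but not in ``cell_ids``, and duplicated cell rows, are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["cell_id", "metacell_id"]:
        raise ValueError("partition file must have columns cell_id, metacell_id")
    known = set(cell_ids)
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicated cell rows in partition file: {dupes[:5]}")
    unknown = [c for c in df["cell_id"] if c not in known]
    if unknown:
        raise ValueError(f"partition file names unknown cells: {unknown[:5]}")
    mapping = dict(zip(df["cell_id"], df["metacell_id"]))
    assignment = {}
    for cell in cell_ids:
        label = mapping.get(cell, UNASSIGNED)
        assignment[cell] = UNASSIGNED if label in _NA_TOKENS else label
    part = MetacellPartition(assignment)
    logger.info(
        "read partition: %d metacells, %d unassigned of %d cells",
        part.n_metacells, part.n_unassigned(), len(cell_ids),
    )
    return part


def write_partition(partition: MetacellPartition, path: str | Path) -> None:
    rows = [
        {"cell_id": c, "metacell_id": m if m != UNASSIGNED else "NA"}
        for c, m in partition.assignment.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
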