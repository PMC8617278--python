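"""Count-matrix containers, readers/writers, QC, normalisation and splitting.

The framework compares a *real* (reference) single-cell count matrix with a
*simulated* one.  Both live in :class:`CountMatrix`: raw non-negative integer
counts, genes as rows and cells as columns, with optional per-cell group
(cell-type) labels.  Expression-scale analyses operate on
:class:`NormalizedMatrix`, which carries log2 counts-per-million (CPM) values
with a pseudocount of 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Input data violates a structural contract (negative count, NaN, ...)."""


class ConfigurationError(ValueError):
    """A file, sidecar or option required to interpret the input is missing."""


@dataclass
class CountMatrix:
    """Raw counts, genes x cells, with identifiers and optional group labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x cells array")
        if np.issubdtype(self.counts.dtype, np.floating):
            if np.isnan(self.counts).any():
                raise ValidationError("counts contain NaN entries")
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts contain non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts contain negative entries")
        n_genes, n_cells = self.counts.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell ids are not unique")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if self.groups.shape != (n_cells,):
                raise ValidationError("groups must label every cell exactly once")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell (column sums)."""
        return self.counts.sum(axis=0)

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            counts=self.counts[:, index],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
            groups=None if self.groups is None else self.groups[index],
        )


@dataclass
class NormalizedMatrix:
    """log2-CPM values (pseudocount 1); zero iff the raw count was zero."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    groups: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _read_id_file(path: Path) -> list[str]:
    # 10x-style sidecars may carry extra columns (ensembl id, symbol, type);
    # the first column is the identifier.
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ids = df.iloc[:, 0].tolist()
    # Prefer the symbol column when the first two columns differ (10x style)
    # only if first column is not unique; identifiers must be unique.
    if len(set(ids)) != len(ids) and df.shape[1] > 1:
        ids = df.iloc[:, 1].tolist()
    return ids


def read_counts(
    path: str | Path,
    format: str | None = None,
    transpose: bool = False,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> CountMatrix:
    """Read a genes x cells count matrix from MTX or dense CSV/TSV.

    MTX input expects ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``
    sidecars next to the matrix unless explicit paths are given.  Dense files
    have a header row of cell ids and the first column holding gene ids;
    ``transpose=True`` accepts cells-as-rows files.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            suffix
        )
        if format is None:
            raise ConfigurationError(f"cannot infer format from suffix {suffix!r}")

    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        gene_ids, cell_ids = _mtx_sidecars(
            path, mat.shape, features_path, barcodes_path
        )
        counts = mat
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ConfigurationError(f"unknown format {format!r}")

    if transpose:
        counts = counts.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids)


def _mtx_sidecars(path, shape, features_path, barcodes_path):
    n_genes, n_cells = shape
    directory = path.parent
    if features_path is None:
        for candidate in ("features.tsv", "genes.tsv"):
            if (directory / candidate).exists():
                features_path = directory / candidate
                break
        else:
            raise ConfigurationError(
                f"no features.tsv/genes.tsv sidecar found next to {path}"
            )
    if barcodes_path is None:
        barcodes_path = directory / "barcodes.tsv"
        if not barcodes_path.exists():
            raise ConfigurationError(f"no barcodes.tsv sidecar found next to {path}")
    gene_ids = _read_id_file(Path(features_path))
    cell_ids = _read_id_file(Path(barcodes_path))
    if len(gene_ids) != n_genes or len(cell_ids) != n_cells:
        raise ConfigurationError(
            f"sidecar lengths ({len(gene_ids)}, {len(cell_ids)}) do not match "
            f"matrix shape {shape}"
        )
    return gene_ids, cell_ids


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (cell_id, group) into a mapping.

    A headerless one-column file is accepted as labels in cell order, returned
    under integer-position keys handled by :func:`attach_groups`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"group file does not exist: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 1:
        return {str(i): g for i, g in enumerate(df.iloc[:, 0])}
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def attach_groups(m: CountMatrix, mapping: dict[str, str]) -> CountMatrix:
    """Return a copy of ``m`` with group labels from a cell_id -> group map."""
    if all(k.isdigit() for k in mapping):
        labels = [mapping[str(i)] for i in range(m.n_cells)]
    else:
        missing = [c for c in m.cell_ids if c not in mapping]
        if missing:
            raise ConfigurationError(
                f"{len(missing)} cells missing from group file (e.g. {missing[0]!r})"
            )
        labels = [mapping[c] for c in m.cell_ids]
    return replace(m, groups=np.asarray(labels, dtype=object))


def qc_filter(m: CountMatrix, min_fraction: float = 0.01) -> CountMatrix:
    """Remove low-quality cells / empty droplets.

    A cell is kept when its library size is at least ``min_fraction`` times the
    median library size across cells.  The gene set is unchanged.
    """
    if not 0 <= min_fraction < 1:
        raise ValidationError("min_fraction must be in [0, 1)")
    lib = m.library_sizes()
    threshold = min_fraction * np.median(lib)
    keep = np.nonzero(lib >= threshold)[0]
    if keep.size == 0:
        raise ValidationError("QC filter removed every cell")
    if keep.size == m.n_cells:
        return m
    return m.subset_cells(keep)


def normalize_log2cpm(m: CountMatrix) -> NormalizedMatrix:
    """log2(count / library_size * 1e6 + 1) per entry."""
    lib = m.library_sizes().astype(float)
    zero = np.nonzero(lib == 0)[0]
    if zero.size:
        raise ValidationError(
            f"cell {m.cell_ids[zero[0]]!r} has zero library size; "
            "run qc_filter first"
        )
    cpm = m.counts / lib[None, :] * 1e6
    return NormalizedMatrix(
        values=np.log2(cpm + 1.0),
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        groups=None if m.groups is None else m.groups.copy(),
    )


def split_train_test(
    m: CountMatrix, seed: int
) -> tuple[CountMatrix, CountMatrix]:
    """Seeded 50/50 cell-wise split, stratified by group when labels exist.

    The two halves are disjoint and exhaustive; for odd sizes the extra cell
    goes to the test (reference) half.
    """
    rng = np.random.default_rng(seed)
    if m.n_cells < 2:
        raise ValidationError("need at least 2 cells to split")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if m.groups is not None:
        for g in pd.unique(m.groups):
            idx = np.nonzero(m.groups == g)[0]
            if idx.size < 2:
                raise ValidationError(
                    f"group {g!r} has a single cell; cannot stratify"
                )
            perm = rng.permutation(idx)
            half = idx.size // 2
            train_idx.append(perm[:half])
            test_idx.append(perm[half:])
    else:
        perm = rng.permutation(m.n_cells)
        half = m.n_cells // 2
        train_idx.append(perm[:half])
        test_idx.append(perm[half:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return m.subset_cells(train), m.subset_cells(test)


SCORE_COLUMNS = [
    "method",
    "dataset",
    "cell_group",
    "criterion",
    "measure",
    "raw",
    "transformed",
    "weight",
]


def make_score_table(rows: list[dict]) -> pd.DataFrame:
    """Build a long-form score table, filling absent optional columns."""
    df = pd.DataFrame(rows)
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in ("raw", "transformed", "weight") else "all"
    return df[SCORE_COLUMNS]


def write_scores(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a long-form score table as CSV or JSON (lossless round-trip)."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty score table")
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=1))
    else:
        raise ConfigurationError(f"unknown score format {format!r}")


def read_scores(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    else:
        df = pd.DataFrame(json.loads(path.read_text()))
    return df
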