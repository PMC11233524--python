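"""Readers and writers for the external formats the pipeline touches.

Single-cell counts travel as MatrixMarket triplet directories (matrix.mtx +
barcodes.tsv + features.tsv, optionally gzipped, genes in rows as in 10x
feature-major output); pathway collections as Broad-dialect GMT; cell
metadata, bulk expression and clinical tables as TSV with a header.

Gene identity is by symbol string, case-sensitive; no alias mapping is
attempted. Indices are 0-based in memory; serialized MTX stays 1-based per
the MatrixMarket standard.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class FormatError(ValueError):
    """Malformed or internally inconsistent input file."""


GRADE_LEVELS = ("II", "III", "IV")
IDH_LEVELS = ("WT", "Mutant")
CODEL_LEVELS = ("codel", "non-codel")
PRS_LEVELS = ("Primary", "Recurrent", "Secondary")

META_REQUIRED_COLUMNS = ("cell_id", "sample_id", "condition", "cell_type")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifier vectors."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} gene rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} cell columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("cell ids are not unique")
        data = self.values.data
        if data.size:
            if np.issubdtype(data.dtype, np.floating):
                if not np.all(data == np.floor(data)):
                    raise FormatError("count matrix contains non-integer entries")
                self.values = self.values.astype(np.int64)
            if self.values.data.size and self.values.data.min() < 0:
                raise FormatError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class GeneSetCollection:
    """Ordered pathway -> member gene lists; duplicates within a set collapsed."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def membership_counts(self) -> dict[str, int]:
        """Number of pathways each universe gene belongs to."""
        counts: dict[str, int] = {}
        for genes in self.sets.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class BulkCohort:
    """Samples x genes log2 expression with clinical covariates and survival."""

    expr: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            raise FormatError("duplicate sample ids in expression table")
        if not self.expr.index.equals(self.clinical.index):
            missing = set(self.expr.index) ^ set(self.clinical.index)
            raise FormatError(
                f"expression and clinical tables disagree on samples: {sorted(missing)[:5]}"
            )
        _validate_factor(self.clinical, "grade", GRADE_LEVELS)
        _validate_factor(self.clinical, "idh_status", IDH_LEVELS)
        _validate_factor(self.clinical, "codel_1p19q", CODEL_LEVELS)
        _validate_factor(self.clinical, "prs_type", PRS_LEVELS)
        if "os_time" in self.clinical:
            t = pd.to_numeric(self.clinical["os_time"], errors="raise")
            if (t.dropna() <= 0).any():
                raise FormatError("os_time must be positive where present")
        if "os_event" in self.clinical:
            ev = self.clinical["os_event"].dropna()
            if not set(np.unique(ev.astype(int))) <= {0, 1}:
                raise FormatError("os_event must be 0/1")

    @property
    def samples(self) -> pd.Index:
        return self.expr.index


def _validate_factor(clinical: pd.DataFrame, column: str, levels: tuple[str, ...]) -> None:
    if column not in clinical:
        return
    observed = set(clinical[column].dropna().astype(str))
    bad = observed - set(levels)
    if bad:
        raise FormatError(f"column {column!r} has unknown levels {sorted(bad)}")


# ---------------------------------------------------------------------------
# MTX triplet directories
# ---------------------------------------------------------------------------

def _find_triplet_file(dir_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dir_path / name
            if p.exists():
                return p
    raise FormatError(f"no file among {stems} found in {dir_path}")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_id_column(path: Path, symbol_column: int | None = None) -> list[str]:
    rows: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if symbol_column is not None and len(parts) > symbol_column:
                rows.append(parts[symbol_column])
            else:
                rows.append(parts[0])
    return rows


def _deduplicate(symbols: list[str]) -> list[str]:
    """Disambiguate repeated symbols with .1, .2 suffixes in file order."""
    seen: dict[str, int] = {}
    out: list[str] = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_mtx_triplet(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet directory into a CountMatrix.

    The directory must contain ``matrix.mtx``, ``barcodes.tsv`` and
    ``features.tsv`` (or ``genes.tsv``), each optionally gzipped. Features are
    genes-in-rows; when the features file carries two or more columns the
    second (the 10x symbol column) is used.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FormatError(f"{dir_path} is not a directory")
    mtx = _find_triplet_file(dir_path, ("matrix.mtx",))
    barcodes = _find_triplet_file(dir_path, ("barcodes.tsv",))
    features = _find_triplet_file(dir_path, ("features.tsv", "genes.tsv"))

    with _open_maybe_gzip(mtx, "rb") as fh:
        try:
            mat = mmread(fh)
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and np.issubdtype(mat.data.dtype, np.floating):
        if not np.all(mat.data == np.floor(mat.data)):
            raise FormatError(f"{mtx} contains non-integer entries")

    # 10x features files carry (id, symbol, ...); plain lists carry one column
    with _open_maybe_gzip(features) as fh:
        first = fh.readline().rstrip("\n")
    n_cols = len(first.split("\t")) if first else 1
    gene_symbols = _read_id_column(features, symbol_column=1 if n_cols >= 2 else None)
    cell_barcodes = _read_id_column(barcodes)

    if len(gene_symbols) != mat.shape[0]:
        raise FormatError(
            f"matrix header declares {mat.shape[0]} genes but features file has "
            f"{len(gene_symbols)} rows"
        )
    if len(cell_barcodes) != mat.shape[1]:
        raise FormatError(
            f"matrix header declares {mat.shape[1]} cells but barcodes file has "
            f"{len(cell_barcodes)} rows"
        )
    return CountMatrix(mat.tocsr(), _deduplicate(gene_symbols), cell_barcodes)


def write_mtx_triplet(m: CountMatrix, dir_path: str | Path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(m.values))
    (dir_path / "barcodes.tsv").write_text("\n".join(map(str, m.cell_ids)) + "\n")
    (dir_path / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_ids)
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (name, description, member genes...)."""
    sets: dict[str, list[str]] = {}
    with _open_maybe_gzip(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in parts[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(gs: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gs.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Cell metadata
# ---------------------------------------------------------------------------

def validate_cell_meta(meta: pd.DataFrame, matrix: CountMatrix) -> pd.DataFrame:
    """Check a metadata frame against a matrix; returns meta ordered like the matrix."""
    for col in META_REQUIRED_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise FormatError(f"duplicate metadata rows for cells {dups[:5]}")
    meta = meta.set_index("cell_id", drop=False)
    matrix_cells = list(matrix.cell_ids)
    missing = [c for c in matrix_cells if c not in meta.index]
    if missing:
        raise FormatError(f"cells missing from metadata: {missing[:5]}")
    extra = [c for c in meta.index if c not in set(matrix_cells)]
    if extra:
        raise FormatError(f"metadata rows for unknown cells: {extra[:5]}")
    levels = sorted(set(meta["condition"].astype(str)))
    if len(levels) != 2:
        raise FormatError(
            f"condition must have exactly 2 levels, found {len(levels)}: {levels}"
        )
    return meta.loc[matrix_cells]


def read_cell_meta(path: str | Path, matrix: CountMatrix) -> pd.DataFrame:
    """Read a per-cell metadata TSV and validate it against the matrix."""
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return validate_cell_meta(meta, matrix)


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------

def read_bulk_cohort(expr_path: str | Path, clinical_path: str | Path) -> BulkCohort:
    """Read samples x genes log2 expression plus a clinical covariate table."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    clinical = pd.read_csv(clinical_path, sep="\t", index_col=0)
    clinical.index = clinical.index.astype(str)
    expr.index = expr.index.astype(str)
    try:
        clinical = clinical.loc[expr.index]
    except KeyError as exc:
        raise FormatError(f"clinical table missing samples present in expression: {exc}")
    return BulkCohort(expr=expr, clinical=clinical)


def write_bulk_cohort(cohort: BulkCohort, expr_path: str | Path, clinical_path: str | Path) -> None:
    cohort.expr.to_csv(expr_path, sep="\t", index_label="sample")
    cohort.clinical.to_csv(clinical_path, sep="\t", index_label="sample")
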