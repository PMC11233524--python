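"""Per-cell quality statistics and threshold filtering.

Defaults (min_genes=200, min_umi=500, max_mito_frac=0.2) are conventional
droplet-QC cut-offs; all are overridable. No algorithmic doublet detection is
attempted — an optional max_genes cap stands in for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class QcThresholds:
    min_genes: int = 200
    max_genes: int | None = None
    min_umi: int = 500
    max_mito_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.max_genes is not None and self.max_genes < self.min_genes:
            raise ValueError("max_genes must be >= min_genes")
        if not 0 < self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must be in (0, 1]")
        if self.min_genes < 0 or self.min_umi < 0:
            raise ValueError("minimum thresholds must be non-negative")


def compute_cell_qc(m: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell n_umi, n_genes and mitochondrial count fraction.

    mito_frac is 0 for all-zero cells and when no gene id starts with
    ``mito_prefix``.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("count matrix is empty")
    csc = m.values.tocsc()
    n_umi = np.asarray(csc.sum(axis=0)).ravel()
    n_genes = np.diff(csc.indptr)  # nonzeros per cell column
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in m.gene_ids])
    if mito_mask.any():
        mito_counts = np.asarray(csc[mito_mask, :].sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_counts / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {"n_umi": n_umi.astype(int), "n_genes": n_genes.astype(int), "mito_frac": mito_frac},
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def filter_cells(
    m: CountMatrix, meta: pd.DataFrame, thr: QcThresholds
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Keep cells passing every threshold; report per-criterion removals.

    ``meta`` must carry the qc columns from :func:`compute_cell_qc` (indexed by
    cell id, one row per matrix cell). A cell failing several criteria counts
    once under each and once in ``unique_removed``. The gene set is unchanged.
    """
    for col in ("n_umi", "n_genes", "mito_frac"):
        if col not in meta.columns:
            raise ValueError(f"qc column {col!r} missing; run compute_cell_qc first")
    meta = meta.loc[list(m.cell_ids)]
    fail_min_genes = meta["n_genes"].to_numpy() < thr.min_genes
    fail_max_genes = (
        meta["n_genes"].to_numpy() > thr.max_genes
        if thr.max_genes is not None
        else np.zeros(m.n_cells, dtype=bool)
    )
    fail_min_umi = meta["n_umi"].to_numpy() < thr.min_umi
    fail_mito = meta["mito_frac"].to_numpy() > thr.max_mito_frac
    fail_any = fail_min_genes | fail_max_genes | fail_min_umi | fail_mito
    keep = ~fail_any
    if not keep.any():
        raise ValueError(
            "no cells survive QC filtering; review thresholds "
            f"(min_genes={thr.min_genes}, min_umi={thr.min_umi}, "
            f"max_mito_frac={thr.max_mito_frac})"
        )
    report = {
        "n_before": int(m.n_cells),
        "n_after": int(keep.sum()),
        "min_genes": int(fail_min_genes.sum()),
        "max_genes": int(fail_max_genes.sum()),
        "min_umi": int(fail_min_umi.sum()),
        "max_mito_frac": int(fail_mito.sum()),
        "unique_removed": int(fail_any.sum()),
    }
    filtered = CountMatrix(
        m.values[:, keep].tocsr(), m.gene_ids, np.asarray(m.cell_ids)[keep]
    )
    return filtered, meta.loc[keep].copy(), report
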