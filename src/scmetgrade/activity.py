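"""Cell-type-resolved metabolic pathway activity with permutation significance.

The statistic: within one condition, each gene's mean normalized expression is
computed per cell type (E[g, j]) and divided by its average across cell types
to give a relative expression r[g, j] whose row mean is 1 by construction. A
pathway's activity in cell type j is the weighted mean of r[g, j] over its
member genes, weighting each gene by the reciprocal of the number of supplied
pathways that contain it, after excluding per-cell-type outliers
(r > Q3 + 3*IQR over all defined genes in that cell type). Activity 1 means
average metabolic activity; significance comes from re-computing the score
under random permutations of the cell-type labels.

Normalization is linear counts-per-10k: the score is a ratio of means, so
only library-size correction is needed and a log transform would distort it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSetCollection

DEFAULT_MIN_CELLS = 10
DEFAULT_TRIM_IQR_FACTOR = 3.0


@dataclass
class NormalizedMatrix:
    """Counts scaled so every non-empty cell sums to ``scale`` (linear, no log)."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale: float


@dataclass
class GroupMeans:
    """E[g, j]: mean normalized expression of gene g over cells of type j."""

    E: np.ndarray
    gene_ids: np.ndarray
    cell_types: list[str]
    n_cells_per_type: np.ndarray
    condition: str


@dataclass
class RelativeExpression:
    """r[g, j] = E[g, j] / mean_k E[g, k]; genes with zero mean are undefined."""

    r: np.ndarray
    defined: np.ndarray
    gene_ids: np.ndarray
    cell_types: list[str]
    condition: str


@dataclass
class ActivityTable:
    """Pathway x cell-type activity scores with optional permutation p-values."""

    A: pd.DataFrame
    n_genes_used: pd.DataFrame
    condition: str
    pvals: pd.DataFrame | None = None
    n_perm: int = 0

    def to_tidy(self) -> pd.DataFrame:
        out = self.A.stack(future_stack=True).rename("activity").reset_index()
        out.columns = ["pathway", "cell_type", "activity"]
        out["n_genes_used"] = self.n_genes_used.stack(future_stack=True).to_numpy()
        if self.pvals is not None:
            out["pval"] = self.pvals.stack(future_stack=True).to_numpy()
        out.insert(0, "condition", self.condition)
        return out


def normalize_counts(m: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Scale each cell to a constant total; all-zero cells stay zero."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    csc = m.values.tocsc().astype(float)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    factors = np.where(totals > 0, scale / np.maximum(totals, 1), 0.0)
    values = (csc @ sp.diags(factors)).tocsr()
    return NormalizedMatrix(values, m.gene_ids, m.cell_ids, scale)


def _condition_subset(nm: NormalizedMatrix, meta: pd.DataFrame, condition: str):
    meta = meta.loc[list(nm.cell_ids)]
    conditions = meta["condition"].astype(str)
    if condition not in set(conditions):
        raise ValueError(f"condition {condition!r} absent from metadata")
    mask = (conditions == condition).to_numpy()
    return nm.values[:, mask], meta.loc[mask]


def _type_codes(meta_sub: pd.DataFrame, min_cells: int) -> tuple[np.ndarray, list[str], np.ndarray]:
    counts = meta_sub["cell_type"].value_counts()
    kept = sorted(counts.index[counts >= min_cells])
    dropped = sorted(counts.index[counts < min_cells])
    if dropped:
        warnings.warn(
            f"dropping cell types with < {min_cells} cells: {dropped}", stacklevel=3
        )
    if not kept:
        raise ValueError("no cell type retains enough cells for scoring")
    keep_mask = meta_sub["cell_type"].isin(kept).to_numpy()
    codes = pd.Categorical(
        meta_sub.loc[keep_mask, "cell_type"], categories=kept
    ).codes.astype(np.int64)
    return codes, kept, keep_mask


def _group_means_from_codes(x_dense: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    onehot = np.zeros((x_dense.shape[1], k))
    onehot[np.arange(codes.size), codes] = 1.0
    sums = x_dense @ onehot
    return sums / onehot.sum(axis=0)


def group_mean_expression(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    condition: str,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> GroupMeans:
    """Arithmetic per-cell-type means of normalized expression in one condition."""
    x, meta_sub = _condition_subset(nm, meta, condition)
    codes, kept, keep_mask = _type_codes(meta_sub, min_cells)
    x_dense = np.asarray(x[:, keep_mask].todense(), dtype=float)
    E = _group_means_from_codes(x_dense, codes, len(kept))
    counts = np.bincount(codes, minlength=len(kept))
    return GroupMeans(E, nm.gene_ids, kept, counts, condition)


def relative_expression(gm: GroupMeans) -> RelativeExpression:
    """Divide each gene's cell-type means by their average across cell types."""
    if len(gm.cell_types) < 2:
        raise ValueError("relative expression needs at least 2 cell types")
    r, defined = _relative_from_E(gm.E)
    return RelativeExpression(r, defined, gm.gene_ids, gm.cell_types, gm.condition)


def _relative_from_E(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    row_mean = E.mean(axis=1)
    defined = row_mean > 0
    r = np.zeros_like(E)
    r[defined] = E[defined] / row_mean[defined, None]
    return r, defined


def pathway_weights(gs: GeneSetCollection) -> dict[str, float]:
    """w_g = 1 / (number of supplied pathways containing g)."""
    return {g: 1.0 / c for g, c in gs.membership_counts().items()}


def _membership_matrices(
    gs: GeneSetCollection, gene_ids: np.ndarray
) -> tuple[sp.csr_matrix, sp.csr_matrix, list[str]]:
    """(weighted, binary) pathway x gene membership matrices on the matrix genes."""
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    weights = pathway_weights(gs)
    rows, cols, w_data = [], [], []
    names = list(gs.sets)
    for p_idx, (name, genes) in enumerate(gs.sets.items()):
        for g in genes:
            i = gene_index.get(g)
            if i is not None:
                rows.append(p_idx)
                cols.append(i)
                w_data.append(weights[g])
    shape = (len(names), len(gene_ids))
    weighted = sp.csr_matrix((w_data, (rows, cols)), shape=shape)
    binary = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=shape)
    return weighted, binary, names


def _scores_from_r(
    r: np.ndarray,
    defined: np.ndarray,
    weighted: sp.csr_matrix,
    binary: sp.csr_matrix,
    trim: bool,
    trim_iqr_factor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate relative expression into pathway x cell-type activity."""
    usable = np.repeat(defined[:, None], r.shape[1], axis=1)
    if trim and defined.any():
        r_def = r[defined]
        q1 = np.percentile(r_def, 25, axis=0)
        q3 = np.percentile(r_def, 75, axis=0)
        thr = q3 + trim_iqr_factor * (q3 - q1)
        usable &= r <= thr[None, :]
    u = usable.astype(float)
    num = weighted @ (r * u)
    den = weighted @ u
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    n_used = np.asarray((binary @ u), dtype=int)
    return A, n_used


def pathway_activity(
    re_: RelativeExpression,
    gs: GeneSetCollection,
    trim: bool = True,
    trim_iqr_factor: float = DEFAULT_TRIM_IQR_FACTOR,
) -> ActivityTable:
    """Weighted-mean pathway activity from relative expression (no p-values)."""
    weighted, binary, names = _membership_matrices(gs, re_.gene_ids)
    covered = np.asarray(binary.sum(axis=1)).ravel()
    if not (covered > 0).any():
        raise ValueError("no pathway gene present in the matrix")
    empty = [names[i] for i in np.nonzero(covered == 0)[0]]
    if empty:
        warnings.warn(f"pathways with no genes in the matrix: {empty}", stacklevel=2)
    A, n_used = _scores_from_r(re_.r, re_.defined, weighted, binary, trim, trim_iqr_factor)
    cols = re_.cell_types
    return ActivityTable(
        A=pd.DataFrame(A, index=names, columns=cols),
        n_genes_used=pd.DataFrame(n_used, index=names, columns=cols),
        condition=re_.condition,
    )


def compute_activity(
    m: CountMatrix,
    meta: pd.DataFrame,
    gs: GeneSetCollection,
    condition: str,
    scale: float = 1e4,
    trim: bool = True,
    trim_iqr_factor: float = DEFAULT_TRIM_IQR_FACTOR,
    min_cells: int = DEFAULT_MIN_CELLS,
    n_perm: int = 0,
    seed: int | None = None,
) -> ActivityTable:
    """End-to-end activity scoring for one condition.

    With ``n_perm`` > 0, two-sided permutation p-values around the neutral
    value 1 are attached (cell-type labels shuffled within the condition, the
    full score recomputed per permutation, +1 small-sample correction so p is
    never 0).
    """
    nm = normalize_counts(m, scale)
    x, meta_sub = _condition_subset(nm, meta, condition)
    codes, kept, keep_mask = _type_codes(meta_sub, min_cells)
    x_dense = np.asarray(x[:, keep_mask].todense(), dtype=float)
    weighted, binary, names = _membership_matrices(gs, nm.gene_ids)
    if not np.asarray(binary.sum(axis=1)).ravel().any():
        raise ValueError("no pathway gene present in the matrix")
    k = len(kept)

    def score(codes_vec: np.ndarray) -> np.ndarray:
        E = _group_means_from_codes(x_dense, codes_vec, k)
        r, defined = _relative_from_E(E)
        A, n_used = _scores_from_r(r, defined, weighted, binary, trim, trim_iqr_factor)
        return A, n_used

    A_obs, n_used = score(codes)
    table = ActivityTable(
        A=pd.DataFrame(A_obs, index=names, columns=kept),
        n_genes_used=pd.DataFrame(n_used, index=names, columns=kept),
        condition=condition,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        dev_obs = np.abs(A_obs - 1.0)
        exceed = np.zeros_like(A_obs)
        for _ in range(n_perm):
            A_perm, _ = score(rng.permutation(codes))
            dev = np.abs(A_perm - 1.0)
            exceed += np.where(np.isnan(dev), 0.0, (dev >= dev_obs).astype(float))
        pvals = (1.0 + exceed) / (n_perm + 1.0)
        pvals = np.where(np.isnan(A_obs), np.nan, pvals)
        table.pvals = pd.DataFrame(pvals, index=names, columns=kept)
        table.n_perm = n_perm
    return table


def permutation_pvalues(
    m: CountMatrix,
    meta: pd.DataFrame,
    gs: GeneSetCollection,
    condition: str,
    n_perm: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> ActivityTable:
    """Activity table with permutation p-values; ``n_perm`` must be >= 1."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return compute_activity(
        m, meta, gs, condition, n_perm=n_perm, seed=seed, **kwargs
    )
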