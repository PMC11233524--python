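"""Two-condition differential expression, single-cell and bulk.

Single-cell testing is a per-gene two-sided Wilcoxon rank-sum on normalized
expression between the two conditions' cells of one cell type; bulk testing
is a per-gene Welch t-test on log2 expression. The pass rule follows the
raw-p criterion p < 0.05 and |log2 fold change| > 0.58 (a 1.5-fold change);
both inequalities are strict. BH-adjusted p-values are always reported
alongside but do not enter the pass rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .activity import NormalizedMatrix
from .io import BulkCohort, GeneSetCollection

DEFAULT_P_CUT = 0.05
DEFAULT_LFC_CUT = 0.58
EXACT_MAX_N = 30  # exact Mann-Whitney below this per-group size (tie-free data only)

RECORD_COLUMNS = [
    "gene",
    "context",
    "log2fc",
    "pval",
    "padj",
    "direction",
    "passes",
    "zero_variance",
]


def _finish_records(
    genes, context, log2fc, pval, zero_var, p_cut, lfc_cut
) -> pd.DataFrame:
    pval = np.where(np.isnan(pval), 1.0, pval)
    padj = multipletests(pval, method="fdr_bh")[1]
    passes = (pval < p_cut) & (np.abs(log2fc) > lfc_cut)
    return pd.DataFrame(
        {
            "gene": genes,
            "context": context,
            "log2fc": log2fc,
            "pval": pval,
            "padj": padj,
            "direction": np.where(log2fc > 0, "up", "down"),
            "passes": passes,
            "zero_variance": zero_var,
        },
        columns=RECORD_COLUMNS,
    )


def sc_de_test(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    conditions: tuple[str, str] = ("HG", "LG"),
    p_cut: float = DEFAULT_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE within one cell type, condition A over B.

    log2fc = log2((mean_A + 1) / (mean_B + 1)) on normalized values. Genes
    constant across both groups get p = 1 and are flagged zero_variance.
    """
    meta = meta.loc[list(nm.cell_ids)]
    cond = meta["condition"].astype(str).to_numpy()
    ct = meta["cell_type"].astype(str).to_numpy()
    groups = []
    for level in conditions:
        mask = (ct == cell_type) & (cond == level)
        if mask.sum() < min_cells:
            raise ValueError(
                f"cell type {cell_type!r} has {int(mask.sum())} cells in condition "
                f"{level!r}; need >= {min_cells}"
            )
        groups.append(np.asarray(nm.values[:, mask].todense(), dtype=float))
    x, y = groups
    mean_a, mean_b = x.mean(axis=1), y.mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    zero_var = np.array(
        [np.ptp(np.concatenate([x[i], y[i]])) == 0 for i in range(x.shape[0])]
    )

    method = "exact" if max(x.shape[1], y.shape[1]) < EXACT_MAX_N else "asymptotic"
    if method == "exact":
        # scipy's exact distribution assumes no ties; fall back when tied
        has_ties = any(
            np.unique(np.concatenate([x[i], y[i]])).size < x.shape[1] + y.shape[1]
            for i in range(x.shape[0])
        )
        if has_ties:
            method = "asymptotic"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = st.mannwhitneyu(x, y, axis=1, alternative="two-sided", method=method)
    pval = np.asarray(res.pvalue, dtype=float)
    pval[zero_var] = 1.0
    return _finish_records(
        list(nm.gene_ids), cell_type, log2fc, pval, zero_var, p_cut, lfc_cut
    )


def _resolve_level(clinical_col: pd.Series, level_spec: str) -> np.ndarray:
    """A level spec may union several factor levels with '+', e.g. 'II+III'."""
    members = set(level_spec.split("+"))
    return clinical_col.astype(str).isin(members).to_numpy()


def bulk_de_test(
    cohort: BulkCohort,
    group_factor: str,
    levels: tuple[str, str],
    p_cut: float = DEFAULT_P_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 expression, level A over level B."""
    if group_factor not in cohort.clinical:
        raise ValueError(f"clinical factor {group_factor!r} not present")
    col = cohort.clinical[group_factor]
    mask_a, mask_b = (_resolve_level(col, lv) for lv in levels)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError(
            f"each level needs >= 3 samples; got {int(mask_a.sum())} and {int(mask_b.sum())}"
        )
    xa = cohort.expr.loc[mask_a].to_numpy()
    xb = cohort.expr.loc[mask_b].to_numpy()
    log2fc = xa.mean(axis=0) - xb.mean(axis=0)
    zero_var = (xa.std(axis=0) == 0) & (xb.std(axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = st.ttest_ind(xa, xb, axis=0, equal_var=False)
    pval = np.asarray(res.pvalue, dtype=float)
    pval[zero_var] = 1.0
    return _finish_records(
        list(cohort.expr.columns),
        f"bulk:{levels[0]}_vs_{levels[1]}",
        log2fc,
        pval,
        zero_var,
        p_cut,
        lfc_cut,
    )


def restrict_to_universe(records: pd.DataFrame, gs: GeneSetCollection) -> pd.DataFrame:
    """Keep records whose gene belongs to the gene-set universe."""
    universe = gs.universe
    return records.loc[records["gene"].isin(universe)].reset_index(drop=True)


def cross_validate(sc: pd.DataFrame, bulk: pd.DataFrame) -> pd.DataFrame:
    """Intersect passing single-cell and bulk DEGs with direction agreement.

    One output row per (gene, single-cell context) whose gene also passes in
    the bulk contrast with the same direction.
    """
    sc_pass = sc.loc[sc["passes"]]
    bulk_pass = bulk.loc[bulk["passes"], ["gene", "log2fc", "direction"]].rename(
        columns={"log2fc": "bulk_log2fc", "direction": "bulk_direction"}
    )
    merged = sc_pass.merge(bulk_pass, on="gene", how="inner")
    merged = merged.loc[merged["direction"] == merged["bulk_direction"]]
    out = merged[["gene", "context", "log2fc", "bulk_log2fc", "direction"]].rename(
        columns={"context": "cell_type", "log2fc": "sc_log2fc"}
    )
    return out.sort_values(["gene", "cell_type"]).reset_index(drop=True)
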