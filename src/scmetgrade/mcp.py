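"""Metabolically changed pathway (MCP) calling between two conditions.

A (pathway, cell type) pair is a lenient MCP when its activity straddles the
neutral value: HG-activity > 1 and LG-activity < 1, or the reverse. Strict
MCPs additionally require the HG/LG activity ratio to exceed 1.1 or fall
below 0.9. Activities exactly 1.0 fail the strict inequalities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .activity import ActivityTable

RECORD_COLUMNS = [
    "pathway",
    "cell_type",
    "a_hg",
    "a_lg",
    "ratio",
    "direction",
    "klass",
    "infinite_ratio",
]


def call_mcps(
    hg: ActivityTable,
    lg: ActivityTable,
    strict_hi: float = 1.1,
    strict_lo: float = 0.9,
    p_gate: float | None = None,
) -> pd.DataFrame:
    """Call lenient and strict MCPs from per-condition activity tables.

    Every (pathway, cell type) with a non-missing activity in both conditions
    is evaluated; cell types present in only one condition are skipped. With
    ``p_gate`` set, both conditions' permutation p-values must be below it.
    Records are sorted by |log(ratio)| descending; an HG activity over a zero
    LG activity yields ratio +inf and is flagged.
    """
    if not strict_lo < 1.0 < strict_hi:
        raise ValueError("need strict_lo < 1 < strict_hi")
    pathways = hg.A.index.intersection(lg.A.index)
    cell_types = hg.A.columns.intersection(lg.A.columns)
    if p_gate is not None and (hg.pvals is None or lg.pvals is None):
        raise ValueError("p_gate requires permutation p-values on both tables")

    rows = []
    for pathway in pathways:
        for ct in cell_types:
            a_hg = hg.A.at[pathway, ct]
            a_lg = lg.A.at[pathway, ct]
            if np.isnan(a_hg) or np.isnan(a_lg):
                continue
            if a_hg == 0 and a_lg == 0:
                warnings.warn(
                    f"skipping ({pathway}, {ct}): zero activity in both conditions",
                    stacklevel=2,
                )
                continue
            if p_gate is not None:
                if not (
                    hg.pvals.at[pathway, ct] < p_gate and lg.pvals.at[pathway, ct] < p_gate
                ):
                    continue
            lenient = (a_hg > 1 and a_lg < 1) or (a_hg < 1 and a_lg > 1)
            if not lenient:
                continue
            infinite = a_lg == 0
            ratio = np.inf if infinite else a_hg / a_lg
            strict = ratio > strict_hi or ratio < strict_lo
            rows.append(
                {
                    "pathway": pathway,
                    "cell_type": ct,
                    "a_hg": a_hg,
                    "a_lg": a_lg,
                    "ratio": ratio,
                    "direction": "HG_up" if a_hg > a_lg else "HG_down",
                    "klass": "strict" if strict else "lenient",
                    "infinite_ratio": infinite,
                }
            )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if len(records):
        with np.errstate(divide="ignore"):
            order = np.abs(np.log(records["ratio"].to_numpy()))
        records = (
            records.assign(_order=order)
            .sort_values("_order", ascending=False, kind="mergesort")
            .drop(columns="_order")
            .reset_index(drop=True)
        )
    return records


def summarize_mcps(records: pd.DataFrame, share_threshold: int = 5) -> dict:
    """Per-cell-type and per-pathway tallies of MCP records.

    ``shared_pathways`` lists pathways affected in strictly more than
    ``share_threshold`` cell types. An empty record list yields zero counts.
    """
    if records.empty:
        return {
            "n_records": 0,
            "per_cell_type": {},
            "per_pathway": {},
            "shared_pathways": [],
            "frac_hg_up_per_cell_type": {},
        }
    per_ct = records.groupby("cell_type").size()
    per_pw = records.groupby("pathway")["cell_type"].nunique()
    shared = per_pw[per_pw > share_threshold]
    frac_up = (
        records.assign(up=records["direction"] == "HG_up")
        .groupby("cell_type")["up"]
        .mean()
    )
    return {
        "n_records": int(len(records)),
        "per_cell_type": per_ct.to_dict(),
        "per_pathway": per_pw.to_dict(),
        "shared_pathways": sorted(shared.index.tolist()),
        "frac_hg_up_per_cell_type": {k: float(v) for k, v in frac_up.items()},
    }
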