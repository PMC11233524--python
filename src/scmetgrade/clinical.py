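"""Bulk-cohort validation: sample-level gene-set scoring, clinical-factor
association tests, and prognostic screening.

The per-sample pathway score is a rank-based single-sample enrichment
statistic: genes are ordered by expression within the sample and the score is
the mean difference between the weighted running CDF of member genes and that
of non-member genes, both weighted by rank^alpha. Weighting both sides
identically centres the null (random gene sets) at zero; it is a documented
stand-in for GSVA, and the downstream stages accept any externally computed
per-sample score table. Being rank-based, scores are invariant to monotone
per-sample transforms of expression.

Survival machinery (Kaplan-Meier, log-rank, Cox proportional hazards with
Breslow tie handling) is delegated to lifelines; covariates are standardized
to unit variance before Cox fits so hazard ratios are per-SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .io import BulkCohort, GeneSetCollection

DEFAULT_ALPHA = 0.25


@dataclass
class SurvivalResult:
    feature: str
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    logrank_p: float
    n: int
    direction: str  # unfavorable iff hr > 1


# ---------------------------------------------------------------------------
# Sample-level gene-set scoring
# ---------------------------------------------------------------------------

def score_samples(
    cohort: BulkCohort | pd.DataFrame,
    gs: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Single-sample enrichment scores, samples x pathways.

    Pathways with no measured gene get a missing column with a warning.
    """
    expr = cohort.expr if isinstance(cohort, BulkCohort) else cohort
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    genes = list(expr.columns)
    gene_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    members: dict[str, np.ndarray] = {}
    for name, gset in gs.sets.items():
        idx = np.array([gene_index[g] for g in gset if g in gene_index], dtype=int)
        if idx.size == 0:
            warnings.warn(f"pathway {name!r} has no measured genes", stacklevel=2)
        members[name] = idx

    values = expr.to_numpy(dtype=float)
    scores = np.full((values.shape[0], len(gs.sets)), np.nan)
    for s in range(values.shape[0]):
        ranks = st.rankdata(values[s])  # ascending; ties get average rank
        order = np.lexsort((np.arange(n), -ranks))  # descending, index-stable
        w = ranks[order] ** alpha
        member_mask = np.zeros(n, dtype=bool)
        for p_idx, idx in enumerate(members.values()):
            if idx.size == 0:
                continue
            member_mask[:] = False
            member_mask[idx] = True
            m_ord = member_mask[order]
            w_in = np.where(m_ord, w, 0.0)
            w_out = np.where(m_ord, 0.0, w)
            p_in = np.cumsum(w_in)
            p_out = np.cumsum(w_out)
            tot_out = p_out[-1]
            if tot_out == 0:
                continue
            p_in /= p_in[-1]
            p_out /= tot_out
            scores[s, p_idx] = float(np.mean(p_in - p_out))
    return pd.DataFrame(scores, index=expr.index, columns=list(gs.sets))


# ---------------------------------------------------------------------------
# Clinical-factor association
# ---------------------------------------------------------------------------

def group_tests(values: pd.Series, factor: pd.Series) -> dict:
    """Welch t-test (2 levels) or one-way ANOVA (>2) of values across a factor.

    Levels with fewer than 2 samples are dropped with a warning.
    """
    df = pd.DataFrame({"value": values, "factor": factor}).dropna()
    counts = df["factor"].value_counts()
    small = counts.index[counts < 2].tolist()
    if small:
        warnings.warn(f"dropping factor levels with < 2 samples: {small}", stacklevel=2)
        df = df.loc[~df["factor"].isin(small)]
    levels = sorted(df["factor"].unique())
    if len(levels) < 2:
        raise ValueError("fewer than 2 usable factor levels")
    groups = [df.loc[df["factor"] == lv, "value"].to_numpy() for lv in levels]
    if len(levels) == 2:
        stat, p = st.ttest_ind(groups[0], groups[1], equal_var=False)
        test = "welch_t"
    else:
        stat, p = st.f_oneway(*groups)
        test = "anova"
    return {
        "test": test,
        "statistic": float(stat),
        "pval": float(p),
        "levels": levels,
        "level_means": {lv: float(g.mean()) for lv, g in zip(levels, groups)},
    }


def associate_panel(
    scores: pd.DataFrame, clinical: pd.DataFrame, factors: list[str]
) -> pd.DataFrame:
    """group_tests for every (feature, factor) with BH adjustment per factor."""
    rows = []
    for factor in factors:
        if factor not in clinical:
            warnings.warn(f"clinical factor {factor!r} absent; skipped", stacklevel=2)
            continue
        for feature in scores.columns:
            vals = scores[feature]
            if vals.dropna().empty:
                continue
            try:
                res = group_tests(vals, clinical[factor])
            except ValueError:
                continue
            rows.append(
                {
                    "feature": feature,
                    "factor": factor,
                    "test": res["test"],
                    "statistic": res["statistic"],
                    "pval": res["pval"],
                }
            )
    out = pd.DataFrame(rows, columns=["feature", "factor", "test", "statistic", "pval"])
    if len(out):
        out["padj"] = np.nan
        for factor, idx in out.groupby("factor").groups.items():
            out.loc[idx, "padj"] = multipletests(out.loc[idx, "pval"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def km_median_split(
    values: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, float, dict]:
    """Median-split Kaplan-Meier with a two-group log-rank test.

    Ties at the median go to the low group (so for odd n the low group gets
    the extra sample). Returns (labels, logrank p, per-group KM curves).
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(values) < 10:
        raise ValueError("need at least 10 samples with survival data")
    median = np.median(values)
    low = values <= median
    if low.all() or not low.any():
        raise ValueError("median split impossible: all values on one side")
    labels = np.where(low, "low", "high")
    res = logrank_test(time[low], time[~low], event[low], event[~low])
    curves = {}
    for name, mask in (("low", low), ("high", ~low)):
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask])
        sf = km.survival_function_
        curves[name] = {
            "time": sf.index.to_numpy().tolist(),
            "survival": sf.iloc[:, 0].to_numpy().tolist(),
        }
    return labels, float(res.p_value), curves


def cox_univariate(
    values: np.ndarray, time: np.ndarray, event: np.ndarray, feature: str = "feature"
) -> SurvivalResult:
    """Univariate Cox PH (Breslow ties) on a covariate standardized to unit SD."""
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events observed")
    if n_events < 10:
        raise ValueError(f"need >= 10 events for a stable fit, got {n_events}")
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate covariate: zero variance")
    z = (values - values.mean()) / sd
    df = pd.DataFrame({"z": z, "time": time, "event": event})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit failed for {feature!r}: {exc}") from exc
    row = cph.summary.loc["z"]
    hr = float(np.exp(row["coef"]))
    return SurvivalResult(
        feature=feature,
        hr=hr,
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        wald_p=float(row["p"]),
        logrank_p=np.nan,
        n=len(values),
        direction="unfavorable" if hr > 1 else "favorable",
    )


def prognostic_screen(features: pd.DataFrame, cohort: BulkCohort) -> pd.DataFrame:
    """Cox + median-split log-rank per feature column, BH-adjusted across features.

    ``features`` is samples x features (pathway scores or a gene expression
    panel) aligned to the cohort's samples. Degenerate features are skipped
    with a warning and reported as NaN rows.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    clin = cohort.clinical
    time = pd.to_numeric(clin["os_time"]).to_numpy()
    event = clin["os_event"].astype(int).to_numpy()
    rows = []
    for feature in features.columns:
        vals = features[feature].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        base = {"feature": feature, "n": int(ok.sum())}
        try:
            res = cox_univariate(vals[ok], time[ok], event[ok], feature=feature)
            _, lr_p, _ = km_median_split(vals[ok], time[ok], event[ok])
            rows.append(
                {
                    **base,
                    "hr": res.hr,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "wald_p": res.wald_p,
                    "logrank_p": lr_p,
                    "direction": res.direction,
                }
            )
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"feature {feature!r} skipped: {exc}", stacklevel=2)
            rows.append(
                {
                    **base,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "wald_p": np.nan,
                    "logrank_p": np.nan,
                    "direction": "NA",
                }
            )
    out = pd.DataFrame(rows)
    for col in ("wald_p", "logrank_p"):
        mask = out[col].notna()
        out[f"{col.split('_')[0]}_padj"] = np.nan
        if mask.any():
            out.loc[mask, f"{col.split('_')[0]}_padj"] = multipletests(
                out.loc[mask, col], method="fdr_bh"
            )[1]
    return out


def intersect_screens(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    alpha: float = 0.05,
    p_col: str = "logrank_p",
) -> pd.DataFrame:
    """Features significant (p_col < alpha) in both cohorts, with direction check."""
    sig_a = res_a.loc[res_a[p_col] < alpha].set_index("feature")
    sig_b = res_b.loc[res_b[p_col] < alpha].set_index("feature")
    common = sig_a.index.intersection(sig_b.index)
    out = pd.DataFrame(
        {
            "feature": common,
            "hr_a": sig_a.loc[common, "hr"].to_numpy(),
            "hr_b": sig_b.loc[common, "hr"].to_numpy(),
            "direction_a": sig_a.loc[common, "direction"].to_numpy(),
            "direction_b": sig_b.loc[common, "direction"].to_numpy(),
        }
    )
    out["direction_agrees"] = out["direction_a"] == out["direction_b"]
    return out.sort_values("feature").reset_index(drop=True)
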