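"""End-to-end orchestration: QC -> per-condition activity -> MCP -> DE ->
cross-validation -> clinical validation, from a single config.

One global seed is expanded into independent per-stage streams
(numpy SeedSequence.spawn) so changing one stage's permutation count does not
perturb another stage's draws. All tables are TSV with fixed column order and
6-significant-digit floats; the manifest records parameters, seed, package
version and SHA-256 checksums of every input and output, so byte-identical
re-runs are checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import __version__
from .activity import compute_activity
from .clinical import associate_panel, intersect_screens, prognostic_screen, score_samples
from .dge import bulk_de_test, cross_validate, restrict_to_universe, sc_de_test
from .io import (
    BulkCohort,
    CountMatrix,
    read_bulk_cohort,
    read_gmt,
    read_mtx_triplet,
    validate_cell_meta,
)
from .mcp import call_mcps, summarize_mcps
from .qc import QcThresholds, compute_cell_qc, filter_cells

log = logging.getLogger("scmetgrade")

DEFAULT_FACTORS = ["grade", "histology", "idh_status", "codel_1p19q", "prs_type"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; see from_file for the on-disk layout."""

    seed: int = 0
    sc: dict = field(default_factory=dict)  # mtx (dir or {cond: dir}), meta, gmt
    bulk: dict = field(default_factory=dict)  # cohorts {name: {expr, clinical}}, factor, levels
    qc: dict = field(default_factory=dict)
    activity: dict = field(default_factory=dict)  # scale, trim, n_perm, min_cells
    mcp: dict = field(default_factory=dict)  # strict_hi, strict_lo, p_gate
    dge: dict = field(default_factory=dict)  # p_cut, lfc_cut, min_cells
    clinical: dict = field(default_factory=dict)  # alpha, significance, factors, gene_panel

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_sc(self) -> None:
        for key in ("mtx", "meta", "gmt"):
            if key not in self.sc:
                raise ConfigError(f"sc stage requires sc.{key}")
        mtx = self.sc["mtx"]
        paths = list(mtx.values()) if isinstance(mtx, dict) else [mtx]
        for p in paths + [self.sc["meta"], self.sc["gmt"]]:
            if not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {p}")

    def validate_clinical(self) -> None:
        cohorts = self.bulk.get("cohorts", {})
        if not cohorts:
            raise ConfigError("clinical stage requires bulk.cohorts")
        if "gmt" not in self.sc and "gmt" not in self.bulk:
            raise ConfigError("clinical stage requires a gmt path (sc.gmt or bulk.gmt)")
        for name, spec in cohorts.items():
            for key in ("expr", "clinical"):
                if key not in spec:
                    raise ConfigError(f"cohort {name!r} missing {key!r} path")
                if not Path(spec[key]).exists():
                    raise ConfigError(f"configured path does not exist: {spec[key]}")

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("activity_a", "activity_b", "dge", "clinical")
        return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_sc_inputs(cfg: PipelineConfig):
    mtx = cfg.sc["mtx"]
    if isinstance(mtx, dict):
        parts = [read_mtx_triplet(p) for p in mtx.values()]
        genes = list(parts[0].gene_ids)
        for part in parts[1:]:
            if list(part.gene_ids) != genes:
                raise ConfigError("per-condition matrices must share an identical gene list")
        matrix = CountMatrix(
            sp.hstack([p.values for p in parts], format="csr"),
            genes,
            np.concatenate([p.cell_ids for p in parts]),
        )
    else:
        matrix = read_mtx_triplet(mtx)
    meta = pd.read_csv(cfg.sc["meta"], sep="\t", dtype={"cell_id": str})
    meta = validate_cell_meta(meta, matrix)
    gs = read_gmt(cfg.sc["gmt"])
    return matrix, meta, gs


def run_sc_stage(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """QC, per-condition activity, MCP calling and DE; returns the manifest."""
    cfg.validate_sc()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    matrix, meta, gs = _load_sc_inputs(cfg)
    inputs = {}
    mtx = cfg.sc["mtx"]
    for p in (list(mtx.values()) if isinstance(mtx, dict) else [mtx]):
        for f in sorted(Path(p).iterdir()):
            inputs[str(f)] = _sha256(f)
    for p in (cfg.sc["meta"], cfg.sc["gmt"]):
        inputs[str(p)] = _sha256(Path(p))

    qc_kwargs = dict(cfg.qc)
    mito_prefix = qc_kwargs.pop("mito_prefix", "MT-")
    thr = QcThresholds(**qc_kwargs)
    qc_stats = compute_cell_qc(matrix, mito_prefix=mito_prefix)
    meta = meta.join(qc_stats)
    matrix, meta, qc_report = filter_cells(matrix, meta, thr)
    log.info("QC kept %d/%d cells", qc_report["n_after"], qc_report["n_before"])

    conditions = sorted(set(meta["condition"].astype(str)))
    hg_label = cfg.mcp.get("hg_label", "HG" if "HG" in conditions else conditions[0])
    lg_label = cfg.mcp.get("lg_label", "LG" if "LG" in conditions else conditions[-1])

    act_kwargs = dict(cfg.activity)
    act_kwargs.setdefault("n_perm", 1000)
    tables = {}
    outputs: dict[str, Path] = {"qc_report.json": outdir / "qc_report.json"}
    (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=2, sort_keys=True))
    for cond, seed_key in ((hg_label, "activity_a"), (lg_label, "activity_b")):
        table = compute_activity(matrix, meta, gs, cond, seed=seeds[seed_key], **act_kwargs)
        tables[cond] = table
        path = outdir / f"activity_{cond}.tsv"
        _write_tsv(table.to_tidy(), path)
        outputs[path.name] = path

    mcp_kwargs = {k: v for k, v in cfg.mcp.items() if k in ("strict_hi", "strict_lo", "p_gate")}
    records = call_mcps(tables[hg_label], tables[lg_label], **mcp_kwargs)
    summary = summarize_mcps(records, share_threshold=cfg.mcp.get("share_threshold", 5))
    _write_tsv(records, outdir / "mcp_records.tsv")
    (outdir / "mcp_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["mcp_records.tsv"] = outdir / "mcp_records.tsv"
    outputs["mcp_summary.json"] = outdir / "mcp_summary.json"

    from .activity import normalize_counts

    dge_kwargs = dict(cfg.dge)
    min_cells = dge_kwargs.pop("min_cells", 10)
    nm = normalize_counts(matrix, scale=cfg.activity.get("scale", 1e4))
    counts = meta.groupby(["cell_type", "condition"]).size().unstack(fill_value=0)
    testable = [
        ct
        for ct in counts.index
        if {hg_label, lg_label} <= set(counts.columns)
        and counts.loc[ct, hg_label] >= min_cells
        and counts.loc[ct, lg_label] >= min_cells
    ]
    sc_records = []
    for ct in testable:
        rec = sc_de_test(
            nm, meta, ct, conditions=(hg_label, lg_label), min_cells=min_cells, **dge_kwargs
        )
        sc_records.append(restrict_to_universe(rec, gs))
    sc_all = (
        pd.concat(sc_records, ignore_index=True)
        if sc_records
        else pd.DataFrame(columns=["gene", "context", "log2fc", "pval", "padj",
                                   "direction", "passes", "zero_variance"])
    )
    _write_tsv(sc_all, outdir / "deg_sc.tsv")
    outputs["deg_sc.tsv"] = outdir / "deg_sc.tsv"

    cohorts = cfg.bulk.get("cohorts", {})
    if cohorts:
        name, spec = next(iter(cohorts.items()))
        cohort = read_bulk_cohort(spec["expr"], spec["clinical"])
        inputs[str(spec["expr"])] = _sha256(Path(spec["expr"]))
        inputs[str(spec["clinical"])] = _sha256(Path(spec["clinical"]))
        factor = cfg.bulk.get("factor", "grade")
        levels = tuple(cfg.bulk.get("levels", ["IV", "II+III"]))
        bulk_rec = restrict_to_universe(
            bulk_de_test(cohort, factor, levels, **dge_kwargs), gs
        )
        _write_tsv(bulk_rec, outdir / "deg_bulk.tsv")
        outputs["deg_bulk.tsv"] = outdir / "deg_bulk.tsv"
        cv = cross_validate(sc_all, bulk_rec)
        _write_tsv(cv, outdir / "cross_validation.tsv")
        outputs["cross_validation.tsv"] = outdir / "cross_validation.tsv"
    else:
        log.info("no bulk cohort configured; cross-validation skipped")

    manifest = _write_manifest(cfg, outdir, "sc", inputs, outputs)
    return manifest


def run_clinical_stage(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Sample scoring, clinical association and prognostic screening."""
    cfg.validate_clinical()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmt_path = cfg.bulk.get("gmt", cfg.sc.get("gmt"))
    gs = read_gmt(gmt_path)
    alpha = cfg.clinical.get("alpha", 0.25)
    significance = cfg.clinical.get("significance", 0.05)
    factors = cfg.clinical.get("factors", DEFAULT_FACTORS)
    gene_panel = cfg.clinical.get("gene_panel", [])

    inputs = {str(gmt_path): _sha256(Path(gmt_path))}
    outputs: dict[str, Path] = {}
    screens: dict[str, pd.DataFrame] = {}
    for name, spec in cfg.bulk["cohorts"].items():
        cohort = read_bulk_cohort(spec["expr"], spec["clinical"])
        inputs[str(spec["expr"])] = _sha256(Path(spec["expr"]))
        inputs[str(spec["clinical"])] = _sha256(Path(spec["clinical"]))
        scores = score_samples(cohort, gs, alpha=alpha)
        _write_tsv(scores, outdir / f"scores_{name}.tsv", index=True)
        assoc = associate_panel(scores, cohort.clinical, factors)
        _write_tsv(assoc, outdir / f"assoc_{name}.tsv")
        surv = prognostic_screen(scores, cohort)
        _write_tsv(surv, outdir / f"surv_pathways_{name}.tsv")
        screens[name] = surv
        for fname in (f"scores_{name}.tsv", f"assoc_{name}.tsv", f"surv_pathways_{name}.tsv"):
            outputs[fname] = outdir / fname
        if gene_panel:
            panel = cohort.expr[[g for g in gene_panel if g in cohort.expr.columns]]
            if panel.shape[1]:
                surv_genes = prognostic_screen(panel, cohort)
                _write_tsv(surv_genes, outdir / f"surv_genes_{name}.tsv")
                outputs[f"surv_genes_{name}.tsv"] = outdir / f"surv_genes_{name}.tsv"

    if len(screens) >= 2:
        names = list(screens)
        inter = intersect_screens(screens[names[0]], screens[names[1]], alpha=significance)
        (outdir / "intersection.json").write_text(
            json.dumps(
                {
                    "cohorts": names[:2],
                    "alpha": significance,
                    "features": inter.to_dict(orient="records"),
                },
                indent=2,
                sort_keys=True,
            )
        )
        outputs["intersection.json"] = outdir / "intersection.json"
    else:
        log.info("single cohort supplied; cross-cohort intersection omitted")

    manifest = _write_manifest(cfg, outdir, "clinical", inputs, outputs)
    return manifest


def _write_manifest(
    cfg: PipelineConfig, outdir: Path, stage: str, inputs: dict, outputs: dict[str, Path]
) -> dict:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "qc": cfg.qc,
            "activity": cfg.activity,
            "mcp": cfg.mcp,
            "dge": cfg.dge,
            "clinical": cfg.clinical,
        },
        "inputs": inputs,
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def run(cfg: PipelineConfig, outdir: str | Path, stage: str = "all") -> dict:
    """Run the requested stage(s); returns a dict of manifests."""
    manifests = {}
    if stage in ("sc", "all"):
        manifests["sc"] = run_sc_stage(cfg, outdir)
    if stage in ("clinical", "all"):
        manifests["clinical"] = run_clinical_stage(cfg, outdir)
    if not manifests:
        raise ConfigError(f"unknown stage {stage!r}; expected sc, clinical or all")
    return manifests
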