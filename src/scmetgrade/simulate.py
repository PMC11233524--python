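"""Synthetic single-cell and bulk cohorts with planted, recoverable structure.

The single-cell generator emulates droplet UMI data: negative-binomial counts
with a common dispersion, lognormal per-cell library-size factors sized so
that typical totals land in the several-thousand-UMI range reported for
droplet gliomas, a mitochondrial gene block carrying a configurable expected
fraction of each cell's counts (so QC has signal to act on), optional
multiplicative cell-type structure, and condition-specific fold shifts
planted on chosen (pathway, cell type) pairs.

The bulk generator emulates a glioma cohort: Gaussian log2 expression with
monotone per-grade shifts planted on chosen genes, and exponential survival
whose log hazard is linear in the standardized expression of chosen
prognostic genes, with independent uniform censoring calibrated to a target
censoring rate.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .io import BulkCohort, CountMatrix, GeneSetCollection

#: grade -> number of steps above grade II, used for planted monotone trends
GRADE_STEP = {"II": 0, "III": 1, "IV": 2}


@dataclass
class ScSimConfig:
    """Configuration of the single-cell UMI count generator.

    planted_shifts entries are (pathway, cell_type, condition, fold) with
    fold > 0; fold multiplies the negative-binomial mean of every member gene
    of the pathway in that cell type and condition only.
    """

    genesets: GeneSetCollection
    n_cell_types: int = 10
    cells_per_type_per_condition: int = 200
    n_genes: int = 2000
    planted_shifts: list[tuple[str, str, str, float]] = field(default_factory=list)
    conditions: tuple[str, str] = ("HG", "LG")
    cell_type_names: list[str] | None = None
    samples_per_condition: int = 2
    baseline_logmean_mu: float = 0.75
    baseline_logmean_sigma: float = 1.0
    cell_type_logsd: float = 0.5
    nb_dispersion: float = 2.0
    libsize_lognormal: tuple[float, float] = (0.0, 0.25)
    mito_gene_count: int = 13
    mito_frac_mean: float = 0.08
    mito_frac_logsd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_type_per_condition < 1:
            raise ValueError("cell type and cell counts must be positive")
        if self.cell_type_names is None:
            width = len(str(self.n_cell_types))
            self.cell_type_names = [f"CT{i + 1:0{width}d}" for i in range(self.n_cell_types)]
        if len(self.cell_type_names) != self.n_cell_types:
            raise ValueError("cell_type_names length must equal n_cell_types")
        universe = self.genesets.universe
        if self.n_genes < len(universe):
            raise ValueError(
                f"n_genes={self.n_genes} smaller than gene-set universe ({len(universe)})"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(set(self.conditions)) != 2:
            raise ValueError("exactly two distinct conditions required")
        for pathway, cell_type, condition, fold in self.planted_shifts:
            if pathway not in self.genesets.sets:
                raise ValueError(f"planted pathway {pathway!r} absent from genesets")
            if cell_type not in self.cell_type_names:
                raise ValueError(f"planted cell type {cell_type!r} not in config")
            if condition not in self.conditions:
                raise ValueError(f"planted condition {condition!r} not in config")
            if fold <= 0:
                raise ValueError("planted folds must be > 0")


@dataclass
class BulkSimConfig:
    """Configuration of the bulk cohort generator.

    grade_effect maps gene -> log2 shift per grade step (II -> III -> IV);
    prognostic_genes lists (gene, per-SD log hazard beta).
    """

    n_samples: int = 300
    n_genes: int = 500
    genes: list[str] | None = None
    grade_proportions: dict[str, float] = field(
        default_factory=lambda: {"II": 0.35, "III": 0.3, "IV": 0.35}
    )
    grade_effect: dict[str, float] = field(default_factory=dict)
    prognostic_genes: list[tuple[str, float]] = field(default_factory=list)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    residual_sd: float = 1.0
    baseline_hazard: float = 1.0 / 365.0
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes is None:
            width = len(str(self.n_genes))
            self.genes = [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]
        self.n_genes = len(self.genes)
        props = self.grade_proportions
        if set(props) != set(GRADE_STEP):
            raise ValueError("grade_proportions must cover grades II, III, IV")
        if not np.isclose(sum(props.values()), 1.0):
            raise ValueError("grade_proportions must sum to 1")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        known = set(self.genes)
        for g in self.grade_effect:
            if g not in known:
                raise ValueError(f"grade_effect gene {g!r} not in gene list")
        for g, _beta in self.prognostic_genes:
            if g not in known:
                raise ValueError(f"prognostic gene {g!r} not in gene list")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and size (var = m + m^2/size)."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def sim_sc_dataset(cfg: ScSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate (CountMatrix, cell metadata) from a single-cell config."""
    rng = np.random.default_rng(cfg.seed)
    universe = sorted(cfg.genesets.universe)
    n_background = cfg.n_genes - len(universe)
    width = len(str(max(n_background, 1)))
    background = [f"BG{i + 1:0{width}d}" for i in range(n_background)]
    body_genes = universe + background
    mito_genes = [f"MT-SIM{i + 1}" for i in range(cfg.mito_gene_count)]
    gene_ids = body_genes + mito_genes
    n_body = len(body_genes)
    types = list(cfg.cell_type_names)
    k = len(types)

    # shared gene x cell-type mean structure (identical in both conditions)
    base = rng.lognormal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sigma, size=n_body)
    if cfg.cell_type_logsd > 0:
        type_effect = rng.lognormal(0.0, cfg.cell_type_logsd, size=(n_body, k))
    else:
        type_effect = np.ones((n_body, k))
    means = base[:, None] * type_effect  # genes x types

    gene_index = {g: i for i, g in enumerate(body_genes)}
    type_index = {t: j for j, t in enumerate(types)}

    # condition-specific fold multipliers on planted pathways
    fold = {c: np.ones((n_body, k)) for c in cfg.conditions}
    for pathway, cell_type, condition, f in cfg.planted_shifts:
        rows = [gene_index[g] for g in cfg.genesets.sets[pathway] if g in gene_index]
        fold[condition][rows, type_index[cell_type]] *= f

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[dict] = []
    mu_lib, sd_lib = cfg.libsize_lognormal
    f = cfg.mito_frac_mean
    for cond in cfg.conditions:
        for t_idx, cell_type in enumerate(types):
            n_c = cfg.cells_per_type_per_condition
            lib = rng.lognormal(mu_lib, sd_lib, size=n_c)
            mu_body = means[:, t_idx] * fold[cond][:, t_idx]  # genes
            cell_means = mu_body[:, None] * lib[None, :]
            counts_body = _nb_sample(rng, cell_means, cfg.nb_dispersion)
            # mito block sized so the expected mito fraction is ~ f, with jitter
            if cfg.mito_gene_count > 0:
                mito_total = f / (1.0 - f) * mu_body.sum()
                mito_mu = np.full(cfg.mito_gene_count, mito_total / cfg.mito_gene_count)
                jitter = rng.lognormal(0.0, cfg.mito_frac_logsd, size=n_c)
                mito_means = mito_mu[:, None] * (lib * jitter)[None, :]
                counts_mito = _nb_sample(rng, mito_means, cfg.nb_dispersion)
                counts = np.vstack([counts_body, counts_mito])
            else:
                counts = counts_body
            blocks.append(sp.csr_matrix(counts.astype(np.int64)))
            for i in range(n_c):
                sample = (i % cfg.samples_per_condition) + 1
                meta_rows.append(
                    {
                        "cell_id": f"{cond}_{cell_type}_{i + 1:05d}",
                        "sample_id": f"{cond}_S{sample}",
                        "condition": cond,
                        "cell_type": cell_type,
                    }
                )
    values = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows)
    matrix = CountMatrix(values, gene_ids, meta["cell_id"].to_numpy())
    return matrix, meta.set_index("cell_id", drop=False)


def _censor_scale(rates: np.ndarray, target: float) -> float:
    """Upper bound tau of U(0, tau) censoring achieving mean censor prob target.

    For T ~ Exp(rate) and C ~ U(0, tau), P(C < T) = (1 - exp(-rate*tau)) /
    (rate*tau); tau solves the average of that over samples = target.
    """

    def mean_censor(tau: float) -> float:
        x = rates * tau
        return float(np.mean(np.where(x > 1e-12, (1.0 - np.exp(-x)) / np.maximum(x, 1e-12), 1.0)))

    lo, hi = 1e-9, 1.0 / rates.mean()
    while mean_censor(hi) > target:
        hi *= 2.0
        if hi > 1e12 / rates.mean():
            break
    return brentq(lambda tau: mean_censor(tau) - target, lo, hi, xtol=1e-12)


def sim_bulk_cohort(cfg: BulkSimConfig) -> BulkCohort:
    """Generate a BulkCohort from a bulk config."""
    rng = np.random.default_rng(cfg.seed)
    n, genes = cfg.n_samples, list(cfg.genes)
    grades = rng.choice(
        list(GRADE_STEP), size=n, p=[cfg.grade_proportions[g] for g in GRADE_STEP]
    )
    steps = np.array([GRADE_STEP[g] for g in grades], dtype=float)

    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(genes))
    expr = base[None, :] + rng.normal(0.0, cfg.residual_sd, size=(n, len(genes)))
    for g, shift in cfg.grade_effect.items():
        expr[:, genes.index(g)] += shift * steps
    expr_df = pd.DataFrame(expr, columns=genes, index=[f"S{i + 1:04d}" for i in range(n)])

    # proportional-hazards survival driven by standardized prognostic genes
    eta = np.zeros(n)
    for g, beta in cfg.prognostic_genes:
        x = expr_df[g].to_numpy()
        eta += beta * (x - x.mean()) / x.std(ddof=0)
    rates = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)
    if cfg.censor_rate > 0:
        tau = _censor_scale(rates, cfg.censor_rate)
        c = rng.uniform(0.0, tau, size=n)
        os_time = np.minimum(t_event, c)
        os_event = (t_event <= c).astype(int)
    else:
        os_time = t_event
        os_event = np.ones(n, dtype=int)
    os_time = np.maximum(os_time, 1e-6)

    idh_p = {"II": 0.8, "III": 0.6, "IV": 0.1}
    codel_p = {"II": 0.4, "III": 0.3, "IV": 0.05}
    hist = {"II": "oligoastrocytoma", "III": "astrocytoma", "IV": "GBM"}
    clinical = pd.DataFrame(
        {
            "grade": grades,
            "histology": [hist[g] for g in grades],
            "idh_status": [
                "Mutant" if rng.random() < idh_p[g] else "WT" for g in grades
            ],
            "codel_1p19q": [
                "codel" if rng.random() < codel_p[g] else "non-codel" for g in grades
            ],
            "prs_type": rng.choice(
                ["Primary", "Recurrent", "Secondary"], size=n, p=[0.7, 0.2, 0.1]
            ),
            "os_time": os_time,
            "os_event": os_event,
        },
        index=expr_df.index,
    )
    return BulkCohort(expr=expr_df, clinical=clinical)


def default_geneset_collection(
    n_pathways: int = 40, genes_per_pathway: int = 12, overlap_every: int = 5
) -> GeneSetCollection:
    """A deterministic synthetic pathway collection for tests and demos.

    Pathways have disjoint member genes except that every ``overlap_every``-th
    pathway also carries the first gene of its predecessor, so membership
    weights < 1 are exercised.
    """
    sets: dict[str, list[str]] = {}
    counter = 0
    prev_first: str | None = None
    for p in range(n_pathways):
        genes = [f"PWG{counter + i + 1:05d}" for i in range(genes_per_pathway)]
        counter += genes_per_pathway
        if overlap_every and p % overlap_every == overlap_every - 1 and prev_first:
            genes.append(prev_first)
        sets[f"PATHWAY_{p + 1:03d}"] = genes
        prev_first = genes[0]
    return GeneSetCollection(sets)
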