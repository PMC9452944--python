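"""Synthetic multi-patient scRNA-seq cohorts with known per-cell asynchrony.

The generator produces a TPM-like genes x cells matrix together with the
ground truth used to create it, so every stage of the toolkit — QC,
normalization, scoring, enrichment, correlation — can be exercised and
validated without any external download.

Generation model (all on the log2 scale before the final exponentiation):

* each gene gets a baseline log-expression drawn once per cohort;
* each cell adds small Gaussian noise to every gene;
* a cell with true asynchrony ``a`` in [0, 1] has a random subset of
  ``perturbed_gene_fraction * a * n_genes`` genes hit by heavy-tailed
  (Laplace) perturbations.  Because only some genes move, and by very
  unequal amounts, higher ``a`` widens the dispersion of that cell's
  absolute z-scores — the exact signal the heterogeneity score measures.
  A uniform shift of all genes would be invisible to the score (per-gene
  affine invariance), so the perturbation is deliberately sparse and
  heavy-tailed rather than additive across the board;
* signature modules are disjoint gene blocks whose mean expression can be
  coupled positively or negatively to ``a``, giving the correlation
  analyses a known answer;
* designated high-mitochondrial cells have their MT- genes rescaled to a
  mitochondrial fraction above the QC threshold; designated low-quality
  cells have all but a few genes zeroed;
* finally values are exponentiated and each cell is rescaled to a fixed
  TPM-like column sum so the log2(TPM+1) path is exercised realistically.

Everything is driven by one mandatory seed; the same config reproduces the
same cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import RAW, ExpressionMatrix, GeneSet
from .core import SCOPE_COHORT, ataxic_scores
from .errors import ConfigError
from .preprocess import normalize_log2
from .stats import spearman

COUPLINGS = ("positive", "negative", "none")


@dataclass
class ModuleSpec:
    """A signature gene module and how its mean expression tracks asynchrony."""

    name: str
    size: int
    coupling: str = "none"  # positive | negative | none

    def __post_init__(self) -> None:
        if self.coupling not in COUPLINGS:
            raise ConfigError(f"unknown coupling {self.coupling!r}")
        if self.size < 1:
            raise ConfigError(f"module {self.name!r} has non-positive size")


def default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec("proliferation", 30, "positive"),
        ModuleSpec("cell_cycle", 30, "positive"),
        ModuleSpec("neutral", 30, "none"),
    ]


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.  ``seed`` is mandatory.

    ``asynchrony`` is either the string ``"uniform"`` (per-cell draws from
    ``asynchrony_range``), a single float applied to every cell, or an
    explicit per-cell sequence.
    """

    seed: int
    n_genes: int = 2000
    n_cells_per_sample: Sequence[int] = (100, 100, 100)
    n_mito_genes: int = 10
    asynchrony: str | float | Sequence[float] = "uniform"
    asynchrony_range: tuple[float, float] = (0.0, 1.0)
    perturbed_gene_fraction: float = 0.2
    perturbation_scale: float = 1.0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 2.0
    cell_noise_sd: float = 0.3
    signature_modules: list[ModuleSpec] = field(default_factory=default_modules)
    module_coupling_strength: float = 1.0
    low_quality_cell_fraction: float = 0.0
    low_quality_expressed_genes: int = 150
    high_mito_cell_fraction: float = 0.0
    high_mito_target_range: tuple[float, float] = (0.15, 0.5)
    tpm_total: float = 1e6

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if self.n_genes < 2 or self.n_mito_genes < 0:
            raise ConfigError("need at least 2 genes and non-negative mito count")
        if self.n_mito_genes >= self.n_genes:
            raise ConfigError("mito genes must leave room for nuclear genes")
        if not self.n_cells_per_sample or any(n < 1 for n in self.n_cells_per_sample):
            raise ConfigError("every sample needs at least one cell")
        for frac, name in (
            (self.perturbed_gene_fraction, "perturbed_gene_fraction"),
            (self.low_quality_cell_fraction, "low_quality_cell_fraction"),
            (self.high_mito_cell_fraction, "high_mito_cell_fraction"),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.perturbation_scale < 0:
            raise ConfigError("perturbation_scale must be non-negative")
        module_total = sum(m.size for m in self.signature_modules)
        if module_total > self.n_genes - self.n_mito_genes:
            raise ConfigError(
                f"signature modules need {module_total} genes but only "
                f"{self.n_genes - self.n_mito_genes} nuclear genes exist"
            )
        lo, hi = self.asynchrony_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("asynchrony_range must satisfy 0 <= lo <= hi <= 1")

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_sample))


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth aligned with the generated matrix."""

    cell_ids: list[str]
    gene_ids: list[str]
    asynchrony: np.ndarray  # per cell, in [0, 1]
    low_quality: np.ndarray  # bool per cell
    high_mito: np.ndarray  # bool per cell
    is_mito_gene: np.ndarray  # bool per gene
    module_of_gene: dict[str, str]  # gene id -> module name (members only)


def _draw_asynchrony(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    t = cfg.n_cells
    if isinstance(cfg.asynchrony, str):
        if cfg.asynchrony != "uniform":
            raise ConfigError(f"unknown asynchrony mode {cfg.asynchrony!r}")
        lo, hi = cfg.asynchrony_range
        return rng.uniform(lo, hi, size=t)
    if np.isscalar(cfg.asynchrony):
        a = float(cfg.asynchrony)  # type: ignore[arg-type]
        if not (0.0 <= a <= 1.0):
            raise ConfigError("asynchrony must lie in [0, 1]")
        return np.full(t, a)
    a = np.asarray(cfg.asynchrony, dtype=float)
    if a.shape != (t,):
        raise ConfigError(f"asynchrony sequence must have length {t}")
    if np.any(a < 0) or np.any(a > 1):
        raise ConfigError("asynchrony values must lie in [0, 1]")
    return a


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, GroundTruth, list[GeneSet]]:
    """Generate one cohort: raw TPM-like matrix, ground truth, fixture gene sets.

    The returned gene sets are the signature modules plus a ``mito`` set,
    ready to be written as a GMT fixture.
    """
    rng = np.random.default_rng(cfg.seed)
    n_mito = cfg.n_mito_genes
    gene_ids = [f"MT-{i + 1}" for i in range(n_mito)] + [
        f"G{i + 1:05d}" for i in range(cfg.n_genes - n_mito)
    ]
    cell_ids: list[str] = []
    sample_of_cell: dict[str, str] = {}
    for s, n in enumerate(cfg.n_cells_per_sample, start=1):
        sid = f"P{s:02d}"
        for i in range(n):
            cid = f"{sid}_c{i + 1:04d}"
            cell_ids.append(cid)
            sample_of_cell[cid] = sid
    t = cfg.n_cells

    asynchrony = _draw_asynchrony(cfg, rng)

    # modules occupy the first nuclear genes, in spec order
    module_rows: dict[str, np.ndarray] = {}
    cursor = n_mito
    module_of_gene: dict[str, str] = {}
    for spec in cfg.signature_modules:
        rows = np.arange(cursor, cursor + spec.size)
        module_rows[spec.name] = rows
        for r in rows:
            module_of_gene[gene_ids[r]] = spec.name
        cursor += spec.size

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    logx = baseline[:, None] + rng.normal(0.0, cfg.cell_noise_sd, size=(cfg.n_genes, t))

    for spec in cfg.signature_modules:
        if spec.coupling == "none":
            continue
        sign = 1.0 if spec.coupling == "positive" else -1.0
        logx[module_rows[spec.name], :] += (
            sign * cfg.module_coupling_strength * asynchrony[None, :]
        )

    # sparse heavy-tailed perturbations: the asynchrony signal
    for j in range(t):
        k = int(round(cfg.perturbed_gene_fraction * asynchrony[j] * cfg.n_genes))
        if k == 0:
            continue
        rows = rng.choice(cfg.n_genes, size=k, replace=False)
        logx[rows, j] += rng.laplace(0.0, cfg.perturbation_scale, size=k)

    x = np.exp2(logx)

    high_mito = np.zeros(t, dtype=bool)
    if cfg.high_mito_cell_fraction > 0 and n_mito > 0:
        n_hm = int(round(cfg.high_mito_cell_fraction * t))
        high_mito[rng.choice(t, size=n_hm, replace=False)] = True
        lo, hi = cfg.high_mito_target_range
        for j in np.nonzero(high_mito)[0]:
            target = rng.uniform(lo, hi)
            mito_sum = x[:n_mito, j].sum()
            other_sum = x[n_mito:, j].sum()
            if mito_sum > 0:
                x[:n_mito, j] *= target / (1.0 - target) * other_sum / mito_sum

    low_quality = np.zeros(t, dtype=bool)
    if cfg.low_quality_cell_fraction > 0:
        n_lq = int(round(cfg.low_quality_cell_fraction * t))
        low_quality[rng.choice(t, size=n_lq, replace=False)] = True
        for j in np.nonzero(low_quality)[0]:
            keep = rng.choice(cfg.n_genes, size=cfg.low_quality_expressed_genes,
                              replace=False)
            mask = np.ones(cfg.n_genes, dtype=bool)
            mask[keep] = False
            x[mask, j] = 0.0

    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    x *= cfg.tpm_total / totals

    mat = ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        values=x,
        sample_of_cell=sample_of_cell,
        norm_state=RAW,
    )
    truth = GroundTruth(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        asynchrony=asynchrony,
        low_quality=low_quality,
        high_mito=high_mito,
        is_mito_gene=np.array([i < n_mito for i in range(cfg.n_genes)]),
        module_of_gene=module_of_gene,
    )
    gene_sets = [
        GeneSet(spec.name, frozenset(gene_ids[r] for r in module_rows[spec.name]))
        for spec in cfg.signature_modules
    ]
    if n_mito:
        gene_sets.append(GeneSet("mito", frozenset(gene_ids[:n_mito])))
    return mat, truth, gene_sets


@dataclass
class RecoveryReport:
    """Spearman agreement between true asynchrony and computed scores."""

    rhos: list[float]
    n_reps: int
    n_genes: int
    n_cells: int

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.rhos))

    @property
    def sd_rho(self) -> float:
        return float(np.std(self.rhos, ddof=1)) if len(self.rhos) > 1 else 0.0

    @property
    def mean_abs_rho(self) -> float:
        return float(np.mean(np.abs(self.rhos)))


def recovery_experiment(cfg: SimConfig, n_reps: int = 10) -> RecoveryReport:
    """Repeatedly simulate, score, and correlate scores with the truth.

    Each replicate re-seeds the generator deterministically from the config
    seed, simulates a cohort, log2-normalizes, scores the whole cohort as
    one population, and reports the Spearman rho between the known per-cell
    asynchrony and the computed score.  Low-quality cells (if any) are
    excluded from the correlation, as QC would remove them.
    """
    if n_reps < 1:
        raise ConfigError("need at least one replicate")
    if isinstance(cfg.asynchrony, (int, float)) and not isinstance(cfg.asynchrony, bool):
        raise ConfigError(
            "recovery needs variation in asynchrony; a constant level is degenerate"
        )
    rhos: list[float] = []
    for rep in range(n_reps):
        rep_cfg = SimConfig(**{**cfg.__dict__, "seed": (cfg.seed + rep) % 2**31})
        mat, truth, _ = simulate_cohort(rep_cfg)
        norm = normalize_log2(mat)
        keep = ~truth.low_quality
        if keep.sum() < 3:
            raise ConfigError("too few usable cells for recovery")
        if not keep.all():
            norm = norm.subset_cells(keep)
        scores = ataxic_scores(norm, scope=SCOPE_COHORT).table.scores
        rho, _ = spearman(truth.asynchrony[keep], scores)
        rhos.append(rho)
    return RecoveryReport(
        rhos=rhos, n_reps=n_reps, n_genes=cfg.n_genes, n_cells=cfg.n_cells
    )
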