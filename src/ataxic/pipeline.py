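"""End-to-end workflow: QC -> score -> enrichment -> correlation.

A run is described by a plain-text YAML config so it can be archived and
replayed; every output directory carries a provenance file with the tool
version, a hash of the resolved config, and the seed.  Outputs contain no
timestamps, so a rerun of the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .containers import ExpressionMatrix, GeneSet
from .core import SCOPE_SAMPLE, ataxic_scores, summarize_scores
from .errors import ConfigError
from .io import (
    read_dense_matrix,
    read_gmt,
    read_labels,
    write_dense_matrix,
    write_gmt,
    write_labels,
    write_score_table,
)
from .preprocess import QCParams, run_qc_pipeline
from .signatures import score_all_signatures
from .simulate import ModuleSpec, SimConfig, simulate_cohort
from .stats import correlate_by_group, correlation_frame

logger = logging.getLogger("ataxic")


@dataclass
class RunConfig:
    """Resolved configuration of one full pipeline run."""

    output_dir: str
    seed: int = 0
    matrix: str | None = None
    labels: str | None = None
    gmt: str | None = None
    simulate: dict[str, Any] | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    scope: str = SCOPE_SAMPLE
    case_insensitive_genes: bool = False
    fdr_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError(f"{path}: output_dir is required")
        return cls(**raw)

    def validate(self) -> None:
        if (self.matrix is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of 'matrix' (input file) or 'simulate' "
                "(generator parameters) must be given"
            )
        for key, p in (("matrix", self.matrix), ("labels", self.labels),
                       ("gmt", self.gmt)):
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"{key} path does not exist: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(params: dict[str, Any], seed: int) -> SimConfig:
    params = dict(params)
    modules = params.pop("signature_modules", None)
    params.setdefault("seed", seed)
    try:
        if modules is not None:
            params["signature_modules"] = [
                ModuleSpec(**m) if isinstance(m, dict) else ModuleSpec(*m)
                for m in modules
            ]
        return SimConfig(**params)
    except TypeError as exc:
        raise ConfigError(f"bad simulate parameters: {exc}") from exc


def run_full_pipeline(cfg: RunConfig) -> Path:
    """Execute qc -> score -> enrich -> correlate and write all result tables.

    Returns the output directory.  Stage failures propagate with the stage
    name in the message.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        gene_sets: list[GeneSet]
        if cfg.simulate is not None:
            sim = _sim_config(cfg.simulate, cfg.seed)
            mat, truth, gene_sets = simulate_cohort(sim)
            write_dense_matrix(mat, out / "simulated_matrix.tsv")
            write_labels(mat, out / "simulated_labels.tsv")
            write_gmt(gene_sets, out / "simulated_signatures.gmt")
            import pandas as pd

            pd.DataFrame(
                {
                    "cell_id": truth.cell_ids,
                    "asynchrony": truth.asynchrony,
                    "low_quality": truth.low_quality.astype(int),
                    "high_mito": truth.high_mito.astype(int),
                }
            ).to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                     float_format="%.17g")
        else:
            labels = read_labels(cfg.labels) if cfg.labels else None
            mat = read_dense_matrix(cfg.matrix, labels=labels)  # type: ignore[arg-type]
            gene_sets = read_gmt(cfg.gmt) if cfg.gmt else []
        logger.info("[load] %d genes x %d cells, %d gene sets",
                    mat.n_genes, mat.n_cells, len(gene_sets))

        stage = "qc"
        qc_params = QCParams(**cfg.qc) if cfg.qc else QCParams()
        mat, report = run_qc_pipeline(mat, qc_params)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        logger.info("[qc] kept %d genes x %d cells", mat.n_genes, mat.n_cells)

        stage = "score"
        result = ataxic_scores(mat, scope=cfg.scope)
        write_score_table(result.table, out / "scores.tsv")
        summarize_scores(result.table).to_csv(
            out / "score_summary.tsv", sep="\t", index=False, float_format="%.17g"
        )
        with open(out / "dropped_genes.tsv", "w") as fh:
            fh.write("group\tgene_id\n")
            for group in sorted(result.dropped_genes):
                for g in result.dropped_genes[group]:
                    fh.write(f"{group}\t{g}\n")
        logger.info("[score] scored %d cells (scope=%s)", len(result.table), cfg.scope)

        if gene_sets:
            stage = "enrich"
            sig = score_all_signatures(
                mat, gene_sets, case_insensitive=cfg.case_insensitive_genes
            )
            sig.frame.to_csv(out / "enrichment.tsv", sep="\t",
                             float_format="%.17g")
            for w in sig.warnings:
                logger.warning("[enrich] %s", w)

            stage = "correlate"
            frames = []
            for name in sig.frame.columns:
                records = correlate_by_group(result.table, sig.column(name))
                frame = correlation_frame(records)
                frame.insert(0, "signature", name)
                frames.append(frame)
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(
                out / "correlations.tsv", sep="\t", index=False,
                float_format="%.17g"
            )
            logger.info("[correlate] %d signatures x groups", len(frames))

        stage = "provenance"
        provenance = {
            "tool": "ataxic",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": asdict(cfg),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        try:
            wrapped = type(exc)(f"[stage {stage}] {exc}")
        except TypeError:
            wrapped = RuntimeError(f"[stage {stage}] {exc}")
        raise wrapped from exc
    return out
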