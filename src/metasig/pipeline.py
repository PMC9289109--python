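"""End-to-end orchestration: discovery → validation → deconvolution.

The discovery stage normalizes the discovery cohorts, computes per-gene
Hedges' g effects per cohort, pools them with DerSimonian-Laird random
effects, applies the FDR/effect-size filter, and runs the greedy forward
search to produce the signature. Validation scores held-out cohorts with
that signature and reports per-cohort ROC/AUC with bootstrap CIs plus the
pooled summary AUC. The deconvolution stage quantifies marker panels and
tests group shifts per cell type. All functions operate on in-memory
cohorts; file-facing wrappers used by the CLI live at the bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import deconvolution as deconv_mod
from . import meta_effects
from .errors import EmptyResultError, InputError
from .evaluation import RocSummary, evaluate_cohorts
from .expression_io import ExpressionCohort, ensure_log2, quantile_normalize
from .signature import Signature, forward_search, score_cohorts

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable thresholds and settings of a pipeline run."""

    fdr_max: float = 0.01
    effect_min: float = 0.8
    min_improvement: float = 0.0
    max_genes: int | None = None
    weighted_objective: bool = True
    min_cohorts: int | None = None  # None = gene must be in all discovery cohorts
    n_boot: int = 2000
    seed: int = 0
    apply_quantile_normalization: bool = True

    def __post_init__(self) -> None:
        if self.fdr_max <= 0 or self.effect_min < 0:
            raise InputError("thresholds must be positive")


@dataclass
class DiscoveryResult:
    pooled: pd.DataFrame
    candidates: pd.DataFrame
    signature: Signature
    scores: dict[str, pd.DataFrame]
    roc: RocSummary
    effects_by_cohort: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class ValidationResult:
    scores: dict[str, pd.DataFrame]
    roc: RocSummary


def normalize_cohort(cohort: ExpressionCohort, config: RunConfig) -> ExpressionCohort:
    cohort = ensure_log2(cohort)
    if config.apply_quantile_normalization:
        cohort = quantile_normalize(cohort)
    return cohort


def run_discovery(
    cohorts: list[ExpressionCohort], config: RunConfig | None = None
) -> DiscoveryResult:
    """Derive the signature from discovery cohorts.

    Raises :class:`EmptyResultError` when no gene survives the
    differential-expression filter (e.g. under a null dataset).
    """
    config = config or RunConfig()
    discovery = [c for c in cohorts if c.role == "discovery"]
    if not discovery:
        raise InputError("no discovery cohorts supplied")
    discovery = [normalize_cohort(c, config) for c in discovery]
    logger.info("discovery on %d cohorts, %s", len(discovery), [c.cohort_id for c in discovery])

    effects = {c.cohort_id: meta_effects.cohort_effects(c) for c in discovery}
    pooled = meta_effects.pool_cohort_effects(effects, min_cohorts=config.min_cohorts)
    logger.info("pooled %d genes", len(pooled))
    candidates = meta_effects.filter_significant(
        pooled, fdr_max=config.fdr_max, effect_min=config.effect_min
    )
    logger.info(
        "%d candidate genes at q<%g, |mu|>%g", len(candidates), config.fdr_max, config.effect_min
    )
    if len(candidates) == 0:
        raise EmptyResultError(
            f"no gene passes q<{config.fdr_max}, |mu|>{config.effect_min}"
        )

    signature = forward_search(
        discovery,
        candidates,
        min_improvement=config.min_improvement,
        max_genes=config.max_genes,
        weighted=config.weighted_objective,
    )
    logger.info(
        "signature: %d up %s, %d down %s",
        len(signature.up_genes),
        signature.up_genes,
        len(signature.down_genes),
        signature.down_genes,
    )
    scores = score_cohorts(discovery, signature)
    roc = evaluate_cohorts(scores, n_boot=config.n_boot, seed=config.seed)
    return DiscoveryResult(pooled, candidates, signature, scores, roc, effects)


def run_validation(
    cohorts: list[ExpressionCohort],
    signature: Signature,
    config: RunConfig | None = None,
) -> ValidationResult:
    """Score and evaluate held-out cohorts with a fixed signature."""
    config = config or RunConfig()
    validation = [c for c in cohorts if c.role == "validation"]
    if not validation:
        raise InputError("no validation cohorts supplied")
    if not signature.genes:
        raise InputError("empty signature")
    validation = [normalize_cohort(c, config) for c in validation]
    scores = score_cohorts(validation, signature)
    if not scores:
        raise EmptyResultError("signature genes absent from every validation cohort")
    roc = evaluate_cohorts(scores, n_boot=config.n_boot, seed=config.seed)
    return ValidationResult(scores, roc)


def run_deconvolution(
    cohorts: list[ExpressionCohort],
    panel: dict[str, list[str]],
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-cohort cell-type comparison tables for a marker panel."""
    config = config or RunConfig()
    results = {}
    for cohort in cohorts:
        cohort = normalize_cohort(cohort, config)
        scores = deconv_mod.cell_scores(cohort, panel)
        results[cohort.cohort_id] = deconv_mod.compare_groups(scores, cohort.labels)
    return results


# ---------------------------------------------------------------------------
# file-facing helpers (used by the CLI)
# ---------------------------------------------------------------------------


def _scores_frame(scores: dict[str, pd.DataFrame]) -> pd.DataFrame:
    parts = []
    for cid, table in sorted(scores.items()):
        part = table.reset_index(names="sample_id")
        part.insert(0, "cohort_id", cid)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_discovery_outputs(result: DiscoveryResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.pooled.to_csv(out / "pooled_effects.tsv", sep="\t")
    result.candidates.to_csv(out / "candidate_genes.tsv", sep="\t")
    result.signature.to_json(out / "signature.json")
    _scores_frame(result.scores).to_csv(out / "discovery_scores.tsv", sep="\t", index=False)
    result.roc.to_frame().to_csv(out / "discovery_roc.tsv", sep="\t", index=False)
    forest = []
    for gene in result.signature.genes:
        rows = meta_effects.forest_data(result.effects_by_cohort, result.pooled, gene)
        rows.insert(0, "gene_id", gene)
        forest.append(rows)
    if forest:
        pd.concat(forest, ignore_index=True).to_csv(out / "forest_data.tsv", sep="\t", index=False)


def write_validation_outputs(result: ValidationResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _scores_frame(result.scores).to_csv(out / "validation_scores.tsv", sep="\t", index=False)
    result.roc.to_frame().to_csv(out / "validation_roc.tsv", sep="\t", index=False)


def write_deconvolution_outputs(
    results: dict[str, pd.DataFrame], out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parts = []
    for cid, table in sorted(results.items()):
        part = table.reset_index()
        part.insert(0, "cohort_id", cid)
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(
        out / "deconvolution_results.tsv", sep="\t", index=False
    )


def write_report(out_dir: str | Path) -> Path:
    """Assemble a markdown run report from the artifacts present in out_dir."""
    out = Path(out_dir)
    lines = ["# Pipeline run report", ""]

    sig_path = out / "signature.json"
    if sig_path.exists():
        sig = Signature.from_json(sig_path)
        lines += [
            "## Signature",
            "",
            f"- up-regulated ({len(sig.up_genes)}): {', '.join(sig.up_genes)}",
            f"- down-regulated ({len(sig.down_genes)}): {', '.join(sig.down_genes)}",
            "",
            "| step | gene | objective (weighted mean AUC) |",
            "|---|---|---|",
        ]
        lines += [f"| {i+1} | {g} | {v:.4f} |" for i, (g, v) in enumerate(sig.trace)]
        lines.append("")

    for name, title in [
        ("discovery_roc.tsv", "Discovery ROC"),
        ("validation_roc.tsv", "Validation ROC"),
        ("deconvolution_results.tsv", "Deconvolution"),
    ]:
        path = out / name
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            lines += [f"## {title}", "", "```", df.to_string(index=False), "```", ""]

    linked = [p.name for p in sorted(out.iterdir()) if p.suffix in {".tsv", ".json"}]
    lines += ["## Artifacts", ""] + [f"- [{n}]({n})" for n in linked]
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
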