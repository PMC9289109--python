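"""Synthetic multi-cohort expression data with planted differential signals.

The generator mirrors the statistical structure the downstream analysis
assumes, so every stage is testable without downloading the original
datasets:

* K cohorts drawing from a shared gene universe, each with its own
  case/control group sizes;
* a planted set of up- and down-regulated genes whose true standardized
  effect varies between cohorts as d_ik ~ Normal(mu_effect, tau^2)
  (negated for the down set) — the random-effects structure the
  DerSimonian-Laird pooling estimates;
* gene-constant per-cohort location (batch) shifts;
* i.i.d. Gaussian log2 noise within groups.

Case samples of a planted gene i in cohort k have mean
``baseline + batch_k + d_ik * noise_sd``; controls ``baseline + batch_k``;
all other genes have equal group means. Everything is generated directly on
the log2 scale. A companion mixture simulator produces cohorts whose marker
genes respond linearly to known per-sample cell-type abundances, for
deconvolution recovery tests.

All randomness flows from one integer seed via deterministically spawned
child streams, so output is bit-identical across calls with the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .expression_io import ExpressionCohort, write_cohort
from .study_design import DEFAULT_CASE_FRACTION, STUDY_COHORTS

__all__ = [
    "CohortSpec",
    "SimulationConfig",
    "simulate_cohorts",
    "simulate_mixture_cohort",
    "default_study_cohort_specs",
    "gene_universe",
    "write_simulation",
]


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    n_cases: int
    n_controls: int
    role: str = "discovery"
    sample_type: str = "Whole Blood"


def default_study_cohort_specs() -> list[CohortSpec]:
    """Cohort dimensions of the emulated nine-dataset study (~55% cases)."""
    specs = []
    for cid, sample_type, n, role in STUDY_COHORTS:
        n_cases = round(n * DEFAULT_CASE_FRACTION)
        specs.append(CohortSpec(cid, n_cases, n - n_cases, role, sample_type))
    return specs


def gene_universe(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


@dataclass
class SimulationConfig:
    """Parameters of the multi-cohort generator.

    Defaults reproduce the emulated study design: nine cohorts at the
    published sample sizes, a 4-up/1-down planted signature with mean true
    effect 1.5 SMD and between-cohort SD 0.2, unit log2 noise, and mild
    gene-constant batch shifts.
    """

    n_genes: int = 200
    cohorts: list[CohortSpec] = field(default_factory=default_study_cohort_specs)
    planted_up: list[str] = field(default_factory=lambda: gene_universe(200)[:4])
    planted_down: list[str] = field(default_factory=lambda: gene_universe(200)[4:5])
    mu_effect: float = 1.5  # mean true effect, SMD units
    tau: float = 0.2  # between-cohort effect SD, SMD units
    batch_shift_sd: float = 0.5  # per-cohort location offset SD, log2 units
    noise_sd: float = 1.0  # within-group SD, log2 units
    baseline_mean: float = 8.0  # grand mean, log2 units
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        universe = set(gene_universe(self.n_genes))
        up, down = set(self.planted_up), set(self.planted_down)
        if up & down:
            raise ConfigurationError(
                f"planted_up and planted_down overlap: {sorted(up & down)}"
            )
        stray = (up | down) - universe
        if stray:
            raise ConfigurationError(f"planted genes outside universe: {sorted(stray)}")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not self.cohorts:
            raise ConfigurationError("at least one cohort required")
        for c in self.cohorts:
            if c.n_cases < 1 or c.n_controls < 1:
                raise ConfigurationError(f"{c.cohort_id}: group sizes must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.tau < 0:
            raise ConfigurationError("tau must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "cohorts" in raw:
            raw["cohorts"] = [CohortSpec(**c) for c in raw["cohorts"]]
        return cls(**raw)


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionCohort], dict]:
    """Generate the cohorts plus a truth record.

    Returns ``(cohorts, truth)`` where ``truth`` holds the planted gene sets
    and the realized per-cohort true effects ``d_ik`` (a DataFrame, planted
    genes × cohorts, SMD units).
    """
    config.validate()
    genes = gene_universe(config.n_genes)
    planted = list(config.planted_up) + list(config.planted_down)
    sign = np.array([1.0] * len(config.planted_up) + [-1.0] * len(config.planted_down))
    planted_idx = [genes.index(g) for g in planted]

    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(len(config.cohorts))]

    cohorts = []
    realized = {}
    for spec, rng in zip(config.cohorts, streams):
        n = spec.n_cases + spec.n_controls
        batch = rng.normal(0.0, config.batch_shift_sd)
        d = sign * rng.normal(config.mu_effect, config.tau, size=len(planted))
        means = np.full((config.n_genes, n), config.baseline_mean + batch)
        # case columns first, then controls
        if planted:
            means[np.array(planted_idx), : spec.n_cases] += d[:, None] * config.noise_sd
        x = means + rng.normal(0.0, config.noise_sd, size=means.shape)
        sample_ids = [f"{spec.cohort_id}_S{j:04d}" for j in range(1, n + 1)]
        labels = pd.Series(
            ["case"] * spec.n_cases + ["control"] * spec.n_controls,
            index=pd.Index(sample_ids, name="sample_id"),
        )
        cohorts.append(
            ExpressionCohort(
                cohort_id=spec.cohort_id,
                values=pd.DataFrame(x, index=genes, columns=sample_ids),
                labels=labels,
                role=spec.role,
                sample_type=spec.sample_type,
            )
        )
        realized[spec.cohort_id] = d

    truth = {
        "planted_up": list(config.planted_up),
        "planted_down": list(config.planted_down),
        "effects": pd.DataFrame(realized, index=planted),
    }
    return cohorts, truth


# ---------------------------------------------------------------------------
# cell-mixture fixtures for deconvolution
# ---------------------------------------------------------------------------


def simulate_mixture_cohort(
    panel: dict[str, list[str]],
    case_proportions: dict[str, float],
    control_proportions: dict[str, float],
    n_cases: int = 30,
    n_controls: int = 30,
    seed: int = 0,
    *,
    slope: float = 4.0,  # log2 units across the full abundance range
    proportion_sd: float = 0.1,  # per-sample abundance jitter
    noise_sd: float = 0.3,  # log2 measurement noise
    baseline: float = 6.0,
    n_background_genes: int = 100,
    cohort_id: str = "mixture",
) -> tuple[ExpressionCohort, pd.DataFrame]:
    """Cohort whose marker genes respond linearly to known cell abundances.

    Each sample draws a true abundance per cell type around its group's
    proportion (truncated-normal jitter, clipped to [0, 1]); every marker of
    that cell type then reads ``baseline + slope * abundance + noise``.
    Abundances are drawn independently per cell type (relative abundances,
    not a simplex). Returns the cohort and the truth abundances
    (cell type × sample).
    """
    from .deconvolution import validate_panel  # local import avoids a cycle

    validate_panel(panel)
    cells = list(panel)
    for props in (case_proportions, control_proportions):
        missing = set(cells) - set(props)
        if missing:
            raise ConfigurationError(f"proportions missing for cell types: {sorted(missing)}")
        bad = {c: p for c, p in props.items() if not (0.0 <= p <= 1.0)}
        if bad:
            raise ConfigurationError(f"proportions outside [0, 1]: {bad}")
    if n_cases < 1 or n_controls < 1:
        raise ConfigurationError("group sizes must be >= 1")

    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    sample_ids = [f"{cohort_id}_S{j:04d}" for j in range(1, n + 1)]
    group_p = np.array(
        [[case_proportions[c]] * n_cases + [control_proportions[c]] * n_controls for c in cells]
    )
    abundance = np.clip(group_p + rng.normal(0.0, proportion_sd, size=group_p.shape), 0.0, 1.0)

    marker_rows = []
    marker_ids = []
    for ci, cell in enumerate(cells):
        for m in panel[cell]:
            marker_ids.append(m)
            marker_rows.append(baseline + slope * abundance[ci])
    x_markers = np.asarray(marker_rows)
    x_background = baseline + rng.normal(
        0.0, noise_sd, size=(n_background_genes, n)
    )
    bg_ids = [f"BG{i:04d}" for i in range(1, n_background_genes + 1)]
    x = np.vstack([x_markers + rng.normal(0.0, noise_sd, size=x_markers.shape), x_background])

    labels = pd.Series(
        ["case"] * n_cases + ["control"] * n_controls,
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = ExpressionCohort(
        cohort_id=cohort_id,
        values=pd.DataFrame(x, index=marker_ids + bg_ids, columns=sample_ids),
        labels=labels,
        role="validation",
        sample_type="cell mixture",
    )
    truth = pd.DataFrame(abundance, index=pd.Index(cells, name="cell_type"), columns=sample_ids)
    return cohort, truth


# ---------------------------------------------------------------------------
# on-disk output
# ---------------------------------------------------------------------------


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[list[ExpressionCohort], dict]:
    """Simulate and write cohorts (TSV pairs), a manifest and the truth record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts, truth = simulate_cohorts(config)
    manifest = []
    for cohort in cohorts:
        matrix = f"{cohort.cohort_id}_expression.tsv"
        metadata = f"{cohort.cohort_id}_samples.tsv"
        write_cohort(cohort, out / matrix, out / metadata)
        manifest.append(
            {
                "cohort_id": cohort.cohort_id,
                "matrix": matrix,
                "metadata": metadata,
                "role": cohort.role,
                "sample_type": cohort.sample_type,
            }
        )
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "planted_up": truth["planted_up"],
                "planted_down": truth["planted_down"],
                "effects": truth["effects"].to_dict(),
            },
            fh,
            indent=2,
        )
    return cohorts, truth
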