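"""Reading, validation and normalization of cohort expression matrices.

A cohort is a genes × samples matrix of log2-scale expression with a binary
case/control label per sample. Matrices arrive as tab-delimited text (gene
ids in the first column, sample ids in the header); sample metadata is a
two-column TSV (``sample_id``, ``class``). All downstream stages consume the
validated :class:`ExpressionCohort` container produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError

logger = logging.getLogger(__name__)

CLASSES = ("case", "control")
ROLES = ("discovery", "validation")


@dataclass
class ExpressionCohort:
    """One cohort: log2 expression matrix plus per-sample class labels.

    Parameters
    ----------
    cohort_id:
        Dataset identifier.
    values:
        genes × samples DataFrame of log2 expression. Row index = gene ids,
        columns = sample ids.
    labels:
        Series indexed by sample id with values ``"case"`` / ``"control"``,
        aligned with ``values.columns``.
    role:
        ``"discovery"`` or ``"validation"``.
    sample_type:
        Free-text tissue/cell description (e.g. "Whole Blood").
    """

    cohort_id: str
    values: pd.DataFrame
    labels: pd.Series
    role: str = "discovery"
    sample_type: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.role not in ROLES:
            raise InputError(
                f"{self.cohort_id}: role must be one of {ROLES}, got {self.role!r}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(
                f"{self.cohort_id}: duplicate gene ids after collapsing: {list(dups)[:5]}"
            )
        if self.values.columns.duplicated().any():
            raise InputError(f"{self.cohort_id}: duplicate sample ids")
        missing = self.values.columns.difference(self.labels.index)
        extra = self.labels.index.difference(self.values.columns)
        if len(missing) or len(extra):
            raise InputError(
                f"{self.cohort_id}: sample/label mismatch; "
                f"unlabelled samples: {list(missing)}; labels without samples: {list(extra)}"
            )
        self.labels = self.labels.reindex(self.values.columns)
        bad = set(self.labels.unique()) - set(CLASSES)
        if bad:
            raise InputError(
                f"{self.cohort_id}: class labels must be in {CLASSES}, got {sorted(bad)}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError(f"{self.cohort_id}: matrix contains non-finite values")
        if self.role == "discovery" and (self.n_case == 0 or self.n_control == 0):
            raise InputError(
                f"{self.cohort_id}: discovery cohort must contain both classes "
                f"(n_case={self.n_case}, n_control={self.n_control})"
            )

    # -- convenience --------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels == "case").to_numpy()

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return self.n_samples - self.n_case

    def with_values(self, values: pd.DataFrame) -> "ExpressionCohort":
        """Copy of this cohort with a replacement matrix (same samples)."""
        return replace(self, values=values)


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------


def load_cohort(
    matrix_path: str | Path,
    metadata_path: str | Path,
    cohort_id: str,
    role: str = "discovery",
    sample_type: str = "",
) -> ExpressionCohort:
    """Load a cohort from a gene×sample TSV and a sample-metadata TSV.

    Rows containing any missing or non-finite value are dropped (count
    logged). Duplicate gene ids — e.g. multiple probes mapped to one symbol —
    are collapsed by the arithmetic mean of their rows.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample_id", "class"} <= set(meta.columns):
        raise InputError(
            f"{cohort_id}: metadata must have columns sample_id, class; got {list(meta.columns)}"
        )
    labels = pd.Series(
        meta["class"].to_numpy(), index=pd.Index(meta["sample_id"], name="sample_id")
    )

    missing_meta = matrix.columns.difference(labels.index)
    if len(missing_meta):
        raise InputError(
            f"{cohort_id}: metadata missing sample ids: {sorted(missing_meta)}"
        )

    matrix = matrix.apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(matrix.to_numpy())
    keep = finite.all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d gene rows with missing values", cohort_id, n_dropped)
        matrix = matrix.loc[keep]

    if matrix.index.duplicated().any():
        n_before = matrix.shape[0]
        matrix = matrix.groupby(level=0, sort=False).mean()
        logger.info(
            "%s: collapsed %d duplicate gene rows by mean", cohort_id, n_before - matrix.shape[0]
        )

    return ExpressionCohort(
        cohort_id=cohort_id,
        values=matrix,
        labels=labels.reindex(matrix.columns),
        role=role,
        sample_type=sample_type,
    )


def write_cohort(
    cohort: ExpressionCohort, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a cohort back to the TSV pair accepted by :func:`load_cohort`."""
    cohort.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": cohort.sample_ids, "class": cohort.labels.to_numpy()}
    ).to_csv(metadata_path, sep="\t", index=False)


def load_manifest(manifest_path: str | Path) -> list[ExpressionCohort]:
    """Load all cohorts listed in a YAML manifest.

    The manifest is a list of mappings with keys ``cohort_id``, ``matrix``,
    ``metadata``, ``role`` and optional ``sample_type``; relative paths are
    resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list) or not entries:
        raise InputError(f"manifest {manifest_path} must be a non-empty list")
    base = manifest_path.parent
    cohorts = []
    for entry in entries:
        cohorts.append(
            load_cohort(
                base / entry["matrix"],
                base / entry["metadata"],
                cohort_id=entry["cohort_id"],
                role=entry.get("role", "discovery"),
                sample_type=entry.get("sample_type", ""),
            )
        )
    return cohorts


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def ensure_log2(
    cohort: ExpressionCohort, max_raw_threshold: float = 50.0
) -> ExpressionCohort:
    """Guarantee the matrix is on the log2 scale.

    If the matrix maximum exceeds ``max_raw_threshold`` the values are taken
    to be raw intensities and mapped through ``log2(x + 1)``; otherwise the
    cohort passes through unchanged. Negative values together with an
    above-threshold maximum are contradictory (raw intensities are
    non-negative) and raise :class:`InputError`.
    """
    x = cohort.values.to_numpy()
    if (x <= -30).any():
        raise InputError(f"{cohort.cohort_id}: values at or below -30 fail sanity bound")
    if x.max() <= max_raw_threshold:
        return cohort
    if (x < 0).any():
        raise InputError(
            f"{cohort.cohort_id}: matrix maximum {x.max():.3g} exceeds "
            f"{max_raw_threshold} but negative values are present; "
            "cannot be raw intensities"
        )
    logger.info(
        "%s: matrix maximum %.3g above %.3g; applying log2(x+1)",
        cohort.cohort_id,
        x.max(),
        max_raw_threshold,
    )
    return cohort.with_values(
        pd.DataFrame(np.log2(x + 1.0), index=cohort.gene_ids, columns=cohort.sample_ids)
    )


def quantile_normalize(cohort: ExpressionCohort) -> ExpressionCohort:
    """Quantile-normalize samples so every column shares one distribution.

    The reference distribution is the across-sample mean of the order
    statistics. Ties within a column receive the mean of the reference values
    over the tied ranks, so the map is well defined and symmetric in the tied
    entries.
    """
    if cohort.n_samples < 2:
        logger.warning("%s: single sample; quantile normalization is a no-op", cohort.cohort_id)
        return cohort.with_values(cohort.values.copy())

    x = cohort.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)

    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col_sorted = sorted_x[:, j]
        # boundaries of tie blocks in the sorted column
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        block_sums = np.add.reduceat(reference, starts)
        block_lens = np.diff(np.r_[starts, n])
        block_means = block_sums / block_lens
        normalized_sorted = np.repeat(block_means, block_lens)
        out[order[:, j], j] = normalized_sorted

    return cohort.with_values(
        pd.DataFrame(out, index=cohort.gene_ids, columns=cohort.sample_ids)
    )
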