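import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metasig.expression_io import ExpressionCohort
from metasig.synthetic import CohortSpec, SimulationConfig, gene_universe

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("metasig").setLevel(logging.ERROR)

GENES_200 = gene_universe(200)


def make_cohort(matrix, labels, cohort_id="C1", role="discovery", genes=None, samples=None):
    """Small hand-built cohort from a nested list / array."""
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"G{i+1}" for i in range(matrix.shape[0])]
    samples = samples or [f"S{j+1}" for j in range(matrix.shape[1])]
    return ExpressionCohort(
        cohort_id=cohort_id,
        values=pd.DataFrame(matrix, index=genes, columns=samples),
        labels=pd.Series(labels, index=pd.Index(samples, name="sample_id")),
        role=role,
    )


def planted_config(
    seed, n_up=4, n_down=1, n_cohorts=3, n_cases=40, n_controls=40, role="discovery", **kw
):
    """The scaled planted-signature study conditions used throughout the tests."""
    return SimulationConfig(
        n_genes=200,
        cohorts=[CohortSpec(f"D{i}", n_cases, n_controls, role) for i in range(n_cohorts)],
        planted_up=GENES_200[:n_up],
        planted_down=GENES_200[n_up : n_up + n_down],
        seed=seed,
        **kw,
    )


def null_config(seed, **kw):
    return planted_config(seed, n_up=0, n_down=0, **kw)


@pytest.fixture
def small_cohort():
    return make_cohort(
        [[2.0, 3.0, 4.0, 1.0], [5.0, 6.0, 1.0, 2.0], [1.0, 1.0, 2.0, 2.0]],
        ["case", "case", "control", "control"],
    )
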