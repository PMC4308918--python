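import numpy as np
import pandas as pd
import pytest

from mirnome.datagen import SimulationConfig, simulate_cohort
from mirnome.expression import ExpressionMatrix, rpm_normalize


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (30 tumors / 10 normals) with all effect types planted."""
    cfg = SimulationConfig(
        n_tumor=30, n_normal=10, n_validation=20, n_mirna=80, n_mrna=60,
        n_de_mirna=8, n_regulatory_pairs=6, n_survival_mirna=2,
        n_cluster_markers=10, seed=42,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_rpm(small_cohort):
    cfg, (mirna, mrna, ann, clin, truth) = small_cohort
    return rpm_normalize(mirna, ann.table["aligned_reads"])


def matrix(values, features=None, samples=None, unit="RPM") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=samples), unit=unit
    )
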