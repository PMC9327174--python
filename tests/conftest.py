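import numpy as np
import pandas as pd
import pytest

from endomix import CohortTable, FeatureSpec, default_scheme, generate_cohort


def small_schema():
    return [
        FeatureSpec("pid", "nominal", role="id"),
        FeatureSpec("glucose", "continuous", units="mmol/L"),
        FeatureSpec("lactate", "continuous", units="mmol/L"),
        FeatureSpec("gcs_total", "ordinal", levels=tuple(range(3, 16))),
        FeatureSpec("sedated", "binary", levels=("no", "yes")),
        FeatureSpec("cause", "nominal", levels=("road", "fall", "other")),
        FeatureSpec("gose", "ordinal", levels=tuple(range(1, 9)), role="outcome"),
    ]


@pytest.fixture
def schema():
    return small_schema()


def make_cohort(schema, columns: dict) -> CohortTable:
    records = pd.DataFrame(columns, columns=[f.name for f in schema])
    return CohortTable(schema, records)


@pytest.fixture
def make():
    return make_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """A 600-patient default-scheme cohort with known labels (master seed 3)."""
    cfg = default_scheme(n_patients=600, seed=3)
    cohort, labels = generate_cohort(cfg)
    return cfg, cohort, labels
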