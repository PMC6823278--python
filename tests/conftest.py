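import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from snprisk import (
    PopulationBaseline,
    build_model,
    load_lung_cancer_catalog,
)

# First-batch cohort of 48 published subject risks (id, absolute risk, sex),
# used to check ranking, relative-risk and per-stratum averaging conventions.
COHORT_48 = [
    ("17", 0.283, "M"), ("23", 0.174, "M"), ("27", 0.174, "M"), ("25", 0.152, "M"),
    ("26", 0.145, "M"), ("16", 0.141, "M"), ("2", 0.138, "M"), ("32", 0.122, "M"),
    ("22", 0.119, "M"), ("24", 0.119, "M"), ("19", 0.094, "M"), ("4", 0.092, "M"),
    ("10", 0.092, "M"), ("11", 0.092, "M"), ("30", 0.087, "M"), ("28", 0.086, "F"),
    ("15", 0.084, "M"), ("43", 0.081, "M"), ("18", 0.081, "F"), ("33", 0.078, "M"),
    ("8", 0.077, "M"), ("31", 0.077, "F"), ("9", 0.076, "M"), ("34", 0.073, "M"),
    ("1", 0.072, "M"), ("47", 0.072, "M"), ("38", 0.071, "M"), ("21", 0.069, "F"),
    ("14", 0.067, "F"), ("48", 0.064, "M"), ("40", 0.063, "M"), ("12", 0.061, "M"),
    ("29", 0.058, "F"), ("42", 0.056, "M"), ("20", 0.054, "M"), ("39", 0.053, "M"),
    ("37", 0.044, "M"), ("6", 0.042, "M"), ("3", 0.040, "M"), ("41", 0.040, "M"),
    ("44", 0.040, "M"), ("46", 0.040, "F"), ("35", 0.038, "M"), ("7", 0.035, "M"),
    ("45", 0.035, "M"), ("5", 0.035, "F"), ("13", 0.022, "F"), ("36", 0.019, "F"),
]


@pytest.fixture(scope="session")
def catalog():
    return load_lung_cancer_catalog()


@pytest.fixture(scope="session")
def baselines():
    return [PopulationBaseline("men", 0.0562), PopulationBaseline("women", 0.0256)]


@pytest.fixture(scope="session")
def model(catalog, baselines):
    return build_model(catalog, baselines)
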