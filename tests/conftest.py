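import pandas as pd
import pytest

from oncolot.dictionaries import (
    load_ae_code_map, load_charlson_map, load_drug_dictionary, load_regimen_catalog,
)
from oncolot.reporting import PipelineConfig, run_pipeline
from oncolot.synthetic import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def dictionary():
    return load_drug_dictionary()


@pytest.fixture(scope="session")
def catalog():
    return load_regimen_catalog()


@pytest.fixture(scope="session")
def charlson_map():
    return load_charlson_map()


@pytest.fixture(scope="session")
def ae_map():
    return load_ae_code_map()


@pytest.fixture(scope="session")
def small_bundle(dictionary, catalog):
    """300-patient synthetic bundle with ground truth."""
    return generate_bundle(SimulationConfig(n_patients=300, seed=1), dictionary, catalog)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Full pipeline result on the 300-patient bundle."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = PipelineConfig(out_dir=out, simulation=SimulationConfig(n_patients=300, seed=1))
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Large default-condition run used for parameter-recovery checks.

    20000 patients keeps the Monte-Carlo noise of the third-line KM median
    (~1.44 * median / sqrt(n_line3)) well inside the recovery tolerance.
    """
    out = tmp_path_factory.mktemp("recovery_run")
    cfg = PipelineConfig(out_dir=out, simulation=SimulationConfig(n_patients=20000, seed=7))
    return run_pipeline(cfg)


def make_rx(pid, day_codes, start="2018-01-01", setting="outpatient", points=100.0):
    """Prescription frame from (day_offset, drug_code) pairs."""
    base = pd.Timestamp(start)
    rows = [(pid, base + pd.Timedelta(days=d), c, setting, points) for d, c in day_codes]
    return pd.DataFrame(rows, columns=["patient_id", "date", "drug_code", "setting", "points"])
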