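"""Shared fixtures: the reference synthetic assemblage and derived tables."""
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pesmorph.ingest import aggregate_repeats, measurement_columns
from pesmorph.pipeline import RunConfig, run_pipeline
from pesmorph.synthetic import demo_config, simulate_assemblage

settings.register_profile(
    "pesmorph", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pesmorph")

#: fixed fixture seed — the reference study conditions
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_config():
    return demo_config(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def assemblage(fixture_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_assemblage(fixture_config)


@pytest.fixture(scope="session")
def specimen_table(assemblage):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aggregate_repeats(assemblage.repeats, assemblage.metadata)


@pytest.fixture(scope="session")
def training_table(specimen_table):
    return specimen_table[specimen_table["provenance"] == "modern"].reset_index(drop=True)


@pytest.fixture(scope="session")
def measurements(specimen_table):
    return measurement_columns(specimen_table)


@pytest.fixture(scope="session")
def pipeline_run(assemblage, tmp_path_factory):
    """One full pipeline run on the reference assemblage (shared, read-only)."""
    d = tmp_path_factory.mktemp("pipeline")
    assemblage.repeats.to_csv(d / "repeats.csv", index=False)
    assemblage.metadata.to_csv(d / "metadata.csv", index=False)
    cfg = RunConfig(
        repeats_csv=str(d / "repeats.csv"), metadata_csv=str(d / "metadata.csv"),
        outdir=str(d / "out"), seed=FIXTURE_SEED,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(cfg)
    return cfg, report


def make_repeat_table(values_by_specimen, measurement="M1", element="astragalus"):
    """Long repeat table from {specimen_id: [replicates]} (test helper)."""
    rows = []
    for sid, reps in values_by_specimen.items():
        for i, v in enumerate(reps, start=1):
            rows.append({"specimen_id": sid, "element": element,
                         "measurement_name": measurement,
                         "replicate_index": i, "value_mm": v})
    return pd.DataFrame(rows)


def make_metadata(specimen_ids, element="astragalus", genus="Bettongia",
                  species="lesueur", provenance="modern"):
    return pd.DataFrame([
        {"specimen_id": sid, "genus": genus, "species": species, "element": element,
         "age_class": "adult", "sex": "F", "provenance": provenance, "stratum": ""}
        for sid in specimen_ids
    ])
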