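import logging

import numpy as np
import pandas as pd
import pytest

import osteowarn as ow

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (seed 1) with the planted DNB."""
    cohort, truth = ow.generate_cohort(ow.SimConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    cohort, truth = default_cohort
    filtered, _ = ow.filter_missing(cohort)
    return filtered, truth


@pytest.fixture()
def toy_tables(tmp_path):
    """A 4-sample x 3-metabolite CSV pair with matching ids."""
    abundance = tmp_path / "abundance.csv"
    metadata = tmp_path / "metadata.csv"
    abundance.write_text(
        "sample_id,M1,M2,M3\n"
        "S1,1.0,2.0,3.0\n"
        "S2,1.5,2.5,3.5\n"
        "S3,0.5,1.5,2.5\n"
        "S4,2.0,3.0,4.0\n"
    )
    metadata.write_text(
        "sample_id,gender,stage\n"
        "S1,female,control\n"
        "S2,female,control\n"
        "S3,female,osteopenia\n"
        "S4,female,osteoporosis\n"
    )
    return abundance, metadata


def make_cohort(abundance: np.ndarray, stages, metadata_extra=None) -> ow.Cohort:
    """Build a small in-memory cohort from an array and stage labels."""
    n, p = abundance.shape
    idx = pd.Index([f"S{i:04d}" for i in range(n)])
    cols = [f"M{i:03d}" for i in range(p)]
    meta = pd.DataFrame({"stage": list(stages)}, index=idx)
    if metadata_extra:
        for k, v in metadata_extra.items():
            meta[k] = v
    return ow.Cohort(pd.DataFrame(abundance, index=idx, columns=cols), meta)
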