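import numpy as np
import pandas as pd
import pytest

from rarecell import synthetic
from rarecell.assays import SampleMeta


@pytest.fixture(scope="session")
def small_cohort():
    """A 4 SCLC + 3 ND cohort at the default abundance calibration."""
    spec = synthetic.CohortSpec(n_sclc=4, n_nd=3, seed=11)
    meta, events = synthetic.generate_cohort(spec)
    return spec, meta, events


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_events(groups_and_counts, sample_id="S1", assay="landscape", seed=0):
    """Hand-built event table: intensities engineered per group name.

    ``groups_and_counts``: list of (group_name, n_events). Positive markers
    get intensity 300, negatives 50, DAPI 400 (static gates at 100).
    """
    from rarecell.assays import ASSAY_MARKERS

    markers = ASSAY_MARKERS[assay]
    rows = []
    i = 0
    for group, n in groups_and_counts:
        parts = group.split("|") if group != "DAPI" else []
        for _ in range(n):
            row = {
                "cell_id": f"{sample_id}-c{i:04d}",
                "sample_id": sample_id,
                "slide_id": f"{sample_id}-S1",
                "dapi": 400.0,
            }
            for col, disp in markers:
                row[col] = 300.0 if disp in parts else 50.0
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture
def meta_one_sample():
    return [SampleMeta("S1", "SCLC", volume_ml=1.0, nucleated_cells=4_000_000)]
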