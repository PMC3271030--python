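import warnings

import numpy as np
import pandas as pd
import pytest

from healthspace import (
    ResponseClustering,
    SampleTable,
    SimulationConfig,
    build_health_space,
    default_axes,
    generate_study,
)


def make_table(records, parameters):
    """Build a SampleTable from (subject, arm, timepoint, values...) tuples."""
    meta = pd.DataFrame(
        [r[:3] for r in records], columns=["subject_id", "arm", "timepoint"]
    )
    values = pd.DataFrame([r[3:] for r in records], columns=parameters)
    return SampleTable(values, meta)


@pytest.fixture
def small_table():
    """4 complete subjects x 2 arms x 2 timepoints, 3 parameters."""
    rng = np.random.default_rng(11)
    records = []
    for s in ["s1", "s2", "s3", "s4"]:
        for arm in ["treated", "control"]:
            for tp in ["t0", "t1"]:
                records.append((s, arm, tp, *rng.normal(size=3)))
    return make_table(records, ["CRP", "IL6", "GSH"])


@pytest.fixture
def tiny_config():
    """Reduced three-process study used where only mechanics are under test."""
    return SimulationConfig(
        n_subjects=14,
        blocks={"oxidation": 3, "inflammation": 4, "metabolism": 6},
        seed=7,
    )


@pytest.fixture(scope="session")
def fitted_pipeline():
    """One fitted pipeline (space + clustering) shared across read-only tests."""
    cfg = SimulationConfig(
        n_subjects=16,
        blocks={"oxidation": 4, "inflammation": 5, "metabolism": 8},
        effect_size=2.0,
        seed=13,
    )
    table, truth = generate_study(cfg)
    axes = default_axes(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, scores = build_health_space(table, axes, seed=5)
        clusterer = ResponseClustering(n_clusters=2).fit(scores)
    return {
        "config": cfg,
        "table": table,
        "truth": truth,
        "axes": axes,
        "model": model,
        "scores": scores,
        "clusterer": clusterer,
    }
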