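"""Shared fixtures: synthetic study data and the full-scale reference fit.

The expensive pieces (the 173-subject dataset and its mixed-effects fit) are
session-scoped so the recovery, diagnostics and acceptance tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popkin import estimation, population, synth
from popkin.dataset import Dataset, apply_lloq_filter

STUDY_SEED = 101


def perturbed_start(model: population.PopulationModel, factor: float = 1.5):
    """Starting values: generative typical values perturbed by ``factor``."""
    typ = {k: v * factor for k, v in model.typical_values().items()}
    return population.PopulationModel.from_typical(
        typ, model.omega, min(model.sigma * factor, 0.5), model.covariate_effects
    )


@pytest.fixture(scope="session")
def study_dataset() -> Dataset:
    """Study-scale synthetic trial (173 subjects), LLOQ-censored."""
    ds = synth.simulate_preset("pooled-study-like", STUDY_SEED)
    ds, removed = apply_lloq_filter(ds, synth.DEFAULT_LLOQ)
    assert removed == 19
    return ds


@pytest.fixture(scope="session")
def study_fit(study_dataset) -> estimation.FitResult:
    """Reference full-scale fit, started from x1.5-perturbed truth."""
    start = perturbed_start(population.final_model())
    return estimation.fit(start, study_dataset)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """40-subject dataset for fast fitting tests."""
    ds = synth.simulate_preset("pooled-study-like", 7, n_subjects=40, plant_blq=0)
    return ds


def toy_frame(n_subjects: int = 2) -> pd.DataFrame:
    """Tiny canonical event table: 1 dose + 2 observations per subject."""
    rows = []
    for i in range(n_subjects):
        sid = f"T{i + 1}"
        cov = dict(WT=60.0 + 5 * i, ALB=38.0, SEX="M", THERAPY="mono")
        rows.append(dict(ID=sid, TIME=0.0, EVID=1, AMT=900.0, DUR=0.0208, DV=np.nan, MDV=1, **cov))
        rows.append(dict(ID=sid, TIME=1.0, EVID=0, AMT=0.0, DUR=0.0, DV=200.0, MDV=0, **cov))
        rows.append(dict(ID=sid, TIME=7.0, EVID=0, AMT=0.0, DUR=0.0, DV=120.0, MDV=0, **cov))
    return pd.DataFrame(rows)
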