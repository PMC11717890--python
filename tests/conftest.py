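"""Shared fixtures: small seeded phantom studies and a trained model.

Everything is generated in memory at test time; session scope keeps the
expensive training run to a single execution.
"""

import numpy as np
import pytest

import hsifob as h


@pytest.fixture(scope="session")
def small_study():
    """A 16-case, 2-areas-per-case training-style phantom study."""
    return h.generate_study(n_cases=16, areas_per_case=2, seed=42)


@pytest.fixture(scope="session")
def study_cubes(small_study):
    return {c.case_id: h.calibrate_reflectance(c.raw, c.white)
            for c in small_study.cases}


@pytest.fixture(scope="session")
def study_areas(small_study):
    return [{"case_id": cid, "area_id": aid, "mask": m, "fit_ng_ml": f}
            for cid, aid, m, f in small_study.areas()]


@pytest.fixture(scope="session")
def training_set(study_areas, study_cubes):
    return h.assemble_training_set(study_areas, study_cubes,
                                   h.PreprocessConfig())


@pytest.fixture(scope="session")
def trained_model(training_set, study_cubes, study_areas):
    model = h.sequential_backward_elimination(
        training_set, min_bands=6, seed=42,
        start_bands=np.arange(0, 121, 4))
    return h.calibrate_decision_threshold(model, study_cubes, study_areas)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
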