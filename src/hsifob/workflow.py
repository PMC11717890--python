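"""High-level workflows tying the pipeline stages together.

These are the programmatic equivalents of the two study phases: fit the
band-selected discriminator on a training batch of areas + FIT values, and
score a batch of captures area-by-area (or pattern-by-pattern) against
quantitative FIT.
"""

from __future__ import annotations

import numpy as np

from .decision import (aggregate_case, classify_pattern, judge_area,
                       select_validation_areas)
from .diagnostics import ContingencyTable, DiagnosticMetrics, \
    diagnostic_metrics, make_contingency
from .hypercube import calibrate_reflectance
from .model import (TrainedDiscriminator, assemble_training_set,
                    calibrate_decision_threshold, classify_cube,
                    sequential_backward_elimination)
from .phantom import StudyFixture, simulate_fit_values
from .preprocess import PreprocessConfig

__all__ = ["train_on_study", "evaluate_per_area", "evaluate_validation_batch"]


def _calibrated(fixture: StudyFixture) -> dict:
    return {c.case_id: calibrate_reflectance(c.raw, c.white)
            for c in fixture.cases}


def _area_records(fixture: StudyFixture) -> list:
    return [{"case_id": cid, "area_id": aid, "mask": mask, "fit_ng_ml": fit}
            for cid, aid, mask, fit in fixture.areas()]


def train_on_study(fixture: StudyFixture, config: PreprocessConfig | None = None,
                   min_bands: int = 6, band_step: int = 3, seed: int = 0,
                   kernel: str = "rbf", c_param: float = 1.0,
                   ) -> TrainedDiscriminator:
    """Fit the discriminator on a training-style phantom study.

    Band elimination starts from every ``band_step``-th band of the grid
    (a coarse sub-grid keeps the wrapper search tractable at full fidelity
    of the wavelength axis); the decision threshold is then calibrated at
    the area-judging operating point.
    """
    cubes = _calibrated(fixture)
    areas = _area_records(fixture)
    config = config or PreprocessConfig()
    ts = assemble_training_set(areas, cubes, config,
                               cutoff=fixture.cutoff_ng_ml)
    model = sequential_backward_elimination(
        ts, min_bands=min_bands, seed=seed, kernel=kernel, c_param=c_param,
        start_bands=np.arange(0, ts.spectra.shape[1], band_step))
    return calibrate_decision_threshold(model, cubes, areas)


def evaluate_per_area(model: TrainedDiscriminator, fixture: StudyFixture,
                      min_positive_fraction: float = 0.05,
                      ) -> tuple[ContingencyTable, DiagnosticMetrics]:
    """Judge every sampled area of a study and tabulate against FIT."""
    records = []
    for case in fixture.cases:
        refl = calibrate_reflectance(case.raw, case.white)
        img = classify_cube(refl, model)
        for aid, mask, fit in zip(case.area_ids, case.area_masks,
                                  case.fit_values):
            records.append({
                "algorithm_call": judge_area(img, mask,
                                             min_positive_fraction),
                "fit_ng_ml": float(fit),
            })
    table = make_contingency(records, cutoff=fixture.cutoff_ng_ml)
    return table, diagnostic_metrics(table)


def evaluate_validation_batch(model: TrainedDiscriminator,
                              fixture: StudyFixture, area_radius: float = 4.0,
                              seed: int = 0, fit_noise_cv: float = 0.15,
                              ) -> dict:
    """Replay the validation protocol on a pattern-composition study.

    Each capture is classified, its pattern determined, the five
    validation areas drawn by the pattern rule, their FIT values measured
    (simulated from the ground-truth hemoglobin load), and the per-area and
    per-case 2x2 concordance assembled.
    """
    rng = np.random.default_rng(seed)
    patterns = []
    area_records = []
    case_records = []
    for case in fixture.cases:
        refl = calibrate_reflectance(case.raw, case.white)
        img = classify_cube(refl, model)
        pattern = classify_pattern(img, case.stool_mask)
        patterns.append(pattern.value)
        areas = select_validation_areas(img, case.stool_mask, pattern,
                                        case_id=case.case_id,
                                        radius=area_radius,
                                        seed=int(rng.integers(2 ** 31)))
        fits = simulate_fit_values(case.truth_map,
                                   [a.mask for a in areas],
                                   gain=fixture.gain, noise_cv=fit_noise_cv,
                                   seed=int(rng.integers(2 ** 31)))
        for a, fit in zip(areas, fits):
            a.fit_ng_ml = float(fit)
            area_records.append({"algorithm_call": a.algorithm_call,
                                 "fit_ng_ml": float(fit)})
        case_records.append({
            "algorithm_call": aggregate_case(areas, by="algorithm"),
            "fit_ng_ml": max(float(f) for f in fits),
        })
    area_table = make_contingency(area_records, cutoff=fixture.cutoff_ng_ml)
    case_table = make_contingency(case_records, cutoff=fixture.cutoff_ng_ml)
    return {
        "patterns": patterns,
        "area_table": area_table,
        "area_metrics": diagnostic_metrics(area_table),
        "case_table": case_table,
        "case_metrics": diagnostic_metrics(case_table),
    }
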