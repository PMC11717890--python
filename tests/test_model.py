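"""Training-set assembly, SVM wrapper selection, cube classification,
model persistence."""

import numpy as np
import pytest

import hsifob as h
from hsifob.model import _cv_folds, _cv_accuracy, _standardize
from hsifob.preprocess import PreprocessConfig


def toy_training_set(x, y, wavelengths=None):
    """Wrap a plain matrix as a TrainingSet (no preprocessing provenance)."""
    n, b = x.shape
    return h.TrainingSet(
        spectra=x, labels=y, area_ids=[f"t/{i}" for i in range(n)],
        training_mean=np.zeros(b), preprocess=PreprocessConfig(steps=()),
        wavelengths=(np.arange(b, dtype=float) if wavelengths is None
                     else wavelengths))


def separable_set(rng, n=40, b=6, informative=3):
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(0, 1.0, (n, b))
    x[:, informative] += 6.0 * y
    return toy_training_set(x, y)


class TestAssembleTrainingSet:
    def test_labels_match_cutoff(self, study_areas, study_cubes):
        ts = h.assemble_training_set(study_areas, study_cubes,
                                     h.PreprocessConfig(), cutoff=400.0)
        expected = np.array([a["fit_ng_ml"] >= 400.0 for a in study_areas],
                            int)
        np.testing.assert_array_equal(ts.labels, expected)
        assert ts.spectra.shape == (len(study_areas), 121)
        assert ts.training_mean.shape == (121,)

    def test_boundary_fit_is_positive(self, study_areas, study_cubes):
        areas = [dict(a) for a in study_areas]
        areas[0]["fit_ng_ml"] = 400.0
        ts = h.assemble_training_set(areas, study_cubes, h.PreprocessConfig())
        assert ts.labels[0] == 1

    def test_missing_cube_is_an_error(self, study_areas, study_cubes):
        areas = [dict(study_areas[0], case_id="ghost")] + study_areas[1:]
        with pytest.raises(ValueError, match="missing cube"):
            h.assemble_training_set(areas, study_cubes, h.PreprocessConfig())

    def test_single_class_rejected(self, study_areas, study_cubes):
        areas = [dict(a, fit_ng_ml=10.0) for a in study_areas]
        with pytest.raises(ValueError, match="both classes"):
            h.assemble_training_set(areas, study_cubes, h.PreprocessConfig())


class TestTrainSvm:
    def test_separable_toy_reaches_perfect_cv(self, rng):
        ts = separable_set(rng)
        _, acc = h.train_svm(ts, seed=0)
        assert acc == 1.0

    def test_shuffled_labels_score_near_chance(self, rng):
        ts = separable_set(rng)
        y = ts.labels.copy()
        rng.shuffle(y)
        ts_null = toy_training_set(ts.spectra, y)
        _, acc = h.train_svm(ts_null, seed=0)
        assert 0.3 <= acc <= 0.7

    def test_phantom_training_set_is_learnable(self):
        # full 121-band CV accuracy at the study scale (100 areas)
        fix = h.generate_study(n_cases=50, areas_per_case=2, seed=0)
        cubes = {c.case_id: h.calibrate_reflectance(c.raw, c.white)
                 for c in fix.cases}
        areas = [{"case_id": cid, "area_id": aid, "mask": m, "fit_ng_ml": f}
                 for cid, aid, m, f in fix.areas()]
        ts = h.assemble_training_set(areas, cubes, h.PreprocessConfig())
        _, acc = h.train_svm(ts, seed=0)
        assert acc >= 0.9

    def test_fold_reduction_warns(self, rng):
        x = rng.normal(0, 1, (10, 4))
        y = np.array([0] * 7 + [1] * 3)
        x[:, 0] += 5 * y
        ts = toy_training_set(x, y)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            h.train_svm(ts, k_folds=5, seed=0)


class TestSequentialBackwardElimination:
    def test_informative_band_survives_and_matches_exhaustive(self, rng):
        """On 6-band toys with one informative band, SBE never discards it
        and its final criterion is near the exhaustive best-subset optimum."""
        from itertools import combinations

        n_ok = 0
        for seed in range(6):
            r = np.random.default_rng(seed)
            ts = separable_set(r, n=30, b=6, informative=3)
            model = h.sequential_backward_elimination(ts, min_bands=1,
                                                      tolerance=0.0,
                                                      kernel="linear",
                                                      seed=seed)
            assert 3 in model.selected_bands
            folds = _cv_folds(ts.labels, 5, seed)
            z, _, _ = _standardize(ts.spectra)
            best = max(
                _cv_accuracy(z[:, list(sub)], ts.labels, folds, "linear",
                             1.0, seed)
                for size in range(1, 7)
                for sub in combinations(range(6), size))
            n_ok += model.cv_accuracy >= 0.95 * best
        assert n_ok >= 5

    def test_exchangeable_bands_run_to_min_bands(self, rng):
        y = np.repeat([0, 1], 20)
        signal = np.where(y, 3.0, -3.0) + rng.normal(0, 0.3, 40)
        x = np.tile(signal[:, None], (1, 6))
        ts = toy_training_set(x, y)
        model = h.sequential_backward_elimination(ts, min_bands=2,
                                                  tolerance=0.01, seed=0)
        assert model.selected_bands.size == 2
        assert len(model.selection_history) == 4

    def test_tie_break_removes_lowest_index_first(self, rng):
        y = np.repeat([0, 1], 20)
        signal = np.where(y, 3.0, -3.0)
        x = np.tile(signal[:, None], (1, 4))  # identical bands, exact ties
        ts = toy_training_set(x, y)
        model = h.sequential_backward_elimination(ts, min_bands=1,
                                                  tolerance=0.01, seed=0)
        assert [b for b, _ in model.selection_history] == [0, 1, 2]
        assert model.selected_bands.tolist() == [3]

    def test_history_bookkeeping(self, trained_model):
        start = 31  # every-4th-band start grid on the 121-band grid
        assert len(trained_model.selection_history) == \
            start - trained_model.selected_bands.size
        assert np.all(np.diff(trained_model.selected_bands) > 0)

    def test_determinism(self, rng):
        ts = separable_set(rng, n=30)
        runs = [h.sequential_backward_elimination(ts, min_bands=2, seed=5)
                for _ in range(2)]
        np.testing.assert_array_equal(runs[0].selected_bands,
                                      runs[1].selected_bands)
        assert runs[0].selection_history == runs[1].selection_history
        np.testing.assert_array_equal(runs[0].dual_coef, runs[1].dual_coef)


class TestClassifyCube:
    def test_training_point_consistency(self, small_study, study_cubes,
                                        trained_model, training_set):
        """Pixels drawn from well-separated training areas score on the
        correct side of the threshold."""
        z = (training_set.spectra - trained_model.feature_mean) \
            / trained_model.feature_scale
        scores = trained_model.decision_function(
            z[:, trained_model.selected_bands])
        margin = 1.0
        hi = scores > trained_model.decision_threshold + margin
        lo = scores < trained_model.decision_threshold - margin
        assert hi.any() and lo.any()
        assert training_set.labels[hi].mean() > 0.5
        assert training_set.labels[lo].mean() < 0.5

    def test_blood_disc_recovered(self, trained_model):
        """Median IoU between the on-stool detected region and the true
        blood disc across ten captures; the stool intersection reflects the
        decision rule (a detection counts when it lies on the stool)."""
        ious = []
        for seed in range(70, 80):
            spec = h.PhantomSpec(
                blood_regions=(h.BloodRegion((24, 24), 10, 0.5),), seed=seed)
            raw, white, dark, stool, truth = h.generate_stool_phantom(spec)
            img = h.classify_cube(h.calibrate_reflectance(raw, white),
                                  trained_model)
            blood = truth > 0
            pos = img.positives & stool.pixels
            ious.append((pos & blood).sum() / (pos | blood).sum())
        assert np.median(ious) >= 0.7

    def test_wavelength_mismatch_rejected(self, trained_model, rng):
        grid = h.WavelengthGrid(np.linspace(350, 900, 121))
        cube = h.Hypercube(rng.random((4, 4, 121)), grid, kind="reflectance")
        with pytest.raises(ValueError, match="wavelength"):
            h.classify_cube(cube, trained_model)

    def test_requires_reflectance(self, trained_model, rng):
        cube = h.Hypercube(rng.random((4, 4, 121)),
                           h.WavelengthGrid.default(), kind="raw")
        with pytest.raises(ValueError, match="reflectance"):
            h.classify_cube(cube, trained_model)


class TestPersistence:
    def test_round_trip_preserves_scores(self, trained_model, tmp_path,
                                         small_study, study_cubes):
        path = tmp_path / "model.json"
        h.save_model(trained_model, path)
        back = h.load_model(path)
        np.testing.assert_array_equal(back.selected_bands,
                                      trained_model.selected_bands)
        assert back.preprocess == trained_model.preprocess
        cube = study_cubes[small_study.cases[0].case_id]
        img_a = h.classify_cube(cube, trained_model)
        img_b = h.classify_cube(cube, back)
        np.testing.assert_array_equal(img_a.scores, img_b.scores)
        np.testing.assert_array_equal(img_a.positives, img_b.positives)

    def test_tampering_detected(self, trained_model, tmp_path):
        path = tmp_path / "model.json"
        h.save_model(trained_model, path)
        text = path.read_text()
        # corrupt one digit inside the payload
        idx = text.find('"intercept":') + len('"intercept": ') + 2
        corrupted = text[:idx] + ("7" if text[idx] != "7" else "3") \
            + text[idx + 1:]
        path.write_text(corrupted)
        with pytest.raises(ValueError, match="integrity|corrupted"):
            h.load_model(path)

    def test_version_checked(self, trained_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        h.save_model(trained_model, path)
        wrapper = json.loads(path.read_text())
        wrapper["model"]["format_version"] = "hsifob-model-0"
        body = json.dumps(wrapper["model"], sort_keys=True)
        import hashlib

        wrapper["digest"] = hashlib.sha256(body.encode()).hexdigest()
        path.write_text(json.dumps(wrapper, sort_keys=True))
        with pytest.raises(ValueError, match="format"):
            h.load_model(path)
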