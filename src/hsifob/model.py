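"""Band-selected support-vector discrimination of high-FIT spectra.

Training operates on one ROI-mean spectrum per sampling area (labels exist
only per area); inference scores every pixel of a reflectance cube.  Band
selection is a sequential-backward-elimination wrapper around a stratified
cross-validated SVM accuracy criterion: starting from the full band set,
the band whose removal best preserves (or most improves) the criterion is
dropped, until a minimum band count is reached or the criterion falls more
than a tolerance below the best seen so far.

The cross-validation fold assignment is fixed once per elimination run
(seeded), so criterion comparisons between candidate subsets are paired
and the whole procedure is deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .hypercube import Hypercube, RoiMask, extract_roi_spectrum
from .preprocess import (PreprocessConfig, apply_pipeline, partial_config)

__all__ = [
    "TrainingSet",
    "TrainedDiscriminator",
    "DiscriminantImage",
    "assemble_training_set",
    "train_svm",
    "sequential_backward_elimination",
    "classify_cube",
    "calibrate_decision_threshold",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "hsifob-model-1"


@dataclass
class TrainingSet:
    """Preprocessed per-area spectra with binary high-FIT labels."""

    spectra: np.ndarray            # (n_areas, n_bands)
    labels: np.ndarray             # 1 = FIT >= cutoff
    area_ids: list
    cutoff_ng_ml: float = 400.0
    training_mean: np.ndarray | None = None  # MSC reference actually used
    preprocess: PreprocessConfig | None = None
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, float)
        self.labels = np.asarray(self.labels, int)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a (n_areas, n_bands) matrix")
        if len(self.labels) != len(self.spectra) or \
                len(self.area_ids) != len(self.spectra):
            raise ValueError("spectra, labels and area_ids lengths differ")
        classes = set(self.labels.tolist())
        if classes != {0, 1}:
            raise ValueError(
                f"both classes must be present, got labels {sorted(classes)}"
            )
        if self.cutoff_ng_ml <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class TrainedDiscriminator:
    """Everything needed to score a cube: preprocessing, bands, SVM, threshold.

    ``feature_mean``/``feature_scale`` are the per-band standardization
    parameters fitted on the preprocessed training matrix; second-derivative
    features are orders of magnitude smaller than reflectance, and the SVM
    margin is only meaningful on a standardized scale.
    """

    preprocess: PreprocessConfig
    training_mean: np.ndarray
    feature_mean: np.ndarray            # per-band standardizer (full grid)
    feature_scale: np.ndarray
    selected_bands: np.ndarray          # sorted band indices into the grid
    kernel: str
    c_param: float
    gamma: float | str
    support_vectors: np.ndarray         # restricted to selected bands
    dual_coef: np.ndarray
    intercept: float
    decision_threshold: float
    selection_history: list             # [(removed_band, criterion), ...]
    cv_accuracy: float
    wavelengths: np.ndarray
    cutoff_ng_ml: float
    seed: int
    format_version: str = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        bands = np.asarray(self.selected_bands, int)
        if bands.size == 0:
            raise ValueError("selected_bands must be non-empty")
        if not np.all(np.diff(bands) > 0):
            raise ValueError("selected_bands must be strictly increasing")
        if bands.max() >= len(self.wavelengths):
            raise ValueError("band index exceeds wavelength grid")
        self.selected_bands = bands

    def decision_function(self, spectra: np.ndarray) -> np.ndarray:
        """SVM margin scores for already-preprocessed, band-restricted rows."""
        x = np.atleast_2d(np.asarray(spectra, float))
        sv = self.support_vectors
        if self.kernel == "linear":
            k = x @ sv.T
        elif self.kernel == "rbf":
            g = float(self.gamma)
            d2 = (np.sum(x ** 2, axis=1)[:, None] + np.sum(sv ** 2, axis=1)[None]
                  - 2.0 * x @ sv.T)
            k = np.exp(-g * d2)
        else:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        return k @ self.dual_coef.ravel() + self.intercept

    @property
    def selected_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.selected_bands]


@dataclass
class DiscriminantImage:
    """Per-pixel margin scores and thresholded positives for one capture."""

    scores: np.ndarray
    positives: np.ndarray
    decision_threshold: float
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.positives = np.asarray(self.positives, bool)
        if self.scores.shape != self.positives.shape:
            raise ValueError("scores/positives shape mismatch")
        if not np.array_equal(self.positives,
                              self.scores > self.decision_threshold):
            raise ValueError("positives must equal scores > threshold exactly")


def assemble_training_set(areas, cubes: dict, config: PreprocessConfig,
                          cutoff: float = 400.0) -> TrainingSet:
    """Build the training matrix from sampling areas and calibrated cubes.

    ``areas`` is an iterable of objects/mappings with ``case_id``,
    ``area_id``, ``mask`` (RoiMask) and ``fit_ng_ml``; ``cubes`` maps
    case_id to its calibrated reflectance cube.  Each area contributes its
    ROI-mean spectrum, preprocessed with ``config``; the label is
    FIT >= cutoff.  The mean of the partially preprocessed spectra (steps
    before MSC) is recorded as the MSC training reference.
    """
    recs = []
    for a in areas:
        get = a.get if isinstance(a, dict) else lambda k, _a=a: getattr(_a, k)
        recs.append((get("case_id"), get("area_id"), get("mask"),
                     float(get("fit_ng_ml"))))
    if not recs:
        raise ValueError("no sampling areas supplied")
    raw_spectra, ids, labels = [], [], []
    wavelengths = None
    for case_id, area_id, mask, fit in recs:
        cube = cubes.get(case_id)
        if cube is None:
            raise ValueError(f"area {case_id}/{area_id} references a missing cube")
        raw_spectra.append(extract_roi_spectrum(cube, mask, reducer="mean"))
        ids.append(f"{case_id}/{area_id}")
        labels.append(1 if fit >= cutoff else 0)
        wavelengths = cube.wavelengths.values
    raw = np.vstack(raw_spectra)

    # MSC reference = mean of training spectra after the steps preceding MSC
    pre_msc = apply_pipeline(raw, partial_config(config, "msc"))
    training_mean = pre_msc.mean(axis=0)
    spectra = apply_pipeline(raw, config, training_mean=training_mean)
    return TrainingSet(spectra=spectra, labels=np.array(labels),
                       area_ids=ids, cutoff_ng_ml=cutoff,
                       training_mean=training_mean, preprocess=config,
                       wavelengths=wavelengths)


def _standardize(spectra: np.ndarray):
    """Per-band z-scoring of the preprocessed training matrix."""
    mean = spectra.mean(axis=0)
    scale = spectra.std(axis=0, ddof=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return (spectra - mean) / scale, mean, scale


def _make_svm(kernel: str, c_param: float, seed: int) -> SVC:
    return SVC(kernel=kernel, C=c_param, gamma="scale",
               class_weight="balanced", random_state=seed)


def _cv_folds(labels: np.ndarray, k: int, seed: int):
    """Fixed stratified fold assignment; k is reduced if a class is small."""
    smallest = int(np.bincount(labels).min())
    k_eff = min(k, smallest)
    if k_eff < k:
        import warnings
        warnings.warn(f"reducing CV folds from {k} to {k_eff} "
                      f"(smallest class has {smallest} samples)")
    if k_eff < 2:
        raise ValueError("need at least 2 samples per class for CV")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _cv_accuracy(x: np.ndarray, y: np.ndarray, folds, kernel: str,
                 c_param: float, seed: int) -> float:
    correct = 0
    for train_idx, test_idx in folds:
        clf = _make_svm(kernel, c_param, seed)
        clf.fit(x[train_idx], y[train_idx])
        correct += int(np.sum(clf.predict(x[test_idx]) == y[test_idx]))
    return correct / len(y)


def train_svm(ts: TrainingSet, bands=None, kernel: str = "rbf",
              c_param: float = 1.0, k_folds: int = 5, seed: int = 0):
    """Fit the SVM on the given band subset; report CV accuracy.

    Returns (fitted sklearn SVC, stratified k-fold CV accuracy).
    """
    if bands is None:
        bands = np.arange(ts.spectra.shape[1])
    bands = np.asarray(bands, int)
    z, _, _ = _standardize(ts.spectra)
    x = z[:, bands]
    y = ts.labels
    if int(np.bincount(y).min()) < 2:
        raise ValueError("need >= 2 samples per class")
    folds = _cv_folds(y, k_folds, seed)
    acc = _cv_accuracy(x, y, folds, kernel, c_param, seed)
    clf = _make_svm(kernel, c_param, seed)
    clf.fit(x, y)
    return clf, acc


def sequential_backward_elimination(ts: TrainingSet, min_bands: int = 10,
                                    tolerance: float = 0.01,
                                    kernel: str = "rbf",
                                    c_param: float = 1.0,
                                    k_folds: int = 5, seed: int = 0,
                                    start_bands=None,
                                    decision_threshold: float = 0.0,
                                    ) -> TrainedDiscriminator:
    """Greedy wrapper band selection.

    From the starting band set (all bands by default), repeatedly remove
    the single band whose removal maximizes the CV-accuracy criterion
    (ties break toward the lowest band index), stopping at ``min_bands``
    or when even the best candidate falls more than ``tolerance`` below
    the best criterion seen on the elimination path.
    """
    if min_bands < 1:
        raise ValueError("min_bands must be >= 1")
    n_total = ts.spectra.shape[1]
    bands = (np.arange(n_total) if start_bands is None
             else np.asarray(sorted(start_bands), int))
    y = ts.labels
    folds = _cv_folds(y, k_folds, seed)
    z, feature_mean, feature_scale = _standardize(ts.spectra)

    def criterion(subset: np.ndarray) -> float:
        return _cv_accuracy(z[:, subset], y, folds, kernel, c_param, seed)

    history: list = []
    current = criterion(bands)
    best_seen = current
    while bands.size > min_bands:
        best_acc, best_pos = -np.inf, None
        for pos in range(bands.size):
            subset = np.delete(bands, pos)
            acc = criterion(subset)
            # strict > keeps the first (lowest-index) band on ties
            if acc > best_acc:
                best_acc, best_pos = acc, pos
        if best_acc < best_seen - tolerance:
            break
        history.append((int(bands[best_pos]), float(best_acc)))
        bands = np.delete(bands, best_pos)
        best_seen = max(best_seen, best_acc)
        current = best_acc

    clf = _make_svm(kernel, c_param, seed)
    clf.fit(z[:, bands], y)
    gamma = clf._gamma if kernel == "rbf" else "scale"
    if ts.preprocess is None or ts.training_mean is None:
        raise ValueError("training set lacks preprocessing provenance")
    return TrainedDiscriminator(
        preprocess=ts.preprocess,
        training_mean=np.asarray(ts.training_mean, float),
        feature_mean=feature_mean, feature_scale=feature_scale,
        selected_bands=np.sort(bands),
        kernel=kernel, c_param=c_param,
        gamma=float(gamma) if kernel == "rbf" else "scale",
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.copy(),
        intercept=float(clf.intercept_[0]),
        decision_threshold=decision_threshold,
        selection_history=history,
        cv_accuracy=float(current),
        wavelengths=(ts.wavelengths if ts.wavelengths is not None
                     else np.arange(n_total, dtype=float)),
        cutoff_ng_ml=ts.cutoff_ng_ml,
        seed=seed,
    )


def calibrate_decision_threshold(model: TrainedDiscriminator, cubes: dict,
                                 areas, cutoff: float | None = None,
                                 min_positive_fraction: float = 0.05,
                                 ) -> TrainedDiscriminator:
    """Choose the margin threshold that best separates areas at the
    area-judging rule.

    Training happens on area-mean spectra, whose noise is far below that
    of single pixels, so the default margin threshold of 0 is not a
    meaningful pixel-level operating point.  An area is later judged
    positive when at least ``min_positive_fraction`` of its pixels exceed
    the threshold; equivalently, when the area's k-th largest pixel score
    (k = ceil(fraction * pixels)) exceeds it.  This calibration scores the
    training cubes, computes that order statistic for every training area,
    and places the threshold midway between the two adjacent statistics
    that maximize Youden's J (sensitivity + specificity - 1) against the
    FIT labels; ties resolve toward the higher threshold (fewer false
    positives).  Deterministic; mutates and returns the model.
    """
    if cutoff is None:
        cutoff = model.cutoff_ng_ml
    stats, labels = [], []
    img_cache: dict = {}
    for a in areas:
        get = a.get if isinstance(a, dict) else lambda k, _a=a: getattr(_a, k)
        cid = get("case_id")
        if cid not in img_cache:
            img_cache[cid] = classify_cube(cubes[cid], model)
        px = img_cache[cid].scores[get("mask").pixels]
        k = max(1, int(np.ceil(min_positive_fraction * px.size)))
        stats.append(float(np.sort(px)[-k]))
        labels.append(float(get("fit_ng_ml")) >= cutoff)
    stats = np.asarray(stats)
    labels = np.asarray(labels, bool)
    if not labels.any() or labels.all():
        raise ValueError("threshold calibration needs both FIT classes")
    order = np.argsort(stats)
    s, y = stats[order], labels[order]
    # candidate thresholds between consecutive order statistics (+ extremes)
    cands = np.concatenate(([s[0] - 1.0], (s[:-1] + s[1:]) / 2.0,
                            [s[-1] + 1.0]))
    n_pos, n_neg = labels.sum(), (~labels).sum()
    js = np.array([((stats > thr) & labels).sum() / n_pos
                   + (~(stats > thr) & ~labels).sum() / n_neg - 1.0
                   for thr in cands])
    # the empirical J curve is jagged on ~100 areas; taking the median of
    # all near-optimal candidates is markedly more stable across samples
    # than the raw argmax
    near = cands[js >= js.max() - 0.02]
    model.decision_threshold = float(np.median(near))
    return model


def classify_cube(cube: Hypercube, model: TrainedDiscriminator
                  ) -> DiscriminantImage:
    """Score every pixel of a calibrated cube with the stored pipeline."""
    if cube.kind != "reflectance":
        raise ValueError("classify_cube expects a calibrated reflectance cube")
    if cube.n_bands != len(model.wavelengths) or not np.allclose(
            cube.wavelengths.values, model.wavelengths, atol=1e-6):
        raise ValueError("cube wavelength grid does not match the model's")
    rows, cols, _ = cube.shape
    flat = cube.data.reshape(-1, cube.n_bands)
    pre = apply_pipeline(flat, model.preprocess,
                         training_mean=model.training_mean)
    z = (pre - model.feature_mean) / model.feature_scale
    scores = model.decision_function(z[:, model.selected_bands])
    scores = scores.reshape(rows, cols)
    return DiscriminantImage(scores=scores,
                             positives=scores > model.decision_threshold,
                             decision_threshold=model.decision_threshold,
                             source_meta=dict(cube.meta))


# ---------------------------------------------------------------------------
# Model persistence: single JSON archive with an integrity digest

def _model_payload(model: TrainedDiscriminator) -> dict:
    return {
        "format_version": model.format_version,
        "preprocess": model.preprocess.to_text(),
        "training_mean": model.training_mean.tolist(),
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "selected_bands": model.selected_bands.tolist(),
        "kernel": model.kernel,
        "c_param": model.c_param,
        "gamma": model.gamma,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "decision_threshold": model.decision_threshold,
        "selection_history": [[b, c] for b, c in model.selection_history],
        "cv_accuracy": model.cv_accuracy,
        "wavelengths": model.wavelengths.tolist(),
        "cutoff_ng_ml": model.cutoff_ng_ml,
        "seed": model.seed,
    }


def save_model(model: TrainedDiscriminator, path) -> None:
    body = json.dumps(_model_payload(model), sort_keys=True)
    digest = hashlib.sha256(body.encode()).hexdigest()
    with open(path, "w") as fh:
        json.dump({"digest": digest, "model": json.loads(body)}, fh,
                  sort_keys=True)


def load_model(path) -> TrainedDiscriminator:
    with open(path) as fh:
        try:
            wrapper = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted model file: {exc}") from exc
    if set(wrapper) != {"digest", "model"}:
        raise ValueError("corrupted model file: unexpected layout")
    body = json.dumps(wrapper["model"], sort_keys=True)
    if hashlib.sha256(body.encode()).hexdigest() != wrapper["digest"]:
        raise ValueError("corrupted model file: integrity digest mismatch")
    d = wrapper["model"]
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format {d.get('format_version')!r}"
        )
    return TrainedDiscriminator(
        preprocess=PreprocessConfig.from_text(d["preprocess"]),
        training_mean=np.asarray(d["training_mean"], float),
        feature_mean=np.asarray(d["feature_mean"], float),
        feature_scale=np.asarray(d["feature_scale"], float),
        selected_bands=np.asarray(d["selected_bands"], int),
        kernel=d["kernel"], c_param=float(d["c_param"]),
        gamma=d["gamma"],
        support_vectors=np.asarray(d["support_vectors"], float),
        dual_coef=np.asarray(d["dual_coef"], float),
        intercept=float(d["intercept"]),
        decision_threshold=float(d["decision_threshold"]),
        selection_history=[(int(b), float(c))
                           for b, c in d["selection_history"]],
        cv_accuracy=float(d["cv_accuracy"]),
        wavelengths=np.asarray(d["wavelengths"], float),
        cutoff_ng_ml=float(d["cutoff_ng_ml"]),
        seed=int(d["seed"]),
    )
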