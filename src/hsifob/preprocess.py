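"""Chemometric preprocessing of reflectance spectra.

The discrimination chain applies, in order: Savitzky-Golay smoothing,
per-spectrum normalization (SNV by default), multiplicative scatter
correction against a reference spectrum, and a Savitzky-Golay second
derivative with physical band spacing.  Each step is deterministic and
operates identically on a single spectrum or per pixel on a whole cube.

Default filter windows (5 bands smoothing, 7 bands derivative, at the
instrument's 5 nm spacing) are deliberately narrower than the ~20-25 nm
full width of the hemoglobin Q bands: wider windows smear those narrow
features into their neighbours and blur the very structure the band
selection is meant to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessConfig",
    "savitzky_golay_smooth",
    "normalize",
    "msc_correct",
    "second_derivative",
    "apply_pipeline",
]

DEFAULT_STEPS = ("smooth", "normalize", "msc", "second_derivative")
_KNOWN_STEPS = frozenset(DEFAULT_STEPS)
_NORM_METHODS = frozenset({"snv", "unit_vector", "minmax"})

#: Marker for "use the mean preprocessed training spectrum" as MSC reference.
TRAINING_MEAN = "training_mean"


@dataclass(frozen=True)
class PreprocessConfig:
    """Ordered preprocessing chain and its filter parameters.

    Windows are in bands (odd, larger than the polynomial order); the
    derivative spacing is in nm and defaults to the instrument's 5 nm step.
    """

    steps: tuple = DEFAULT_STEPS
    smooth_window: int = 5
    smooth_polyorder: int = 2
    deriv_window: int = 7
    deriv_polyorder: int = 3
    normalize_method: str = "snv"
    msc_reference: str = TRAINING_MEAN  # or an explicit spectrum via apply_pipeline
    spacing_nm: float = 5.0

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        unknown = set(steps) - _KNOWN_STEPS
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")
        object.__setattr__(self, "steps", steps)
        for win, order, name in (
            (self.smooth_window, self.smooth_polyorder, "smooth"),
            (self.deriv_window, self.deriv_polyorder, "deriv"),
        ):
            if win % 2 == 0:
                raise ValueError(f"{name}_window must be odd, got {win}")
            if win > 121:
                raise ValueError(f"{name}_window must be <= 121, got {win}")
            if order >= win:
                raise ValueError(f"{name}_polyorder must be < window")
        if self.deriv_polyorder < 2:
            raise ValueError("deriv_polyorder must be >= 2 for a 2nd derivative")
        if self.normalize_method not in _NORM_METHODS:
            raise ValueError(f"unknown normalize_method {self.normalize_method!r}")

    # -- flat text (key=value) serialization, stored verbatim inside models --
    def to_text(self) -> str:
        lines = [
            f"steps={','.join(self.steps)}",
            f"smooth_window={self.smooth_window}",
            f"smooth_polyorder={self.smooth_polyorder}",
            f"deriv_window={self.deriv_window}",
            f"deriv_polyorder={self.deriv_polyorder}",
            f"normalize_method={self.normalize_method}",
            f"msc_reference={self.msc_reference}",
            f"spacing_nm={self.spacing_nm!r}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PreprocessConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        steps = tuple(s for s in kv.get("steps", "").split(",") if s)
        return cls(
            steps=steps,
            smooth_window=int(kv["smooth_window"]),
            smooth_polyorder=int(kv["smooth_polyorder"]),
            deriv_window=int(kv["deriv_window"]),
            deriv_polyorder=int(kv["deriv_polyorder"]),
            normalize_method=kv["normalize_method"],
            msc_reference=kv["msc_reference"],
            spacing_nm=float(kv["spacing_nm"]),
        )


def _as_2d(x: np.ndarray):
    """View input as (n_spectra, n_bands); remember the original shape."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], arr.shape
    if arr.ndim == 2:
        return arr, arr.shape
    if arr.ndim == 3:
        return arr.reshape(-1, arr.shape[2]), arr.shape
    raise ValueError("expected a spectrum, a matrix of spectra, or a cube")


def savitzky_golay_smooth(spectrum, window: int = 11,
                          polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing along the band axis.

    Edges are handled by scipy's polynomial-interpolation mode, i.e. a
    least-squares polynomial fit over the truncated edge window.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    arr, shape = _as_2d(spectrum)
    out = savgol_filter(arr, window, polyorder, axis=-1, mode="interp")
    return out.reshape(shape)


def normalize(spectrum, method: str = "snv") -> np.ndarray:
    """Per-spectrum normalization.

    snv
        Standard normal variate: subtract the mean, divide by the standard
        deviation (each computed over bands).
    unit_vector
        Scale to unit Euclidean norm.
    minmax
        Affine map of the range onto [0, 1].
    """
    arr, shape = _as_2d(spectrum)
    if method == "snv":
        mu = arr.mean(axis=-1, keepdims=True)
        sd = arr.std(axis=-1, ddof=0, keepdims=True)
        if np.any(sd <= 1e-13 * (np.abs(mu) + 1.0)):
            raise ValueError("SNV undefined for a zero-variance spectrum")
        out = (arr - mu) / sd
    elif method == "unit_vector":
        nrm = np.linalg.norm(arr, axis=-1, keepdims=True)
        if np.any(nrm == 0):
            raise ValueError("unit-vector normalization undefined for all-zero input")
        out = arr / nrm
    elif method == "minmax":
        lo = arr.min(axis=-1, keepdims=True)
        hi = arr.max(axis=-1, keepdims=True)
        rng = hi - lo
        if np.any(rng == 0):
            raise ValueError("minmax undefined for a constant spectrum")
        out = (arr - lo) / rng
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return out.reshape(shape)


def msc_correct(spectrum, reference) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum s is regressed on the reference r over all bands,
    s ~= a + b*r (ordinary least squares), and (s - a) / b is returned.
    A slope estimate with |b| < 1e-12 is a degenerate scatter fit and
    raises.
    """
    ref = np.asarray(reference, dtype=float)
    arr, shape = _as_2d(spectrum)
    if arr.shape[-1] != ref.shape[-1]:
        raise ValueError("spectrum and reference lengths differ")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0.0:
        raise ValueError("MSC reference must not be constant")
    # closed-form OLS slope/intercept, vectorized over spectra
    b = (arr - arr.mean(axis=-1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("degenerate scatter fit: |slope| < 1e-12")
    a = arr.mean(axis=-1) - b * ref.mean()
    out = (arr - a[..., None]) / b[..., None]
    return out.reshape(shape)


def second_derivative(spectrum, window: int = 15, polyorder: int = 3,
                      spacing: float = 5.0) -> np.ndarray:
    """Savitzky-Golay second derivative with physical band spacing (nm)."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder < 2:
        raise ValueError("polyorder must be >= 2 for a second derivative")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    arr, shape = _as_2d(spectrum)
    out = savgol_filter(arr, window, polyorder, deriv=2, delta=spacing,
                        axis=-1, mode="interp")
    return out.reshape(shape)


def apply_pipeline(x, config: PreprocessConfig,
                   training_mean: np.ndarray | None = None) -> np.ndarray:
    """Apply the configured chain to a spectrum, spectra matrix, or cube.

    When the chain includes MSC with the ``training_mean`` marker, the mean
    preprocessed training spectrum must be supplied; a trained model stores
    it so inference needs no training data.
    """
    out = np.asarray(x, dtype=float)
    for step in config.steps:
        if step == "smooth":
            out = savitzky_golay_smooth(out, config.smooth_window,
                                        config.smooth_polyorder)
        elif step == "normalize":
            out = normalize(out, config.normalize_method)
        elif step == "msc":
            if config.msc_reference == TRAINING_MEAN:
                if training_mean is None:
                    raise ValueError(
                        "MSC reference is 'training_mean' but no training "
                        "mean spectrum was supplied"
                    )
                ref = training_mean
            else:
                ref = np.asarray(config.msc_reference, dtype=float)
            out = msc_correct(out, ref)
        elif step == "second_derivative":
            out = second_derivative(out, config.deriv_window,
                                    config.deriv_polyorder, config.spacing_nm)
        else:  # pragma: no cover - config validation forbids this
            raise ValueError(f"unknown step {step!r}")
    return out


def partial_config(config: PreprocessConfig, upto: str) -> PreprocessConfig:
    """Config truncated to the steps strictly before ``upto`` (helper for
    computing the MSC training reference)."""
    steps = []
    for s in config.steps:
        if s == upto:
            break
        steps.append(s)
    return replace(config, steps=tuple(steps))
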