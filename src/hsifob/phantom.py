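"""Seeded synthetic hypercube phantoms with known hemoglobin ground truth.

No clinical hyperspectral images of stool are publicly deposited, so every
other module is exercised on phantoms built here: smooth diffuse
backgrounds (stool-like matrix or the verification liquids), localized
hemoglobin absorption following Beer-Lambert attenuation of the background
reflectance, per-pixel multiplicative scatter, additive sensor noise, and
quantitative FIT values tied to the simulated surface hemoglobin load.

The built-in oxy/deoxy-hemoglobin extinction table is synthetic: a
parametric sum of Gaussian absorption bands with the literature peak
positions (oxy Soret ~415 nm, Q bands ~540/577 nm; deoxy Soret ~430 nm,
single Q ~555 nm, NIR band ~760 nm) in arbitrary consistent units.  Only
that peak structure is relied upon, not absolute extinction values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import DEFAULT_WAVELENGTHS, Hypercube, RoiMask, WavelengthGrid

__all__ = [
    "HbExtinctionTable",
    "PhantomSpec",
    "BloodRegion",
    "hb_extinction_table",
    "hb_extinction_spectrum",
    "background_reflectance",
    "generate_stool_phantom",
    "generate_liquid_phantom",
    "simulate_fit_values",
    "generate_study",
    "StudyCase",
    "StudyFixture",
]

LIQUID_BACKGROUNDS = ("water", "milk", "tomato_juice", "tea", "coffee")

#: FIT ng/mL produced per unit of mean surface Hb load (absorbance units).
DEFAULT_FIT_GAIN = 2000.0


@dataclass(frozen=True)
class HbExtinctionTable:
    """Oxy/deoxy extinction curves on the 121-band grid (arbitrary units)."""

    wavelengths: np.ndarray
    oxy: np.ndarray
    deoxy: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        for name in ("oxy", "deoxy"):
            curve = np.asarray(getattr(self, name), float)
            if curve.shape != wl.shape:
                raise ValueError(f"{name} curve length mismatch")
            if np.any(curve <= 0):
                raise ValueError(f"{name} extinction must be positive")
            ratio = curve[1:] / curve[:-1]
            if np.any(ratio > 10) or np.any(ratio < 0.1):
                raise ValueError(f"{name} curve has adjacent-band jumps > 10x")
        soret = wl[np.argmax(self.oxy)]
        if not (410 <= soret <= 420):
            raise ValueError("oxy global maximum must lie in the Soret band")


def _gauss(wl: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)


def hb_extinction_table(wavelengths: np.ndarray | None = None) -> HbExtinctionTable:
    """Built-in synthetic hemoglobin extinction table (see module docstring)."""
    wl = np.asarray(DEFAULT_WAVELENGTHS if wavelengths is None else wavelengths,
                    float)
    base = 0.02 + 0.015 * np.exp(-(wl - 400.0) / 250.0)
    oxy = (base
           + _gauss(wl, 415.0, 13.0, 10.0)     # Soret
           + _gauss(wl, 540.0, 11.0, 1.00)     # Q beta
           + _gauss(wl, 577.0, 9.0, 0.95))     # Q alpha
    deoxy = (base
             + _gauss(wl, 430.0, 14.0, 9.0)
             + _gauss(wl, 555.0, 16.0, 1.10)
             + _gauss(wl, 760.0, 22.0, 0.12))
    return HbExtinctionTable(wl, oxy, deoxy)


def hb_extinction_spectrum(table: HbExtinctionTable,
                           oxy_fraction: float) -> np.ndarray:
    """Convex mix oxy_fraction * oxy + (1 - oxy_fraction) * deoxy."""
    if not (0.0 <= oxy_fraction <= 1.0):
        raise ValueError(f"oxy_fraction must be in [0, 1], got {oxy_fraction}")
    return oxy_fraction * table.oxy + (1.0 - oxy_fraction) * table.deoxy


def background_reflectance(background: str, wl: np.ndarray) -> np.ndarray:
    """Smooth parametric diffuse-reflectance curve for each background.

    The liquids are shaped so that color alone cannot mimic hemoglobin:
    milk is high and flat, tea/coffee low with a gentle slope, tomato juice
    is red-shifted (a single sigmoidal step, no Q-band double dip), water
    moderate and flat with mild NIR roll-off.
    """
    x = (wl - 400.0) / 600.0
    if background == "stool":
        return 0.08 + 0.45 / (1.0 + np.exp(-(wl - 620.0) / 60.0))
    if background == "water":
        return 0.30 - 0.10 * x ** 2
    if background == "milk":
        return 0.85 - 0.08 * x
    if background == "tomato_juice":
        return 0.06 + 0.45 / (1.0 + np.exp(-(wl - 585.0) / 18.0))
    if background == "tea":
        return 0.05 + 0.30 * x
    if background == "coffee":
        return 0.03 + 0.22 * x
    raise ValueError(f"unknown background {background!r}")


@dataclass(frozen=True)
class BloodRegion:
    """A disc of blood: center (row, col), radius px, surface Hb load
    (absorbance units at unit extinction), and placement."""

    center: tuple
    radius: float
    load: float
    placement: str = "surface"  # or "subsurface"

    def __post_init__(self) -> None:
        if self.load < 0:
            raise ValueError("Hb load must be non-negative")
        if self.placement not in ("surface", "subsurface"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic capture."""

    shape: tuple = (48, 48)
    background: str = "stool"
    blood_regions: tuple = ()
    scatter_sd: float = 0.10
    noise_sd: float = 0.5
    oxy_fraction: float = 0.95
    depth_attenuation: float = 100.0
    white_level: float = 20000.0
    background_variation: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scatter_sd < 0 or self.noise_sd < 0:
            raise ValueError("scatter/noise levels must be non-negative")
        r, c = self.shape
        for reg in self.blood_regions:
            cr, cc = reg.center
            if not (0 <= cr < r and 0 <= cc < c):
                raise ValueError(f"blood region center {reg.center} out of bounds")


def _disc_mask(shape: tuple, center: tuple, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _ellipse_mask(shape: tuple) -> np.ndarray:
    # centered ellipse covering ~2/3 of the frame: the stool on its dish
    r, c = shape
    rr, cc = np.ogrid[:r, :c]
    a, b = 0.78 * (r / 2 - 1), 0.88 * (c / 2 - 1)
    return ((rr - (r - 1) / 2) / a) ** 2 + ((cc - (c - 1) / 2) / b) ** 2 <= 1.0


def _lamp_curve(wl: np.ndarray, level: float) -> np.ndarray:
    # halogen-like: weak in the blue, rising steeply toward the NIR
    x = (wl - 400.0) / 600.0
    return level * (0.05 + 0.95 * x ** 1.7)


def _render(spec: PhantomSpec, subject_mask: np.ndarray,
            table: HbExtinctionTable):
    """Shared renderer: reflectance model -> raw counts + references."""
    rng = np.random.default_rng(spec.seed)
    wl = table.wavelengths
    nb = wl.size
    rows, cols = spec.shape
    eps = hb_extinction_spectrum(table, spec.oxy_fraction)

    subject_curve = background_reflectance(spec.background, wl)
    if spec.background_variation > 0:
        # Per-capture diffuse-background variation (stool color/albedo
        # differs between patients): a random gain plus a smooth random
        # bump field in log-reflectance (broad bumps, width >= 60 nm).
        # Diffuse matrices vary smoothly and with many degrees of freedom;
        # without this, a per-spectrum-normalized global level becomes an
        # unrealistic proxy for total hemoglobin absorption, whereas the
        # narrow Hb bands survive smooth variation.
        v = spec.background_variation
        log_jitter = rng.normal(0.0, v)  # overall gain
        n_bumps = 8
        centers = rng.uniform(380.0, 1020.0, n_bumps)
        widths = rng.uniform(60.0, 150.0, n_bumps)
        amps = rng.normal(0.0, v, n_bumps)
        field = sum(a * np.exp(-0.5 * ((wl - c) / w) ** 2)
                    for a, c, w in zip(amps, centers, widths))
        subject_curve = subject_curve * np.exp(log_jitter + field)
        subject_curve = np.clip(subject_curve, 5e-3, None)
    r_bg = np.empty((rows, cols, nb))
    plate_curve = np.full(nb, 0.35)  # neutral gray dish/plate
    r_bg[:] = plate_curve
    r_bg[subject_mask] = subject_curve

    load = np.zeros((rows, cols))
    effective = np.zeros((rows, cols))
    for reg in spec.blood_regions:
        disc = _disc_mask(spec.shape, reg.center, reg.radius)
        load[disc] = np.maximum(load[disc], reg.load)
        eff = reg.load if reg.placement == "surface" else (
            reg.load / spec.depth_attenuation)
        effective[disc] = np.maximum(effective[disc], eff)

    refl = r_bg * np.power(10.0, -effective[..., None] * eps[None, None, :])

    if spec.scatter_sd > 0:
        gain = rng.lognormal(mean=0.0, sigma=spec.scatter_sd,
                             size=(rows, cols, 1))
        offset = rng.normal(0.0, 0.02 * spec.scatter_sd, size=(rows, cols, 1))
        # additive offsets can drive reflectance negative; floor it there
        refl = np.clip(gain * refl + offset, 1e-6, None)

    white = np.broadcast_to(_lamp_curve(wl, spec.white_level),
                            (rows, cols, nb)).copy()
    raw = refl * white
    if spec.noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.noise_sd, size=raw.shape)
    raw = np.clip(raw, 0.0, None)

    grid = WavelengthGrid(wl)
    meta = {"seed": str(spec.seed), "background": spec.background}
    raw_cube = Hypercube(raw, grid, kind="raw", meta=dict(meta))
    white_cube = Hypercube(white, grid, kind="raw",
                           meta={"frame": "white_reference"})
    dark_cube = Hypercube(np.zeros_like(raw), grid, kind="raw",
                          meta={"frame": "dark_reference"})
    return raw_cube, white_cube, dark_cube, RoiMask(subject_mask), load


def generate_stool_phantom(spec: PhantomSpec,
                           table: HbExtinctionTable | None = None):
    """Synthesize one stool capture.

    Returns (raw cube, white cube, dark cube, stool mask, truth map of
    per-pixel surface Hb load).  Subsurface blood regions appear in the
    truth map at their nominal load but their optical signature is
    attenuated by ``depth_attenuation`` (default 100x), emulating blood
    inside the stool bulk that the camera cannot see.
    """
    if table is None:
        table = hb_extinction_table()
    return _render(spec, _ellipse_mask(spec.shape), table)


def generate_liquid_phantom(spec: PhantomSpec,
                            table: HbExtinctionTable | None = None):
    """Synthesize a petri-dish liquid capture (vessel mask instead of stool)."""
    if spec.background not in LIQUID_BACKGROUNDS:
        raise ValueError(
            f"liquid phantom background must be one of {LIQUID_BACKGROUNDS}, "
            f"got {spec.background!r}"
        )
    if table is None:
        table = hb_extinction_table()
    return _render(spec, _disc_mask(spec.shape,
                                    ((spec.shape[0] - 1) / 2,
                                     (spec.shape[1] - 1) / 2),
                                    min(spec.shape) / 2 - 1), table)


def simulate_fit_values(truth_map: np.ndarray, area_masks,
                        gain: float = DEFAULT_FIT_GAIN,
                        noise_cv: float = 0.15,
                        seed: int = 0) -> np.ndarray:
    """Quantitative FIT (ng/mL) per area from the simulated Hb load.

    FIT = gain * (mean load over the area) * mean-one lognormal noise with
    coefficient of variation ``noise_cv``; exactly monotone in mean load
    when noise_cv = 0.
    """
    rng = np.random.default_rng(seed)
    out = []
    for mask in area_masks:
        px = mask.pixels if isinstance(mask, RoiMask) else np.asarray(mask, bool)
        if not px.any():
            raise ValueError("empty area mask")
        mean_load = float(truth_map[px].mean())
        value = gain * mean_load
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            value *= rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma)
        out.append(value)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Mini-study generation (training batch + validation batch)

@dataclass
class StudyCase:
    """One synthetic case: cube + references + masks + sampled areas."""

    case_id: str
    spec: PhantomSpec
    raw: Hypercube
    white: Hypercube
    dark: Hypercube
    stool_mask: RoiMask
    truth_map: np.ndarray
    pattern_truth: str  # intended pattern: whole_positive/partial/whole_negative
    area_masks: list = field(default_factory=list)
    area_ids: list = field(default_factory=list)
    fit_values: np.ndarray | None = None


@dataclass
class StudyFixture:
    cases: list
    cutoff_ng_ml: float
    gain: float
    seed: int

    def areas(self):
        """Flat iterator of (case_id, area_id, mask, fit) tuples."""
        for case in self.cases:
            for aid, mask, fit in zip(case.area_ids, case.area_masks,
                                      case.fit_values):
                yield case.case_id, aid, mask, float(fit)


def _place_disc_centers(rng, subject: np.ndarray, n: int, radius: float,
                        max_tries: int = 2000):
    """Seeded non-overlapping disc placement with the disc fully on-subject."""
    from scipy.ndimage import binary_erosion

    r_int = int(np.ceil(radius))
    struct = _disc_mask((2 * r_int + 1, 2 * r_int + 1), (r_int, r_int), radius)
    eligible = binary_erosion(subject, structure=struct)
    coords = np.argwhere(eligible)
    if coords.size == 0:
        raise ValueError("no eligible pixels for area placement")
    centers: list = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        cand = coords[rng.integers(len(coords))]
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 > (2 * radius) ** 2
               for c in centers):
            centers.append(tuple(int(v) for v in cand))
    if len(centers) < n:
        raise ValueError(
            f"could not place {n} non-overlapping areas (placed {len(centers)})"
        )
    return centers


def generate_study(n_cases: int = 50, areas_per_case: int = 2,
                   composition: tuple | None = None,
                   shape: tuple = (48, 48), area_radius: float = 4.0,
                   positive_fraction: float = 0.35,
                   scatter_sd: float = 0.10, noise_sd: float = 0.5,
                   fit_noise_cv: float = 0.15,
                   gain: float = DEFAULT_FIT_GAIN,
                   cutoff_ng_ml: float = 400.0,
                   seed: int = 0) -> StudyFixture:
    """Generate a reproducible mini-study with known ground truth.

    Without ``composition`` the fixture mirrors the algorithm-construction
    batch: ``areas_per_case`` abrasion areas per case, with blood discs
    placed under a seeded ~``positive_fraction`` of areas (load drawn above
    the FIT cutoff) and trace-to-zero load elsewhere.  With
    ``composition = (P, Q, R)`` it mirrors the validation batch instead:
    P whole-positive cases (blood across the stool), Q partial-positive
    (one blood patch), R whole-negative (no blood); validation areas are
    then chosen downstream from the discriminant image.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    cutoff_load = cutoff_ng_ml / gain
    cases: list = []

    if composition is None:
        # Blood on roughly half the areas, with a continuous lognormal load
        # straddling the cutoff so that the overall positive fraction is
        # ~positive_fraction and boundary areas are genuinely ambiguous.
        blood_prob = min(1.0, 2.0 * positive_fraction)
        q = positive_fraction / blood_prob  # P(load >= cutoff | blood)
        from scipy.stats import norm

        load_sigma = 0.9
        load_mu = np.log(cutoff_load) - load_sigma * norm.ppf(1.0 - q)
        for i in range(n_cases):
            case_seed = int(rng.integers(2 ** 31))
            case_rng = np.random.default_rng(case_seed)
            subject = _ellipse_mask(shape)
            centers = _place_disc_centers(case_rng, subject, areas_per_case,
                                          area_radius)
            regions = []
            for center in centers:
                if case_rng.random() < blood_prob:
                    load = float(np.exp(case_rng.normal(load_mu, load_sigma)))
                    regions.append(BloodRegion(center, area_radius * 1.6,
                                               load))
            spec = PhantomSpec(shape=shape, background="stool",
                               blood_regions=tuple(regions),
                               scatter_sd=scatter_sd, noise_sd=noise_sd,
                               seed=case_seed)
            raw, white, dark, stool_mask, truth = generate_stool_phantom(spec)
            case = StudyCase(case_id=f"case{i:03d}", spec=spec, raw=raw,
                             white=white, dark=dark, stool_mask=stool_mask,
                             truth_map=truth, pattern_truth="training")
            case.area_masks = [RoiMask(_disc_mask(shape, c, area_radius))
                               for c in centers]
            case.area_ids = [f"area{j}" for j in range(len(centers))]
            case.fit_values = simulate_fit_values(
                truth, case.area_masks, gain=gain, noise_cv=fit_noise_cv,
                seed=int(rng.integers(2 ** 31)))
            cases.append(case)
    else:
        n_pos, n_partial, n_neg = composition
        if n_pos + n_partial + n_neg != n_cases:
            raise ValueError("composition must sum to n_cases")
        patterns = (["whole_positive"] * n_pos + ["partial_positive"] * n_partial
                    + ["whole_negative"] * n_neg)
        for i, pattern in enumerate(patterns):
            case_seed = int(rng.integers(2 ** 31))
            case_rng = np.random.default_rng(case_seed)
            subject = _ellipse_mask(shape)
            regions = []
            if pattern == "whole_positive":
                load = cutoff_load * np.exp(case_rng.normal(1.2, 0.3))
                # one large disc blanketing the stool
                regions.append(BloodRegion(((shape[0] - 1) / 2,
                                            (shape[1] - 1) / 2),
                                           max(shape), load))
            elif pattern == "partial_positive":
                load = cutoff_load * np.exp(case_rng.normal(1.2, 0.3))
                center = _place_disc_centers(case_rng, subject, 1,
                                             min(shape) * 0.22)[0]
                regions.append(BloodRegion(center, min(shape) * 0.22, load))
            spec = PhantomSpec(shape=shape, background="stool",
                               blood_regions=tuple(regions),
                               scatter_sd=scatter_sd, noise_sd=noise_sd,
                               seed=case_seed)
            raw, white, dark, stool_mask, truth = generate_stool_phantom(spec)
            cases.append(StudyCase(case_id=f"case{i:03d}", spec=spec, raw=raw,
                                   white=white, dark=dark,
                                   stool_mask=stool_mask, truth_map=truth,
                                   pattern_truth=pattern))
    return StudyFixture(cases=cases, cutoff_ng_ml=cutoff_ng_ml, gain=gain,
                        seed=seed)
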