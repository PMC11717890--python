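"""Area-, pattern- and case-level calls from discriminant images.

A sampling area (the abrasion spot of the stool collection kit) is judged
positive when at least a small fraction of its pixels score positive.  A
whole capture is classified by the extent of positive area over the stool:
whole-positive, partial-positive or whole-negative.  The validation
sampling scheme then draws five areas per case according to the pattern
(5 positive / 3 positive + 2 negative / 5 negative), and a case-level call
aggregates its areas with an any-positive rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import RoiMask
from .model import DiscriminantImage

__all__ = [
    "SamplingArea",
    "StoolPattern",
    "judge_area",
    "classify_pattern",
    "select_validation_areas",
    "aggregate_case",
    "write_area_table",
    "read_area_table",
]

PATTERNS = ("whole_positive", "partial_positive", "whole_negative")


@dataclass
class SamplingArea:
    """One region-of-interest with its FIT value and algorithm call."""

    case_id: str
    area_id: str
    mask: RoiMask
    fit_ng_ml: float | None = None
    algorithm_call: str = "undetermined"
    center: tuple | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.fit_ng_ml is not None and self.fit_ng_ml < 0:
            raise ValueError("fit_ng_ml must be >= 0")
        if self.algorithm_call not in ("positive", "negative", "undetermined"):
            raise ValueError(f"bad algorithm_call {self.algorithm_call!r}")


@dataclass(frozen=True)
class StoolPattern:
    """Three-way pattern of a discriminant image over the stool mask."""

    value: str
    positive_fraction: float

    def __post_init__(self) -> None:
        if self.value not in PATTERNS:
            raise ValueError(f"unknown pattern {self.value!r}")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")


def judge_area(img: DiscriminantImage, mask: RoiMask,
               min_positive_fraction: float = 0.05) -> str:
    """Positive iff >= min_positive_fraction of the mask's pixels are positive.

    The small nonzero default rejects isolated noise pixels while keeping
    the judgement close to "any detected region on the area is positive".
    """
    if mask.shape != img.positives.shape:
        raise ValueError("mask shape does not match discriminant image")
    frac = img.positives[mask.pixels].mean()
    return "positive" if frac >= min_positive_fraction else "negative"


def classify_pattern(img: DiscriminantImage, stool_mask: RoiMask,
                     hi: float = 0.80, lo: float = 0.01) -> StoolPattern:
    """Pattern by positive fraction f over the stool: whole-positive when
    f >= hi, whole-negative when f <= lo, else partial-positive."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    if stool_mask.shape != img.positives.shape:
        raise ValueError("stool mask shape does not match discriminant image")
    f = float(img.positives[stool_mask.pixels].mean())
    if f >= hi:
        value = "whole_positive"
    elif f <= lo:
        value = "whole_negative"
    else:
        value = "partial_positive"
    return StoolPattern(value=value, positive_fraction=f)


def _disc(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _draw_centers(rng, eligible: np.ndarray, n: int, radius: float,
                  taken: list, max_tries: int = 5000) -> list:
    coords = np.argwhere(eligible)
    centers: list = []
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        if coords.size == 0:
            break
        cand = tuple(int(v) for v in coords[rng.integers(len(coords))])
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 > (2 * radius) ** 2
               for c in taken + centers):
            centers.append(cand)
    if len(centers) < n:
        raise ValueError(
            f"could not place {n} non-overlapping areas of radius {radius} "
            f"(placed {len(centers)}; {len(coords)} eligible pixels)"
        )
    return centers


def select_validation_areas(img: DiscriminantImage, stool_mask: RoiMask,
                            pattern: StoolPattern, case_id: str = "case",
                            radius: float = 10.0, seed: int = 0,
                            min_positive_fraction: float = 0.05,
                            ) -> list:
    """Draw the five validation areas prescribed by the image pattern.

    whole_positive: 5 areas centered on algorithm-positive stool pixels;
    partial_positive: 3 positive + 2 negative; whole_negative: 5 negative.
    Areas are fixed-radius discs, seeded-randomly placed, non-overlapping,
    centered inside the stool.  The returned areas carry the algorithm
    call implied by their placement polarity.
    """
    if stool_mask.shape != img.positives.shape:
        raise ValueError("stool mask shape does not match discriminant image")
    rng = np.random.default_rng(seed)
    want = {"whole_positive": (5, 0), "partial_positive": (3, 2),
            "whole_negative": (0, 5)}[pattern.value]
    pos_eligible = img.positives & stool_mask.pixels
    neg_eligible = (~img.positives) & stool_mask.pixels
    taken: list = []
    areas: list = []
    shape = img.positives.shape
    for polarity, count, eligible in (("positive", want[0], pos_eligible),
                                      ("negative", want[1], neg_eligible)):
        if count == 0:
            continue
        centers = _draw_centers(rng, eligible, count, radius, taken)
        taken.extend(centers)
        for center in centers:
            mask = RoiMask(_disc(shape, center, radius) & stool_mask.pixels)
            areas.append(SamplingArea(
                case_id=case_id, area_id=f"v{len(areas)}", mask=mask,
                algorithm_call=polarity, center=center, radius=radius))
    return areas


def aggregate_case(areas, by: str = "algorithm",
                   cutoff: float = 400.0) -> str:
    """Case-level call: positive iff any area is positive on the chosen
    channel (the algorithm call, or FIT >= cutoff)."""
    areas = list(areas)
    if not areas:
        raise ValueError("no areas to aggregate")
    case_ids = {a.case_id for a in areas}
    if len(case_ids) != 1:
        raise ValueError(f"areas span multiple cases: {sorted(case_ids)}")
    if by == "algorithm":
        calls = [a.algorithm_call for a in areas]
        if "undetermined" in calls:
            raise ValueError("cannot aggregate undetermined algorithm calls")
        return "positive" if "positive" in calls else "negative"
    if by == "fit":
        if any(a.fit_ng_ml is None for a in areas):
            raise ValueError("cannot aggregate: missing FIT value")
        return ("positive"
                if any(a.fit_ng_ml >= cutoff for a in areas) else "negative")
    raise ValueError(f"unknown aggregation channel {by!r}")


# ---------------------------------------------------------------------------
# Delimited-text area tables

def write_area_table(areas, path) -> None:
    import pandas as pd

    rows = []
    for a in areas:
        rows.append({
            "case_id": a.case_id, "area_id": a.area_id,
            "center_row": a.center[0] if a.center else "",
            "center_col": a.center[1] if a.center else "",
            "radius": a.radius if a.radius is not None else "",
            "fit_ng_per_ml": a.fit_ng_ml if a.fit_ng_ml is not None else "",
            "algorithm_call": a.algorithm_call,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_area_table(path):
    """Read an area table as plain records (masks are not reconstructed)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"case_id", "area_id", "algorithm_call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    return df
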