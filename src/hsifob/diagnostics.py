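"""Diagnostic-accuracy statistics for algorithm calls vs quantitative FIT.

The reference standard is the quantitative fecal immunochemical test (FIT)
dichotomized at a cutoff (400 ng/mL by default); the index test is the
per-area or per-case call of the discriminant algorithm.  Agreement is
summarized in a 2x2 table with sensitivity, specificity, accuracy, PPV and
NPV, each with an exact (Clopper-Pearson) 95% confidence interval, plus the
Pearson chi-square / Fisher exact group-comparison tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "DiagnosticMetrics",
    "make_contingency",
    "diagnostic_metrics",
    "clopper_pearson_ci",
    "compare_proportions",
    "lesion_sensitivity_table",
    "format_report",
]

LESION_CLASSES = ("cancer_advanced", "cancer_early", "advanced_adenoma",
                  "non_advanced_adenoma", "no_lesion")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 concordance counts (reference = FIT >= cutoff, test = algorithm)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact 95% CI; value None means undefined."""

    value: float | None
    ci: tuple | None
    k: int
    n: int
    reason: str | None = None


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    accuracy: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    n_reference_positive: int
    n_reference_negative: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def make_contingency(records, cutoff: float = 400.0) -> ContingencyTable:
    """Cross-tabulate algorithm calls against FIT >= cutoff.

    ``records`` is an iterable of objects or mappings exposing
    ``algorithm_call`` ("positive"/"negative") and ``fit_ng_ml``.
    """
    tp = fp = fn = tn = 0
    for rec in records:
        if isinstance(rec, dict):
            call, fit = rec.get("algorithm_call"), rec.get("fit_ng_ml")
        else:
            call = getattr(rec, "algorithm_call", None)
            fit = getattr(rec, "fit_ng_ml", None)
        if call not in ("positive", "negative") or fit is None:
            raise ValueError(
                "every record needs an algorithm call and a FIT value"
            )
        ref_pos = fit >= cutoff
        if call == "positive":
            tp, fp = tp + ref_pos, fp + (not ref_pos)
        else:
            fn, tn = fn + ref_pos, tn + (not ref_pos)
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson_ci(k: int, n: int, alpha: float = 0.05) -> tuple:
    """Exact two-sided binomial CI by inversion of the binomial test.

    Endpoints are the usual beta quantiles; the lower bound is 0 when
    k = 0 and the upper bound is 1 when k = n.
    """
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _estimate(k: int, n: int, what: str, alpha: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(None, None, k, n,
                              reason=f"{what} undefined: empty denominator")
    return MetricEstimate(k / n, clopper_pearson_ci(k, n, alpha), k, n)


def diagnostic_metrics(t: ContingencyTable,
                       ci_method: str = "clopper_pearson",
                       alpha: float = 0.05) -> DiagnosticMetrics:
    """The five accuracy statistics with exact binomial CIs.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    accuracy = (tp+tn)/total, ppv = tp/(tp+fp), npv = tn/(tn+fn).
    A zero denominator yields an undefined metric (flagged, not an error).
    """
    if ci_method != "clopper_pearson":
        raise ValueError(f"unsupported CI method {ci_method!r}")
    return DiagnosticMetrics(
        sensitivity=_estimate(t.tp, t.tp + t.fn, "sensitivity", alpha),
        specificity=_estimate(t.tn, t.tn + t.fp, "specificity", alpha),
        accuracy=_estimate(t.tp + t.tn, t.total, "accuracy", alpha),
        ppv=_estimate(t.tp, t.tp + t.fp, "ppv", alpha),
        npv=_estimate(t.tn, t.tn + t.fn, "npv", alpha),
        n_reference_positive=t.tp + t.fn,
        n_reference_negative=t.tn + t.fp,
    )


def compare_proportions(table, method: str = "auto") -> float:
    """Two-sided p-value for a 2x2 group comparison.

    method="auto" uses the Fisher exact test when any expected cell count
    is below 5 and the continuity-corrected Pearson chi-square otherwise;
    both are available explicitly as "fisher_exact" and "pearson_chi2_cc"
    (plus "pearson_chi2" without the correction).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column sums to zero")
    if method == "auto":
        expected = stats.contingency.expected_freq(arr)
        method = "fisher_exact" if np.any(expected < 5) else "pearson_chi2_cc"
    if method == "fisher_exact":
        return float(stats.fisher_exact(arr.astype(int))[1])
    if method in ("pearson_chi2_cc", "pearson_chi2"):
        correction = method.endswith("_cc")
        return float(stats.chi2_contingency(arr, correction=correction)[1])
    raise ValueError(f"unknown method {method!r}")


def lesion_sensitivity_table(cases, cutoffs=(100.0, 400.0, 800.0),
                             channel: str = "fit") -> dict:
    """Per-lesion-class detection grid across FIT cutoffs.

    ``cases`` is an iterable of mappings with keys ``lesion_class`` (one of
    LESION_CLASSES), optional ``subsite`` ("proximal"/"distal"), and either
    ``fit_ng_ml`` (channel="fit") or ``algorithm_call`` (channel="algorithm").
    Returns {cutoff: {class: (detected, total, percent)}} with the derived
    row ``cancer_any`` = advanced + early cancer.
    """
    cases = list(cases)
    for c in cases:
        if c["lesion_class"] not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {c['lesion_class']!r}")

    def detected(c, cutoff):
        if channel == "fit":
            return c["fit_ng_ml"] >= cutoff
        return c["algorithm_call"] == "positive"

    grid: dict = {}
    for cutoff in cutoffs:
        per_class: dict = {}
        for cls in LESION_CLASSES + ("cancer_any",):
            if cls == "cancer_any":
                members = [c for c in cases
                           if c["lesion_class"] in ("cancer_advanced",
                                                    "cancer_early")]
            else:
                members = [c for c in cases if c["lesion_class"] == cls]
            n = len(members)
            k = sum(detected(c, cutoff) for c in members)
            pct = 100.0 * k / n if n else None
            per_class[cls] = (k, n, pct)
        grid[cutoff] = per_class
    return grid


def _pct(x: float) -> str:
    # half-up rounding to 1 decimal in percent, as in clinical reporting
    from decimal import Decimal, ROUND_HALF_UP

    return str(Decimal(str(100 * x)).quantize(Decimal("0.1"),
                                              rounding=ROUND_HALF_UP))


def format_report(m: DiagnosticMetrics, label: str = "") -> str:
    """Plain-text summary (percent at 1 d.p., CI in brackets)."""
    parts = []
    for name, est in m.as_dict().items():
        if est.value is None:
            parts.append(f"{name}: undefined ({est.reason})")
        else:
            lo, hi = est.ci
            parts.append(f"{name}: {_pct(est.value)}% "
                         f"[95% CI: {_pct(lo)}-{_pct(hi)}]")
    head = f"{label}: " if label else ""
    return head + ", ".join(parts)
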