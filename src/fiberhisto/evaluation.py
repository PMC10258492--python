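"""Method-agreement metrics: coefficient of variance, accuracy rate,
productivity, and a pooled comparison report between two analysis methods
(typically manual vs. automated measurement of the same sections).

The accuracy rate is asymmetric by construction — its denominator is the
reference (manual) value — so comparison reports label direction explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "coefficient_of_variance",
    "accuracy_rate",
    "productivity",
    "MethodComparison",
    "compare_methods",
]


def coefficient_of_variance(values: Sequence[float]) -> float:
    """CV (%) = sample standard deviation / mean × 100.

    Requires at least two values and a nonzero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if v.size < 2:
        raise ValueError(f"coefficient of variance needs n >= 2, got n={v.size}")
    mean = v.mean()
    if mean == 0:
        raise ValueError("coefficient of variance undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)


def accuracy_rate(test_value: float, reference_value: float) -> float:
    """Agreement (%) of a test value against a reference value:
    (1 − |test − reference| / |reference|) × 100.

    100% iff the two values are equal; decreases linearly in the absolute
    difference. The denominator is always the reference, so the metric is
    asymmetric in its arguments.
    """
    if reference_value == 0:
        raise ValueError("accuracy rate undefined for zero reference value")
    return float(
        (1.0 - abs(test_value - reference_value) / abs(reference_value)) * 100.0
    )


def productivity(n_data_sets: int, hours: float) -> float:
    """Throughput of an analysis method: data sets generated per hour.

    One measured quantity on one fiber is one data set; a fiber measured
    for both diameter and area therefore contributes two.
    """
    if hours <= 0 or not math.isfinite(hours):
        raise ValueError(f"hours must be positive, got {hours}")
    if n_data_sets < 0:
        raise ValueError(f"n_data_sets must be nonnegative, got {n_data_sets}")
    return float(n_data_sets) / float(hours)


@dataclass
class MethodComparison:
    """Agreement report between a reference and a test analysis method."""

    reference_label: str
    test_label: str
    n_reference: int
    n_test: int
    mean_diameter_reference_um: float
    mean_diameter_test_um: float
    cv_reference_percent: float
    cv_test_percent: float
    accuracy_diameter_percent: float
    mean_area_reference_um2: float
    mean_area_test_um2: float
    accuracy_area_percent: float
    productivity_reference_per_h: float
    productivity_test_per_h: float


def _pooled(summaries: Sequence, value: str) -> tuple[int, float, float]:
    """Pool per-section (n, mean, sd) into overall (n, mean, sd).

    Only the pooled multiset of fiber values matters; partitioning into
    sections is immaterial. Sections with a single fiber contribute no
    within-section scatter.
    """
    ns = np.array([s.n_fibers for s in summaries], dtype=float)
    means = np.array([getattr(s, f"mean_{value}") for s in summaries], dtype=float)
    if value == "diameter_um":
        cvs = np.array([s.cv_diameter_percent for s in summaries], dtype=float)
        sds = np.where(np.isnan(cvs), 0.0, cvs) * means / 100.0
    else:
        sems = np.array([getattr(s, f"sem_{value}") for s in summaries], dtype=float)
        sds = np.where(np.isnan(sems), 0.0, sems) * np.sqrt(ns)
    keep = ns > 0
    ns, means, sds = ns[keep], means[keep], sds[keep]
    n = ns.sum()
    if n == 0 or np.isnan(means).any():
        return 0, float("nan"), float("nan")
    grand = float((ns * means).sum() / n)
    ss = float(((ns - 1) * sds**2).sum() + (ns * (means - grand) ** 2).sum())
    sd = math.sqrt(ss / (n - 1)) if n > 1 else float("nan")
    return int(n), grand, sd


def compare_methods(
    reference: Sequence,
    test: Sequence,
    hours_reference: float,
    hours_test: float,
    *,
    datasets_per_fiber_reference: int = 1,
    datasets_per_fiber_test: int = 2,
    reference_label: str = "manual",
    test_label: str = "automated",
) -> MethodComparison:
    """Build an agreement report from two sets of ``SectionSummary``.

    Means and CVs are pooled over all fibers in each set. Accuracy is
    computed on the pooled mean diameter and, when both sides report it, on
    the pooled mean area. Productivity counts data sets per fiber per the
    supplied rates — by default 1 for the reference (diameter only, as in
    manual measurement) and 2 for the test (diameter and area).
    """
    if not reference or not test:
        raise ValueError("both summary sets must be nonempty")
    if hours_reference <= 0 or hours_test <= 0:
        raise ValueError("analysis hours must be positive")

    n_ref, mean_d_ref, sd_d_ref = _pooled(reference, "diameter_um")
    n_test, mean_d_test, sd_d_test = _pooled(test, "diameter_um")
    if n_ref == 0 or n_test == 0:
        raise ValueError("each summary set must contain at least one fiber")
    _, mean_a_ref, _ = _pooled(reference, "area_um2")
    _, mean_a_test, _ = _pooled(test, "area_um2")

    acc_area = float("nan")
    if not (math.isnan(mean_a_ref) or math.isnan(mean_a_test)):
        acc_area = accuracy_rate(mean_a_test, mean_a_ref)

    return MethodComparison(
        reference_label=reference_label,
        test_label=test_label,
        n_reference=n_ref,
        n_test=n_test,
        mean_diameter_reference_um=mean_d_ref,
        mean_diameter_test_um=mean_d_test,
        cv_reference_percent=sd_d_ref / mean_d_ref * 100.0,
        cv_test_percent=sd_d_test / mean_d_test * 100.0,
        accuracy_diameter_percent=accuracy_rate(mean_d_test, mean_d_ref),
        mean_area_reference_um2=mean_a_ref,
        mean_area_test_um2=mean_a_test,
        accuracy_area_percent=acc_area,
        productivity_reference_per_h=productivity(
            n_ref * datasets_per_fiber_reference, hours_reference
        ),
        productivity_test_per_h=productivity(
            n_test * datasets_per_fiber_test, hours_test
        ),
    )
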