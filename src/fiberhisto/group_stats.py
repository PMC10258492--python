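"""Two-group treatment comparison of fiber morphometry.

Diameter and area are compared at the fiber level — the very small SEMs
typical of reports on tens of thousands of fibers are only attainable with
fiber-level n, at the cost of treating fibers within an image as
independent (pseudoreplication; see the methods note). Fiber density
(fibers/mm²) is an image-level quantity and is compared across images.
Each metric gets a one-way ANOVA across the two groups followed by a
two-sample Student's t test with pooled variance; with two groups the two
procedures coincide (F = t²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GroupReport", "compare_groups"]


@dataclass
class GroupReport:
    """One group's side of a two-group comparison. The p-values and
    significance flags are shared between the paired reports."""

    group_label: str
    n_fibers: int
    n_images: int
    mean_diameter_um: float
    sem_diameter_um: float
    mean_area_um2: float
    sem_area_um2: float
    fibers_per_mm2: float
    sem_fibers_per_mm2: float
    p_value_diameter: float
    p_value_area: float
    p_value_density: float
    significant_diameter: bool
    significant_area: bool
    significant_density: bool
    alpha: float


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sem = (
        float(values.std(ddof=1) / math.sqrt(values.size))
        if values.size > 1
        else float("nan")
    )
    return mean, sem


def _anova_then_t(a: np.ndarray, b: np.ndarray) -> float:
    """One-way ANOVA across the two groups, then pooled-variance Student's
    t; returns the t test's two-sided p-value (identical to the ANOVA p for
    two groups). Identical groups give t = 0, p = 1."""
    stats.f_oneway(a, b)  # screening step; equals the t test for 2 groups
    t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
    if np.isnan(t_p):  # zero variance in both groups
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(t_p)


def compare_groups(
    group_a: Sequence[Sequence],
    group_b: Sequence[Sequence],
    alpha: float = 0.05,
    *,
    tissue_areas_a: Sequence[float] | None = None,
    tissue_areas_b: Sequence[float] | None = None,
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> tuple[GroupReport, GroupReport]:
    """Compare two treatment groups of per-image fiber records.

    Parameters
    ----------
    group_a, group_b
        One sequence of :class:`~fiberhisto.morphometry.FiberRecord` per
        image, per group.
    tissue_areas_a, tissue_areas_b
        Per-image tissue areas (mm²), matching the image order; required
        for the density comparison. When omitted the density entries are
        NaN and density is not tested.
    alpha
        Significance level; a metric is flagged significant when
        p ≤ alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")

    def _flatten(group, attr):
        return np.array(
            [getattr(r, attr) for image in group for r in image], dtype=float
        )

    d_a = _flatten(group_a, "lesser_diameter_um")
    d_b = _flatten(group_b, "lesser_diameter_um")
    a_a = _flatten(group_a, "area_um2")
    a_b = _flatten(group_b, "area_um2")
    for name, arr in (("diameter", d_a), ("diameter", d_b)):
        if arr.size < 2:
            raise ValueError(
                f"each group needs >= 2 fiber observations to test {name}"
            )

    p_diameter = _anova_then_t(d_a, d_b)
    p_area = _anova_then_t(a_a, a_b)

    nan = float("nan")
    dens_a = dens_b = np.array([])
    p_density = nan
    if tissue_areas_a is not None and tissue_areas_b is not None:
        if len(tissue_areas_a) != len(group_a) or len(tissue_areas_b) != len(group_b):
            raise ValueError("tissue areas must match the per-image grouping")
        dens_a = np.array(
            [len(img) / area for img, area in zip(group_a, tissue_areas_a)]
        )
        dens_b = np.array(
            [len(img) / area for img, area in zip(group_b, tissue_areas_b)]
        )
        if dens_a.size < 2 or dens_b.size < 2:
            raise ValueError("each group needs >= 2 images to test density")
        p_density = _anova_then_t(dens_a, dens_b)

    def _report(label, d, a, dens, n_images) -> GroupReport:
        mean_d, sem_d = _mean_sem(d)
        mean_a, sem_a = _mean_sem(a)
        mean_dens, sem_dens = _mean_sem(dens)
        return GroupReport(
            group_label=label,
            n_fibers=int(d.size),
            n_images=n_images,
            mean_diameter_um=mean_d,
            sem_diameter_um=sem_d,
            mean_area_um2=mean_a,
            sem_area_um2=sem_a,
            fibers_per_mm2=mean_dens,
            sem_fibers_per_mm2=sem_dens,
            p_value_diameter=p_diameter,
            p_value_area=p_area,
            p_value_density=p_density,
            significant_diameter=p_diameter <= alpha,
            significant_area=p_area <= alpha,
            significant_density=(not math.isnan(p_density)) and p_density <= alpha,
            alpha=alpha,
        )

    return (
        _report(labels[0], d_a, a_a, dens_a, len(group_a)),
        _report(labels[1], d_b, a_b, dens_b, len(group_b)),
    )
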