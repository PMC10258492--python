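import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberhisto.evaluation import (
    accuracy_rate,
    coefficient_of_variance,
    compare_methods,
    productivity,
)
from tests.conftest import make_records


# ---------------------------------------------------------------- CV


def test_cv_of_constant_values_is_zero():
    assert coefficient_of_variance([5, 5, 5, 5]) == pytest.approx(0.0)


def test_cv_hand_arithmetic():
    # sample SD of {1,2,3} is 1, mean is 2
    assert coefficient_of_variance([1, 2, 3]) == pytest.approx(50.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    values=st.lists(st.floats(min_value=0.5, max_value=100.0), min_size=2, max_size=30),
    scale=st.floats(min_value=0.01, max_value=1000.0),
)
def test_cv_scale_invariant(values, scale):
    base = coefficient_of_variance(values)
    scaled = coefficient_of_variance([v * scale for v in values])
    assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


def test_cv_validation():
    with pytest.raises(ValueError):
        coefficient_of_variance([3.0])
    with pytest.raises(ValueError):
        coefficient_of_variance([-1.0, 1.0])  # zero mean


# ---------------------------------------------------------------- accuracy


def test_accuracy_on_reported_diameter_means():
    # automated 22.84 µm vs manual 22.86 µm
    assert accuracy_rate(22.84, 22.86) == pytest.approx(99.91, abs=0.005)


def test_accuracy_on_reported_area_means():
    # 27-image area mean 717.69 µm² vs 84-image reference 676.44 µm²
    assert accuracy_rate(717.69, 676.44) == pytest.approx(93.90, abs=0.005)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(x=st.floats(min_value=0.01, max_value=1e6))
def test_accuracy_identity(x):
    assert accuracy_rate(x, x) == pytest.approx(100.0)


def test_accuracy_asymmetric_and_monotone():
    assert accuracy_rate(22.84, 22.86) != accuracy_rate(22.86, 22.84)
    # strictly decreasing in |test - reference| at fixed reference
    accs = [accuracy_rate(20.0 + delta, 20.0) for delta in (0.0, 0.5, 1.0, 3.0)]
    assert all(a > b for a, b in zip(accs, accs[1:]))
    assert all(a <= 100.0 for a in accs)


def test_accuracy_zero_reference_rejected():
    with pytest.raises(ValueError):
        accuracy_rate(1.0, 0.0)


# ---------------------------------------------------------------- productivity


def test_productivity_of_reported_automated_run():
    # 15,881 fibers x 2 metrics in 1.4 h
    assert round(productivity(2 * 15881, 1.4)) == 22687


def test_productivity_of_reported_manual_run():
    # 17,333 diameter-only measurements in 54 h
    assert round(productivity(17333, 54)) == 321


def test_productivity_edge_cases():
    assert productivity(0, 5.0) == 0.0
    with pytest.raises(ValueError):
        productivity(10, 0.0)
    with pytest.raises(ValueError):
        productivity(-1, 1.0)


def test_productivity_linear_in_data_and_inverse_in_hours():
    assert productivity(300, 2.0) == pytest.approx(3 * productivity(100, 2.0))
    assert productivity(100, 4.0) == pytest.approx(productivity(100, 2.0) / 2)


# ---------------------------------------------------------------- compare_methods


def _summaries_from_values(diameters, areas=None, n_sections=1):
    """Split fiber-level values into sections and summarize each."""
    chunks_d = np.array_split(np.asarray(diameters, dtype=float), n_sections)
    chunks_a = (
        np.array_split(np.asarray(areas, dtype=float), n_sections)
        if areas is not None
        else [None] * n_sections
    )
    summaries = []
    for k, (d, a) in enumerate(zip(chunks_d, chunks_a)):
        records = make_records(d, areas=a, source_id=f"img{k}")
        mask_free = _summary_from_records(records, f"img{k}")
        summaries.append(mask_free)
    return summaries


def _summary_from_records(records, source_id):
    from fiberhisto.morphometry import SectionSummary

    d = np.array([r.lesser_diameter_um for r in records])
    a = np.array([r.area_um2 for r in records])
    n = len(records)
    nan = float("nan")
    return SectionSummary(
        source_id=source_id,
        n_fibers=n,
        mean_diameter_um=float(d.mean()),
        sem_diameter_um=float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else nan,
        cv_diameter_percent=coefficient_of_variance(d) if n > 1 else nan,
        mean_area_um2=float(a.mean()),
        sem_area_um2=float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else nan,
        fibers_per_mm2=nan,
        tissue_area_mm2=nan,
        image_area_mm2=nan,
        fibers_per_mm2_image=nan,
    )


def test_identical_sets_agree_perfectly():
    rng = np.random.default_rng(1)
    d = rng.normal(23, 7, 200)
    ref = _summaries_from_values(d, n_sections=4)
    test = _summaries_from_values(d, n_sections=4)
    cmp = compare_methods(ref, test, hours_reference=1.0, hours_test=1.0)
    assert cmp.accuracy_diameter_percent == pytest.approx(100.0)
    assert cmp.cv_reference_percent == pytest.approx(cmp.cv_test_percent)


def test_accuracy_from_pooled_means_matches_reported_value():
    ref = _summaries_from_values(np.full(100, 22.86))
    test = _summaries_from_values(np.full(100, 22.84))
    cmp = compare_methods(ref, test, hours_reference=54.0, hours_test=1.4)
    assert cmp.accuracy_diameter_percent == pytest.approx(99.91, abs=0.005)


def test_pooled_statistics_invariant_to_sectioning():
    """Only the pooled multiset of fibers matters, not how they are split
    into sections."""
    rng = np.random.default_rng(8)
    d = rng.normal(23, 7, 240)
    a = rng.normal(700, 150, 240)
    for n_sections in (1, 3, 8):
        ref = _summaries_from_values(d, areas=a, n_sections=n_sections)
        cmp = compare_methods(ref, ref, hours_reference=1.0, hours_test=1.0)
        if n_sections == 1:
            base = cmp
        else:
            assert cmp.mean_diameter_reference_um == pytest.approx(
                base.mean_diameter_reference_um
            )
            assert cmp.cv_reference_percent == pytest.approx(
                base.cv_reference_percent
            )
            assert cmp.mean_area_reference_um2 == pytest.approx(
                base.mean_area_reference_um2
            )


def test_pooled_cv_equals_direct_fiber_level_cv():
    rng = np.random.default_rng(4)
    d = rng.normal(20, 6, 150)
    summaries = _summaries_from_values(d, n_sections=5)
    cmp = compare_methods(summaries, summaries, hours_reference=1.0, hours_test=1.0)
    assert cmp.cv_reference_percent == pytest.approx(coefficient_of_variance(d))


def test_swapping_roles_changes_accuracy():
    ref = _summaries_from_values(np.full(50, 22.86))
    test = _summaries_from_values(np.full(50, 23.58))
    forward = compare_methods(ref, test, 1.0, 1.0)
    backward = compare_methods(test, ref, 1.0, 1.0)
    assert forward.accuracy_diameter_percent != backward.accuracy_diameter_percent


def test_dataset_counting_rule_in_productivity():
    ref = _summaries_from_values(np.full(100, 22.0))
    test = _summaries_from_values(np.full(200, 22.0))
    cmp = compare_methods(ref, test, hours_reference=2.0, hours_test=2.0)
    assert cmp.productivity_reference_per_h == pytest.approx(100 / 2.0)  # 1/fiber
    assert cmp.productivity_test_per_h == pytest.approx(2 * 200 / 2.0)  # 2/fiber


def test_compare_methods_rejects_empty_or_bad_hours():
    s = _summaries_from_values(np.full(10, 20.0))
    with pytest.raises(ValueError):
        compare_methods([], s, 1.0, 1.0)
    with pytest.raises(ValueError):
        compare_methods(s, s, 0.0, 1.0)
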