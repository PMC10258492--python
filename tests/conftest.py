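import numpy as np
import pytest

from fiberhisto.synth import SectionParams, generate_section


@pytest.fixture(scope="session")
def medium_section():
    """A ~110-fiber synthetic section at 2 px/µm, shared across tests.

    2 px/µm keeps fibers ~45 px across (quantization error well under the
    tolerances exercised) while the whole section stays small enough to
    segment in about a second.
    """
    params = SectionParams(
        image_size_px=(800, 800),
        px_per_um=2.0,
        seed=11,
    )
    image, gt = generate_section(params)
    return params, image, gt


@pytest.fixture(scope="session")
def large_section():
    """A >=1000-fiber synthetic section at the study's target morphology
    (mean lesser diameter 22.8 µm, CV 32%), used for parameter-recovery and
    segmentation-quality checks."""
    params = SectionParams(
        image_size_px=(2500, 2500),
        px_per_um=2.0,
        target_mean_diameter_um=22.8,
        target_cv_percent=32.0,
        seed=1,
    )
    image, gt = generate_section(params)
    assert len(gt.true_records) >= 1000
    return params, image, gt


def make_records(diameters, areas=None, source_id="img", start_id=1):
    """Build FiberRecord lists from raw metric arrays for statistics tests."""
    from fiberhisto.morphometry import FiberRecord

    diameters = np.asarray(diameters, dtype=float)
    if areas is None:
        areas = 0.7 * diameters**2
    return [
        FiberRecord(
            source_id=source_id,
            fiber_id=start_id + i,
            lesser_diameter_um=float(d),
            area_um2=float(a),
            centroid_x_px=0.0,
            centroid_y_px=0.0,
        )
        for i, (d, a) in enumerate(zip(diameters, areas))
    ]
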