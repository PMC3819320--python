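import numpy as np
import pytest

import pibquant as pq
from pibquant.phantom import frame_average, reference_curve


@pytest.fixture(scope="session")
def schedule():
    return pq.default_frame_schedule()


@pytest.fixture(scope="session")
def fine_ref():
    """Fine-grid cerebellar reference curve (t in minutes, activity)."""
    return reference_curve()


@pytest.fixture(scope="session")
def ref_tac(fine_ref, schedule):
    t, cr = fine_ref
    return pq.TimeActivityCurve(
        region="Cerebellum-Cortex",
        values=frame_average(t, cr, schedule),
        mid_times=schedule.mid_times,
        n_voxels=1000,
    )


@pytest.fixture(scope="session")
def default_phantom():
    """The default noiseless, unblurred phantom subject with ground truth."""
    return pq.build_phantom()


@pytest.fixture(scope="session")
def quantified_phantom(default_phantom):
    img, labels, truth = default_phantom
    report, results, tacs = pq.quantify(img, labels)
    return report, results, tacs, truth
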