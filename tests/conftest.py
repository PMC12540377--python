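import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scvq import synthetic_data as sd

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom():
    """Default zero-noise 12-tube phantom: (slab, truth mask, analytic truths)."""
    return sd.generate_phantom(sd.default_phantom_spec())


@pytest.fixture(scope="session")
def phantom_segments(phantom):
    from scvq import morphometry as mm

    _, truth_mask, _ = phantom
    return mm.extract_segments(truth_mask, min_skeleton_px=5)


@pytest.fixture(scope="session")
def cohort():
    """Default simulated cohort (364 subjects, male/female strata)."""
    return sd.generate_cohort(sd.default_cohort_spec(), seed=20251008)


def match_segment_to_truth(segment, truths):
    """Pair a measured segment with the same-side analytic tube it came from."""
    candidates = [t for t in truths if t.hemisphere == segment.hemisphere]
    return min(
        candidates,
        key=lambda t: abs(t.chord_mm - segment.chord_mm)
        + abs(t.tortuosity - segment.curvature),
    )
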