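import numpy as np
import pytest

from penaltypose import body25
from penaltypose.keypoint_io import Landmark, PersonFrame


def make_person(
    frame_index: int = 0,
    person_index: int = 0,
    base: tuple[float, float] = (400.0, 300.0),
    confidence: float = 0.9,
    missing_parts: set[int] = frozenset(),
    overrides: dict[int, tuple[float, float, float]] | None = None,
) -> PersonFrame:
    """A fully populated skeleton on a small grid, with optional sentinel
    landmarks and per-part overrides."""
    overrides = overrides or {}
    landmarks = []
    for part in range(body25.N_PARTS):
        if part in missing_parts:
            landmarks.append(Landmark(0.0, 0.0, 0.0))
        elif part in overrides:
            landmarks.append(Landmark(*overrides[part]))
        else:
            landmarks.append(
                Landmark(base[0] + 2.0 * part, base[1] + 1.0 * part, confidence)
            )
    return PersonFrame(frame_index, person_index, tuple(landmarks))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def person_factory():
    return make_person
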