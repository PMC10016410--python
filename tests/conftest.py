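import numpy as np
import pytest

from sustain_psp.model import EventGrid, SubtypeSequence


@pytest.fixture
def toy_grid():
    """Two biomarkers: A crosses z = 1 and 2 (z_max 3), B crosses z = 1
    (z_max 2). Three events total."""
    return EventGrid(["A", "B"], [[1.0, 2.0], [1.0]], [3.0, 2.0])


@pytest.fixture
def toy_sequence():
    """Ordering A1, B1, A2 on the toy grid (event indices 0, 2, 1)."""
    return SubtypeSequence(np.array([0, 2, 1]))


@pytest.fixture
def flat_grid():
    """Ten biomarkers with a single z = 1 event each, saturating at z = 5."""
    return EventGrid([f"b{i}" for i in range(10)],
                     [[1.0]] * 10, [5.0] * 10)


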