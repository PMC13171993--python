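import pytest

from jointgaze import Roi, RoiRole, ScreenGeometry


@pytest.fixture
def screen():
    return ScreenGeometry()


@pytest.fixture
def face_roi():
    return Roi("Face", RoiRole.FACE, (810, 150, 1110, 450))


@pytest.fixture
def pair_rois(face_roi):
    """Face / Target / Other regions for trigger tests (non-overlapping)."""
    return [
        face_roi,
        Roi("Target", RoiRole.TABLET_LEFT, (150, 500, 650, 850)),
        Roi("Other", RoiRole.OTHER, (1300, 500, 1800, 850)),
    ]
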