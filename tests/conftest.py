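import numpy as np
import pytest

from annovox.core import LabelVolume, Project, add_text_field, define_roi


@pytest.fixture
def project():
    """Two area ROIs (kidney, tumor), one point ROI, one restricted field."""
    proj = Project()
    define_roi(proj, "kidney", radlex_id="RID205")
    define_roi(proj, "tumor", radlex_id="RID3957")
    define_roi(proj, "L3_vertebra", kind="point")
    add_text_field(proj, "contrast_phase", ["non-contrast", "arterial", "venous", "delayed"])
    add_text_field(proj, "comment")
    return proj


@pytest.fixture
def volume():
    return LabelVolume((16, 16, 10))


@pytest.fixture
def image():
    rng = np.random.default_rng(7)
    return rng.normal(50.0, 5.0, size=(16, 16, 10))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_label_volume(rng, shape=(8, 8, 6), bits=(1, 2, 4)) -> LabelVolume:
    vol = LabelVolume(shape)
    for bit in bits:
        mask = rng.random(shape) < 0.3
        vol.labels[mask] |= np.uint64(bit)
    return vol
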