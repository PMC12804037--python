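import numpy as np
import pytest

from tsrquant import DEFAULT_CLASS_MAP, LabelMask

CM = DEFAULT_CLASS_MAP
BG = CM.roles["background"]
TUM = CM.roles["tumor_epithelium"]
STR = CM.roles["tumor_stroma"]
NEC = CM.roles["necrosis"]
MUC = CM.roles["mucin"]
EXC = CM.roles["excluded"]


def make_mask(data, mpp=1.0, slide_id="test", classmap=CM) -> LabelMask:
    return LabelMask(data=np.asarray(data, dtype=np.uint8), mpp=mpp,
                     slide_id=slide_id, classmap=classmap)


@pytest.fixture
def uniform_stroma_mask():
    return make_mask(np.full((120, 120), STR))


@pytest.fixture
def mixed_mask():
    """Checkerboard-ish stroma/tumor mask: eligible everywhere a disc fits."""
    rng = np.random.default_rng(42)
    data = np.where(rng.random((200, 200)) < 0.6, STR, TUM)
    return make_mask(data)
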