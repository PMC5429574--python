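import numpy as np
import pytest

from combistate import MarkPanel

# the nine-mark reference panel, bit order = panel order (leftmost bit first)
NINE_MARKS = ("TCF7L2", "Pol-II", "H3K4me1", "H3K4me3", "H3K9me3",
              "H3K27ac", "H3K36me3", "H3K27me3", "DNase")


@pytest.fixture
def nine_mark_panel() -> MarkPanel:
    return MarkPanel(marks=NINE_MARKS, tf="TCF7L2")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
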