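import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from proximatome.io_model import (
    CountMatrix,
    ProteinAnnotation,
    Sample,
    SampleDesign,
)


@pytest.fixture
def design_3v3():
    return SampleDesign(
        [Sample(f"bait_{r}", "bait", r) for r in (1, 2, 3)]
        + [Sample(f"ctrl_{r}", "control", r) for r in (1, 2, 3)]
    )


@pytest.fixture
def design_2v2():
    return SampleDesign(
        [Sample("b1", "bait", 1), Sample("b2", "bait", 2),
         Sample("c1", "control", 1), Sample("c2", "control", 2)]
    )


@pytest.fixture
def toy_matrix(design_3v3):
    counts = np.array(
        [
            [10, 12, 14, 2, 3, 4],   # enriched
            [5, 5, 5, 5, 5, 5],      # flat
            [9, 9, 9, 0, 0, 0],      # zero control
        ]
    )
    return CountMatrix(["P1", "P2", "P3"], design_3v3.sample_ids, counts)


@pytest.fixture
def annotations():
    return {
        "P1": ProteinAnnotation("P1", "GLS", 669, True, (1, 16), False),
        "P2": ProteinAnnotation("P2", "SPAG5", 1193, False, None, False),
        "P3": ProteinAnnotation("P3", "IMMT", 758, True, (1, 32), False),
    }


def write_tsv(path, text):
    path.write_text(text)
    return path
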