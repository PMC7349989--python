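import hypothesis
import numpy as np
import pandas as pd
import pytest

from cgimeth.io import BetaMatrix, SampleSheet

hypothesis.settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def small_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["T1", "T2", "N1", "N2"],
                "group": ["tumour", "tumour", "normal", "normal"],
                "cohort": ["discovery"] * 4,
                "pair_id": ["p1", "p2", "p1", "p2"],
            }
        )
    )


@pytest.fixture
def small_matrix(small_sheet) -> BetaMatrix:
    from cgimeth.io import CGIKey

    keys = [CGIKey("chr1", 100, 199, "A"), CGIKey("chr2", 500, 899, "B")]
    values = pd.DataFrame(
        [[0.5, 0.6, 0.1, 0.2], [0.4, 0.5, 0.3, 0.35]],
        index=keys,
        columns=["T1", "T2", "N1", "N2"],
    )
    return BetaMatrix(values, small_sheet)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
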