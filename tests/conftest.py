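import numpy as np
import pandas as pd
import pytest

from lepinet import GroupDesign, SpectralCountMatrix


@pytest.fixture
def tiny_counts() -> SpectralCountMatrix:
    """3 proteins x 4 samples, hand-sized."""
    df = pd.DataFrame(
        {
            "A1": [10, 0, 5],
            "A2": [12, 1, 4],
            "B1": [0, 8, 5],
            "B2": [1, 9, 6],
        },
        index=["P1", "P2", "P3"],
        dtype=np.int64,
    )
    return SpectralCountMatrix(df)


@pytest.fixture
def tiny_design() -> GroupDesign:
    return GroupDesign(
        pd.Series(["A", "A", "B", "B"], index=["A1", "A2", "B1", "B2"], name="group")
    )


@pytest.fixture
def cohort_design() -> GroupDesign:
    """The 5/5/4 AIS/MIA/LPA design used throughout."""
    samples = [f"AIS_{i}" for i in range(1, 6)] + [f"MIA_{i}" for i in range(1, 6)] + [
        f"LPA_{i}" for i in range(1, 5)
    ]
    groups = ["AIS"] * 5 + ["MIA"] * 5 + ["LPA"] * 4
    return GroupDesign(pd.Series(groups, index=samples, name="group"))


def write_tsv(path, text: str) -> str:
    path.write_text(text.replace(",", "\t"), encoding="utf-8")
    return str(path)
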