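import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from netswitch.io_formats import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 samples, two groups, linear scale."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(10, 100, size=(4, 6)),
        index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series(["ctl"] * 3 + ["case"] * 3, index=values.columns)
    return ExpressionMatrix(values, groups)


@pytest.fixture
def series_matrix_file(tmp_path):
    text = "\n".join([
        "!Series_title\t\"toy\"",
        '!Sample_characteristics_ch1\t"activity: low"\t"activity: high"',
        "!series_matrix_table_begin",
        '"ID_REF"\t"GSM1"\t"GSM2"',
        '"gA"\t1.5\t2.5',
        '"gB"\t3.0\t4.0',
        "!series_matrix_table_end",
        "",
    ])
    path = tmp_path / "toy_series_matrix.txt"
    path.write_text(text)
    return path
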