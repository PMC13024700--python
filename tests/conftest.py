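import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vmrkit import MethylationMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def matrix_from_counts(meth, total, groups, chrom="chr1", window_size=100):
    """Build a MethylationMatrix from plain count arrays (windows x samples)."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    samples = list(groups)
    n = meth.shape[0]
    windows = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * window_size,
            "end": np.arange(n) * window_size + window_size,
        },
        index=pd.RangeIndex(n, name="window_id"),
    )
    return MethylationMatrix(
        windows=windows,
        meth=pd.DataFrame(meth, index=windows.index, columns=samples).astype(np.int64),
        total=pd.DataFrame(total, index=windows.index, columns=samples).astype(np.int64),
        groups=pd.Series(groups, name="group"),
    )


@pytest.fixture
def two_group_matrix():
    """Six-sample matrix, three windows, with an obvious group contrast."""
    meth = [[5, 6, 5, 15, 16, 14], [0, 1, 0, 0, 1, 1], [18, 19, 17, 18, 19, 17]]
    total = [[20] * 6] * 3
    groups = {
        "a1": "young", "a2": "young", "a3": "young",
        "b1": "old", "b2": "old", "b3": "old",
    }
    return matrix_from_counts(meth, total, groups)
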