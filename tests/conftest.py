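import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hypoxikit import CountMatrix


def make_count_matrix(counts_by_sample: dict[str, list[int]], gene_ids=None,
                      sample_type="cdx") -> CountMatrix:
    """Small CountMatrix with uniform annotations for tests."""
    counts = pd.DataFrame(counts_by_sample)
    counts.index = gene_ids or [f"g{i}" for i in range(len(counts))]
    ann = pd.DataFrame(
        {
            "sample_id": list(counts.columns),
            "sample_type": sample_type,
            "model_id": [f"m{i}" for i in range(len(counts.columns))],
            "replicate": 1,
            "group": "",
        }
    ).set_index("sample_id")
    return CountMatrix(counts=counts.astype(np.int64), annotations=ann)


@pytest.fixture
def toy_matrix():
    return make_count_matrix({"s1": [10, 5, 30], "s2": [5, 5, 60], "s3": [15, 5, 90]})
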