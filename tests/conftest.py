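import numpy as np
import pandas as pd
import pytest

import isophene as ip


@pytest.fixture(scope="session")
def day7():
    """One fixed realization of the day-7 five-component mixture."""
    mix = ip.preset_mixture("day7")
    ratios, truth = ip.generate_ratio_table(mix, seed=11)
    return mix, ratios, truth


@pytest.fixture(scope="session")
def blobs():
    """Four tight, well-separated 2-D blobs with known structure."""
    rng = np.random.default_rng(5)
    centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
    X = np.vstack([c + 0.3 * rng.standard_normal((12, 2)) for c in centers])
    labels = np.repeat(np.arange(1, 5), 12)
    return X, labels, centers


@pytest.fixture
def small_count_table():
    return pd.DataFrame({
        "session": ["s"] * 3, "region": ["r"] * 3, "roi_id": [1, 2, 3],
        "c12": [10000, 900, 5000], "c13": [109, 100, 500],
        "nc14": [20000, 1900, 10000], "nc15": [70, 100, 400],
        "s32": [1000, 500, 800], "s33": [8, 50, 30], "s34": [44, 20, 35],
        "centroid_x": [1.0, 2.0, 3.0], "centroid_y": [1.0, 2.0, 3.0],
        "area_px": [10, 20, 30], "n_planes": [1, 1, 1],
    })
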