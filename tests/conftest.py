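import numpy as np
import pandas as pd
import pytest

from funcprior.annotation import AnnotationMatrix, FeatureDef, HitLabeling, ProxyMap, Variant


@pytest.fixture
def small_variants():
    return [
        Variant("rs1", "1", 100),
        Variant("rs2", "1", 200),
        Variant("rs3", "2", 300),
        Variant("rs4", "6", 30_000_000),
        Variant("rs5", "X", 400),
    ]


@pytest.fixture
def small_matrix():
    data = pd.DataFrame(
        {
            "tf_a": [1.0, 0.0, 0.0, 1.0],
            "tf_b": [0.0, 1.0, 0.0, 0.0],
            "eqtl": [0.0, 0.0, 1.0, 1.0],
            "cons": [0.4, 0.0, 1.3, 0.2],
        },
        index=pd.Index(["rs1", "rs2", "rs3", "rs4"], name="id"),
    )
    defs = [
        FeatureDef("tf_a", "binary", clump_group="tf"),
        FeatureDef("tf_b", "binary", clump_group="tf"),
        FeatureDef("eqtl", "binary"),
        FeatureDef("cons", "quantitative"),
    ]
    return AnnotationMatrix(data, defs)


@pytest.fixture
def proxy_map():
    return ProxyMap([("rs1", "rs2", 0.9), ("rs3", "rs4", 0.85)], r2_threshold=0.8)


@pytest.fixture
def labelled_universe():
    rng = np.random.default_rng(42)
    n = 400
    ids = [f"s{i:04d}" for i in range(n)]
    x = rng.binomial(1, 0.3, size=(n, 3)).astype(float)
    eta = -1.5 + x @ np.array([1.5, 0.8, 0.0])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    data = pd.DataFrame(x, columns=["f0", "f1", "f2"], index=pd.Index(ids, name="id"))
    defs = [FeatureDef(c, "binary") for c in data.columns]
    matrix = AnnotationMatrix(data, defs)
    labels = HitLabeling(
        hit_ids=frozenset(i for i, yy in zip(ids, y) if yy),
        nonhit_ids=frozenset(i for i, yy in zip(ids, y) if not yy),
    )
    return matrix, labels
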