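import warnings

import numpy as np
import pandas as pd
import pytest

import branchforge.pipeline as pipeline
import branchforge.preprocess as preprocess
import branchforge.synthio as synthio


@pytest.fixture(scope="session")
def sgn_small():
    """Small SGN-preset simulation shared by read-only tests."""
    return synthio.simulate_sgn(n_cells=600, n_doublets=12, seed=0)


@pytest.fixture(scope="session")
def sgn_norm(sgn_small):
    """Normalised copy of the small preset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess.normalize_log(sgn_small)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full end-to-end pipeline run at the preset's default conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_sgn_pipeline(seed=0)


@pytest.fixture
def single_segment_spec():
    return synthio.LineageSpec(
        segments=[synthio.Segment("root", None, 0.0, 1.0)],
        time_windows=[("t0", (0.0, 1.0))],
    )


@pytest.fixture
def y_points():
    """Noisy Y-shaped 2-D point cloud with arc-length ground truth."""
    rng = np.random.default_rng(7)
    n = 300
    t = rng.uniform(0, 1, n)
    arm = rng.integers(0, 3, n)
    pts = np.empty((n, 2))
    pts[arm == 0] = np.c_[t[arm == 0], np.zeros((arm == 0).sum())]
    pts[arm == 1] = np.c_[1 + 0.7 * t[arm == 1], 0.7 * t[arm == 1]]
    pts[arm == 2] = np.c_[1 + 0.7 * t[arm == 2], -0.7 * t[arm == 2]]
    pts += rng.normal(0, 0.03, pts.shape)
    return pts, t, arm


@pytest.fixture
def five_cell_qc_fixture():
    """Five cells spanning both QC thresholds; exactly one survives."""
    counts = np.zeros((5, 3000), dtype=np.int64)
    for i, nd in enumerate([999, 1000, 1001, 2000, 3000]):
        counts[i, :nd] = 1
    meta = pd.DataFrame(
        {"spikein_fraction": [0.01, 0.01, 0.06, 0.05, 0.0]},
        index=pd.Index([f"c{i}" for i in range(5)], name="cell"),
    )
    genes = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(3000)], name="gene"))
    return synthio.ExpressionData(counts=counts, cell_meta=meta, gene_meta=genes)
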