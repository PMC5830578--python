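import numpy as np
import pandas as pd
import pytest

from gazescape.gridding import GridSpec, label_frames
from gazescape.pipeline import preprocess_study_gaze
from gazescape.synthetic import StudyConfig, make_study


@pytest.fixture(scope="session")
def mini_study():
    """Default 4 participants x 6 videos study, shared across tests."""
    return make_study(StudyConfig(), seed=11)


@pytest.fixture(scope="session")
def mini_labels(mini_study):
    frame_gaze = preprocess_study_gaze(mini_study)
    return label_frames(frame_gaze, mini_study.config.grid)


@pytest.fixture(scope="session")
def probit_rows():
    """Synthetic case-control-style rows with known coefficients."""
    from scipy.stats import norm

    rng = np.random.default_rng(123)
    n = 3000
    df = pd.DataFrame(
        {
            "centrality_z": rng.normal(size=n),
            "saliency_z": rng.normal(size=n),
            "roi_z": rng.normal(size=n),
        }
    )
    eta = 0.1 + 0.4 * df["centrality_z"] - 0.3 * df["saliency_z"] + 0.6 * df["roi_z"]
    df["fixated"] = (rng.random(n) < norm.cdf(eta)).astype(int)
    return df


@pytest.fixture
def grid_32x18():
    return GridSpec(cell_px=40, n_cols=32, n_rows=18)
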