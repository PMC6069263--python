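import numpy as np
import pytest

import hrvselect as hv


@pytest.fixture(scope="session")
def calibrated_table():
    """One calibrated three-group feature table (n=30/group, fixed seed)."""
    return hv.generate_feature_table(n_per_group=30, seed=0)


@pytest.fixture(scope="session")
def calibrated_ranking(calibrated_table):
    return hv.SVMRFE.from_dataframe(calibrated_table).fit()


@pytest.fixture(scope="session")
def clean_tachogram():
    """150-s mixed LF+HF tachogram with mild jitter."""
    profile = hv.RRProfile(mean_rr=150.0, lf_amp=5.0, hf_amp=3.0,
                           lf_freq=0.4, hf_freq=2.0, noise_sd=1.0,
                           duration=150.0)
    return hv.generate_rr_tachogram(profile, seed=3)


@pytest.fixture(scope="session")
def separable_toy():
    """Three well-separated Gaussian blobs in 2-D (trivially classifiable)."""
    rng = np.random.default_rng(42)
    centers = {"control": (0.0, 0.0), "SS": (10.0, 0.0), "LS": (0.0, 10.0)}
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(c, 0.1, size=(20, 2)))
        y += [label] * 20
    return np.vstack(X), np.array(y)
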