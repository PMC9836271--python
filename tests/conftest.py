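import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ergosc.preprocess import Epoch, Recording

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

FS = 1000.0


@pytest.fixture
def tone_recording():
    """60 s unit-amplitude 5 Hz sinusoid at 1 kHz."""
    t = np.arange(int(60 * FS)) / FS
    return Recording(fs=FS, samples=np.sin(2 * np.pi * 5.0 * t), subject_id="tone")


@pytest.fixture
def tone_epoch(tone_recording):
    return Epoch(fs=FS, samples=tone_recording.samples)


def gaussian_feature_table(
    n_per_class: int,
    class_shifts: dict,
    n_features: int = 10,
    seed: int = 0,
    frags_per_subject: int = 1,
) -> pd.DataFrame:
    """Small synthetic feature table: isotropic Gaussians with per-class mean
    shift on the first feature (stands in for spectral features in classifier
    unit tests)."""
    rng = np.random.default_rng(seed)
    rows, labels, sids, fids = [], [], [], []
    for lab, shift in class_shifts.items():
        for i in range(n_per_class):
            x = rng.standard_normal(n_features)
            x[0] += shift
            rows.append(x)
            labels.append(lab)
            sids.append(f"{lab}_{i // frags_per_subject}")
            fids.append(f"{lab}_{i}")
    df = pd.DataFrame(np.vstack(rows), columns=[f"v{j}" for j in range(n_features)])
    df["fragment_id"] = fids
    df["subject_id"] = sids
    df["label"] = labels
    return df
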