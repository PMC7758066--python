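import numpy as np
import pandas as pd
import pytest

from distexp import EpochSet, Montage, SimConfig, generate_design, simulate_rts


@pytest.fixture(scope="session")
def montage():
    return Montage.default_64()


def make_trials(n: int, condition: str = "DpTp_unique",
                subject_id: int = 0) -> pd.DataFrame:
    """Minimal valid trial table with n rows (distractor-present)."""
    rows = []
    for i in range(n):
        rows.append(dict(
            subject_id=subject_id, session=1, condition=condition,
            block=1, trial=i + 1, distractor_loc=2, target_loc=0,
            high_prob_loc=2, distractor_sf="low",
            target_sf="low" if condition == "DpTp_identical" else "medium",
            target_tilt="left", distractor_orient="vertical",
            rt_ms=500.0, correct=True))
    from distexp.data_model import TRIAL_COLUMNS
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    df["distractor_loc"] = df["distractor_loc"].astype("Int64")
    return df


def make_epochs(data: np.ndarray, montage: Montage, sfreq: float = 256.0,
                tmin_ms: float = -500.0,
                trials: pd.DataFrame | None = None) -> EpochSet:
    n_trials, n_ch, n_samp = data.shape
    assert n_ch == len(montage.channels)
    times = tmin_ms + 1000.0 / sfreq * np.arange(n_samp)
    if trials is None:
        trials = make_trials(n_trials)
    return EpochSet(data=data, sfreq=sfreq, times=times, montage=montage,
                    trials=trials)


@pytest.fixture(scope="session")
def exp2_table():
    cfg = SimConfig(seed=11, experiment=2, n_subjects=1)
    return simulate_rts(generate_design(cfg, 0), cfg)
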