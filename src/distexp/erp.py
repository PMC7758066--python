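"""Lateralized ERP analysis (N2pc / Pd).

Trials with one lateral and one vertical-midline stimulus isolate the
stimulus-evoked lateralized response: contralateral and ipsilateral
waveforms over the posterior electrode pool (O1/O2, PO3/PO4, PO7/PO8) are
averaged separately, and their difference carries the N2pc (negative,
attentional selection) and Pd (positive, active suppression) components.
Component windows are chosen data-driven: the extreme peak of the
condition-averaged difference wave inside 100-400 ms, padded by 40 ms on
both sides.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import (
    ERP_POOL,
    LATERAL_BELOW_LOCS,
    MIDLINE_LOCS,
    EpochSet,
    ERPWaveforms,
    location_side,
)
from .exceptions import ParameterError

__all__ = [
    "select_lateralized_trials", "contra_ipsi_waveforms",
    "find_component_window", "mean_amplitude",
]


def select_lateralized_trials(table: pd.DataFrame, stimulus_class: str
                              ) -> dict[tuple[str, str], np.ndarray]:
    """Row indices per (condition, probability) for lateralized-ERP analysis.

    ``stimulus_class='distractor'``: distractor at a lateral below-midline
    location with the target on the vertical midline. ``'target'``: the
    mirror criterion (lateral target, distractor on the midline; for
    distractor-absent trials a lateral target suffices). Probability tags
    the lateral stimulus's location as 'high' (== high_prob_loc) or 'low'.
    """
    if stimulus_class not in ("target", "distractor"):
        raise ParameterError(f"stimulus_class must be target|distractor, "
                             f"got {stimulus_class!r}")
    d_loc = table["distractor_loc"]
    t_loc = table["target_loc"]
    present = d_loc.notna().to_numpy()
    d_lat = present & d_loc.isin(LATERAL_BELOW_LOCS).to_numpy()
    t_mid = t_loc.isin(MIDLINE_LOCS).to_numpy()
    t_lat = t_loc.isin(LATERAL_BELOW_LOCS).to_numpy()
    d_mid = present & d_loc.isin(MIDLINE_LOCS).to_numpy()

    if stimulus_class == "distractor":
        mask = d_lat & t_mid
        lat_loc = d_loc
    else:
        mask = t_lat & (d_mid | ~present)
        lat_loc = t_loc

    is_high = (lat_loc.to_numpy(dtype=float, na_value=-1)
               == table["high_prob_loc"].to_numpy())
    subsets: dict[tuple[str, str], np.ndarray] = {}
    for cond in pd.unique(table["condition"]):
        cmask = (table["condition"] == cond).to_numpy()
        for prob, pmask in (("high", is_high), ("low", ~is_high)):
            idx = np.flatnonzero(mask & cmask & pmask)
            if len(idx) == 0:
                warnings.warn(f"empty lateralized subset "
                              f"({cond}, {prob}, {stimulus_class})")
                continue
            subsets[(cond, prob)] = idx
    return subsets


def contra_ipsi_waveforms(epochs: EpochSet,
                          subsets: dict[str, dict[tuple[str, str], np.ndarray]],
                          pool: tuple[str, ...] = ERP_POOL) -> ERPWaveforms:
    """Average contralateral/ipsilateral waveforms over the electrode pool.

    ``subsets`` maps stimulus class ('target'/'distractor') to the output of
    :func:`select_lateralized_trials`. The contralateral hemisphere is the
    one opposite the lateral stimulus; pooling is trials first, then the
    three channels of the hemisphere.
    """
    left_pool = [epochs.montage.index(c)
                 for c in epochs.montage.hemisphere_pool(pool, "left")]
    right_pool = [epochs.montage.index(c)
                  for c in epochs.montage.hemisphere_pool(pool, "right")]
    contra: dict[tuple[str, str, str], np.ndarray] = {}
    ipsi: dict[tuple[str, str, str], np.ndarray] = {}
    n_trials: dict[tuple[str, str, str], int] = {}
    for stim_class, class_subsets in subsets.items():
        loc_col = "distractor_loc" if stim_class == "distractor" else "target_loc"
        for (cond, prob), idx in class_subsets.items():
            locs = epochs.trials[loc_col].iloc[idx].to_numpy(dtype=float)
            sides = np.array([location_side(int(l)) for l in locs])
            if np.any(sides == "midline"):
                raise RuntimeError("midline stimulus in a lateralized subset; "
                                   "trial selection is inconsistent")
            contra_sum = np.zeros(len(epochs.times))
            ipsi_sum = np.zeros(len(epochs.times))
            for i, side in zip(idx, sides):
                c_pool, i_pool = ((right_pool, left_pool) if side == "left"
                                  else (left_pool, right_pool))
                contra_sum += epochs.data[i, c_pool, :].mean(axis=0)
                ipsi_sum += epochs.data[i, i_pool, :].mean(axis=0)
            key = (cond, prob, stim_class)
            contra[key] = contra_sum / len(idx)
            ipsi[key] = ipsi_sum / len(idx)
            n_trials[key] = len(idx)
    return ERPWaveforms(times=epochs.times.copy(), contra=contra, ipsi=ipsi,
                        n_trials=n_trials)


def find_component_window(diff: np.ndarray, times: np.ndarray,
                          search: tuple[float, float] = (100.0, 400.0),
                          polarity: str = "negative",
                          pad_ms: float = 40.0) -> tuple[float, float]:
    """Peak +- 40 ms window around the extreme of a difference waveform.

    The peak is the most negative (N2pc) or most positive (Pd) sample inside
    the closed search window on the native time grid; ties resolve to the
    earliest sample. A peak on the search boundary triggers a warning.
    """
    mask = (times >= search[0]) & (times <= search[1])
    if not mask.any():
        raise ParameterError(f"search window {search} outside the time axis")
    seg = diff[mask]
    seg_times = times[mask]
    pick = np.argmin(seg) if polarity == "negative" else np.argmax(seg)
    if pick in (0, len(seg) - 1):
        warnings.warn("component peak lies on the search-window boundary")
    peak = float(seg_times[pick])
    return (peak - pad_ms, peak + pad_ms)


def mean_amplitude(waves: ERPWaveforms,
                   window: tuple[float, float]) -> pd.DataFrame:
    """Mean contra/ipsi voltage in a component window, per design cell.

    Returns one row per (condition, probability, stimulus_class, hemifield)
    with the mean microvolts, ready for a repeated-measures ANOVA with
    factors Stimulus Class x Condition x Location x Hemifield.
    """
    mask = (waves.times >= window[0]) & (waves.times <= window[1])
    if not mask.any():
        raise ParameterError(f"window {window} outside the epoch")
    rows = []
    for key in waves.keys():
        cond, prob, stim_class = key
        for hemi, data in (("contra", waves.contra[key]),
                           ("ipsi", waves.ipsi[key])):
            rows.append({"condition": cond, "probability": prob,
                         "stimulus_class": stim_class, "hemifield": hemi,
                         "mean_uv": float(data[mask].mean()),
                         "n_trials": waves.n_trials[key]})
    return pd.DataFrame(rows)
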