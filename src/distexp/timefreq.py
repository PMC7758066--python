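"""Morlet wavelet time-frequency decomposition and alpha lateralization.

Power is obtained by convolving each trial and channel with a family of
complex Morlet wavelets (frequency-domain multiplication) and taking the
squared magnitude. Hemispheric asymmetry of anticipatory alpha power is
quantified with the self-normalizing lateralization index
(P_contra - P_ipsi) / (P_contra + P_ipsi), which needs no pre-stimulus
baseline window.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal

from .data_model import ALPHA_POOL, EpochSet, TFRSet, WaveletParams, location_side
from .exceptions import ParameterError

__all__ = [
    "morlet_family", "tfr_power", "lateralization_index",
    "lateralization_index_by_high_prob", "alpha_band_average",
]


def morlet_family(params: WaveletParams, sfreq: float) -> list[np.ndarray]:
    """Complex Morlet wavelets w(t) = exp(i*2*pi*f*t) * exp(-t^2 / 2 s^2).

    The Gaussian width is s = cycles / (2*pi*f); support is +-5 s and each
    wavelet is L2-normalized.
    """
    if np.any(params.freqs >= sfreq / 2.0):
        raise ParameterError("wavelet frequencies must stay below Nyquist")
    wavelets = []
    for f, s in zip(params.freqs, params.widths):
        n_half = int(np.ceil(5.0 * s * sfreq))
        t = np.arange(-n_half, n_half + 1) / sfreq
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2.0 * s ** 2))
        wavelets.append(w / np.linalg.norm(w))
    return wavelets


def tfr_power(epochs: EpochSet, params: WaveletParams | None = None,
              decim: int = 4, channels: tuple[str, ...] | None = None) -> TFRSet:
    """Wavelet power per trial x frequency x channel x time.

    Convolution runs in the frequency domain (FFT product); the time axis is
    decimated by ``decim`` after the squared magnitude. A warning is issued
    when the epoch padding cannot absorb the widest wavelet's edge effects.
    """
    params = params or WaveletParams.default()
    channels = channels or epochs.montage.scalp_channels
    ch_idx = np.array([epochs.montage.index(c) for c in channels])
    data = epochs.data[:, ch_idx, :]
    n_samp = data.shape[-1]
    wavelets = morlet_family(params, epochs.sfreq)
    if max(len(w) for w in wavelets) // 2 > n_samp // 4:
        warnings.warn("epoch shorter than 2x the widest wavelet half-length; "
                      "edge samples will leak into the analysis window")
    times = epochs.times[::decim]
    power = np.empty((data.shape[0], len(wavelets), len(ch_idx), len(times)))
    for k, w in enumerate(wavelets):
        conv = sp_signal.fftconvolve(data, w[None, None, :], mode="same", axes=-1)
        power[:, k] = np.abs(conv[..., ::decim]) ** 2
    return TFRSet(power=power, freqs=params.freqs.copy(), times=times,
                  cycles=params.cycles.copy(), channels=tuple(channels),
                  trials=epochs.trials.copy())


def _pool_power(tfr: TFRSet, pool: tuple[str, ...],
                trial_mask: np.ndarray | None = None) -> np.ndarray:
    idx = [tfr.channels.index(c) for c in pool]
    p = tfr.power if trial_mask is None else tfr.power[trial_mask]
    return p[:, :, idx, :].mean(axis=(0, 2))  # trials then channels -> (freq, time)


def lateralization_index(tfr: TFRSet, contra: tuple[str, ...],
                         ipsi: tuple[str, ...]) -> np.ndarray:
    """(P_contra - P_ipsi) / (P_contra + P_ipsi) over frequency x time.

    Power is averaged over trials, then over the channels of each pool
    (ratio of means). Points with zero total power are returned as NaN.
    """
    pc = _pool_power(tfr, contra)
    pi = _pool_power(tfr, ipsi)
    denom = pc + pi
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (pc - pi) / denom, np.nan)
    return out


def lateralization_index_by_high_prob(tfr: TFRSet,
                                      pairs: tuple[str, ...] = ALPHA_POOL
                                      ) -> np.ndarray:
    """Lateralization index with contra/ipsi resolved per trial.

    Each trial's contralateral pool is the hemisphere opposite its
    high-probability distractor location (which must be lateral). Power is
    pooled over all trials before the ratio.
    """
    trials = tfr.trials
    sides = trials["high_prob_loc"].map(location_side)
    if (sides == "midline").any():
        raise ParameterError("high_prob_loc on the vertical midline has no "
                             "contra/ipsi hemisphere")
    left_chs = tuple(c for c in pairs if c.endswith(("1", "3", "5", "7", "9")))
    right_chs = tuple(c for c in pairs if c not in left_chs)
    pc_parts, pi_parts, weights = [], [], []
    for side, contra, ipsi in (("left", right_chs, left_chs),
                               ("right", left_chs, right_chs)):
        mask = (sides == side).to_numpy()
        if not mask.any():
            continue
        pc_parts.append(_pool_power(tfr, contra, mask))
        pi_parts.append(_pool_power(tfr, ipsi, mask))
        weights.append(mask.sum())
    w = np.asarray(weights, dtype=float)[:, None, None] / sum(weights)
    pc = (np.stack(pc_parts) * w).sum(axis=0)
    pi = (np.stack(pi_parts) * w).sum(axis=0)
    denom = pc + pi
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (pc - pi) / denom, np.nan)


def alpha_band_average(index: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                       band: tuple[float, float] = (8.0, 12.0),
                       window: tuple[float, float] = (-750.0, 0.0)
                       ) -> tuple[np.ndarray, float]:
    """Average a frequency x time series over the alpha band and a window.

    Frequency bins are included when their center lies inside the closed
    ``band`` interval. Returns (time series, scalar window mean).
    """
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    if not fmask.any():
        raise ParameterError(f"no frequency bins inside band {band}")
    series = np.nanmean(index[fmask, :], axis=0)
    tmask = (times >= window[0]) & (times <= window[1])
    if not tmask.any():
        raise ParameterError(f"no timepoints inside window {window}")
    return series, float(np.nanmean(series[tmask]))
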