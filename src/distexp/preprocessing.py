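"""EEG cleaning chain.

Order of operations mirrors standard lab practice for this paradigm:
re-reference to the earlobe average, 0.1 Hz zero-phase high-pass, epoching
(done by the generator), adaptive EMG-burst rejection in the 110-140 Hz
band, ocular regression, bad-channel interpolation, and HEOG step rejection.
Every step appends itself with its parameters to the EpochSet provenance log.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .data_model import EpochSet
from .exceptions import ChannelError, InsufficientDataError, ParameterError

__all__ = [
    "rereference", "fir_filter", "baseline_correct", "detect_emg_artifacts",
    "detect_heog_steps", "interpolate_channels", "ocular_regression",
    "preprocess",
]


def rereference(epochs: EpochSet, ref_channels=("A1", "A2")) -> EpochSet:
    """Subtract the mean of ``ref_channels`` from every channel."""
    try:
        ref_idx = [epochs.montage.index(c) for c in ref_channels]
    except ChannelError:
        raise ChannelError(f"reference channels {ref_channels} not all present")
    ref = epochs.data[:, ref_idx, :].mean(axis=1, keepdims=True)
    out = epochs.copy(data=epochs.data - ref)
    out.log("rereference", ref_channels=list(ref_channels))
    return out


def design_fir(kind: str, cutoff_hz: float, sfreq: float,
               max_taps: int | None = None) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) FIR kernel.

    Transition bandwidth is max(0.25 * cutoff, 0.1 Hz). High-pass kernels
    are built by spectral inversion of the complementary low-pass, which
    pins the DC gain to exactly zero even when the kernel is truncated to
    the epoch length.
    """
    nyq = sfreq / 2.0
    if cutoff_hz >= nyq:
        raise ParameterError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    trans_bw = max(0.25 * cutoff_hz, 0.1)
    n_taps = int(np.ceil(3.3 * sfreq / trans_bw))
    n_taps |= 1  # odd length -> symmetric, integer group delay
    if max_taps is not None and n_taps > max_taps:
        n_taps = (max_taps - 1) | 1
    lp = sp_signal.firwin(n_taps, cutoff_hz, window="hamming", fs=sfreq)
    if kind == "lowpass":
        return lp
    if kind == "highpass":
        hp = -lp
        hp[n_taps // 2] += 1.0
        return hp
    raise ParameterError(f"kind must be 'lowpass' or 'highpass', got {kind!r}")


def fir_filter(epochs: EpochSet, kind: str, cutoff_hz: float) -> EpochSet:
    """Zero-phase FIR filter along time (symmetric kernel, 'same' output).

    The kernel is capped at half the epoch length so that at least the
    central half of every epoch is covered by full kernel overlap (the
    epochs carry 500 ms padding on both sides for exactly this reason);
    a very low cutoff on short epochs therefore gets a wider transition
    band, but its DC null is exact.
    """
    taps = design_fir(kind, cutoff_hz, epochs.sfreq,
                      max_taps=epochs.data.shape[-1] // 2)
    out_data = sp_signal.fftconvolve(
        epochs.data, taps[None, None, :], mode="same", axes=-1)
    out = epochs.copy(data=out_data)
    out.log("fir_filter", kind=kind, cutoff_hz=cutoff_hz, n_taps=len(taps))
    return out


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Per trial and channel, subtract the mean over ``window`` (ms)."""
    lo, hi = window
    mask = epochs.time_mask(lo, hi)
    if not mask.any():
        raise ParameterError(f"baseline window {window} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    out = epochs.copy(data=epochs.data - base)
    out.log("baseline_correct", window=list(window))
    return out


def detect_emg_artifacts(epochs: EpochSet, band: tuple[float, float] = (110.0, 140.0),
                         z_init: float = 4.0, z_cap: float = 12.0,
                         z_step: float = 0.5
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Flag trials with high-frequency muscle bursts.

    Scalp data are band-passed (default 110-140 Hz), Hilbert-enveloped and
    averaged over channels; the pooled envelope is z-scored across all
    trials and timepoints, and each trial is summarized by its maximum z.
    The cutoff adapts per subject: starting from ``z_init`` it is raised in
    ``z_step`` increments until raising it further no longer changes the
    flagged set, capped at ``z_cap``.

    Returns (flag mask, per-trial max z, cutoff used).
    """
    n_trials = epochs.n_trials
    if n_trials < 10:
        raise InsufficientDataError("EMG detection needs at least 10 trials")
    lo, hi = band
    if hi >= epochs.sfreq / 2.0:
        raise ParameterError(f"band {band} exceeds Nyquist {epochs.sfreq / 2}")
    scalp_idx = [epochs.montage.index(c) for c in epochs.montage.scalp_channels]
    n_taps = min(int(epochs.sfreq // 4) | 1, epochs.data.shape[-1] - 1 | 1)
    taps = sp_signal.firwin(n_taps, [lo, hi], pass_zero=False, fs=epochs.sfreq)
    filtered = sp_signal.fftconvolve(epochs.data[:, scalp_idx, :],
                                     taps[None, None, :], mode="same", axes=-1)
    envelope = np.abs(sp_signal.hilbert(filtered, axis=-1)).mean(axis=1)
    mu, sd = envelope.mean(), envelope.std()
    if sd == 0:
        z = np.zeros(n_trials)
    else:
        z = ((envelope - mu) / sd).max(axis=-1)
    if np.allclose(z, z[0]):
        # no between-trial variance: nothing stands out, nothing to flag
        return np.zeros(n_trials, dtype=bool), z, z_init

    cutoff = z_init
    while cutoff < z_cap:
        if np.array_equal(z > cutoff, z > cutoff + z_step):
            break
        cutoff += z_step
    mask = z > cutoff
    return mask, z, cutoff


def detect_heog_steps(epochs: EpochSet, win_ms: float = 200.0,
                      step_ms: float = 10.0, thresh_uv: float = 20.0,
                      channel: str = "HEOG") -> np.ndarray:
    """Flag trials whose HEOG shows a step-like jump (saccade signature).

    Two adjacent half-windows of ``win_ms / 2`` each slide over the trial in
    ``step_ms`` increments; a trial is flagged when the absolute difference
    of the half-window means exceeds ``thresh_uv`` anywhere.
    """
    heog = epochs.channel_data(channel)
    dt = 1000.0 / epochs.sfreq
    half = max(int(round(win_ms / 2.0 / dt)), 1)
    step = max(int(round(step_ms / dt)), 1)
    n_samp = heog.shape[-1]
    if 2 * half > n_samp:
        raise ParameterError("step window longer than the epoch")
    csum = np.concatenate([np.zeros((heog.shape[0], 1)), np.cumsum(heog, axis=-1)],
                          axis=-1)
    starts = np.arange(0, n_samp - 2 * half + 1, step)
    m1 = (csum[:, starts + half] - csum[:, starts]) / half
    m2 = (csum[:, starts + 2 * half] - csum[:, starts + half]) / half
    return (np.abs(m1 - m2) > thresh_uv).any(axis=-1)


def interpolate_channels(epochs: EpochSet, bad: set[str] | list[str],
                         power: float = 2.0) -> EpochSet:
    """Replace bad scalp channels by inverse-distance-weighted neighbors.

    Weights are 1/d^power over the good scalp channels on the 2D montage.
    """
    bad = set(bad)
    scalp = list(epochs.montage.scalp_channels)
    unknown = bad - set(scalp)
    if unknown:
        raise ChannelError(f"cannot interpolate non-scalp channels: {sorted(unknown)}")
    good = [c for c in scalp if c not in bad]
    if len(good) < 4:
        raise ChannelError("fewer than 4 good channels left; unrecoverable")
    pos = epochs.montage.positions
    good_idx = np.array([epochs.montage.index(c) for c in good])
    good_pos = np.array([pos[c] for c in good])
    out_data = epochs.data.copy()
    for ch in bad:
        d = np.linalg.norm(good_pos - np.array(pos[ch]), axis=1)
        w = 1.0 / np.maximum(d, 1e-9) ** power
        w /= w.sum()
        out_data[:, epochs.montage.index(ch), :] = np.einsum(
            "g,tgs->ts", w, epochs.data[:, good_idx, :])
    out = epochs.copy(data=out_data)
    out.log("interpolate_channels", bad=sorted(bad), power=power)
    return out


def ocular_regression(epochs: EpochSet, veog_channel: str = "VEOG",
                      segment_mask: np.ndarray | None = None) -> EpochSet:
    """Regress the VEOG channel out of every scalp channel.

    The regression coefficient per channel is estimated by least squares
    over all timepoints of all trials (optionally restricted to
    artifact-labelled trials via ``segment_mask``), then the scaled VEOG is
    subtracted everywhere. A surrogate for component-based blink removal.
    """
    veog = epochs.channel_data(veog_channel)
    fit_trials = np.arange(epochs.n_trials) if segment_mask is None \
        else np.flatnonzero(np.asarray(segment_mask))
    v = veog[fit_trials].ravel()
    v = v - v.mean()
    var = float(v @ v)
    if var == 0.0:
        warnings.warn("VEOG has zero variance; ocular regression skipped")
        return epochs.copy()
    scalp_idx = np.array([epochs.montage.index(c)
                          for c in epochs.montage.scalp_channels])
    X = epochs.data[fit_trials][:, scalp_idx, :]
    Xc = X - X.mean(axis=(0, 2), keepdims=True)
    beta = np.einsum("tcs,ts->c", Xc, (veog[fit_trials] - veog[fit_trials].mean())) / var
    out_data = epochs.data.copy()
    out_data[:, scalp_idx, :] -= beta[None, :, None] * veog[:, None, :]
    out = epochs.copy(data=out_data)
    out.log("ocular_regression", veog_channel=veog_channel)
    return out


def preprocess(epochs: EpochSet, bad_channels: set[str] = frozenset(),
               highpass_hz: float = 0.1,
               emg_band: tuple[float, float] | None = (110.0, 140.0),
               emg_z_init: float = 4.0,
               heog_thresh_uv: float = 20.0,
               ) -> tuple[EpochSet, pd.DataFrame]:
    """Run the full cleaning chain; return (clean epochs, rejection report).

    Chain: re-reference -> 0.1 Hz high-pass -> EMG rejection -> ocular
    regression -> interpolation of listed bad channels -> HEOG step
    rejection. Flagged trials are dropped deterministically. EMG detection
    requires a sampling rate above twice the band's upper edge; pass
    ``emg_band=None`` to skip it for low-rate data.
    """
    report_rows = []
    out = rereference(epochs)
    out = fir_filter(out, "highpass", highpass_hz)

    if emg_band is None:
        emg_mask = np.zeros(out.n_trials, dtype=bool)
        emg_z, cutoff = np.zeros(out.n_trials), float("nan")
    else:
        emg_mask, emg_z, cutoff = detect_emg_artifacts(out, band=emg_band,
                                                       z_init=emg_z_init)
    for i in np.flatnonzero(emg_mask):
        report_rows.append({"trial": int(i), "reason": "emg",
                            "statistic": float(emg_z[i])})
    out = out.select_trials(~emg_mask)
    out.log("reject_emg", n_rejected=int(emg_mask.sum()), z_cutoff=cutoff)

    out = ocular_regression(out)
    if bad_channels:
        out = interpolate_channels(out, bad_channels)

    step_mask = detect_heog_steps(out, thresh_uv=heog_thresh_uv)
    kept = np.flatnonzero(~emg_mask)
    for i in np.flatnonzero(step_mask):
        report_rows.append({"trial": int(kept[i]), "reason": "heog_step",
                            "statistic": float("nan")})
    out = out.select_trials(~step_mask)
    out.log("reject_heog_steps", n_rejected=int(step_mask.sum()))

    report = pd.DataFrame(report_rows, columns=["trial", "reason", "statistic"])
    return out, report
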