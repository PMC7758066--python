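"""Synthetic designs, reaction times and EEG epochs with known ground truth.

The generator reproduces the structure of a six-location additional-singleton
visual-search study in which the distractor appears at one high-probability
location on 70% of distractor-present trials and target/distractor spatial
frequencies are blocked to create feature expectations:

* Experiment 1 — 18 blocks (6 per condition) of 50 distractor-present
  trials, two spatial frequencies, condition cycling within the session.
* Experiment 2 — 2 sessions x 54 blocks of 56 trials (50 distractor-present
  + 6 distractor-absent with the target once at every location), three
  spatial frequencies, 18 consecutive blocks per condition, and the
  high-probability location restricted to the two lateralized positions
  below the horizontal midline (mirrored between conditions).

Reaction times follow an ex-Gaussian (Gaussian + exponential) trial model
with additive condition/location effects; EEG epochs are 1/f + white noise
plus optional ground-truth components (lateralized anticipatory alpha,
N2pc/Pd-like contralateral deflections, spatial-frequency-specific
topographic patterns, EMG bursts, HEOG steps), each individually switchable
so that every downstream analysis can be calibrated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .data_model import (
    ALPHA_POOL,
    ERP_POOL,
    EXP1_CONDITIONS,
    EXP2_CONDITIONS,
    LATERAL_BELOW_LOCS,
    SF_LEVELS,
    EpochSet,
    Montage,
    location_side,
    mirror_location,
)
from .exceptions import ConfigError

N_LOCATIONS = 6

#: Which conditions carry an anticipatory (pre-search) spatial-frequency
#: pattern for each stimulus role: target foreknowledge is only usable when
#: the target's frequency is both fixed and unique (DpTp_unique), distractor
#: foreknowledge drives anticipatory coding when only the distractor is
#: predictable (DpTv_unique).
ANTICIPATORY_CONDITIONS = {
    "target": ("DpTp_unique",),
    "distractor": ("DpTv_unique",),
}


@dataclass
class SimConfig:
    """All generator knobs: design, RT model, EEG model, artifact rates.

    RT parameters are in ms, EEG amplitudes in microvolts. The high-probability
    location benefit is condition-specific with between-subject variability
    (each simulated subject draws its own benefit from a normal distribution).
    """

    seed: int = 0
    experiment: int = 2
    n_subjects: int = 24

    # design scale (defaults = the full designs described above)
    blocks_per_condition: int | None = None   # None -> 6 (Exp 1) / 18 (Exp 2)
    n_sessions: int | None = None             # None -> 1 (Exp 1) / 2 (Exp 2)

    # --- RT model (ex-Gaussian + additive effects, ms) ---
    rt_mu: float = 450.0
    rt_sigma: float = 60.0
    rt_tau: float = 60.0
    distractor_cost: float = 40.0
    high_prob_benefit: dict = field(default_factory=lambda: {
        "DpTp_identical": 50.9, "DpTp_unique": 30.6,
        "DpTv_unique": 41.7, "DvTv_unique": 41.7,
    })
    benefit_between_sd: dict = field(default_factory=lambda: {
        "DpTp_identical": 24.4, "DpTp_unique": 10.7,
        "DpTv_unique": 20.1, "DvTv_unique": 20.1,
    })
    target_at_high_cost: float = 15.0
    accuracy: float = 0.92
    response_window_ms: float = 1000.0

    # --- EEG model ---
    sfreq: float = 512.0
    epoch_tmin_ms: float = -1250.0
    epoch_tmax_ms: float = 1050.0
    noise_white_sd: float = 1.0           # uV
    noise_pink_sd: float = 1.0            # uV, 1/f^exponent shaped
    noise_exponent: float = 1.0
    alpha_freq_hz: float = 10.0
    alpha_base_amp: float = 1.0           # uV, both hemispheres
    alpha_lateralization_amp: float = 0.0  # uV added contralateral to high-prob loc
    n2pc_latency_ms: float = 154.0
    n2pc_width_ms: float = 30.0           # Gaussian SD
    n2pc_amp_target: float = 0.0          # uV (negative deflection injected as -amp)
    n2pc_amp_distractor: float = 0.0
    pd_latency_ms: float = 283.0
    pd_width_ms: float = 30.0
    pd_amp: float = 0.0                   # uV at low-probability locations
    pd_high_prob_scale: float = 0.2       # Pd shrinkage at the high-prob location
    pattern_amp_evoked: float = 0.0       # uV, class topography after display onset
    pattern_evoked_onset_ms: float = 80.0
    pattern_evoked_dur_ms: float = 320.0
    pattern_amp_anticipatory: float = 0.0  # uV, class topography before onset
    topo_seed: int = 12345                # fixed seed for the class topographies
    emg_rate: float = 0.0                 # per-trial burst probability
    emg_amp_mult: float = 10.0            # burst amplitude in units of white SD
    heog_rate: float = 0.0                # per-trial HEOG step probability
    heog_step_uv: float = 40.0

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ConfigError(f"experiment must be 1 or 2, got {self.experiment}")
        if self.rt_mu < 0:
            raise ConfigError("rt_mu must be nonnegative")
        for name in ("rt_sigma", "rt_tau", "n2pc_width_ms", "pd_width_ms",
                     "noise_white_sd", "noise_pink_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("emg_rate", "heog_rate", "accuracy"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")

    @property
    def conditions(self) -> tuple[str, ...]:
        return EXP1_CONDITIONS if self.experiment == 1 else EXP2_CONDITIONS

    def resolved_blocks(self) -> int:
        if self.blocks_per_condition is not None:
            return self.blocks_per_condition
        return 6 if self.experiment == 1 else 18

    def resolved_sessions(self) -> int:
        if self.n_sessions is not None:
            return self.n_sessions
        return 1 if self.experiment == 1 else 2


def _rng(config: SimConfig, subject_id: int, stream: int) -> np.random.Generator:
    # independent stream per (seed, subject, purpose)
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, int(subject_id), stream]))


# --------------------------------------------------------------------------
# Design generation
# --------------------------------------------------------------------------

def _distractor_present_locs(high_prob_loc: int, n_present: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Exactly 70% of distractor-present trials at the high-probability
    location; the rest spread equally over the remaining five."""
    n_high = int(round(0.7 * n_present))
    others = [l for l in range(N_LOCATIONS) if l != high_prob_loc]
    n_each, rem = divmod(n_present - n_high, len(others))
    locs = [high_prob_loc] * n_high
    for j, l in enumerate(others):
        locs += [l] * (n_each + (1 if j < rem else 0))
    locs = np.array(locs)
    rng.shuffle(locs)
    return locs


def _exp2_block_sfs(condition: str, block_in_cond: int, n_present: int,
                    rng: np.random.Generator):
    """Target/distractor spatial frequencies for one Experiment-2 block.

    Returns (target_sfs, distractor_sfs) for the distractor-present trials
    plus a callable giving the target sf of distractor-absent trials.
    Blocked frequencies rotate across blocks so that over blocks every
    frequency serves in every pairing equally often.
    """
    sfs = list(SF_LEVELS)
    if condition == "DpTp_identical":
        sf = sfs[block_in_cond % 3]
        return ([sf] * n_present, [sf] * n_present, lambda: sf)
    if condition == "DpTp_unique":
        pairs = [(t, d) for t in sfs for d in sfs if t != d]  # 6 ordered pairs
        t_sf, d_sf = pairs[block_in_cond % 6]
        return ([t_sf] * n_present, [d_sf] * n_present, lambda: t_sf)
    if condition == "DpTv_unique":
        d_sf = sfs[block_in_cond % 3]
        others = [s for s in sfs if s != d_sf]
        # balanced 50/50 split of the two remaining target frequencies
        t = others * (n_present // 2) + others[: n_present % 2]
        t = list(np.array(t)[rng.permutation(n_present)])
        return (t, [d_sf] * n_present, lambda: others[rng.integers(2)])
    raise ConfigError(f"condition {condition} not part of Experiment 2")


def _exp1_block_sfs(condition: str, block_in_cond: int, n_present: int,
                    rng: np.random.Generator):
    sfs = ["low", "high"]
    if condition == "DpTp_identical":
        sf = sfs[block_in_cond % 2]
        return [sf] * n_present, [sf] * n_present
    if condition == "DpTp_unique":
        t_sf = sfs[block_in_cond % 2]
        d_sf = sfs[1 - block_in_cond % 2]
        return [t_sf] * n_present, [d_sf] * n_present
    if condition == "DvTv_unique":
        # varies trial by trial, counterbalanced across trials
        t = np.array((["low"] * (n_present // 2) + ["high"] * (n_present - n_present // 2)))
        t = t[rng.permutation(n_present)]
        d = np.where(t == "low", "high", "low")
        return list(t), list(d)
    raise ConfigError(f"condition {condition} not part of Experiment 1")


def generate_design(config: SimConfig, subject_id: int) -> pd.DataFrame:
    """Generate the full trial table for one subject (no RTs yet).

    Condition order and high-probability locations are counterbalanced
    across subjects; within each block exactly 70% of distractor-present
    trials carry the distractor at the high-probability location.
    """
    rng = _rng(config, subject_id, stream=0)
    conds = list(config.conditions)
    order = conds[subject_id % 3:] + conds[:subject_id % 3]
    n_blocks = config.resolved_blocks()
    rows: list[dict] = []

    if config.experiment == 1:
        high_prob_loc = subject_id % N_LOCATIONS
        for b in range(3 * n_blocks):
            condition = order[b % 3]
            bi = b // 3
            n_present = 50
            d_locs = _distractor_present_locs(high_prob_loc, n_present, rng)
            t_sfs, d_sfs = _exp1_block_sfs(condition, bi, n_present, rng)
            for i in range(n_present):
                d_loc = int(d_locs[i])
                t_loc = int(rng.choice([l for l in range(N_LOCATIONS) if l != d_loc]))
                rows.append(dict(
                    subject_id=subject_id, session=1, condition=condition,
                    block=b + 1, trial=i + 1,
                    distractor_loc=d_loc, target_loc=t_loc,
                    high_prob_loc=high_prob_loc,
                    distractor_sf=d_sfs[i], target_sf=t_sfs[i],
                    target_tilt=("left", "right")[rng.integers(2)],
                    distractor_orient=("horizontal", "vertical")[rng.integers(2)],
                    rt_ms=np.nan, correct=True,
                ))
    else:
        # one high-probability side per condition, mirrored between
        # consecutive condition runs, identical across the two sessions
        base = 2 if subject_id % 2 == 0 else 4
        cond_high = {c: (base if i % 2 == 0 else mirror_location(base))
                     for i, c in enumerate(order)}
        for session in range(1, config.resolved_sessions() + 1):
            for b in range(3 * n_blocks):
                condition = order[b // n_blocks]
                bi = b % n_blocks
                high_prob_loc = cond_high[condition]
                n_present, n_absent = 50, 6
                d_locs = _distractor_present_locs(high_prob_loc, n_present, rng)
                t_sfs, d_sfs, absent_t_sf = _exp2_block_sfs(condition, bi, n_present, rng)
                block_rows = []
                for i in range(n_present):
                    d_loc = int(d_locs[i])
                    t_loc = int(rng.choice([l for l in range(N_LOCATIONS) if l != d_loc]))
                    block_rows.append(dict(
                        distractor_loc=d_loc, target_loc=t_loc,
                        distractor_sf=d_sfs[i], target_sf=t_sfs[i],
                        distractor_orient=("horizontal", "vertical")[rng.integers(2)],
                    ))
                for t_loc in range(n_absent):  # target once at each location
                    block_rows.append(dict(
                        distractor_loc=pd.NA, target_loc=t_loc,
                        distractor_sf=np.nan, target_sf=absent_t_sf(),
                        distractor_orient=np.nan,
                    ))
                idx = rng.permutation(len(block_rows))
                for i, j in enumerate(idx):
                    r = block_rows[j]
                    rows.append(dict(
                        subject_id=subject_id, session=session,
                        condition=condition, block=b + 1, trial=i + 1,
                        distractor_loc=r["distractor_loc"],
                        target_loc=r["target_loc"],
                        high_prob_loc=high_prob_loc,
                        distractor_sf=r["distractor_sf"],
                        target_sf=r["target_sf"],
                        target_tilt=("left", "right")[rng.integers(2)],
                        distractor_orient=r["distractor_orient"],
                        rt_ms=np.nan, correct=True,
                    ))

    table = pd.DataFrame(rows)
    table["distractor_loc"] = table["distractor_loc"].astype("Int64")
    return table


# --------------------------------------------------------------------------
# Behavioral simulation
# --------------------------------------------------------------------------

def simulate_rts(table: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Fill ``rt_ms`` and ``correct`` with ex-Gaussian trials + additive effects.

    RT = mu + sigma*N(0,1) + Exp(tau) + distractor-present cost
         - (subject's condition benefit, if the distractor sits at the
           high-probability location)
         + target-at-high-probability cost (if the target sits there).
    Draws exceeding the response window become non-responses (missing RT,
    incorrect). Each subject draws its condition benefits once from
    N(benefit mean, between-subject SD).
    """
    table = table.copy()
    rts = np.empty(len(table))
    correct = np.empty(len(table), dtype=bool)
    for subject_id, idx in table.groupby("subject_id").indices.items():
        rng = _rng(config, int(subject_id), stream=1)
        sub = table.iloc[idx]
        benefits = {c: rng.normal(config.high_prob_benefit.get(c, 0.0),
                                  config.benefit_between_sd.get(c, 0.0))
                    for c in config.conditions}
        n = len(sub)
        rt = (config.rt_mu
              + rng.normal(0.0, config.rt_sigma, n) if config.rt_sigma > 0
              else np.full(n, config.rt_mu))
        rt = rt + (rng.exponential(config.rt_tau, n) if config.rt_tau > 0 else 0.0)
        present = sub["distractor_loc"].notna().to_numpy()
        d_at_high = present & (sub["distractor_loc"].to_numpy(dtype=float, na_value=-1)
                               == sub["high_prob_loc"].to_numpy())
        t_at_high = (sub["target_loc"] == sub["high_prob_loc"]).to_numpy()
        rt = rt + config.distractor_cost * present
        cond_benefit = sub["condition"].map(benefits).to_numpy(dtype=float)
        rt = rt - cond_benefit * d_at_high
        rt = rt + config.target_at_high_cost * t_at_high
        ok = rng.random(n) < config.accuracy
        missed = rt > config.response_window_ms
        rts[idx] = np.where(missed, np.nan, rt)
        correct[idx] = ok & ~missed
    table["rt_ms"] = rts
    table["correct"] = correct
    return table


# --------------------------------------------------------------------------
# EEG simulation
# --------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float,
                exponent: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit variance."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / sfreq)
    freqs[0] = freqs[1]
    spec *= freqs ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def class_topographies(config: SimConfig, n_channels: int = 64) -> dict:
    """Fixed unit-norm topography per (role, spatial-frequency class).

    Drawn once from a dedicated seed so that the codes are reproducible and
    role-distinct (target and distractor patterns are independent draws).
    """
    rng = np.random.default_rng(config.topo_seed)
    topos = {}
    for role in ("target", "distractor"):
        for sf in SF_LEVELS:
            v = rng.standard_normal(n_channels)
            topos[(role, sf)] = v / np.linalg.norm(v)
    return topos


def _gauss_bump(times_ms: np.ndarray, latency: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - latency) / width) ** 2)


def _hann_window(times_ms: np.ndarray, lo: float, hi: float) -> np.ndarray:
    env = np.zeros_like(times_ms)
    m = (times_ms >= lo) & (times_ms <= hi)
    env[m] = 0.5 * (1 - np.cos(2 * np.pi * (times_ms[m] - lo) / (hi - lo)))
    return env


def simulate_epochs(table: pd.DataFrame, config: SimConfig,
                    montage: Montage | None = None
                    ) -> tuple[EpochSet, dict]:
    """Simulate epoched EEG for the given trials; return (epochs, injection log).

    Epochs span the analysis window extended by 500 ms on both sides so that
    filtering and wavelet convolution have padding. All ground-truth
    components default to zero amplitude — the baseline output is pure
    1/f + white noise.
    """
    montage = montage or Montage.default_64()
    scalp = montage.scalp_channels
    n_scalp = len(scalp)
    required = set(ERP_POOL) | set(ALPHA_POOL)
    if not required <= set(scalp):
        raise ConfigError("montage lacks the posterior mirror-pair pools")

    dt = 1000.0 / config.sfreq
    n_samp = int(round((config.epoch_tmax_ms - config.epoch_tmin_ms) / dt)) + 1
    times = config.epoch_tmin_ms + dt * np.arange(n_samp)
    n_trials = len(table)
    n_ch = len(montage.channels)
    data = np.zeros((n_trials, n_ch, n_samp))

    subjects = table["subject_id"].unique()
    topos = class_topographies(config, n_scalp)
    scalp_idx = np.array([montage.index(c) for c in scalp])
    heog_idx = montage.index("HEOG")
    veog_idx = montage.index("VEOG")

    pools = {
        "left": [montage.index(c) for c in montage.hemisphere_pool(ERP_POOL, "left")],
        "right": [montage.index(c) for c in montage.hemisphere_pool(ERP_POOL, "right")],
    }
    alpha_pools = {
        "left": [montage.index(c) for c in montage.hemisphere_pool(ALPHA_POOL, "left")],
        "right": [montage.index(c) for c in montage.hemisphere_pool(ALPHA_POOL, "right")],
    }

    env_anticip = _hann_window(times, -750.0, 0.0)
    env_evoked = _hann_window(times, config.pattern_evoked_onset_ms,
                              config.pattern_evoked_onset_ms + config.pattern_evoked_dur_ms)

    log = {"emg_trials": [], "heog_trials": [],
           "topographies": topos,
           "params": asdict(config)}

    # band-pass FIR for EMG bursts, designed once (only when needed)
    emg_taps = None
    if config.emg_rate > 0:
        nyq = config.sfreq / 2.0
        emg_taps = sp_signal.firwin(int(config.sfreq // 4) | 1, [110, 140],
                                    pass_zero=False, fs=config.sfreq) \
            if nyq > 140 else None

    table = table.reset_index(drop=True)
    for subject_id in subjects:
        rng = _rng(config, int(subject_id), stream=2)
        idx = np.flatnonzero((table["subject_id"] == subject_id).to_numpy())
        n_sub = len(idx)
        if config.noise_white_sd > 0:
            data[np.ix_(idx, np.arange(n_ch))] += rng.normal(
                0.0, config.noise_white_sd, (n_sub, n_ch, n_samp))
        if config.noise_pink_sd > 0:
            data[np.ix_(idx, scalp_idx)] += config.noise_pink_sd * _pink_noise(
                rng, (n_sub, n_scalp, n_samp), config.sfreq, config.noise_exponent)

        for i in idx:
            row = table.iloc[i]
            high_side = location_side(row["high_prob_loc"])

            # anticipatory alpha, lateralized w.r.t. the high-probability loc
            if config.alpha_base_amp > 0 or config.alpha_lateralization_amp > 0:
                if high_side in ("left", "right"):
                    contra = "right" if high_side == "left" else "left"
                    ipsi = high_side
                    phase = rng.uniform(0, 2 * np.pi)
                    osc = np.sin(2 * np.pi * config.alpha_freq_hz * times / 1000.0
                                 + phase) * env_anticip
                    a_c = config.alpha_base_amp + config.alpha_lateralization_amp
                    a_i = config.alpha_base_amp
                    data[i, alpha_pools[contra], :] += a_c * osc
                    data[i, alpha_pools[ipsi], :] += a_i * osc

            d_present = pd.notna(row["distractor_loc"])
            d_side = location_side(int(row["distractor_loc"])) if d_present else "none"
            t_side = location_side(int(row["target_loc"]))

            # N2pc (negative, contra to the lateral stimulus) and Pd
            # (positive, contra to the distractor; reduced at the
            # high-probability location)
            if t_side in ("left", "right") and config.n2pc_amp_target > 0:
                contra = "right" if t_side == "left" else "left"
                bump = _gauss_bump(times, config.n2pc_latency_ms, config.n2pc_width_ms)
                data[i, pools[contra], :] -= config.n2pc_amp_target * bump
            if d_present and d_side in ("left", "right"):
                contra = "right" if d_side == "left" else "left"
                if config.n2pc_amp_distractor > 0:
                    bump = _gauss_bump(times, config.n2pc_latency_ms, config.n2pc_width_ms)
                    data[i, pools[contra], :] -= config.n2pc_amp_distractor * bump
                if config.pd_amp > 0:
                    amp = config.pd_amp
                    if int(row["distractor_loc"]) == int(row["high_prob_loc"]):
                        amp *= config.pd_high_prob_scale
                    bump = _gauss_bump(times, config.pd_latency_ms, config.pd_width_ms)
                    data[i, pools[contra], :] += amp * bump

            # spatial-frequency class topographies
            roles = [("target", row["target_sf"])]
            if d_present:
                roles.append(("distractor", row["distractor_sf"]))
            for role, sf in roles:
                if pd.isna(sf):
                    continue
                topo = topos[(role, sf)]
                if config.pattern_amp_evoked > 0:
                    data[i, scalp_idx, :] += (config.pattern_amp_evoked
                                              * topo[:, None] * env_evoked[None, :])
                if (config.pattern_amp_anticipatory > 0
                        and row["condition"] in ANTICIPATORY_CONDITIONS[role]):
                    data[i, scalp_idx, :] += (config.pattern_amp_anticipatory
                                              * topo[:, None] * env_anticip[None, :])

            # artifacts
            if config.emg_rate > 0 and rng.random() < config.emg_rate:
                log["emg_trials"].append(int(i))
                burst_len = int(0.1 * config.sfreq)
                start = rng.integers(0, n_samp - burst_len)
                noise = rng.standard_normal(burst_len + (len(emg_taps) if emg_taps is not None else 0))
                if emg_taps is not None:
                    noise = np.convolve(noise, emg_taps, mode="valid")[:burst_len]
                    noise /= max(noise.std(), 1e-12)
                burst = config.emg_amp_mult * config.noise_white_sd * noise[:burst_len]
                data[i, scalp_idx, start:start + burst_len] += burst[None, :]
            if config.heog_rate > 0 and rng.random() < config.heog_rate:
                log["heog_trials"].append(int(i))
                onset = rng.integers(n_samp // 4, 3 * n_samp // 4)
                sign = 1 if rng.random() < 0.5 else -1
                data[i, heog_idx, onset:] += sign * config.heog_step_uv

        # small independent ocular baseline activity
        if config.noise_white_sd > 0:
            data[idx, veog_idx, :] += rng.normal(0, 0.1 * config.noise_white_sd,
                                                 (n_sub, n_samp))

    epochs = EpochSet(data=data, sfreq=config.sfreq, times=times,
                      montage=montage, trials=table.copy())
    epochs.log("simulate_epochs", seed=config.seed)
    return epochs, log
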