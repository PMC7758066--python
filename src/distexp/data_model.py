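"""Shared domain containers for the distractor-expectation pipeline.

The pipeline passes around four kinds of objects:

* a *trial table* — a plain :class:`pandas.DataFrame`, one row per trial,
  holding the design factors (condition, locations, spatial frequencies)
  together with the behavioral outcome (RT, accuracy);
* an :class:`EpochSet` — epoched multichannel EEG (trials x channels x
  samples, microvolts) with its time axis, sampling rate and montage;
* a :class:`TFRSet` — wavelet power (observations x frequencies x channels
  x timepoints);
* small result records (:class:`DecodingResult`, :class:`ClusterTestResult`,
  :class:`ERPWaveforms`).

Epochs serialize to a flat little-endian float32 ``.dat`` array plus a JSON
sidecar, and the trial table to CSV, so every artifact stays diff-able and
language-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ChannelError,
    FormatError,
    IntegrityError,
    SchemaError,
)

# --------------------------------------------------------------------------
# Design vocabulary
# --------------------------------------------------------------------------

#: All conditions across both experiments. "Dp"/"Tp" = predictable distractor/
#: target spatial frequency, "Dv"/"Tv" = variable; "identical" means target
#: and distractor share the same spatial frequency within a block.
CONDITIONS = ("DpTp_identical", "DpTp_unique", "DvTv_unique", "DpTv_unique")

EXP1_CONDITIONS = ("DpTp_identical", "DpTp_unique", "DvTv_unique")
EXP2_CONDITIONS = ("DpTp_identical", "DpTp_unique", "DpTv_unique")

SF_LEVELS = ("low", "medium", "high")
TILTS = ("left", "right")
ORIENTS = ("horizontal", "vertical")

#: Stimulus positions on an imaginary circle, indexed 0-5 clockwise from the
#: top, at these polar angles (degrees). Two positions sit on the vertical
#: midline (0: top, 3: bottom) and two lateralized positions lie below the
#: horizontal midline (2: lower-right, 4: lower-left).
LOCATION_ANGLES = (90.0, 30.0, -30.0, -90.0, -150.0, 150.0)

MIDLINE_LOCS = frozenset({0, 3})
LATERAL_BELOW_LOCS = frozenset({2, 4})  # eligible high-probability locations

TRIAL_COLUMNS = (
    "subject_id", "session", "condition", "block", "trial",
    "distractor_loc", "target_loc", "high_prob_loc",
    "distractor_sf", "target_sf", "target_tilt", "distractor_orient",
    "rt_ms", "correct",
)


def location_side(loc: int) -> str:
    """Return 'left', 'right' or 'midline' for a display location index."""
    x = np.cos(np.deg2rad(LOCATION_ANGLES[int(loc)]))
    if abs(x) < 1e-9:
        return "midline"
    return "right" if x > 0 else "left"


def mirror_location(loc: int) -> int:
    """Display location mirrored across the vertical meridian."""
    return {0: 0, 1: 5, 2: 4, 3: 3, 4: 2, 5: 1}[int(loc)]


# --------------------------------------------------------------------------
# Montage
# --------------------------------------------------------------------------

# 64-channel 10-10 layout (standard 64-electrode cap order), positions
# projected onto the unit disc (azimuthal-equidistant, nose up: +y anterior,
# +x right).
_SCALP_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.1738, 0.4954), "AF7": (-0.3361, 0.4203), "AF3": (-0.1692, 0.3857), "F1": (-0.112, 0.2318),
    "F3": (-0.2291, 0.2422), "F5": (-0.348, 0.2593), "F7": (-0.4655, 0.2814), "FT7": (-0.5349, 0.0935),
    "FC5": (-0.3936, 0.095), "FC3": (-0.2557, 0.0965), "FC1": (-0.1244, 0.095), "C1": (-0.1215, -0.0335),
    "C3": (-0.251, -0.0447), "C5": (-0.385, -0.066), "T7": (-0.5252, -0.1), "TP7": (-0.4599, -0.2495),
    "CP5": (-0.3426, -0.2004), "CP3": (-0.2247, -0.1662), "CP1": (-0.1099, -0.1463), "P1": (-0.0904, -0.2542),
    "P3": (-0.1845, -0.2743), "P5": (-0.2734, -0.3101), "P7": (-0.3565, -0.3615), "P9": (-0.436, -0.4405),
    "PO7": (-0.2412, -0.4289), "PO3": (-0.1341, -0.3703), "O1": (-0.1204, -0.4604), "Iz": (0.0, -0.5612),
    "Oz": (0.0004, -0.4596), "POz": (0.0007, -0.3536), "Pz": (0.001, -0.2471), "CPz": (0.0012, -0.1414),
    "Fpz": (0.0006, 0.5062), "Fp2": (0.1743, 0.4952), "AF8": (0.3363, 0.4202), "AF4": (0.1754, 0.3817),
    "AFz": (0.0011, 0.3685), "Fz": (0.0012, 0.2298), "F2": (0.1201, 0.2343), "F4": (0.2358, 0.247),
    "F6": (0.3539, 0.2596), "F8": (0.4651, 0.2829), "FT8": (0.5337, 0.1006), "FC6": (0.3956, 0.0991),
    "FC4": (0.2604, 0.0992), "FC2": (0.1283, 0.0975), "FCz": (0.0013, 0.0954), "Cz": (0.0013, -0.029),
    "C2": (0.1278, -0.0326), "C4": (0.2573, -0.0418), "C6": (0.3894, -0.0596), "T8": (0.5267, -0.093),
    "TP8": (0.462, -0.246), "CP6": (0.3493, -0.1933), "CP4": (0.2326, -0.1629), "CP2": (0.1187, -0.1456),
    "P2": (0.0992, -0.2503), "P4": (0.1913, -0.27), "P6": (0.2762, -0.3088), "P8": (0.3591, -0.3591),
    "P10": (0.4364, -0.4393), "PO8": (0.2438, -0.4276), "PO4": (0.1357, -0.372), "O2": (0.1224, -0.4599),
}

AUX_CHANNELS = ("VEOG", "HEOG", "A1", "A2")  # EOG + left/right earlobe refs


def _mirror_label(label: str) -> str:
    """Mirror a 10-10 label across the midline (odd <-> even suffix)."""
    i = len(label)
    while i > 0 and label[i - 1].isdigit():
        i -= 1
    stem, num = label[:i], label[i:]
    if not num:  # z-line channel
        return label
    n = int(num)
    return f"{stem}{n + 1}" if n % 2 == 1 else f"{stem}{n - 1}"


@dataclass(frozen=True)
class Montage:
    """Channel labels, 2D scalp positions and the left/right mirror map."""

    channels: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    mirror: dict[str, str]
    midline: frozenset[str]

    @classmethod
    def default_64(cls) -> "Montage":
        scalp = tuple(_SCALP_POSITIONS)
        mirror = {ch: _mirror_label(ch) for ch in scalp}
        midline = frozenset(ch for ch, m in mirror.items() if m == ch)
        return cls(
            channels=scalp + AUX_CHANNELS,
            positions=dict(_SCALP_POSITIONS),
            mirror=mirror,
            midline=midline,
        )

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channels if ch not in AUX_CHANNELS)

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise ChannelError(f"channel {label!r} not in montage") from None

    def hemisphere_pool(self, pool: tuple[str, ...], side: str) -> tuple[str, ...]:
        """Restrict a mirror-pair pool (e.g. O1/O2, PO7/PO8) to one side."""
        want_left = side == "left"
        out = []
        for ch in pool:
            if ch in self.midline:
                continue
            x = self.positions[ch][0]
            if (x < 0) == want_left:
                out.append(ch)
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "positions": {k: list(v) for k, v in self.positions.items()},
            "mirror": dict(self.mirror),
            "midline": sorted(self.midline),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            channels=tuple(d["channels"]),
            positions={k: (float(v[0]), float(v[1])) for k, v in d["positions"].items()},
            mirror=dict(d["mirror"]),
            midline=frozenset(d["midline"]),
        )


#: Electrode-of-interest mirror pools used by the ERP and alpha analyses.
ERP_POOL = ("O1", "O2", "PO3", "PO4", "PO7", "PO8")
ALPHA_POOL = ("PO7", "PO8", "O1", "O2")


# --------------------------------------------------------------------------
# EpochSet
# --------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x samples, time in ms (0 = search onset)."""

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    montage: Montage
    trials: pd.DataFrame
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise IntegrityError("epoch data must be trials x channels x samples")
        n_trials, n_ch, n_samp = self.data.shape
        if len(self.times) != n_samp:
            raise IntegrityError(
                f"time axis length {len(self.times)} != n_samples {n_samp}")
        if n_samp > 1 and not np.all(np.diff(self.times) > 0):
            raise IntegrityError("time axis must be strictly increasing")
        if n_ch != len(self.montage.channels):
            raise IntegrityError(
                f"{n_ch} data channels but montage lists {len(self.montage.channels)}")
        if len(self.trials) != n_trials:
            raise IntegrityError(
                f"trial table has {len(self.trials)} rows for {n_trials} epochs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self, data: np.ndarray | None = None) -> "EpochSet":
        return EpochSet(
            data=self.data.copy() if data is None else data,
            sfreq=self.sfreq,
            times=self.times.copy(),
            montage=self.montage,
            trials=self.trials.copy(),
            history=list(self.history),
        )

    def log(self, op: str, **params) -> None:
        self.history.append({"op": op, **params})

    def channel_data(self, label: str) -> np.ndarray:
        return self.data[:, self.montage.index(label), :]

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        return (self.times >= lo_ms) & (self.times <= hi_ms)

    def crop(self, lo_ms: float, hi_ms: float) -> "EpochSet":
        """Restrict the time axis to [lo_ms, hi_ms]."""
        mask = self.time_mask(lo_ms, hi_ms)
        return EpochSet(
            data=self.data[:, :, mask],
            sfreq=self.sfreq,
            times=self.times[mask],
            montage=self.montage,
            trials=self.trials.copy(),
            history=list(self.history),
        )

    def select_trials(self, index) -> "EpochSet":
        """Subset by positional trial indices or a boolean mask."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EpochSet(
            data=self.data[idx],
            sfreq=self.sfreq,
            times=self.times.copy(),
            montage=self.montage,
            trials=self.trials.iloc[idx].reset_index(drop=True),
            history=list(self.history),
        )


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write ``<path>.dat`` (float32 C-order) + ``<path>.json`` + ``<path>.trials.csv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data32 = np.ascontiguousarray(epochs.data, dtype="<f4")
    data32.tofile(path.with_suffix(".dat"))
    sidecar = {
        "sfreq": float(epochs.sfreq),
        "times_ms": [float(t) for t in epochs.times],
        "channels": list(epochs.montage.channels),
        "montage": epochs.montage.to_dict(),
        "n_trials": int(epochs.n_trials),
        "dtype": "float32",
        "order": "C",
        "history": epochs.history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    epochs.trials.to_csv(path.with_suffix(".trials.csv"), index=False)


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    montage = Montage.from_dict(sidecar["montage"])
    n_trials = int(sidecar["n_trials"])
    n_ch = len(sidecar["channels"])
    n_samp = len(sidecar["times_ms"])
    raw = np.fromfile(path.with_suffix(".dat"), dtype="<f4")
    if raw.size != n_trials * n_ch * n_samp:
        raise IntegrityError(
            f"array has {raw.size} values, sidecar implies "
            f"{n_trials}x{n_ch}x{n_samp}")
    trials = read_trial_table(path.with_suffix(".trials.csv"))
    return EpochSet(
        data=raw.reshape(n_trials, n_ch, n_samp),
        sfreq=float(sidecar["sfreq"]),
        times=np.asarray(sidecar["times_ms"], dtype=float),
        montage=montage,
        trials=trials,
        history=list(sidecar.get("history", [])),
    )


# --------------------------------------------------------------------------
# Trial table I/O and validation
# --------------------------------------------------------------------------

_INT_COLS = ("subject_id", "session", "block", "trial", "target_loc", "high_prob_loc")
_NULLABLE_INT_COLS = ("distractor_loc",)


def _coerce_trial_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in _INT_COLS:
        if c in df:
            df[c] = df[c].astype("int64")
    for c in _NULLABLE_INT_COLS:
        if c in df:
            df[c] = df[c].astype("Int64")
    if "correct" in df:
        df["correct"] = df["correct"].astype(bool)
    if "rt_ms" in df:
        df["rt_ms"] = df["rt_ms"].astype(float)
    return df


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"distractor_sf": "string", "target_sf": "string",
                                  "distractor_orient": "string"})
    # empty cells encode ABSENT / MISSING
    for c in ("distractor_sf", "target_sf", "distractor_orient",
              "target_tilt", "condition"):
        if c in df:
            df[c] = df[c].astype(object).where(~pd.isna(df[c]), np.nan)
    return _coerce_trial_dtypes(df)


def validate_trial_table(table: pd.DataFrame) -> list[tuple[int, str]]:
    """Check trial-table invariants; return ``(row, message)`` violations.

    An unknown condition label is a schema error (raised), not a violation,
    because downstream semantics are undefined for it.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    bad_cond = set(table["condition"].dropna()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown condition labels: {sorted(bad_cond)}")

    violations: list[tuple[int, str]] = []
    dloc = table["distractor_loc"]
    present = dloc.notna().to_numpy()
    dsf = table["distractor_sf"]
    dori = table["distractor_orient"]

    for i in np.flatnonzero(present & (dloc.to_numpy(dtype=float, na_value=-1)
                                       == table["target_loc"].to_numpy())):
        violations.append((int(i), "distractor_loc equals target_loc"))

    unique_mask = table["condition"].isin(
        ["DpTp_unique", "DvTv_unique", "DpTv_unique"]).to_numpy()
    ident_mask = (table["condition"] == "DpTp_identical").to_numpy()
    same_sf = (dsf == table["target_sf"]).to_numpy()
    has_dsf = dsf.notna().to_numpy()
    for i in np.flatnonzero(unique_mask & has_dsf & same_sf):
        violations.append((int(i), "distractor_sf equals target_sf in *_unique condition"))
    for i in np.flatnonzero(ident_mask & has_dsf & ~same_sf):
        violations.append((int(i), "distractor_sf differs from target_sf in DpTp_identical"))

    has_ori = dori.notna().to_numpy()
    for i in np.flatnonzero(present != has_dsf):
        violations.append((int(i), "distractor presence inconsistent with distractor_sf"))
    for i in np.flatnonzero(present != has_ori):
        violations.append((int(i), "distractor presence inconsistent with distractor_orient"))

    for (_, _), grp in table.groupby(["subject_id", "condition"], sort=False):
        if grp["high_prob_loc"].nunique() > 1:
            violations.append((int(grp.index[0]),
                               "high_prob_loc varies within (subject, condition)"))
    return sorted(set(violations))


# --------------------------------------------------------------------------
# Analysis result records
# --------------------------------------------------------------------------

@dataclass
class WaveletParams:
    """Morlet family: log-spaced frequencies with log-spaced cycle counts.

    The Gaussian width of the wavelet at frequency f with cycle count d is
    s = d / (2*pi*f) seconds.
    """

    freqs: np.ndarray
    cycles: np.ndarray

    @classmethod
    def default(cls, n: int = 25, fmin: float = 1.0, fmax: float = 40.0,
                cmin: float = 3.0, cmax: float = 12.0) -> "WaveletParams":
        return cls(freqs=np.logspace(np.log10(fmin), np.log10(fmax), n),
                   cycles=np.logspace(np.log10(cmin), np.log10(cmax), n))

    @property
    def widths(self) -> np.ndarray:
        """Gaussian widths s = cycles / (2*pi*f), in seconds."""
        return self.cycles / (2.0 * np.pi * self.freqs)


@dataclass
class TFRSet:
    """Wavelet power: observations x frequencies x channels x timepoints (uV^2)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    cycles: np.ndarray
    channels: tuple[str, ...]
    trials: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        if np.any(self.power < 0):
            raise IntegrityError("power must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise IntegrityError("freqs must be strictly increasing")


@dataclass
class DecodingResult:
    """Time-resolved AUC per condition, with train/test class provenance."""

    auc: np.ndarray                    # conditions x timepoints
    times: np.ndarray                  # ms
    conditions: tuple[str, ...]
    train_class: str                   # 'target' | 'distractor'
    test_class: str
    classes: tuple[str, ...] = SF_LEVELS
    per_fold_auc: np.ndarray | None = None  # conditions x folds x timepoints

    def __post_init__(self) -> None:
        if np.any((self.auc < 0) | (self.auc > 1)):
            raise IntegrityError("AUC must lie in [0, 1]")


@dataclass
class ClusterTestResult:
    """Clusters, their mass statistics and permutation p-values."""

    clusters: list[np.ndarray]     # index arrays (1D) or (n, 2) arrays (2D)
    cluster_mass: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int
    t_obs: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[np.ndarray]:
        return [c for c, p in zip(self.clusters, self.p_values) if p < alpha]


@dataclass
class ERPWaveforms:
    """Contra/ipsilateral waveforms per (condition, probability, stimulus class)."""

    times: np.ndarray
    contra: dict[tuple[str, str, str], np.ndarray]
    ipsi: dict[tuple[str, str, str], np.ndarray]
    n_trials: dict[tuple[str, str, str], int]

    def difference(self, key: tuple[str, str, str]) -> np.ndarray:
        return self.contra[key] - self.ipsi[key]

    def keys(self):
        return self.contra.keys()
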