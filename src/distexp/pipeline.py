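"""Pipeline orchestration: simulate -> preprocess -> analyses -> stats.

Each stage reads its inputs from and writes its tabular artifacts (CSV /
JSON) into a bundle directory, so stages can be rerun selectively; a
provenance log records every stage with its parameters. Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decoding as dec
from . import erp as erp_mod
from . import preprocessing as pre
from . import stats as st
from . import timefreq as tf
from .data_model import (
    ALPHA_POOL,
    EpochSet,
    Montage,
    WaveletParams,
    read_epochs,
    read_trial_table,
    write_epochs,
)
from .exceptions import ConfigError, DependencyError
from .synth import SimConfig, generate_design, simulate_epochs, simulate_rts

STAGES = ("simulate", "preprocess", "behavior", "tfr", "decode", "erp", "stats")

_STAGE_KEYS = {
    "preprocess": {"highpass_hz", "emg_band", "emg_z_init", "heog_thresh_uv",
                   "bad_channels"},
    "behavior": {"min_rt_ms", "sd_cutoff"},
    "tfr": {"decim", "band", "window"},
    "decode": {"k", "shrinkage", "baseline", "target_sfreq", "crop"},
    "erp": {"lowpass_hz", "baseline", "search_window"},
    "stats": {"n_perm", "alpha_cluster"},
}
_TOP_KEYS = {"seed", "sim"} | set(_STAGE_KEYS)
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}


def validate_config(config: dict) -> dict:
    """Schema-check a pipeline config; returns it with defaults filled in."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim = dict(config.get("sim", {}))
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ConfigError(f"unknown sim keys: {sorted(bad)}")
    for stage, keys in _STAGE_KEYS.items():
        bad = set(config.get(stage, {})) - keys
        if bad:
            raise ConfigError(f"unknown {stage} keys: {sorted(bad)}")
    out = {"seed": int(config.get("seed", 0)), "sim": sim}
    for stage in _STAGE_KEYS:
        out[stage] = dict(config.get(stage, {}))
    return out


def _log_stage(out_dir: Path, stage: str, params: dict) -> None:
    log_path = out_dir / "provenance.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else []
    log.append({"stage": stage, "params": {k: repr(v) for k, v in params.items()}})
    log_path.write_text(json.dumps(log, indent=1))


def _sim_config(config: dict) -> SimConfig:
    sim = dict(config["sim"])
    sim.setdefault("seed", config["seed"])
    return SimConfig(**sim)


def _subject_paths(out_dir: Path, stage: str) -> list[Path]:
    return sorted((out_dir / stage).glob("subject_*.json"))


def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' needs output of stage '{stage}' "
            f"({path} missing); run it first")


def stage_simulate(config: dict, out_dir: Path) -> None:
    cfg = _sim_config(config)
    sim_dir = out_dir / "simulate"
    sim_dir.mkdir(parents=True, exist_ok=True)
    montage = Montage.default_64()
    tables = []
    for subject_id in range(cfg.n_subjects):
        table = simulate_rts(generate_design(cfg, subject_id), cfg)
        tables.append(table)
        epochs, _ = simulate_epochs(table, cfg, montage)
        write_epochs(epochs, sim_dir / f"subject_{subject_id:02d}")
    pd.concat(tables, ignore_index=True).to_csv(sim_dir / "trials.csv", index=False)
    _log_stage(out_dir, "simulate", dataclasses.asdict(cfg))


def stage_preprocess(config: dict, out_dir: Path) -> None:
    params = config["preprocess"]
    _require(out_dir / "simulate" / "trials.csv", "simulate", "preprocess")
    pp_dir = out_dir / "preprocess"
    pp_dir.mkdir(parents=True, exist_ok=True)
    emg_band = params.get("emg_band", (110.0, 140.0))
    reports = []
    for path in _subject_paths(out_dir, "simulate"):
        epochs = read_epochs(path.with_suffix(""))
        clean, report = pre.preprocess(
            epochs,
            bad_channels=set(params.get("bad_channels", ())),
            highpass_hz=params.get("highpass_hz", 0.1),
            emg_band=tuple(emg_band) if emg_band is not None else None,
            emg_z_init=params.get("emg_z_init", 4.0),
            heog_thresh_uv=params.get("heog_thresh_uv", 20.0))
        report["subject_id"] = int(path.stem.split("_")[1])
        reports.append(report)
        write_epochs(clean, pp_dir / path.stem)
    pd.concat(reports, ignore_index=True).to_csv(pp_dir / "rejections.csv",
                                                 index=False)
    _log_stage(out_dir, "preprocess", params)


def stage_behavior(config: dict, out_dir: Path) -> None:
    params = config["behavior"]
    src = out_dir / "simulate" / "trials.csv"
    _require(src, "simulate", "behavior")
    beh_dir = out_dir / "behavior"
    beh_dir.mkdir(parents=True, exist_ok=True)
    table = read_trial_table(src)
    filtered, report = beh.filter_rts(table,
                                      min_rt_ms=params.get("min_rt_ms", 200.0),
                                      sd_cutoff=params.get("sd_cutoff", 2.5))
    experiment = _sim_config(config).experiment
    d_means = beh.distractor_tuned_means(filtered)
    t_means = beh.target_tuned_means(filtered, experiment=experiment)
    report.to_csv(beh_dir / "exclusions.csv", index=False)
    d_means.to_csv(beh_dir / "distractor_tuned_means.csv", index=False)
    t_means.to_csv(beh_dir / "target_tuned_means.csv", index=False)
    _log_stage(out_dir, "behavior", params)


def stage_tfr(config: dict, out_dir: Path) -> None:
    params = config["tfr"]
    paths = _subject_paths(out_dir, "preprocess")
    if not paths:
        raise DependencyError("stage 'tfr' needs preprocessed epochs; "
                              "run 'preprocess' first")
    tfr_dir = out_dir / "tfr"
    tfr_dir.mkdir(parents=True, exist_ok=True)
    band = tuple(params.get("band", (8.0, 12.0)))
    window = tuple(params.get("window", (-750.0, 0.0)))
    rows = []
    for path in paths:
        epochs = read_epochs(path.with_suffix(""))
        subject_id = int(path.stem.split("_")[1])
        wp = WaveletParams.default()
        wp = WaveletParams(freqs=wp.freqs[wp.freqs < epochs.sfreq / 2],
                           cycles=wp.cycles[: np.sum(wp.freqs < epochs.sfreq / 2)])
        for cond, sub in epochs.trials.groupby("condition"):
            cond_epochs = epochs.select_trials(sub.index.to_numpy())
            tfr = tf.tfr_power(cond_epochs, wp,
                               decim=params.get("decim", 4), channels=ALPHA_POOL)
            index = tf.lateralization_index_by_high_prob(tfr)
            series, scalar = tf.alpha_band_average(index, tfr.freqs, tfr.times,
                                                   band=band, window=window)
            rows.append({"subject_id": subject_id, "condition": cond,
                         "alpha_lateralization": scalar})
            per_t = pd.DataFrame({"subject_id": subject_id, "condition": cond,
                                  "time_ms": tfr.times, "index": series})
            per_t.to_csv(tfr_dir / f"series_subject_{subject_id:02d}_{cond}.csv",
                         index=False)
    pd.DataFrame(rows).to_csv(tfr_dir / "alpha_lateralization.csv", index=False)
    _log_stage(out_dir, "tfr", params)


def stage_decode(config: dict, out_dir: Path) -> None:
    params = config["decode"]
    paths = _subject_paths(out_dir, "preprocess")
    if not paths:
        raise DependencyError("stage 'decode' needs preprocessed epochs; "
                              "run 'preprocess' first")
    dec_dir = out_dir / "decode"
    dec_dir.mkdir(parents=True, exist_ok=True)
    crop = tuple(params.get("crop", (-750.0, 550.0)))
    rows = []
    for path in paths:
        epochs = read_epochs(path.with_suffix(""))
        subject_id = int(path.stem.split("_")[1])
        prepared = dec.prepare_decoding_epochs(
            epochs, baseline=tuple(params.get("baseline", (-750.0, -550.0))),
            target_sfreq=params.get("target_sfreq", 128.0))
        prepared = prepared.crop(*crop)
        for field in ("target_sf", "distractor_sf"):
            res = dec.time_resolved_cv_decode(
                prepared, label_field=field, k=params.get("k", 10),
                seed=config["seed"] + subject_id,
                shrinkage=params.get("shrinkage", "auto"))
            for ci, cond in enumerate(res.conditions):
                for t, a in zip(res.times, res.auc[ci]):
                    rows.append({"subject_id": subject_id, "condition": cond,
                                 "train_class": res.train_class,
                                 "test_class": res.test_class,
                                 "time_ms": float(t), "auc": float(a)})
    pd.DataFrame(rows).to_csv(dec_dir / "auc.csv", index=False)
    _log_stage(out_dir, "decode", params)


def stage_erp(config: dict, out_dir: Path) -> None:
    params = config["erp"]
    paths = _subject_paths(out_dir, "preprocess")
    if not paths:
        raise DependencyError("stage 'erp' needs preprocessed epochs; "
                              "run 'preprocess' first")
    erp_dir = out_dir / "erp"
    erp_dir.mkdir(parents=True, exist_ok=True)
    wave_rows, subject_waves = [], []
    for path in paths:
        epochs = read_epochs(path.with_suffix(""))
        subject_id = int(path.stem.split("_")[1])
        epochs = pre.fir_filter(epochs, "lowpass", params.get("lowpass_hz", 30.0))
        epochs = pre.baseline_correct(epochs,
                                      tuple(params.get("baseline", (-450.0, -250.0))))
        subsets = {sc: erp_mod.select_lateralized_trials(epochs.trials, sc)
                   for sc in ("target", "distractor")}
        waves = erp_mod.contra_ipsi_waveforms(epochs, subsets)
        subject_waves.append((subject_id, waves))
        for key in waves.keys():
            cond, prob, sc = key
            for hemi, wf in (("contra", waves.contra[key]),
                             ("ipsi", waves.ipsi[key])):
                for t, v in zip(waves.times, wf):
                    wave_rows.append({"subject_id": subject_id, "condition": cond,
                                      "probability": prob, "stimulus_class": sc,
                                      "hemisphere": hemi, "time_ms": float(t),
                                      "uv": float(v)})
    # grand averages for window selection
    times = subject_waves[0][1].times
    all_diffs, distractor_diffs = [], []
    for _, waves in subject_waves:
        for key in waves.keys():
            d = waves.difference(key)
            all_diffs.append(d)
            if key[2] == "distractor":
                distractor_diffs.append(d)
    search = tuple(params.get("search_window", (100.0, 400.0)))
    n2pc_win = erp_mod.find_component_window(np.mean(all_diffs, axis=0), times,
                                             search=search, polarity="negative")
    pd_win = erp_mod.find_component_window(np.mean(distractor_diffs, axis=0),
                                           times, search=search,
                                           polarity="positive")
    amp_rows = []
    for subject_id, waves in subject_waves:
        for comp, win in (("N2pc", n2pc_win), ("Pd", pd_win)):
            amps = erp_mod.mean_amplitude(waves, win)
            amps["component"] = comp
            amps["subject_id"] = subject_id
            amp_rows.append(amps)
    pd.DataFrame(wave_rows).to_csv(erp_dir / "waveforms.csv", index=False)
    pd.concat(amp_rows, ignore_index=True).to_csv(erp_dir / "amplitudes.csv",
                                                  index=False)
    (erp_dir / "windows.json").write_text(json.dumps(
        {"N2pc": list(n2pc_win), "Pd": list(pd_win)}))
    _log_stage(out_dir, "erp", params)


def stage_stats(config: dict, out_dir: Path) -> None:
    params = config["stats"]
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    beh_path = out_dir / "behavior" / "distractor_tuned_means.csv"
    _require(beh_path, "behavior", "stats")
    means = pd.read_csv(beh_path)
    wide = means.pivot_table(index="subject_id",
                             columns=["condition", "distractor_location"],
                             values="mean_rt_ms").sort_index(axis=1)
    conds = wide.columns.get_level_values(0).unique()
    if len(wide) >= 3 and not wide.isna().any().any():
        effects = st.rm_anova(wide.to_numpy(),
                              {"condition": len(conds), "location": 2})
        results["rt_anova"] = [dataclasses.asdict(e) for e in effects]
        for cond in conds:
            t, df, p, d = st.paired_t(wide[(cond, "low")], wide[(cond, "high")])
            results[f"rt_low_vs_high[{cond}]"] = {
                "t": t, "df": df, "p": p, "cohens_d": d,
                "mean_diff_ms": float((wide[(cond, "low")]
                                       - wide[(cond, "high")]).mean())}

    dec_path = out_dir / "decode" / "auc.csv"
    if dec_path.exists():
        auc = pd.read_csv(dec_path)
        cluster_out = []
        for (cond, role), sub in auc.groupby(["condition", "train_class"]):
            mat = sub.pivot_table(index="subject_id", columns="time_ms",
                                  values="auc")
            if len(mat) < 6:
                continue
            res = st.cluster_permutation_1d(
                mat.to_numpy(), null_value=0.5,
                n_perm=params.get("n_perm", 1024),
                alpha_cluster=params.get("alpha_cluster", 0.05),
                seed=config["seed"])
            times = mat.columns.to_numpy(dtype=float)
            for c, m, p in zip(res.clusters, res.cluster_mass, res.p_values):
                cluster_out.append({"condition": cond, "train_class": role,
                                    "start_ms": float(times[c[0]]),
                                    "end_ms": float(times[c[-1]]),
                                    "mass": float(m), "p": float(p)})
        results["decoding_clusters"] = cluster_out

    erp_path = out_dir / "erp" / "amplitudes.csv"
    if erp_path.exists():
        amps = pd.read_csv(erp_path)
        for comp, sub in amps.groupby("component"):
            classes = ["distractor"] if comp == "Pd" else \
                sorted(sub["stimulus_class"].unique())
            sub = sub[sub["stimulus_class"].isin(classes)]
            cols = ["stimulus_class", "condition", "probability", "hemifield"]
            wide = sub.pivot_table(index="subject_id", columns=cols,
                                   values="mean_uv").sort_index(axis=1)
            if wide.isna().any().any() or len(wide) < 3:
                continue
            factors = {c: len(wide.columns.get_level_values(c).unique())
                       for c in cols}
            factors = {k: v for k, v in factors.items() if v > 1}
            if int(np.prod(list(factors.values()))) == wide.shape[1]:
                effects = st.rm_anova(wide.to_numpy(), factors)
                results[f"erp_anova[{comp}]"] = [dataclasses.asdict(e)
                                                 for e in effects]
    (stats_dir / "results.json").write_text(json.dumps(results, indent=1))
    _log_stage(out_dir, "stats", params)


_STAGE_FUNCS = {
    "simulate": stage_simulate, "preprocess": stage_preprocess,
    "behavior": stage_behavior, "tfr": stage_tfr, "decode": stage_decode,
    "erp": stage_erp, "stats": stage_stats,
}


def run_pipeline(config: dict, out_dir: str | Path,
                 stages: tuple[str, ...] | None = None) -> Path:
    """Run the requested stages (default: all) into ``out_dir``."""
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:  # canonical order regardless of request order
        if stage in stages:
            _STAGE_FUNCS[stage](config, out_dir)
    return out_dir
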