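"""Behavioral RT pipeline.

Filtering follows the fixed order: keep correct responded trials, drop
RTs under 200 ms, then trim per participant at mean +- 2.5 SD (statistics
pooled over conditions). Location-tuned cell means control for stimulus
co-occurrence: distractor-tuned analyses exclude trials with the target at
the high-probability distractor location, target-tuned analyses exclude
trials with the distractor there (or keep only distractor-absent trials).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["filter_rts", "distractor_tuned_means", "target_tuned_means",
           "exclude_location_repeats"]


def _trim_cells(sub: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    """Design cells within which trim statistics are computed.

    Trimming around a mean pooled over cells whose true means differ
    attenuates every between-cell difference by about 2*k*phi(k) (~8.8% at
    k = 2.5) because the slower cell loses more of its upper tail; computing
    the bounds within (condition x distractor location x target-at-high-
    probability) cells keeps cell-mean differences unbiased.
    """
    cells = pd.DataFrame({
        "condition": sub["condition"],
        "d_loc": sub["distractor_loc"].astype("float").fillna(-1.0),
        "t_high": sub["target_loc"] == sub["high_prob_loc"],
    })
    return sub.groupby([cells["condition"], cells["d_loc"], cells["t_high"]],
                       observed=True)


def filter_rts(table: pd.DataFrame, min_rt_ms: float = 200.0,
               sd_cutoff: float = 2.5, trim_within_cells: bool = True
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step RT trimming; returns (filtered table, per-subject report).

    Step 0 drops incorrect and non-response trials, step 1 drops
    RT < ``min_rt_ms``, step 2 trims outside mean +- ``sd_cutoff`` * SD per
    participant (mean/SD computed after step 1, two-sided). By default the
    trim statistics are computed within design cells (see
    :func:`_trim_cells`); ``trim_within_cells=False`` pools them over the
    participant's whole session. The report gives per-step exclusion
    percentages relative to the step-0 output, plus a flag for subjects
    left empty.
    """
    rows = []
    kept_parts = []
    for subject_id, sub in table.groupby("subject_id", sort=True):
        n_all = len(sub)
        sub0 = sub[sub["correct"] & sub["rt_ms"].notna()]
        n0 = len(sub0)
        sub1 = sub0[sub0["rt_ms"] >= min_rt_ms]
        if len(sub1) == 0:
            rows.append({"subject_id": subject_id, "n_trials": n_all,
                         "pct_incorrect": 100.0 * (n_all - n0) / max(n_all, 1),
                         "pct_fast": 100.0, "pct_trimmed": 0.0, "flagged": True})
            continue

        def _trim(df: pd.DataFrame) -> pd.DataFrame:
            m, sd = df["rt_ms"].mean(), df["rt_ms"].std(ddof=1)
            if len(df) < 2 or sd == 0 or np.isnan(sd):
                return df
            return df[(df["rt_ms"] >= m - sd_cutoff * sd)
                      & (df["rt_ms"] <= m + sd_cutoff * sd)]

        if trim_within_cells:
            sub2 = pd.concat([_trim(g) for _, g in _trim_cells(sub1)]).sort_index()
        else:
            sub2 = _trim(sub1)
        kept_parts.append(sub2)
        rows.append({
            "subject_id": subject_id, "n_trials": n_all,
            "pct_incorrect": 100.0 * (n_all - n0) / max(n_all, 1),
            "pct_fast": 100.0 * (n0 - len(sub1)) / max(n0, 1),
            "pct_trimmed": 100.0 * (len(sub1) - len(sub2)) / max(n0, 1),
            "flagged": False,
        })
    filtered = (pd.concat(kept_parts).sort_index() if kept_parts
                else table.iloc[0:0])
    return filtered, pd.DataFrame(rows)


def _cell_means(table: pd.DataFrame, group_col: str) -> pd.DataFrame:
    out = (table.groupby(["subject_id", "condition", group_col], observed=True)
           ["rt_ms"].mean().rename("mean_rt_ms").reset_index())
    counts = (table.groupby(["subject_id", "condition", group_col], observed=True)
              ["rt_ms"].size().rename("n_trials").reset_index())
    out = out.merge(counts, on=["subject_id", "condition", group_col])
    out["flagged_empty"] = out["n_trials"] == 0
    return out


def distractor_tuned_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean RT per (subject, condition, distractor-location probability).

    Distractor-absent trials and trials with the target at the
    high-probability distractor location are excluded.
    """
    t = table[table["distractor_loc"].notna()
              & (table["target_loc"] != table["high_prob_loc"])].copy()
    at_high = (t["distractor_loc"].astype("float")
               == t["high_prob_loc"].astype("float"))
    t["distractor_location"] = np.where(at_high, "high", "low")
    return _cell_means(t, "distractor_location")


def target_tuned_means(table: pd.DataFrame, experiment: int = 2) -> pd.DataFrame:
    """Mean RT per (subject, condition, target-at-high-probability?).

    Experiment 1: trials with the distractor at the high-probability
    location are excluded. Experiment 2: only distractor-absent trials are
    included (the target appears once per block at every location).
    """
    if experiment == 1:
        d_at_high = (table["distractor_loc"].astype("float")
                     == table["high_prob_loc"].astype("float")).fillna(False)
        t = table[~d_at_high.to_numpy(dtype=bool)].copy()
    else:
        t = table[table["distractor_loc"].isna()].copy()
    t["target_location"] = np.where(t["target_loc"] == t["high_prob_loc"],
                                    "high", "low")
    return _cell_means(t, "target_location")


def exclude_location_repeats(table: pd.DataFrame) -> pd.DataFrame:
    """Drop trials whose distractor location repeats the previous trial's.

    The intertrial-priming control: both trials must be distractor-present
    and consecutive within the same (subject, session, block).
    """
    t = table.sort_values(["subject_id", "session", "block", "trial"])
    grp = t.groupby(["subject_id", "session", "block"], sort=False)
    prev = grp["distractor_loc"].shift(1)
    repeat = t["distractor_loc"].notna() & prev.notna() \
        & (t["distractor_loc"].astype("float") == prev.astype("float"))
    return table.loc[t.index[~repeat.to_numpy(dtype=bool)].sort_values()]
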