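"""Calibration studies: known-truth simulations exercising the pipeline.

These routines quantify the statistical behavior of the analysis chain
under the study's design conditions — chance-level decoding on signal-free
data, recovery of embedded RT benefits through the full behavioral
filtering pipeline, and the familywise error rate of the cluster-based
permutation test on null data. They are used by the acceptance script and
the test suite, and are part of the public API because the same checks are
what a user should run after modifying the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import distractor_tuned_means, filter_rts
from .decoding import decode_timecourse
from .stats import cluster_permutation_1d
from .synth import SimConfig, generate_design, simulate_rts

__all__ = ["null_decoding_auc", "rt_benefit_recovery", "cluster_fwer"]


def null_decoding_auc(seed: int = 0, n_epochs: int = 300, n_channels: int = 64,
                      n_timepoints: int = 20, n_seeds: int = 20,
                      k: int = 10) -> float:
    """Grand-mean AUC of the balanced k-fold LDA pipeline on label-free noise.

    Per repetition: ``n_epochs`` Gaussian-noise epochs with balanced random
    3-class labels, decoded per timepoint; the AUC is averaged over folds,
    timepoints and ``n_seeds`` repetitions. Unbiased chance level is 0.5.
    """
    means = []
    for r in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        X = rng.standard_normal((n_epochs, n_channels, n_timepoints))
        y = np.repeat(np.array(["low", "medium", "high"]), n_epochs // 3)
        y = np.concatenate([y, np.array(["low", "medium", "high"])[: n_epochs - len(y)]])
        rng.shuffle(y)
        auc, _ = decode_timecourse(X, y, k=k, seed=int(rng.integers(2 ** 31)))
        means.append(auc.mean())
    return float(np.mean(means))


def rt_benefit_recovery(seed: int = 0, n_reps: int = 100, n_subjects: int = 24,
                        conditions: tuple[str, ...] = ("DpTp_identical",
                                                       "DpTp_unique"),
                        ) -> dict[str, float]:
    """Recover the embedded high- vs low-probability RT benefit per condition.

    Simulates Experiment-2 subjects at the generator's default effect sizes,
    runs the full behavioral pipeline (accuracy filter, 200 ms cutoff,
    2.5 SD trim, target-at-high-probability exclusion) and returns the
    group-mean low-minus-high RT difference in ms, averaged over ``n_reps``
    replications of the trial noise and subject-level effects.
    """
    design_cfg = SimConfig(seed=seed, experiment=2, n_subjects=n_subjects)
    designs = [generate_design(design_cfg, s) for s in range(n_subjects)]
    sums = {c: 0.0 for c in conditions}
    for rep in range(n_reps):
        rep_cfg = SimConfig(seed=seed + 1 + rep, experiment=2,
                            n_subjects=n_subjects)
        table = pd.concat([simulate_rts(d, rep_cfg) for d in designs],
                          ignore_index=True)
        filtered, _ = filter_rts(table)
        means = distractor_tuned_means(filtered)
        wide = means.pivot_table(index="subject_id",
                                 columns=["condition", "distractor_location"],
                                 values="mean_rt_ms")
        for c in conditions:
            sums[c] += float((wide[(c, "low")] - wide[(c, "high")]).mean())
    return {c: v / n_reps for c, v in sums.items()}


def cluster_fwer(seed: int = 0, n_datasets: int = 500, n_subjects: int = 20,
                 n_timepoints: int = 100, n_perm: int = 1024,
                 alpha: float = 0.05) -> float:
    """Empirical familywise error rate of the 1D cluster permutation test.

    Fraction of i.i.d.-Gaussian null datasets in which any cluster reaches
    p < ``alpha``; the nominal level is ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_datasets):
        X = rng.standard_normal((n_subjects, n_timepoints))
        res = cluster_permutation_1d(X, null_value=0.0, alpha_cluster=alpha,
                                     n_perm=n_perm,
                                     seed=int(rng.integers(2 ** 31)))
        hits += len(res.p_values) > 0 and bool((res.p_values < alpha).any())
    return hits / n_datasets
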