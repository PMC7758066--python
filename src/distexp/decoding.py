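"""Time-resolved multivariate decoding of spatial frequency.

A shrinkage-regularized linear discriminant is trained per timepoint on all
64 scalp channels, with class-balanced 10-fold cross-validation and
macro-averaged one-vs-rest AUC as the performance measure (0.5 = chance).
Cross-class generalization trains on one stimulus role (e.g. distractor
spatial frequency) and tests on target-only trials to probe whether target
and distractor expectations share a neural code.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

from .data_model import DecodingResult, EpochSet
from .exceptions import InsufficientDataError, LeakageError, ParameterError
from .preprocessing import baseline_correct

__all__ = [
    "prepare_decoding_epochs", "ShrinkageLDA", "multiclass_auc",
    "decode_timecourse", "time_resolved_cv_decode", "cross_class_decode",
    "window_average_auc",
]


def prepare_decoding_epochs(epochs: EpochSet,
                            baseline: tuple[float, float] = (-750.0, -550.0),
                            target_sfreq: float = 128.0) -> EpochSet:
    """Baseline-correct and resample epochs for decoding.

    Resampling uses polyphase filtering at the rational ratio
    target_sfreq / sfreq (anti-alias low-pass included).
    """
    out = baseline_correct(epochs, baseline)
    if out.sfreq != target_sfreq:
        frac = Fraction(target_sfreq / out.sfreq).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
        data = sp_signal.resample_poly(out.data, up, down, axis=-1)
        n_new = data.shape[-1]
        times = out.times[0] + 1000.0 / target_sfreq * np.arange(n_new)
        out = EpochSet(data=data, sfreq=target_sfreq, times=times,
                       montage=out.montage, trials=out.trials,
                       history=list(out.history))
    out.log("prepare_decoding", baseline=list(baseline), sfreq=target_sfreq)
    return out


class ShrinkageLDA(BaseEstimator, ClassifierMixin):
    """LDA with the pooled covariance shrunk toward its diagonal.

    Sigma_reg = (1 - lam) * S + lam * diag(S). With ``shrinkage='auto'`` the
    off-diagonal shrinkage intensity is the analytic (Ledoit-Wolf-style)
    estimate of Schafer & Strimmer; with a float it is used as-is. At
    lam = 1 the classifier reduces to a diagonal-covariance (naive
    Gaussian) discriminant.
    """

    def __init__(self, shrinkage: float | str = "auto"):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = len(self.classes_)
        if np.any(np.bincount(y_idx) < 2):
            raise InsufficientDataError("need at least 2 trials per class")
        means = np.stack([X[y_idx == c].mean(axis=0) for c in range(k)])
        Xc = X - means[y_idx]
        S = (Xc.T @ Xc) / (n - k)

        if self.shrinkage == "auto":
            lam = self._analytic_shrinkage(Xc, S, n)
        else:
            lam = float(self.shrinkage)
            if not 0.0 <= lam <= 1.0:
                raise ParameterError("shrinkage must lie in [0, 1]")
        self.shrinkage_ = lam
        sigma = (1.0 - lam) * S + lam * np.diag(np.diag(S))
        try:
            coef = np.linalg.solve(sigma, means.T)  # p x k
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; use shrinkage > 0") from err
        self.coef_ = coef.T
        priors = np.bincount(y_idx) / n
        self.intercept_ = -0.5 * np.einsum("kp,pk->k", means, coef) + np.log(priors)
        self.means_ = means
        return self

    @staticmethod
    def _analytic_shrinkage(Xc: np.ndarray, S: np.ndarray, n: int) -> float:
        # Schafer-Strimmer target D = diag(S): lam* = sum Var(s_ij) / sum s_ij^2
        # over off-diagonal entries, clipped to [0, 1].
        W = Xc[:, :, None] * Xc[:, None, :]          # n x p x p products
        var_s = W.var(axis=0, ddof=1) * n / (n - 1) ** 2
        off = ~np.eye(S.shape[0], dtype=bool)
        denom = float((S[off] ** 2).sum())
        if denom == 0.0:
            return 1.0
        return float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def multiclass_auc(scores: np.ndarray, y: np.ndarray,
                   classes: np.ndarray | None = None) -> float:
    """Macro one-vs-rest AUC from per-class decision values.

    Each class AUC uses the rank (Mann-Whitney) formulation with 0.5 credit
    for ties; classes absent from ``y`` are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("AUC needs at least 2 classes present")
    aucs = []
    for j, cls in enumerate(classes):
        pos = y == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0:
            warnings.warn(f"class {cls!r} absent from labels; skipped")
            continue
        ranks = rankdata(scores[:, j])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        aucs.append(auc)
    return float(np.mean(aucs))


def _balanced_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per trial (-1 = dropped), equal class counts in every fold."""
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    if m < k:
        raise InsufficientDataError(
            f"smallest class has {m} trials; need >= {k} for {k}-fold CV")
    per_fold = m // k
    folds = np.full(len(y), -1, dtype=int)
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(y == cls))[: per_fold * k]
        folds[idx] = np.repeat(np.arange(k), per_fold)
    return folds


def decode_timecourse(X: np.ndarray, y: np.ndarray, k: int = 10,
                      seed: int = 0, shrinkage: float | str = "auto"
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint k-fold balanced LDA decoding of ``y`` from X.

    X is trials x features x timepoints. Returns (auc[timepoints],
    per_fold_auc[k, timepoints]).
    """
    rng = np.random.default_rng(seed)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("decoding needs at least 2 classes")
    folds = _balanced_folds(y, k, rng)
    n_time = X.shape[-1]
    per_fold = np.empty((k, n_time))
    classes = np.unique(y[folds >= 0])
    for f in range(k):
        train = folds >= 0
        test = folds == f
        train = train & ~test
        for t in range(n_time):
            clf = ShrinkageLDA(shrinkage=shrinkage).fit(X[train, :, t], y[train])
            sc = clf.decision_function(X[test, :, t])
            per_fold[f, t] = multiclass_auc(sc, y[test], classes=classes)
    return per_fold.mean(axis=0), per_fold


def _select_for_labels(trials: pd.DataFrame, label_field: str) -> np.ndarray:
    """Leakage-safe trial selection per label type.

    Distractor decoding uses distractor-present trials only; target decoding
    excludes target-only (distractor-absent) trials, which are reserved for
    cross-class testing.
    """
    if label_field == "distractor_sf":
        return trials["distractor_loc"].notna().to_numpy()
    if label_field == "target_sf":
        return trials["distractor_loc"].notna().to_numpy()
    raise ParameterError(f"label_field must be a spatial-frequency column, "
                         f"got {label_field!r}")


def time_resolved_cv_decode(epochs: EpochSet, label_field: str = "target_sf",
                            k: int = 10, seed: int = 0,
                            shrinkage: float | str = "auto") -> DecodingResult:
    """Within-condition, per-timepoint k-fold decoding of spatial frequency."""
    scalp_idx = np.array([epochs.montage.index(c)
                          for c in epochs.montage.scalp_channels])
    usable = _select_for_labels(epochs.trials, label_field)
    conditions = tuple(pd.unique(epochs.trials["condition"]))
    auc = np.empty((len(conditions), len(epochs.times)))
    per_fold = np.empty((len(conditions), k, len(epochs.times)))
    for ci, cond in enumerate(conditions):
        mask = usable & (epochs.trials["condition"] == cond).to_numpy()
        idx = np.flatnonzero(mask)
        X = epochs.data[np.ix_(idx, scalp_idx)]
        y = epochs.trials[label_field].to_numpy()[idx]
        auc[ci], per_fold[ci] = decode_timecourse(
            X, y, k=k, seed=seed + ci, shrinkage=shrinkage)
    role = "target" if label_field == "target_sf" else "distractor"
    return DecodingResult(auc=auc, times=epochs.times.copy(),
                          conditions=conditions, train_class=role,
                          test_class=role, per_fold_auc=per_fold)


def _trial_ids(trials: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, trials[["subject_id", "session", "block", "trial"]]
                   .to_numpy()))


def cross_class_decode(train_epochs: EpochSet, train_field: str,
                       test_epochs: EpochSet, test_field: str = "target_sf",
                       seed: int = 0, shrinkage: float | str = "auto"
                       ) -> DecodingResult:
    """Train on one stimulus role, test on independent target-only trials.

    One classifier per timepoint is fit on all (class-balanced) training
    trials of each condition and scored on that condition's test trials; no
    cross-validation is needed because the sets are disjoint (enforced).
    """
    overlap = _trial_ids(train_epochs.trials) & _trial_ids(test_epochs.trials)
    if overlap:
        raise LeakageError(f"{len(overlap)} trials appear in both train and test")
    if not np.array_equal(train_epochs.times, test_epochs.times):
        raise ParameterError("train and test epochs must share a time axis")
    scalp_idx = np.array([train_epochs.montage.index(c)
                          for c in train_epochs.montage.scalp_channels])
    rng = np.random.default_rng(seed)
    conditions = tuple(pd.unique(train_epochs.trials["condition"]))
    n_time = len(train_epochs.times)
    auc = np.empty((len(conditions), n_time))
    usable = _select_for_labels(train_epochs.trials, train_field)
    for ci, cond in enumerate(conditions):
        tr_idx = np.flatnonzero(usable
                                & (train_epochs.trials["condition"] == cond).to_numpy())
        y_tr = train_epochs.trials[train_field].to_numpy()[tr_idx]
        # class-balance the training set by subsampling
        classes, counts = np.unique(y_tr, return_counts=True)
        m = counts.min()
        keep = np.concatenate([
            rng.permutation(tr_idx[y_tr == c])[:m] for c in classes])
        y_tr = train_epochs.trials[train_field].to_numpy()[keep]
        Xtr = train_epochs.data[np.ix_(keep, scalp_idx)]
        te_mask = (test_epochs.trials["condition"] == cond).to_numpy()
        if not te_mask.any():
            te_mask = np.ones(test_epochs.n_trials, dtype=bool)
        Xte = test_epochs.data[np.ix_(np.flatnonzero(te_mask), scalp_idx)]
        y_te = test_epochs.trials[test_field].to_numpy()[te_mask]
        for t in range(n_time):
            clf = ShrinkageLDA(shrinkage=shrinkage).fit(Xtr[:, :, t], y_tr)
            sc = clf.decision_function(Xte[:, :, t])
            auc[ci, t] = multiclass_auc(sc, y_te, classes=clf.classes_)
    role = "target" if train_field == "target_sf" else "distractor"
    return DecodingResult(auc=auc, times=train_epochs.times.copy(),
                          conditions=conditions, train_class=role,
                          test_class="target" if test_field == "target_sf"
                          else "distractor")


def window_average_auc(result: DecodingResult,
                       window: tuple[float, float]) -> dict[str, float]:
    """Mean AUC over a time window (ms), per condition."""
    mask = (result.times >= window[0]) & (result.times <= window[1])
    if not mask.any():
        raise ParameterError(f"window {window} contains no timepoints")
    return {cond: float(result.auc[ci, mask].mean())
            for ci, cond in enumerate(result.conditions)}
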