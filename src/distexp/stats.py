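"""Inferential machinery for fully within-subject designs.

* repeated-measures ANOVA (any number of crossed within factors) with
  Greenhouse-Geisser sphericity correction and partial eta squared,
* paired t-tests with Cohen's d,
* 1D (time) and 2D (frequency x time) cluster-based sign-flip permutation
  tests with a parametric cluster-forming threshold, the standard remedy
  for multiple comparisons over densely sampled axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
from scipy import ndimage
from scipy import stats as sp_stats

from .data_model import ClusterTestResult
from .exceptions import InsufficientDataError, ParameterError

__all__ = ["rm_anova", "paired_t", "cluster_permutation_1d",
           "cluster_permutation_2d", "AnovaEffect"]


# --------------------------------------------------------------------------
# Repeated-measures ANOVA
# --------------------------------------------------------------------------

@dataclass
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    epsilon: float
    p: float            # Greenhouse-Geisser corrected
    p_uncorrected: float
    eta_p2: float
    ss_effect: float
    ss_error: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the complement of the mean."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis.T)
    return q[:, : k - 1].T


def _subsets(items):
    return chain.from_iterable(combinations(items, r)
                               for r in range(1, len(items) + 1))


def rm_anova(data: np.ndarray, factors: dict[str, int] | dict[str, list]
             ) -> list[AnovaEffect]:
    """Repeated-measures ANOVA on a complete balanced within-subject design.

    ``data`` is subjects x cells with cells ordered so that the *last*
    factor varies fastest (C order over the factor levels). ``factors`` maps
    factor name to its number of levels (or to the list of level labels).
    Each within effect is tested against its interaction with subjects;
    p-values carry the Greenhouse-Geisser epsilon computed from the
    covariance of the orthonormalized effect contrasts.
    """
    data = np.asarray(data, dtype=float)
    levels = {name: (len(v) if hasattr(v, "__len__") else int(v))
              for name, v in factors.items()}
    names = list(levels)
    shape = tuple(levels[n] for n in names)
    n_subj = data.shape[0]
    if data.shape[1] != int(np.prod(shape)):
        raise ParameterError(
            f"data has {data.shape[1]} cells but factors imply {np.prod(shape)} "
            "(missing cells / imbalance is not supported)")
    if np.any(np.isnan(data)):
        raise ParameterError("missing cells are not supported")
    Y = data.reshape((n_subj,) + shape)
    all_axes = tuple(range(Y.ndim))  # 0 = subject

    def effect_term(keep_axes: tuple[int, ...]) -> np.ndarray:
        """Inclusion-exclusion estimate of the effect for `keep_axes`."""
        term = np.zeros_like(Y)
        for r in range(len(keep_axes) + 1):
            for sub in combinations(keep_axes, r):
                sign = (-1.0) ** (len(keep_axes) - r)
                mean_axes = tuple(a for a in all_axes if a not in sub)
                term = term + sign * Y.mean(axis=mean_axes, keepdims=True)
        return term

    results = []
    for combo in _subsets(range(len(names))):
        axes = tuple(a + 1 for a in combo)
        ss_eff = float((effect_term(axes) ** 2).sum())
        ss_err = float((effect_term((0,) + axes) ** 2).sum())
        df1 = float(np.prod([shape[a - 1] - 1 for a in axes]))
        df2 = (n_subj - 1) * df1
        if ss_eff == 0.0:
            F, p_unc = 0.0, 1.0
        elif ss_err == 0.0:
            F, p_unc = np.inf, 0.0
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            p_unc = float(sp_stats.f.sf(F, df1, df2))

        # GG epsilon from the contrast covariance of the collapsed data
        collapse = tuple(a for a in all_axes[1:] if a not in axes)
        Yc = Y.mean(axis=collapse) if collapse else Y
        Yc = Yc.reshape(n_subj, -1)
        C = _orthonormal_contrasts(Yc.shape[1]) if len(axes) == 1 else None
        if C is None:  # interaction: Kronecker product of factor contrasts
            C = np.ones((1, 1))
            for a in axes:
                C = np.kron(C, _orthonormal_contrasts(shape[a - 1]))
        Z = Yc @ C.T
        d = Z.shape[1]
        if d <= 1:
            eps = 1.0
        else:
            S = np.cov(Z, rowvar=False, ddof=1)
            tr = np.trace(S)
            tr2 = np.trace(S @ S)
            eps = 1.0 if tr2 == 0 else float(tr ** 2 / (d * tr2))
            eps = float(np.clip(eps, 1.0 / d, 1.0))
        if np.isfinite(F) and F > 0:
            p_gg = float(sp_stats.f.sf(F, df1 * eps, df2 * eps))
        else:
            p_gg = p_unc
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        results.append(AnovaEffect(
            effect=" x ".join(names[a] for a in combo),
            F=float(F), df1=df1, df2=df2, epsilon=eps,
            p=p_gg, p_uncorrected=p_unc, eta_p2=float(eta),
            ss_effect=ss_eff, ss_error=ss_err))
    return results


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float, float]:
    """Paired t-test with Cohen's d = mean(diff) / SD(diff).

    Returns (t, df, p, d). A zero-variance nonzero difference is undefined
    and raises; identical vectors give t = d = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("paired_t needs equal-length vectors, n >= 3")
    diff = x - y
    sd = diff.std(ddof=1)
    n = len(diff)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return 0.0, n - 1, 1.0, 0.0
        raise ParameterError("zero-variance nonzero difference: t undefined")
    t = diff.mean() / (sd / np.sqrt(n))
    p = float(2 * sp_stats.t.sf(abs(t), n - 1))
    return float(t), n - 1, p, float(diff.mean() / sd)


# --------------------------------------------------------------------------
# Cluster-based permutation tests
# --------------------------------------------------------------------------

def _t_one_sample(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)


def _clusters_nd(t_map: np.ndarray, thr: float):
    """Supra-threshold clusters (4-connectivity), signed masses."""
    out = []
    for sign in (1.0, -1.0):
        lab, n_lab = ndimage.label(sign * t_map > thr)
        for k in range(1, n_lab + 1):
            idx = np.argwhere(lab == k)
            out.append((idx.squeeze(-1) if t_map.ndim == 1 else idx,
                        float(t_map[tuple(idx.T)].sum())))
    return out


def _max_mass_nd(t_map: np.ndarray, thr: float) -> float:
    if t_map.ndim == 1:  # fast path: run detection without labelling
        best = 0.0
        csum = None
        for sign in (1.0, -1.0):
            m = sign * t_map > thr
            if not m.any():
                continue
            d = np.diff(m.astype(np.int8))
            starts = np.flatnonzero(d == 1) + 1
            ends = np.flatnonzero(d == -1) + 1
            if m[0]:
                starts = np.concatenate([[0], starts])
            if m[-1]:
                ends = np.concatenate([ends, [len(m)]])
            if csum is None:
                csum = np.concatenate([[0.0], np.cumsum(np.abs(t_map))])
            best = max(best, float((csum[ends] - csum[starts]).max()))
        return best
    best = 0.0
    for sign in (1.0, -1.0):
        lab, n_lab = ndimage.label(sign * t_map > thr)
        if n_lab:
            masses = ndimage.sum(np.abs(t_map), lab, index=range(1, n_lab + 1))
            best = max(best, float(np.max(masses)))
    return best


def _cluster_permutation(data: np.ndarray, null_value: float,
                         alpha_cluster: float, n_perm: int,
                         seed: int) -> ClusterTestResult:
    X = np.asarray(data, dtype=float) - null_value
    n = X.shape[0]
    if n < 6:
        raise InsufficientDataError("cluster permutation needs >= 6 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is low; p-values will be coarse")
    thr = float(sp_stats.t.ppf(1.0 - alpha_cluster / 2.0, n - 1))
    t_obs = _t_one_sample(X)
    observed = _clusters_nd(t_obs, thr)

    rng = np.random.default_rng(seed)
    flat = X.reshape(n, -1)
    ssq = (flat ** 2).sum(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ flat / n
    var = (ssq[None, :] / n - means ** 2) * n / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    null_max = np.array([
        _max_mass_nd(t_null[i].reshape(X.shape[1:]), thr)
        for i in range(n_perm)])

    clusters = [c for c, _ in observed]
    masses = np.array([m for _, m in observed])
    p_values = np.array([
        (1.0 + np.sum(null_max >= abs(m))) / (n_perm + 1.0) for m in masses])
    return ClusterTestResult(clusters=clusters, cluster_mass=masses,
                             p_values=p_values, n_permutations=n_perm,
                             seed=seed, t_obs=t_obs)


def cluster_permutation_1d(data: np.ndarray, null_value: float = 0.0,
                           alpha_cluster: float = 0.05, n_perm: int = 1024,
                           seed: int = 0) -> ClusterTestResult:
    """Sign-flip cluster permutation test over time (subjects x timepoints).

    Per-timepoint one-sample t vs ``null_value``; contiguous runs exceeding
    the two-sided parametric threshold form clusters whose mass (summed t)
    is compared against the permutation distribution of the maximal
    absolute cluster mass. The observed statistic counts toward its own
    null (+1 correction), so p >= 1/(n_perm + 1).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.ndim != 2:
        raise ParameterError("1D cluster test expects subjects x timepoints")
    return _cluster_permutation(data, null_value, alpha_cluster, n_perm, seed)


def cluster_permutation_2d(data: np.ndarray, null_value: float = 0.0,
                           alpha_cluster: float = 0.05, n_perm: int = 1024,
                           seed: int = 0) -> ClusterTestResult:
    """As :func:`cluster_permutation_1d` over a frequency x time grid.

    Cluster connectivity is 4-neighborhood (no diagonals).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ParameterError("2D cluster test expects subjects x freq x time")
    return _cluster_permutation(data, null_value, alpha_cluster, n_perm, seed)
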