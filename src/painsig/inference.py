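"""The statistical validation battery.

Forced-choice accuracy with exact binomial tests, ROC/AUC, paired and
robust (Huber) one-sample tests, within-participant SEM, Benjamini-
Hochberg FDR, subject-level bootstrap thresholding of trained weight
maps, and conjunction masks of group-significant voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import StudyDataset
from .errors import (DegenerateDataError, GeometryError, InvalidConfigError,
                     ZeroVarianceError)
from .imgio import BrainMask
from .signature import VoxelPattern

# ---------------------------------------------------------------------------
# Forced choice & ROC


@dataclass
class ForcedChoiceResult:
    """Paired two-alternative accuracy with exact binomial inference."""

    n_pairs: int
    n_correct: float  # ties credited 0.5
    accuracy: float
    p_value: float
    roc_points: np.ndarray  # (k, 2) of (FPR, TPR)
    auc: float


def roc_curve(resp_pos: np.ndarray, resp_neg: np.ndarray):
    """Threshold-sweep ROC and pair-probability AUC.

    AUC equals the probability that a random positive response exceeds a
    random negative one, ties counted half.
    """
    pos = np.asarray(resp_pos, dtype=float)
    neg = np.asarray(resp_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError("both response vectors must be nonempty")
    thresholds = np.r_[np.inf, np.unique(np.r_[pos, neg])[::-1]]
    points = [( (neg >= th).mean(), (pos >= th).mean() ) for th in thresholds]
    points = np.asarray(points)
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (pos.size * neg.size)
    return points, float(auc)


def forced_choice(resp_a: np.ndarray, resp_b: np.ndarray) -> ForcedChoiceResult:
    """Two-alternative forced choice: is A (the higher-intensity condition)
    scored above B for each subject?

    Ties are credited 0.5 toward accuracy and excluded from the exact
    two-sided binomial test against chance.
    """
    a = np.asarray(resp_a, dtype=float)
    b = np.asarray(resp_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidConfigError("paired response vectors differ in length")
    n = a.size
    wins = (a > b).sum()
    ties = (a == b).sum()
    n_correct = wins + 0.5 * ties
    accuracy = n_correct / n
    n_eff = n - ties
    if n_eff > 0:
        p = stats.binomtest(int(wins), int(n_eff), 0.5,
                            alternative="two-sided").pvalue
    else:
        p = 1.0
    points, auc = roc_curve(a, b)
    return ForcedChoiceResult(n_pairs=int(n), n_correct=float(n_correct),
                              accuracy=float(accuracy), p_value=float(p),
                              roc_points=points, auc=auc)


def forced_choice_from_scores(scores: pd.DataFrame, value_col: str = "response",
                              high_level: Optional[int] = None,
                              low_level: Optional[int] = None
                              ) -> ForcedChoiceResult:
    """High-vs-low forced choice from a per-image score table.

    Scores are averaged over sites within subject × level; the pair is
    (high level, low level) per subject. Levels default to the extremes
    present in the table.
    """
    levels = np.sort(scores["level"].unique())
    hi = levels.max() if high_level is None else high_level
    lo = levels.min() if low_level is None else low_level
    per = (scores.groupby(["subject", "level"])[value_col]
           .mean().unstack("level"))
    if hi not in per.columns or lo not in per.columns:
        raise InvalidConfigError("requested levels absent from score table")
    return forced_choice(per[hi].to_numpy(), per[lo].to_numpy())


# ---------------------------------------------------------------------------
# Group tests


def paired_t(a: np.ndarray, b: np.ndarray):
    """One-sample t on paired differences; returns (t, df, p)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 3:
        raise DegenerateDataError("need n >= 3 pairs")
    if np.std(d, ddof=1) == 0:
        raise ZeroVarianceError("paired differences have zero variance")
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), d.size - 1, float(res.pvalue)


HUBER_C = 1.345


def _huber_psi(u: np.ndarray, c: float = HUBER_C) -> np.ndarray:
    return np.clip(u, -c, c)


def huber_location(values: np.ndarray, c: float = HUBER_C,
                   max_iter: int = 50, tol: float = 1e-8):
    """Vectorized Huber M-estimate of location along axis 0.

    Returns ``(mu, se, scale)``. The scale is re-estimated each
    iteration as the normalized MAD of the current residuals (the
    standard joint location/scale iteration). With no residual beyond
    c·scale the estimate and its SE reduce to the mean and classical SE.
    """
    x = np.asarray(values, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    mu = np.median(x, axis=0)
    scale = np.median(np.abs(x - mu), axis=0) / 0.6744897501960817
    degenerate = scale == 0
    safe_scale = np.where(degenerate, 1.0, scale)
    for _ in range(max_iter):
        u = (x - mu) / safe_scale
        wts = np.ones_like(u)
        nz = np.abs(u) > 1e-300
        wts[nz] = _huber_psi(u[nz], c) / u[nz]
        new_mu = (wts * x).sum(axis=0) / wts.sum(axis=0)
        done = np.max(np.abs(new_mu - mu)) < tol
        mu = new_mu
        scale = np.median(np.abs(x - mu), axis=0) / 0.6744897501960817
        degenerate = scale == 0
        safe_scale = np.where(degenerate, 1.0, scale)
        if done:
            break
    u = (x - mu) / safe_scale
    psi = _huber_psi(u, c)
    psi_prime = (np.abs(u) <= c).astype(float)
    num = (psi ** 2).sum(axis=0) / n
    den = np.maximum(psi_prime.mean(axis=0), 1e-12) ** 2
    se = safe_scale * np.sqrt(num / den) / np.sqrt(n - 1)
    mu = np.where(degenerate, x.mean(axis=0), mu)
    se = np.where(degenerate, 0.0, se)
    if squeeze:
        return float(mu[0]), float(se[0]), float(scale[0])
    return mu, se, scale


def robust_group_test(values: np.ndarray):
    """Robust one-sample location test (Huber IRLS, c = 1.345).

    Returns ``(estimate, t, df, p)`` with df = n - 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise DegenerateDataError("need a 1D sample with n >= 3")
    if np.std(x, ddof=1) == 0:
        raise ZeroVarianceError("sample has zero variance")
    mu, se, _ = huber_location(x)
    t = mu / se
    df = x.size - 1
    return mu, float(t), df, float(2.0 * stats.t.sf(abs(t), df))


def robust_group_map(X: np.ndarray):
    """Voxelwise robust one-sample test across subjects.

    ``X`` is (n_subjects, V); returns ``(estimates, t, p)`` arrays.
    Zero-variance voxels get t = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    mu, se, scale = huber_location(X)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mu / np.where(se > 0, se, 1.0), 0.0)
    t = np.where(sd == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd == 0, 1.0, p)
    return mu, t, p


def within_subject_sem(table: pd.DataFrame) -> pd.Series:
    """Within-participant SEM per condition (Cousineau-Morey).

    ``table`` is wide: rows = subjects, columns = conditions, complete.
    Each row is recentered to the grand mean before computing the
    per-condition SEM, which is then scaled by sqrt(C/(C-1)).
    """
    if table.isna().any().any():
        raise InvalidConfigError("subject × condition table has missing cells")
    n, C = table.shape
    if C < 2:
        raise InvalidConfigError("need at least 2 conditions")
    grand = table.to_numpy().mean()
    centered = table.sub(table.mean(axis=1), axis=0) + grand
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(C / (C - 1))


# ---------------------------------------------------------------------------
# Multiple testing


def bh_fdr(p_values: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns (threshold, reject bool array).

    The threshold is the largest p(i) with p(i) <= i·q/m (0 when nothing
    is rejected); all p-values at or below it are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")[:1]
    threshold = p[reject].max() if reject.any() else 0.0
    return float(threshold), reject


# ---------------------------------------------------------------------------
# Bootstrap thresholding


@dataclass
class BootstrapMap:
    """Per-voxel bootstrap inference on a trained pattern's weights."""

    B: int
    mean_w: np.ndarray
    sd_w: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: float
    surviving: np.ndarray       # bool per voxel
    excluded: np.ndarray        # voxels with zero bootstrap SD (not tested)
    fdr_threshold: float


def bootstrap_threshold(dataset: StudyDataset,
                        fit_fn: Callable[[np.ndarray, np.ndarray, BrainMask], VoxelPattern],
                        B: int = 200, q: float = 0.05,
                        seed: int = 0) -> BootstrapMap:
    """Bootstrap the training subjects to threshold a pattern's weights.

    Each of the B resamples draws N subjects with replacement (all of a
    drawn subject's images enter, once per draw), refits the trainer via
    ``fit_fn(X, ratings, mask)``, and records the voxel weights. The
    voxelwise z = mean/SD over resamples is referred to a two-tailed
    normal, with BH-FDR control at level q. Voxels whose bootstrap SD is
    zero are excluded from testing and flagged.
    """
    if B < 100:
        raise InvalidConfigError("B must be >= 100")
    subjects = dataset.subjects
    if subjects.size < 5:
        raise DegenerateDataError("need at least 5 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    subj_col = dataset.info["subject"].to_numpy()
    rows_of = {int(s): np.flatnonzero(subj_col == s) for s in subjects}
    W = np.empty((B, dataset.mask.V))
    for b in range(B):
        draw = rng.choice(subjects, size=subjects.size, replace=True)
        rows = np.concatenate([rows_of[int(s)] for s in draw])
        pat = fit_fn(dataset.X[rows], dataset.ratings[rows], dataset.mask)
        W[b] = pat.weights
    mean_w = W.mean(axis=0)
    sd_w = W.std(axis=0, ddof=1)
    excluded = sd_w == 0
    z = np.zeros_like(mean_w)
    z[~excluded] = mean_w[~excluded] / sd_w[~excluded]
    p = np.ones_like(mean_w)
    p[~excluded] = 2.0 * stats.norm.sf(np.abs(z[~excluded]))
    surviving = np.zeros(mean_w.size, dtype=bool)
    if (~excluded).any():
        thr, rej = bh_fdr(p[~excluded], q)
        surviving[~excluded] = rej
    else:
        thr = 0.0
    return BootstrapMap(B=B, mean_w=mean_w, sd_w=sd_w, z=z, p=p, q=q,
                        surviving=surviving, excluded=excluded,
                        fdr_threshold=float(thr))


def bootstrap_lasso_pcr(dataset: StudyDataset, config=None, B: int = 200,
                        q: float = 0.05, seed: int = 0) -> BootstrapMap:
    """Bootstrap-threshold a LASSO-PCR pattern with fixed hyperparameters.

    The lasso penalty is selected once on the full training set (inner
    CV), then held fixed across bootstrap refits, so the bootstrap
    measures weight stability under subject resampling rather than
    penalty-selection jitter.
    """
    from dataclasses import replace as _replace

    from .train import TrainerConfig, lasso_pcr_fit

    config = config if config is not None else TrainerConfig()
    full = lasso_pcr_fit(dataset.X, dataset.ratings, dataset.mask, config)
    fixed = _replace(config, lasso_lambda=full.meta.get("lambda", 0.0))

    def fit(X, y, mask):
        return lasso_pcr_fit(X, y, mask, fixed)

    return bootstrap_threshold(dataset, fit, B=B, q=q, seed=seed)


# ---------------------------------------------------------------------------
# Conjunction


def group_significance(X: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Voxels with a robust group effect surviving FDR at level q."""
    _, _, p = robust_group_map(X)
    _, reject = bh_fdr(p, q)
    return reject


def conjunction_mask(sig1, sig2) -> np.ndarray:
    """Logical AND of two significance masks (same geometry required).

    Accepts boolean arrays (any matching shape) or BrainMasks and always
    returns a boolean array; warns, rather than errs, when the
    conjunction is empty (an empty set is a legitimate finding).
    """
    if isinstance(sig1, BrainMask) and isinstance(sig2, BrainMask):
        if not sig1.geometry.matches(sig2.geometry):
            raise GeometryError("conjunction requires identical geometry")
        a, b = sig1.include, sig2.include
    else:
        a = np.asarray(sig1, dtype=bool)
        b = np.asarray(sig2, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("significance masks differ in shape")
    out = a & b
    if not out.any():
        warnings.warn("conjunction mask is empty", stacklevel=2)
    return out


def binomial_interval(n: int, p: float = 0.5, level: float = 0.95):
    """Exact central acceptance band for a Binomial(n, p) proportion."""
    alpha = 1.0 - level
    lo = stats.binom.ppf(alpha / 2, n, p) / n
    hi = stats.binom.ppf(1 - alpha / 2, n, p) / n
    return float(lo), float(hi)
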