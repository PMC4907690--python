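"""Minimal first-level modeling.

Canonical-HRF boxcar GLMs, trial-wise "beta series" estimation, and
smoothed finite-impulse-response (sFIR) time courses. Estimators are
ordinary (or smoothness-penalized) least squares; temporal
autocorrelation is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, RankError
from .signature import VoxelPattern

#: canonical double-gamma parameters: response/undershoot delay (s),
#: dispersions, and peak:undershoot amplitude ratio
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_DISPERSION = 1.0
HRF_RATIO = 6.0


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical hemodynamic response sampled every ``tr_s`` seconds.

    Difference of two gamma densities (peak at ~5 s, undershoot around
    16 s), peak-normalized so max(h) = 1.
    """
    if tr_s <= 0:
        raise InvalidConfigError("tr_s must be positive")
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    return _hrf_values(t)


def _hrf_values(t: np.ndarray) -> np.ndarray:
    h = (stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_DISPERSION,
                         scale=HRF_DISPERSION)
         - stats.gamma.pdf(t, HRF_UNDERSHOOT_DELAY / HRF_DISPERSION,
                           scale=HRF_DISPERSION) / HRF_RATIO)
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass
class EventDesign:
    """Event table + scan timing for a first-level model.

    ``events`` columns: onset_s, duration_s, condition (and optionally
    trial_id for beta-series models).
    """

    events: pd.DataFrame
    tr_s: float
    n_scans: int
    nuisance: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.tr_s <= 0:
            raise InvalidConfigError("tr_s must be positive")
        ev = self.events
        for col in ("onset_s", "duration_s", "condition"):
            if col not in ev.columns:
                raise InvalidConfigError(f"events table missing column {col}")
        run_len = self.n_scans * self.tr_s
        if (ev["onset_s"] < 0).any() or (ev["onset_s"] >= run_len).any():
            raise InvalidConfigError("event onsets must lie within the run")
        if self.nuisance is not None:
            self.nuisance = np.atleast_2d(np.asarray(self.nuisance, float))
            if self.nuisance.shape[0] != self.n_scans:
                raise InvalidConfigError("nuisance rows must equal n_scans")


def build_design_matrix(design: EventDesign, oversample: int = 16,
                        hrf_duration_s: float = 32.0):
    """HRF-convolved boxcar regressors, one column per condition.

    Boxcars are built on a fine grid (``tr/oversample``), convolved with
    the canonical HRF sampled on that grid, then read out at scan times.
    Returns ``(X, condition_names)`` without intercept or nuisance.
    """
    ev = design.events
    conditions = list(dict.fromkeys(ev["condition"]))  # order of appearance
    dt = design.tr_s / oversample
    n_fine = design.n_scans * oversample
    hrf = _hrf_values(np.arange(0.0, hrf_duration_s + 1e-9, dt))
    X = np.zeros((design.n_scans, len(conditions)))
    for j, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        for _, row in ev[ev["condition"] == cond].iterrows():
            a = int(round(row["onset_s"] / dt))
            b = int(round((row["onset_s"] + row["duration_s"]) / dt))
            box[a:max(b, a + 1)] = 1.0
        # dt-scaled discrete convolution ≈ continuous boxcar ∗ HRF, so the
        # regressor scale does not depend on the oversampling factor
        conv = np.convolve(box, hrf)[:n_fine] * dt
        X[:, j] = conv[::oversample]
    return X, conditions


@dataclass
class GLMResult:
    betas: np.ndarray          # (n_conditions, V)
    condition_names: list
    intercept: np.ndarray      # (V,)
    residual_var: np.ndarray   # (V,)
    design_matrix: np.ndarray  # full design incl. intercept/nuisance
    column_names: list

    def beta(self, condition) -> np.ndarray:
        return self.betas[self.condition_names.index(condition)]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify columns whose removal restores full column rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == r:
                bad.append(names[j])
        raise RankError(f"design matrix rank deficient; collinear columns: {bad}")


def fit_glm(Y: np.ndarray, design: EventDesign,
            oversample: int = 16) -> GLMResult:
    """Ordinary least-squares GLM with HRF-convolved boxcar regressors."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n_scans:
        raise InvalidConfigError("Y rows must equal n_scans")
    Xc, conditions = build_design_matrix(design, oversample=oversample)
    cols = [Xc, np.ones((design.n_scans, 1))]
    names = [str(c) for c in conditions] + ["intercept"]
    if design.nuisance is not None:
        cols.append(design.nuisance)
        names += [f"nuisance_{k}" for k in range(design.nuisance.shape[1])]
    X = np.hstack(cols)
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(design.n_scans - X.shape[1], 1)
    return GLMResult(betas=beta[:len(conditions)], condition_names=conditions,
                     intercept=beta[len(conditions)],
                     residual_var=(resid ** 2).sum(axis=0) / dof,
                     design_matrix=X, column_names=names)


def beta_series(Y: np.ndarray, trial_onsets: pd.DataFrame, tr_s: float,
                n_scans: int, oversample: int = 16,
                nuisance: Optional[np.ndarray] = None) -> np.ndarray:
    """Single-trial amplitudes: one HRF-convolved regressor per trial.

    ``trial_onsets`` columns: onset_s, duration_s (and optionally
    trial_id; trials are returned in table order). Returns an
    (n_trials, V) array of per-trial betas.
    """
    ev = trial_onsets.copy()
    ev["condition"] = [f"trial_{i:03d}" for i in range(len(ev))]
    design = EventDesign(events=ev, tr_s=tr_s, n_scans=n_scans,
                         nuisance=nuisance)
    res = fit_glm(Y, design, oversample=oversample)
    return res.betas


def trend_test(values: np.ndarray):
    """Regress per-trial values on trial index; returns (slope, t, p).

    The habituation/sensitization check: a systematic drift of per-trial
    signature amplitudes shows up as a nonzero slope.
    """
    values = np.asarray(values, dtype=float)
    idx = np.arange(len(values), dtype=float)
    res = stats.linregress(idx, values)
    n = len(values)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return res.slope, float(t), 2.0 * stats.t.sf(abs(t), df=n - 2)


# ---------------------------------------------------------------------------
# Smoothed FIR


@dataclass
class FIRFit:
    """FIR time-course estimate: one beta per post-onset TR."""

    betas: np.ndarray       # (n_points, V)
    intercept: np.ndarray   # (V,)
    tr_s: float
    window_s: float
    lambda_smooth: float

    def signature_timecourse(self, pattern: VoxelPattern) -> np.ndarray:
        """Apply a signature to each timepoint map: (n_points,) responses."""
        if self.betas.shape[1] != pattern.mask.V:
            raise InvalidConfigError("FIR betas do not match pattern mask")
        return self.betas @ pattern.weights


def _second_difference(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i:i + 3] = (1.0, -2.0, 1.0)
    return D


def fit_sfir(Y: np.ndarray, onsets_s: Sequence[float], tr_s: float,
             n_points: int = 25, lambda_smooth="gcv") -> FIRFit:
    """Finite-impulse-response fit with a smoothness penalty.

    One indicator regressor per post-onset TR (window of ``n_points``
    TRs), shared across trials, plus an unpenalized intercept. Betas
    minimize ``||y - Xb||² + λ ||D b||²`` with D the second-difference
    operator (a Gaussian-process–style smoothness prior on adjacent
    timepoints). ``lambda_smooth = 0`` is plain FIR OLS; ``"gcv"``
    selects λ by generalized cross-validation on the data at hand.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    T = Y.shape[0]
    onset_idx = [int(round(o / tr_s)) for o in onsets_s]
    if any(i < 0 for i in onset_idx):
        raise InvalidConfigError("onsets must be non-negative")
    if any(i + n_points > T for i in onset_idx):
        raise InvalidConfigError("FIR window exceeds run length for some onset")
    X = np.zeros((T, n_points + 1))
    X[:, -1] = 1.0
    for i in onset_idx:
        for j in range(n_points):
            X[i + j, j] += 1.0
    D = _second_difference(n_points)
    P = np.zeros((n_points + 1, n_points + 1))
    P[:n_points, :n_points] = D.T @ D
    XtX, XtY = X.T @ X, X.T @ Y

    def solve(lam):
        return np.linalg.solve(XtX + lam * P, XtY)

    if lambda_smooth == "gcv":
        grid = np.concatenate([[0.0], np.logspace(-2, 4, 13)])
        best, best_score = 0.0, np.inf
        for lam in grid:
            H_trace = np.trace(np.linalg.solve(XtX + lam * P, XtX))
            B = solve(lam)
            rss = ((Y - X @ B) ** 2).sum(axis=0).mean()
            denom = (T - H_trace) ** 2
            score = T * rss / denom if denom > 0 else np.inf
            if score < best_score:
                best, best_score = lam, score
        lam = best
    else:
        lam = float(lambda_smooth)
        if lam < 0:
            raise InvalidConfigError("lambda_smooth must be >= 0")
    B = solve(lam)
    return FIRFit(betas=B[:n_points], intercept=B[-1], tr_s=tr_s,
                  window_s=n_points * tr_s, lambda_smooth=lam)
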