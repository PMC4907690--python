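"""Within-subject local sphere decoding.

A local pattern is trained in a small sphere around every center voxel
to predict trial-wise ratings from one modality; held-out-run
correlations map where local information lives (within-modality), and
applying the sphere pattern to the other modality's held-out trials
maps local *shared* information (cross-modality). Inputs should be
unsmoothed trial-level images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import StudyDataset
from .errors import DegenerateDataError, InvalidConfigError
from .imgio import BrainMask
from .signature import VoxelPattern
from .train import TrainerConfig, lasso_pcr_fit

logger = logging.getLogger(__name__)


@dataclass
class SphereSpec:
    """Membership of one searchlight sphere."""

    radius_mm: float
    center: tuple  # (i, j, k) voxel index
    member_voxels: np.ndarray  # positions in mask vector order


@dataclass
class TrialSet:
    """Single-subject trial-level images for one modality."""

    mask: BrainMask
    X: np.ndarray          # (n_trials, V)
    ratings: np.ndarray
    runs: np.ndarray       # run label per trial (fold unit)
    modality: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=float)
        self.runs = np.asarray(self.runs)
        n = self.X.shape[0]
        if self.X.shape[1] != self.mask.V:
            raise InvalidConfigError("X columns must match mask V")
        if self.ratings.shape != (n,) or self.runs.shape != (n,):
            raise InvalidConfigError("ratings/runs must match trial count")
        if np.unique(self.runs).size < 2:
            raise InvalidConfigError("need at least 2 runs for fold exclusion")


def sphere_indices(mask: BrainMask, center, radius_mm: float) -> SphereSpec:
    """In-mask voxels within ``radius_mm`` (world distance) of a center.

    Distances are computed in mm through the affine, so anisotropic
    voxels are handled; voxels at exactly the radius are included.
    Member ordering follows the mask's lexicographic voxel order.
    """
    center = tuple(int(c) for c in center)
    if not mask.include[center]:
        raise InvalidConfigError(f"center {center} is outside the mask")
    if radius_mm < 0:
        raise InvalidConfigError("radius_mm must be >= 0")
    aff = mask.geometry.affine
    xyz = mask.world_coords()
    c_world = (aff @ np.r_[center, 1.0])[:3]
    d = np.linalg.norm(xyz - c_world, axis=1)
    members = np.flatnonzero(d <= radius_mm + 1e-9)
    return SphereSpec(radius_mm=radius_mm, center=center,
                      member_voxels=members)


def _default_fit(config: TrainerConfig):
    def fit(X, y, mask):
        return lasso_pcr_fit(X, y, mask, config)
    return fit


@dataclass
class SearchlightResult:
    """Per-center decoding outcomes over the searched centers."""

    table: pd.DataFrame  # center i/j/k, n_members, r_* columns
    mask: BrainMask
    radius_mm: float

    def r_map(self, column: str) -> np.ndarray:
        """Scatter one r column back into a volume (NaN off-center)."""
        vol = np.full(self.mask.geometry.shape, np.nan)
        idx = self.table[["i", "j", "k"]].to_numpy()
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = self.table[column].to_numpy()
        return vol


def _safe_corr(pred: np.ndarray, actual: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(actual) == 0:
        return np.nan
    return float(np.corrcoef(pred, actual)[0, 1])


def run_searchlight(set_a: TrialSet, set_b: TrialSet,
                    radius_mm: float = 8.0,
                    centers: Optional[Sequence] = None,
                    fit_fn: Optional[Callable] = None,
                    config: TrainerConfig = TrainerConfig(),
                    ) -> SearchlightResult:
    """Sphere-wise within- and cross-modality rating prediction.

    For every center: per left-out run, a local pattern is fit on the
    remaining runs of each modality and used to predict (i) that
    modality's held-out trials (within-modality r, cross-validated) and
    (ii) the other modality's trials from the same held-out run
    (cross-modality r). Spheres where a correlation is undefined (zero
    variance) yield NaN and are logged.

    ``centers`` defaults to every in-mask voxel; pass a subset (list of
    (i,j,k)) to restrict or stride the search.
    """
    mask = set_a.mask
    if set_b.mask is not mask and not (
            mask.geometry.matches(set_b.mask.geometry)
            and np.array_equal(mask.include, set_b.mask.include)):
        raise InvalidConfigError("both trial sets must share one mask")
    runs = np.unique(set_a.runs)
    if not np.array_equal(runs, np.unique(set_b.runs)):
        raise InvalidConfigError("run labels must match across modalities")
    if fit_fn is None:
        fit_fn = _default_fit(config)
    if centers is None:
        centers = [tuple(v) for v in mask.voxel_coords()]

    rows = []
    for center in centers:
        sphere = sphere_indices(mask, center, radius_mm)
        m = sphere.member_voxels
        sub_mask_inc = np.zeros(mask.geometry.shape, dtype=bool)
        sub_mask_inc.ravel(order="C")[mask.indices[m]] = True
        sub_mask = BrainMask(mask.geometry, sub_mask_inc)
        preds = {k: ([], []) for k in
                 ("within_a", "within_b", "cross_ab", "cross_ba")}
        try:
            for run in runs:
                te_a = set_a.runs == run
                te_b = set_b.runs == run
                pat_a = fit_fn(set_a.X[~te_a][:, m], set_a.ratings[~te_a],
                               sub_mask)
                pat_b = fit_fn(set_b.X[~te_b][:, m], set_b.ratings[~te_b],
                               sub_mask)
                pa = set_a.X[te_a][:, m] @ pat_a.weights + pat_a.intercept
                pb = set_b.X[te_b][:, m] @ pat_b.weights + pat_b.intercept
                pab = set_b.X[te_b][:, m] @ pat_a.weights + pat_a.intercept
                pba = set_a.X[te_a][:, m] @ pat_b.weights + pat_b.intercept
                for key, (p, y) in zip(
                        ("within_a", "within_b", "cross_ab", "cross_ba"),
                        ((pa, set_a.ratings[te_a]), (pb, set_b.ratings[te_b]),
                         (pab, set_b.ratings[te_b]), (pba, set_a.ratings[te_a]))):
                    preds[key][0].append(p)
                    preds[key][1].append(y)
            rs = {}
            for key, (p, y) in preds.items():
                rs[key] = _safe_corr(np.concatenate(p), np.concatenate(y))
        except DegenerateDataError:
            logger.warning("sphere at %s has degenerate data; skipped", center)
            rs = {k: np.nan for k in preds}
        if any(np.isnan(v) for v in rs.values()):
            logger.debug("sphere at %s produced undefined correlations", center)
        rows.append({"i": center[0], "j": center[1], "k": center[2],
                     "n_members": m.size,
                     "r_within_a": rs["within_a"], "r_within_b": rs["within_b"],
                     "r_cross_ab": rs["cross_ab"], "r_cross_ba": rs["cross_ba"]})
    return SearchlightResult(table=pd.DataFrame(rows), mask=mask,
                             radius_mm=radius_mm)


def summarize_searchlight(result: SearchlightResult,
                          top_fraction: float = 0.05,
                          n_bins: int = 20) -> dict:
    """Top-fraction masks and histogram tables per outcome map.

    The top set is chosen by value; ties at the cutoff are all included
    and the realized count is reported alongside the nominal one.
    """
    if result.table.empty:
        raise DegenerateDataError("empty searchlight result")
    if not 0 < top_fraction <= 1:
        raise InvalidConfigError("top_fraction must be in (0, 1]")
    out = {}
    for col in ("r_within_a", "r_within_b", "r_cross_ab", "r_cross_ba"):
        vals = result.table[col].to_numpy()
        ok = ~np.isnan(vals)
        if not ok.any():
            out[col] = {"top_mask": np.zeros(len(vals), dtype=bool),
                        "histogram": pd.DataFrame(), "n_top": 0,
                        "n_nominal": 0, "cutoff": np.nan}
            continue
        v = vals[ok]
        n_top = max(1, int(np.floor(top_fraction * v.size)))
        cutoff = np.sort(v)[::-1][n_top - 1]
        top = ok & (vals >= cutoff)
        counts, edges = np.histogram(v, bins=n_bins)
        hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "count": counts})
        out[col] = {"top_mask": top, "histogram": hist,
                    "n_top": int(top.sum()), "n_nominal": n_top,
                    "cutoff": float(cutoff)}
        if top.sum() > n_top:
            logger.info("%s: %d ties at the top-%d cutoff included",
                        col, int(top.sum()) - n_top, n_top)
    return out
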