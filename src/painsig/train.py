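"""Pattern training.

LASSO-PCR — principal-components rotation of the training images
followed by L1-penalized regression on component scores, with the
coefficients back-projected to a voxel weight map — is the workhorse for
rating-predictive signatures. Leave-one-subject-out (LOSO)
cross-validation wraps it so every subject is scored by a pattern that
never saw their data. A linear soft-margin SVM handles the body-site
(somatotopy) classification, and ROI restriction lets every trainer run
on a subregion unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from .datasets import StudyDataset
from .errors import DegenerateDataError, InvalidConfigError
from .imgio import BrainMask
from .signature import VoxelPattern


@dataclass(frozen=True)
class TrainerConfig:
    """Hyperparameters for LASSO-PCR and SVM trainers.

    ``n_components="full"`` keeps every principal component (a lossless
    rotation; the L1 penalty does the selection). ``lasso_lambda``
    is either a fixed penalty (sklearn's ``alpha`` convention,
    ``(1/2n)·RSS + alpha·||b||₁``) or ``"inner_cv"`` to pick it by
    seeded inner k-fold CV over a log-spaced path.
    """

    n_components: Union[str, int] = "full"
    lasso_lambda: Union[str, float] = "inner_cv"
    inner_folds: int = 5
    n_lambdas: int = 30
    standardize: bool = False
    seed: int = 0
    svm_C: float = 1.0

    def __post_init__(self):
        if isinstance(self.n_components, int) and self.n_components < 1:
            raise InvalidConfigError("n_components must be >= 1 or 'full'")
        if isinstance(self.lasso_lambda, (int, float)) and self.lasso_lambda < 0:
            raise InvalidConfigError("lasso_lambda must be >= 0")
        if self.svm_C <= 0:
            raise InvalidConfigError("svm_C must be positive")


def lasso_pcr_fit(X: np.ndarray, ratings: np.ndarray, mask: BrainMask,
                  config: TrainerConfig = TrainerConfig(),
                  name: str = "") -> VoxelPattern:
    """Train a LASSO-PCR pattern predicting ratings from images.

    Returns a VoxelPattern whose prediction for a new image x is
    ``w·x + intercept``. Constant ratings yield the trivial model
    (w = 0, intercept = mean rating).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[1] != mask.V:
        raise InvalidConfigError("X must be (n_images, V) over the mask")
    if X.shape[0] < 3:
        raise DegenerateDataError("need at least 3 training images")
    if X.shape[0] != y.shape[0]:
        raise InvalidConfigError("ratings length must match image count")
    if not np.all(np.isfinite(y)):
        raise InvalidConfigError("ratings must be finite")
    if np.std(y) == 0:
        return VoxelPattern(mask, np.zeros(mask.V), intercept=float(y.mean()),
                            name=name, meta={"trivial": True})
    xbar = X.mean(axis=0)
    Xc = X - xbar
    scale = None
    if config.standardize:
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    if not np.any(Xc):
        raise DegenerateDataError("all training images identical/zero")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max() * max(Xc.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if config.n_components == "full":
        K = rank
    else:
        K = int(config.n_components)
        if K > rank:
            raise InvalidConfigError(
                f"n_components={K} exceeds training-matrix rank {rank}")
    Z = U[:, :K] * S[:K]  # component scores (columns are zero-mean)

    lam = config.lasso_lambda
    if lam == "inner_cv":
        cv = KFold(n_splits=config.inner_folds, shuffle=True,
                   random_state=config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LassoCV(alphas=config.n_lambdas, eps=1e-3, cv=cv,
                            max_iter=5000, tol=1e-4).fit(Z, y)
        coef, b0 = model.coef_, float(model.intercept_)
        chosen = float(model.alpha_)
    elif float(lam) == 0.0:
        coef, *_ = np.linalg.lstsq(Z, y - y.mean(), rcond=None)
        b0 = float(y.mean())
        chosen = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = Lasso(alpha=float(lam), max_iter=10000).fit(Z, y)
        coef, b0 = model.coef_, float(model.intercept_)
        chosen = float(lam)

    w = Vt[:K].T @ coef
    w[np.all(Xc == 0, axis=0)] = 0.0  # uninformative voxels carry no weight
    if scale is not None:
        w = w / scale
    intercept = b0 - float(w @ xbar)
    import hashlib
    train_hash = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()[:16]
    return VoxelPattern(mask, w, intercept=intercept, name=name,
                        meta={"lambda": chosen, "n_components": K,
                              "n_nonzero_components": int(np.sum(coef != 0)),
                              "training_hash": train_hash})


@dataclass
class CVResult:
    """Leave-one-subject-out cross-validation output.

    ``table`` holds, per image of the trained modality, the
    cross-validated prediction (w·x + b) and signature response (w·x)
    from the fold excluding that image's subject.
    """

    table: pd.DataFrame
    fold_patterns: Dict[int, VoxelPattern]
    full_pattern: VoxelPattern
    modality: str

    def crossval_scores(self, dataset: StudyDataset) -> pd.DataFrame:
        """Score arbitrary images with each subject's held-out fold pattern.

        Used for unbiased cross-modality prediction: a subject's images
        (of any modality) are scored only by the pattern trained without
        that subject.
        """
        out = dataset.info.copy()
        resp = np.full(dataset.n_images, np.nan)
        pred = np.full(dataset.n_images, np.nan)
        subj = dataset.info["subject"].to_numpy()
        for s, pat in self.fold_patterns.items():
            rows = np.flatnonzero(subj == s)
            if rows.size:
                r = dataset.X[rows] @ pat.weights
                resp[rows] = r
                pred[rows] = r + pat.intercept
        out["response"] = resp
        out["prediction"] = pred
        return out


def loso_folds(subjects: Sequence[int]):
    """LOSO scheme: singleton held-out sets, each subject tested once."""
    return [(int(s),) for s in np.unique(np.asarray(subjects))]


def loso_crossval(dataset: StudyDataset, modality: str,
                  config: TrainerConfig = TrainerConfig()) -> CVResult:
    """LOSO LASSO-PCR: train on N-1 subjects, score the held-out one."""
    subset = dataset.select(modality=modality)
    all_subjects = dataset.subjects
    have = set(subset.info["subject"].unique())
    missing = [int(s) for s in all_subjects if s not in have]
    if missing:
        raise DegenerateDataError(
            f"subjects with no {modality} images: {missing}")
    if len(all_subjects) < 3:
        raise DegenerateDataError("need at least 3 subjects for LOSO")
    subj = subset.info["subject"].to_numpy()
    table = subset.info.copy()
    table["prediction"] = np.nan
    table["response"] = np.nan
    fold_patterns: Dict[int, VoxelPattern] = {}
    for (s,) in loso_folds(all_subjects):
        train_rows = subj != s
        pat = lasso_pcr_fit(subset.X[train_rows],
                            subset.ratings[train_rows], subset.mask,
                            config, name=f"{modality}_loso_minus_{s}")
        fold_patterns[s] = pat
        test_rows = np.flatnonzero(subj == s)
        r = subset.X[test_rows] @ pat.weights
        table.loc[test_rows, "response"] = r
        table.loc[test_rows, "prediction"] = r + pat.intercept
    full = lasso_pcr_fit(subset.X, subset.ratings, subset.mask, config,
                         name=f"{modality}_full")
    return CVResult(table=table, fold_patterns=fold_patterns,
                    full_pattern=full, modality=modality)


def save_pattern(pattern: VoxelPattern, path) -> None:
    """Write a trained pattern as NIfTI + JSON sidecar.

    The sidecar records the intercept, name, and training metadata
    (penalty, components, training-set hash) next to the weight map.
    """
    import json
    from pathlib import Path

    path = Path(path)
    pattern.to_nifti(path)
    sidecar = {"intercept": pattern.intercept, "name": pattern.name,
               "meta": pattern.meta}
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, default=str) + "\n")


def load_pattern(path, mask=None) -> VoxelPattern:
    """Load a pattern written by :func:`save_pattern` (sidecar optional)."""
    import json
    from pathlib import Path

    path = Path(path)
    pat = VoxelPattern.from_nifti(path, mask=mask)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        pat.intercept = float(info.get("intercept", 0.0))
        pat.name = info.get("name", "")
        pat.meta = info.get("meta", {})
    return pat


# ---------------------------------------------------------------------------
# Linear SVM (somatotopy)


def svm_fit(X: np.ndarray, labels: Sequence, mask: BrainMask,
            config: TrainerConfig = TrainerConfig(),
            name: str = "") -> VoxelPattern:
    """Linear soft-margin SVM; decision value for x is w·x + intercept.

    The positive class is the lexicographically larger label (so for
    sites, "UL" is positive and "LL" negative); sign of the decision
    value predicts the class, with 0 mapped to the negative class.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise DegenerateDataError(
            f"SVM needs exactly 2 classes, got {list(classes)}")
    clf = SVC(kernel="linear", C=config.svm_C, tol=1e-8).fit(X, labels)
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    return VoxelPattern(mask, w, intercept=b, name=name,
                        meta={"positive_class": str(clf.classes_[1]),
                              "negative_class": str(clf.classes_[0]),
                              "svm_C": config.svm_C})


def svm_loso(dataset: StudyDataset, modality: str,
             config: TrainerConfig = TrainerConfig(),
             label_col: str = "site") -> pd.DataFrame:
    """LOSO linear SVM within one modality; returns per-image decision values.

    Each held-out subject's images get the decision value of the SVM
    trained on all other subjects' images of that modality.
    """
    subset = dataset.select(modality=modality)
    subj = subset.info["subject"].to_numpy()
    table = subset.info.copy()
    table["decision"] = np.nan
    for (s,) in loso_folds(subj):
        train = subj != s
        pat = svm_fit(subset.X[train], subset.info.loc[train, label_col],
                      subset.mask, config)
        rows = np.flatnonzero(subj == s)
        table.loc[rows, "decision"] = subset.X[rows] @ pat.weights + pat.intercept
    return table


# ---------------------------------------------------------------------------
# ROI restriction


def roi_restrict(dataset: StudyDataset, roi) -> StudyDataset:
    """Restrict a dataset to the voxels of an ROI.

    ``roi`` may be a BrainMask (same geometry), a boolean grid array, or
    a boolean/index vector over the dataset's in-mask voxels. Trainers
    operate unchanged on the restricted dataset.
    """
    mask = dataset.mask
    if isinstance(roi, BrainMask):
        new_mask = mask.intersect(roi)
        keep_vec = roi.include[mask.include]
    else:
        roi = np.asarray(roi)
        if roi.shape == mask.geometry.shape:
            new_mask = BrainMask(mask.geometry, mask.include & roi.astype(bool))
            keep_vec = roi.astype(bool)[mask.include]
        else:
            keep_vec = np.zeros(mask.V, dtype=bool)
            if roi.dtype == bool:
                if roi.shape != (mask.V,):
                    raise InvalidConfigError("boolean ROI vector length != V")
                keep_vec = roi
            else:
                keep_vec[np.asarray(roi, dtype=int)] = True
            inc = np.zeros(mask.geometry.shape, dtype=bool)
            inc.ravel(order="C")[mask.indices[keep_vec]] = True
            new_mask = BrainMask(mask.geometry, inc)
    if new_mask.V == 0 or not keep_vec.any():
        raise InvalidConfigError("ROI does not intersect the dataset mask")
    return StudyDataset(new_mask, dataset.X[:, keep_vec], dataset.info.copy())


def central_roi(mask: BrainMask, n_voxels: int = 200) -> BrainMask:
    """Deterministic ROI: the n voxels nearest the mask's world centroid."""
    if n_voxels < 1 or n_voxels > mask.V:
        raise InvalidConfigError("n_voxels must be in [1, V]")
    xyz = mask.world_coords()
    d = np.linalg.norm(xyz - xyz.mean(axis=0), axis=1)
    order = np.argsort(d, kind="stable")[:n_voxels]
    inc = np.zeros(mask.geometry.shape, dtype=bool)
    inc.ravel(order="C")[mask.indices[order]] = True
    return BrainMask(mask.geometry, inc)
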