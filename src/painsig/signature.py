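"""Signature application: dot-product responses and pattern similarity.

A *signature* (VoxelPattern) is a fixed map of per-voxel weights w; its
response to an activation image x is the plain dot product s = Σ_v w_v x_v
over the voxels the two masks share. Any trained intercept is carried on
the pattern for prediction but is excluded from the response itself:
responses are compared within subject and condition, where a constant
cancels, and the field defines the signature response as the weighted
average activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import imgio
from .datasets import StudyDataset
from .errors import CoverageError, GeometryError, ZeroVarianceError
from .imgio import ActivationImage, BrainMask

#: minimum fraction of |w| mass the image mask must cover
DEFAULT_MIN_COVERAGE = 0.9


@dataclass
class VoxelPattern:
    """A signature: one real weight per in-mask voxel, optional intercept."""

    mask: BrainMask
    weights: np.ndarray
    intercept: float = 0.0
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.mask.V,):
            raise GeometryError("weights length does not match mask V")
        if not np.all(np.isfinite(w)):
            raise ValueError("pattern weights must be finite")
        self.weights = w

    def predict(self, x: ActivationImage) -> float:
        """Model prediction w·x + intercept (used for rating prediction)."""
        return signature_response(self, x) + self.intercept

    def to_nifti(self, path) -> None:
        imgio.write_volume(imgio.unvectorize(self.weights, self.mask),
                           self.mask.geometry, path)

    @classmethod
    def from_nifti(cls, path, mask: Optional[BrainMask] = None,
                   name: str = "", intercept: float = 0.0) -> "VoxelPattern":
        """Load a weight map; mask defaults to its nonzero support."""
        vol, geom = imgio.read_volume(path)
        if mask is None:
            mask = BrainMask(geom, vol != 0)
        elif not mask.geometry.matches(geom):
            raise GeometryError("supplied mask geometry differs from weight map")
        return cls(mask, vol[mask.include], intercept=intercept, name=name)


def signature_response(pattern: VoxelPattern, image: ActivationImage,
                       min_coverage: float = DEFAULT_MIN_COVERAGE) -> float:
    """Dot product of pattern weights with an image over the mask overlap.

    If the masks differ (same geometry required — no resampling), scoring
    proceeds on the intersection when it covers at least ``min_coverage``
    of the pattern's absolute weight mass, else a CoverageError reports
    the attained coverage.
    """
    pm, im = pattern.mask, image.mask
    if pm is im or (pm.geometry.matches(im.geometry)
                    and np.array_equal(pm.include, im.include)):
        return float(pattern.weights @ image.values)
    if not pm.geometry.matches(im.geometry):
        raise GeometryError("pattern and image geometries differ; "
                            "resampling is never implicit")
    both = pm.include & im.include
    w_vol = imgio.unvectorize(pattern.weights, pm)
    total = np.abs(pattern.weights).sum()
    covered = np.abs(w_vol[both]).sum()
    coverage = 1.0 if total == 0 else covered / total
    if coverage < min_coverage:
        raise CoverageError(coverage, min_coverage)
    x_vol = imgio.unvectorize(image.values, im)
    return float(w_vol[both] @ x_vol[both])


def score_dataset(pattern: VoxelPattern, dataset: StudyDataset,
                  min_coverage: float = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Score every image of a dataset; one response row per image."""
    if (pattern.mask is dataset.mask
            or (pattern.mask.geometry.matches(dataset.mask.geometry)
                and np.array_equal(pattern.mask.include, dataset.mask.include))):
        responses = dataset.X @ pattern.weights
    else:
        responses = np.array([
            signature_response(pattern, img, min_coverage=min_coverage)
            for img in dataset.images()
        ])
    out = dataset.info.copy()
    out["response"] = responses
    return out


def pattern_similarity(w1: VoxelPattern, w2: VoxelPattern) -> float:
    """Pearson correlation of two weight maps over their mask overlap."""
    if w1.mask is w2.mask or (w1.mask.geometry.matches(w2.mask.geometry)
                              and np.array_equal(w1.mask.include,
                                                 w2.mask.include)):
        a, b = w1.weights, w2.weights
    else:
        if not w1.mask.geometry.matches(w2.mask.geometry):
            raise GeometryError("patterns live on different geometries")
        both = w1.mask.include & w2.mask.include
        a = imgio.unvectorize(w1.weights, w1.mask)[both]
        b = imgio.unvectorize(w2.weights, w2.mask)[both]
    if a.size < 3:
        raise GeometryError("need at least 3 shared voxels for similarity")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ZeroVarianceError("pattern weights have zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def flip_lr(pattern: VoxelPattern) -> VoxelPattern:
    """Left-right mirrored pattern: weights and mask flipped identically."""
    w_vol = imgio.unvectorize(pattern.weights, pattern.mask)
    flipped_mask = imgio.flip_lr_mask(pattern.mask)
    flipped_vol = imgio.flip_lr_volume(w_vol)
    return VoxelPattern(flipped_mask, flipped_vol[flipped_mask.include],
                        intercept=pattern.intercept,
                        name=f"{pattern.name}_lrflip" if pattern.name else "")
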