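"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates a 3 (stimulation level) × 2 (body site) × 2
(modality) within-subject design: each subject contributes one contrast
image per cell. An image is built as

    x = a_l · W_modality + site_effect · W_site + o_s · 1 + ε

where ``a_l`` is the level amplitude multiplier, the four ground-truth
patterns (somatic, vicarious, upper limb, lower limb) are smoothed,
Gram-Schmidt-orthogonalized, unit-norm voxel maps, ``o_s`` is a
subject-constant baseline offset, and ε is Gaussian voxel noise smoothed
with the same FWHM as the patterns. Reported intensity is linear in the
level amplitude on a 0-100 scale with additive Gaussian noise.

All randomness flows from one seed through named substreams, so a
config reproduces its dataset bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import imgio
from .datasets import StudyDataset
from .errors import InvalidConfigError
from .firstlevel import EventDesign, build_design_matrix
from .imgio import BrainMask, VolumeGeometry, gaussian_smooth, isotropic_geometry
from .signature import VoxelPattern

MODALITIES = ("somatic", "vicarious")
SITES = ("UL", "LL")

#: rating points per unit of level amplitude (levels 1,2,3 → 20/40/60 mean)
RATING_SLOPE = 20.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the study conditions."""

    grid_shape: Tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 2.0
    n_subjects: int = 28
    levels: Tuple[float, ...] = (1.0, 2.0, 3.0)
    sites: Tuple[str, ...] = SITES
    modalities: Tuple[str, ...] = MODALITIES
    pattern_smoothness_mm: float = 6.0
    noise_sd: float = 0.2
    site_effect: float = 1.0
    subject_offset_sd: float = 0.5
    rating_noise_sd: float = 5.0
    signal_scale: float = 1.0  # 0 → null images (no embedded modality pattern)
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise InvalidConfigError("grid_shape must be 3 positive integers")
        if math.prod(self.grid_shape) < 500:
            raise InvalidConfigError("grid too small (need >= 500 voxels)")
        if self.voxel_size_mm <= 0:
            raise InvalidConfigError("voxel_size_mm must be positive")
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be positive")
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 1 or np.any(np.diff(lv) <= 0):
            raise InvalidConfigError("levels must be strictly increasing")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        for name in ("pattern_smoothness_mm", "site_effect",
                     "subject_offset_sd", "rating_noise_sd", "signal_scale"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")

    def geometry(self) -> VolumeGeometry:
        return isotropic_geometry(self.grid_shape, self.voxel_size_mm)


@dataclass
class GroundTruth:
    """Latent orthonormal patterns a simulated study is built from."""

    mask: BrainMask
    W_som: VoxelPattern
    W_vic: VoxelPattern
    W_UL: VoxelPattern
    W_LL: VoxelPattern

    def modality_pattern(self, modality: str) -> VoxelPattern:
        return {"somatic": self.W_som, "vicarious": self.W_vic}[modality]

    def site_pattern(self, site: str) -> VoxelPattern:
        return {"UL": self.W_UL, "LL": self.W_LL}[site]

    @property
    def patterns(self) -> dict:
        return {"somatic": self.W_som, "vicarious": self.W_vic,
                "UL": self.W_UL, "LL": self.W_LL}


@dataclass
class SynthDataset:
    dataset: StudyDataset
    truth: GroundTruth
    config: SynthConfig


def _streams(config: SynthConfig):
    """Named, independent random substreams derived from the one seed."""
    ss = np.random.SeedSequence(config.seed)
    truth_ss, data_ss, rating_ss = ss.spawn(3)
    return (np.random.default_rng(truth_ss), np.random.default_rng(data_ss),
            np.random.default_rng(rating_ss))


def default_mask(config: SynthConfig) -> BrainMask:
    """Box-interior mask: the grid minus a one-voxel border."""
    inc = np.zeros(config.grid_shape, dtype=bool)
    inc[1:-1, 1:-1, 1:-1] = True
    return BrainMask(config.geometry(), inc)


def _smooth_field(rng, config: SynthConfig, mask: BrainMask) -> np.ndarray:
    vol = rng.standard_normal(config.grid_shape)
    if config.pattern_smoothness_mm > 0:
        vol = gaussian_smooth(vol, config.pattern_smoothness_mm,
                              config.voxel_size_mm)
    return vol[mask.include]


def make_ground_truth(config: SynthConfig) -> GroundTruth:
    """Four smoothed, orthogonalized, unit-norm patterns over the mask."""
    mask = default_mask(config)
    if mask.V < 8:
        raise InvalidConfigError(
            "mask too small to hold 4 orthogonal patterns")
    rng, _, _ = _streams(config)
    raw = [_smooth_field(rng, config, mask) for _ in range(4)]
    basis = []
    for v in raw:
        v = v - v.mean()  # zero-mean, so dot-orthogonality == Pearson r = 0
        for u in basis:
            v = v - (u @ v) * u
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise InvalidConfigError("degenerate ground-truth field")
        basis.append(v / n)
    names = ["truth_somatic", "truth_vicarious", "truth_UL", "truth_LL"]
    pats = [VoxelPattern(mask, w, name=n) for w, n in zip(basis, names)]
    return GroundTruth(mask, *pats)


def simulate_dataset(config: Optional[SynthConfig] = None,
                     **overrides) -> SynthDataset:
    """Generate a full factorial synthetic study.

    Keyword overrides are applied to the default config, e.g.
    ``simulate_dataset(seed=1, noise_sd=0.2)``.
    """
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    truth = make_ground_truth(config)
    mask = truth.mask
    _, rng, rng_rating = _streams(config)
    levels = np.asarray(config.levels, dtype=float)

    rows, images = [], []
    for s in range(1, config.n_subjects + 1):
        o_s = rng.normal(0.0, config.subject_offset_sd) \
            if config.subject_offset_sd > 0 else 0.0
        for modality in config.modalities:
            w_m = truth.modality_pattern(modality).weights
            for l_rank, a_l in enumerate(levels, start=1):
                for site in config.sites:
                    w_b = truth.site_pattern(site).weights
                    eps = _smooth_field(rng, config, mask) * config.noise_sd
                    x = (config.signal_scale * a_l * w_m
                         + config.site_effect * w_b + o_s + eps)
                    rating = float(np.clip(
                        RATING_SLOPE * a_l
                        + rng_rating.normal(0.0, config.rating_noise_sd),
                        0.0, 100.0))
                    images.append(x)
                    rows.append({"subject": s, "modality": modality,
                                 "level": l_rank, "site": site,
                                 "rating": rating, "amplitude": a_l})
    info = pd.DataFrame(rows)
    dataset = StudyDataset(mask, np.vstack(images), info)
    return SynthDataset(dataset=dataset, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Trial-level time series


@dataclass
class TimeseriesSim:
    """Simulated 4D run plus the quantities it was built from."""

    series: np.ndarray           # (nx, ny, nz, T)
    amplitudes: np.ndarray       # true per-trial amplitudes
    onsets: pd.DataFrame
    pattern: VoxelPattern
    tr_s: float

    @property
    def n_scans(self) -> int:
        return self.series.shape[-1]


def simulate_timeseries(config: SynthConfig, onsets: pd.DataFrame,
                        tr_s: float, n_scans: Optional[int] = None,
                        amplitudes: Optional[Sequence[float]] = None,
                        pattern: Optional[VoxelPattern] = None,
                        noise_sd: Optional[float] = None) -> TimeseriesSim:
    """Voxel time series: HRF-convolved boxcars × a spatial pattern + noise.

    ``onsets`` needs columns onset_s and duration_s, one row per trial;
    trials must not overlap at the modeled resolution. Per-trial
    amplitudes default to 1. The spatial carrier defaults to the somatic
    ground-truth pattern; white noise sd defaults to ``config.noise_sd``
    (pass 0 for a noiseless run).
    """
    if tr_s <= 0:
        raise InvalidConfigError("tr_s must be positive")
    onsets = onsets.reset_index(drop=True)
    ends = onsets["onset_s"] + onsets["duration_s"]
    order = np.argsort(onsets["onset_s"].to_numpy())
    on_sorted = onsets["onset_s"].to_numpy()[order]
    end_sorted = ends.to_numpy()[order]
    if np.any(on_sorted[1:] < end_sorted[:-1] - 1e-9):
        raise InvalidConfigError("trial onsets overlap")
    if n_scans is None:
        n_scans = int(np.ceil((end_sorted[-1] + 20.0) / tr_s))
    n_trials = len(onsets)
    amps = np.ones(n_trials) if amplitudes is None \
        else np.asarray(amplitudes, dtype=float)
    if amps.shape != (n_trials,):
        raise InvalidConfigError("amplitudes must match number of trials")
    if pattern is None:
        pattern = make_ground_truth(config).W_som
    noise = config.noise_sd if noise_sd is None else noise_sd

    ev = onsets.copy()
    ev["condition"] = [f"trial_{i:03d}" for i in range(n_trials)]
    design = EventDesign(events=ev, tr_s=tr_s, n_scans=n_scans)
    X, _ = build_design_matrix(design)
    timecourse = X @ amps  # (T,)

    mask = pattern.mask
    _, rng, _ = _streams(config)
    vol_w = np.zeros(mask.geometry.shape)
    vol_w[mask.include] = pattern.weights
    series = np.einsum("t,xyz->xyzt", timecourse, vol_w)
    if noise > 0:
        series = series + rng.normal(
            0.0, noise, size=series.shape)
    return TimeseriesSim(series=series, amplitudes=amps, onsets=onsets,
                         pattern=pattern, tr_s=tr_s)
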