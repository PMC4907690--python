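"""StudyDataset: the multi-subject collection of labeled activation maps.

This is the unit every trainer consumes: subjects × labeled contrast
images × intensity ratings, all sharing one brain mask. Images are kept
as a dense (n_images × V) matrix over the mask, with labels and ratings
in a parallel pandas table (columns: subject, modality, level, site,
rating). Datasets round-trip to a plain directory layout: one NIfTI per
image plus a tab-separated manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import imgio
from .errors import GeometryError, ValidationError
from .imgio import ActivationImage, BrainMask, ConditionLabel

INFO_COLUMNS = ["subject", "modality", "level", "site", "rating"]


@dataclass
class StudyDataset:
    """Labeled activation images over one shared mask.

    Attributes
    ----------
    mask : BrainMask
        Shared analysis mask; every image is vectorized over it.
    X : ndarray, shape (n_images, V)
        Image data, one row per image, columns in mask voxel order.
    info : DataFrame
        One row per image with columns subject, modality, level
        (1 = low … max = high), site, rating.
    """

    mask: BrainMask
    X: np.ndarray
    info: pd.DataFrame

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.mask.V:
            raise GeometryError("X must be (n_images, V) over the dataset mask")
        missing = [c for c in INFO_COLUMNS if c not in self.info.columns]
        if missing:
            raise ValidationError(f"info table missing columns: {missing}")
        if len(self.info) != self.X.shape[0]:
            raise ValidationError("info rows do not match number of images")
        self.info = self.info.reset_index(drop=True)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_images(self) -> int:
        return self.X.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.info["subject"].to_numpy())

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.info["level"].to_numpy())

    @property
    def modalities(self) -> list:
        return sorted(self.info["modality"].unique())

    @property
    def sites(self) -> list:
        return sorted(self.info["site"].unique())

    @property
    def ratings(self) -> np.ndarray:
        return self.info["rating"].to_numpy(dtype=float)

    def select(self, **criteria) -> "StudyDataset":
        """Subset by equality (scalar) or membership (list/tuple/set)."""
        keep = np.ones(len(self.info), dtype=bool)
        for col, val in criteria.items():
            if col not in self.info.columns:
                raise KeyError(col)
            series = self.info[col]
            if isinstance(val, (list, tuple, set, np.ndarray)):
                keep &= series.isin(list(val)).to_numpy()
            else:
                keep &= (series == val).to_numpy()
        return StudyDataset(self.mask, self.X[keep],
                            self.info.loc[keep].reset_index(drop=True))

    def image(self, i: int) -> ActivationImage:
        row = self.info.iloc[i]
        label = ConditionLabel(subject=int(row["subject"]),
                               modality=str(row["modality"]),
                               level=int(row["level"]), site=str(row["site"]))
        return ActivationImage(self.mask, self.X[i], label=label,
                               rating=float(row["rating"]))

    def images(self) -> Iterable[ActivationImage]:
        return (self.image(i) for i in range(self.n_images))

    # -- validation ---------------------------------------------------------

    def validate_design(self, modalities=None, levels=None, sites=None) -> None:
        """Check the full factorial design is present for every subject."""
        modalities = modalities or self.modalities
        levels = levels if levels is not None else self.levels
        sites = sites or self.sites
        missing = []
        grouped = self.info.groupby(["subject", "modality", "level", "site"]).size()
        for s in self.subjects:
            for m in modalities:
                for l in levels:
                    for b in sites:
                        if (s, m, l, b) not in grouped.index:
                            missing.append((int(s), m, int(l), b))
        if missing:
            raise ValidationError(
                f"incomplete design; missing {len(missing)} cells, e.g. "
                f"{missing[:5]}"
            )

    # -- persistence --------------------------------------------------------

    def to_dir(self, out_dir) -> None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        imgio.write_mask(self.mask, out_dir / "mask.nii")
        rows = []
        for i in range(self.n_images):
            row = self.info.iloc[i]
            name = (f"sub-{int(row['subject']):02d}_{row['modality']}"
                    f"_level-{int(row['level'])}_{row['site']}.nii")
            path = out_dir / "images" / name
            imgio.write_volume(imgio.unvectorize(self.X[i], self.mask),
                               self.mask.geometry, path)
            rows.append({**{c: row[c] for c in INFO_COLUMNS},
                         "path": f"images/{name}"})
        pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, in_dir) -> "StudyDataset":
        in_dir = Path(in_dir)
        mask = imgio.read_mask(in_dir / "mask.nii")
        manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
        X = np.empty((len(manifest), mask.V))
        for i, rel in enumerate(manifest["path"]):
            vol, geom = imgio.read_volume(in_dir / rel)
            if not geom.matches(mask.geometry):
                raise GeometryError(f"{rel}: geometry differs from mask")
            X[i] = vol[mask.include]
        return cls(mask, X, manifest[INFO_COLUMNS].copy())
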