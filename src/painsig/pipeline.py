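"""End-to-end orchestration: dataset → machine-readable analysis report.

``run_full_analysis`` composes the whole validation battery on a
StudyDataset: LOSO signature training per modality, within- and
cross-modality forced-choice (the separate-modifiability matrix),
pattern similarity (including the left-right-flipped control), bootstrap
weight-map thresholding, ROI-restricted cross-prediction, and the
upper-vs-lower-limb SVM somatotopy test. Every stochastic step is
seeded from one master seed through named substreams, so the same
dataset + config + seed reproduce a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .datasets import StudyDataset
from .errors import ValidationError
from .imgio import BrainMask
from .inference import (ForcedChoiceResult, bootstrap_lasso_pcr,
                        forced_choice, forced_choice_from_scores, paired_t)
from .signature import VoxelPattern, flip_lr, pattern_similarity, score_dataset
from .train import (TrainerConfig, central_roi, loso_crossval, roi_restrict,
                    svm_loso)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything `run_full_analysis` needs besides the data and seed."""

    trainer: TrainerConfig = TrainerConfig()
    bootstrap_B: int = 200       # study-scale runs use 5000
    fdr_q: float = 0.05
    roi_voxels: int = 200
    run_bootstrap: bool = True
    run_roi: bool = True
    run_svm: bool = True
    run_flipped: bool = True

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _substream_seeds(seed: int, n: int):
    """Fan a master seed into independent 31-bit substream seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _fc_dict(fc: ForcedChoiceResult) -> dict:
    return {"accuracy": round(fc.accuracy, 10), "n_pairs": fc.n_pairs,
            "n_correct": fc.n_correct, "p_value": float(f"{fc.p_value:.6e}"),
            "auc": round(fc.auc, 10)}


def run_full_analysis(dataset: StudyDataset,
                      config: AnalysisConfig = AnalysisConfig(),
                      seed: int = 0,
                      roi: Optional[BrainMask] = None,
                      exclude: Optional[BrainMask] = None) -> dict:
    """Run the full validation battery; returns a JSON-serializable report.

    ``roi`` (default: a central block of ``config.roi_voxels`` voxels)
    bounds the local cross-prediction analysis; ``exclude``, when given,
    additionally retrains each signature with those voxels removed (the
    sensory-confound exclusion control).
    """
    modalities = dataset.modalities
    if len(modalities) != 2:
        raise ValidationError(
            f"full analysis requires exactly 2 modalities, got {modalities}")
    dataset.validate_design()
    train_seed, boot_seed = _substream_seeds(seed, 2)
    trainer = replace(config.trainer, seed=train_seed)

    report: dict = {
        "schema_version": 1,
        "provenance": {
            "seed": seed,
            "config_hash": config.content_hash(),
            "painsig_version": _pkg_version,
            "n_subjects": int(dataset.subjects.size),
            "n_images": dataset.n_images,
            "n_voxels": dataset.mask.V,
        },
        "skipped": {},
    }

    # -- LOSO signature training per modality ------------------------------
    cv = {m: loso_crossval(dataset, m, trainer) for m in modalities}

    fc_matrix = {}
    for trained in modalities:
        for tested in modalities:
            if tested == trained:
                scores = cv[trained].table
            else:
                scores = cv[trained].crossval_scores(
                    dataset.select(modality=tested))
            fc = forced_choice_from_scores(scores)
            fc_matrix[f"{trained}_pattern_on_{tested}"] = _fc_dict(fc)
    report["forced_choice_matrix"] = fc_matrix

    pred_corr = {}
    for m in modalities:
        t = cv[m].table
        pred_corr[m] = round(float(np.corrcoef(
            t["prediction"], t["rating"])[0, 1]), 10)
    report["crossval_prediction_r"] = pred_corr

    # -- pattern similarity (incl. flipped control) -------------------------
    full = {m: cv[m].full_pattern for m in modalities}
    sim = {}
    for i, a in enumerate(modalities):
        for b in modalities[i + 1:]:
            sim[f"{a}_vs_{b}"] = round(pattern_similarity(full[a], full[b]), 10)
    report["pattern_similarity"] = sim

    if config.run_flipped and len(modalities) == 2:
        flipped = {}
        for m in modalities:
            fpat = flip_lr(full[m])
            for tested in modalities:
                scores = score_dataset(fpat, dataset.select(modality=tested))
                fc = forced_choice_from_scores(scores)
                flipped[f"flipped_{m}_pattern_on_{tested}"] = _fc_dict(fc)
            flipped[f"flipped_{m}_self_similarity"] = round(
                pattern_similarity(
                    VoxelPattern(dataset.mask, _embed(fpat, dataset.mask)),
                    full[m]), 10)
        report["flipped_pattern"] = flipped
    elif config.run_flipped:
        report["skipped"]["flipped_pattern"] = "needs exactly 2 modalities"

    # -- bootstrap thresholding --------------------------------------------
    if config.run_bootstrap:
        boot = {}
        for m in modalities:
            sub = dataset.select(modality=m)
            bmap = bootstrap_lasso_pcr(sub, trainer, B=config.bootstrap_B,
                                       q=config.fdr_q, seed=boot_seed)
            boot[m] = {
                "B": bmap.B, "q": bmap.q,
                "n_surviving": int(bmap.surviving.sum()),
                "n_excluded": int(bmap.excluded.sum()),
                "fdr_threshold": float(f"{bmap.fdr_threshold:.6e}"),
            }
        report["bootstrap"] = boot
    else:
        report["skipped"]["bootstrap"] = "disabled in config"

    # -- ROI-restricted training and cross-prediction ----------------------
    if config.run_roi:
        roi_mask = roi if roi is not None else central_roi(
            dataset.mask, config.roi_voxels)
        roi_ds = roi_restrict(dataset, roi_mask)
        roi_cv = {m: loso_crossval(roi_ds, m, trainer) for m in modalities}
        roi_rep = {"n_roi_voxels": roi_ds.mask.V}
        for trained in modalities:
            for tested in modalities:
                if tested == trained:
                    scores = roi_cv[trained].table
                else:
                    scores = roi_cv[trained].crossval_scores(
                        roi_ds.select(modality=tested))
                fc = forced_choice_from_scores(scores)
                roi_rep[f"{trained}_pattern_on_{tested}"] = _fc_dict(fc)
        report["roi_local_patterns"] = roi_rep
    else:
        report["skipped"]["roi_local_patterns"] = "disabled in config"

    # -- exclusion retraining (sensory-confound control) --------------------
    if exclude is not None:
        keep = dataset.mask.include & ~exclude.include
        excl_ds = roi_restrict(dataset, keep)
        excl_rep = {"n_remaining_voxels": excl_ds.mask.V}
        excl_cv = {m: loso_crossval(excl_ds, m, trainer) for m in modalities}
        for trained in modalities:
            for tested in modalities:
                scores = (excl_cv[trained].table if tested == trained else
                          excl_cv[trained].crossval_scores(
                              excl_ds.select(modality=tested)))
                excl_rep[f"{trained}_pattern_on_{tested}"] = _fc_dict(
                    forced_choice_from_scores(scores))
        report["exclusion_retrain"] = excl_rep
    else:
        report["skipped"]["exclusion_retrain"] = "no exclusion mask supplied"

    # -- somatotopy SVM ------------------------------------------------------
    if config.run_svm and set(dataset.sites) == {"LL", "UL"}:
        svm_rep = {}
        for m in modalities:
            table = svm_loso(dataset, m, trainer)
            fc = _site_forced_choice(table)
            svm_rep[f"{m}_UL_vs_LL"] = _fc_dict(fc)
        # cross-modality somatotopy: full-data SVM from one modality applied
        # to the other's images
        from .train import svm_fit
        for trained in modalities:
            sub = dataset.select(modality=trained)
            pat = svm_fit(sub.X, sub.info["site"], dataset.mask, trainer)
            for tested in modalities:
                if tested == trained:
                    continue
                other = dataset.select(modality=tested)
                tbl = other.info.copy()
                tbl["decision"] = other.X @ pat.weights + pat.intercept
                svm_rep[f"{trained}_sites_on_{tested}"] = _fc_dict(
                    _site_forced_choice(tbl))
        report["somatotopy_svm"] = svm_rep
    elif config.run_svm:
        report["skipped"]["somatotopy_svm"] = "sites are not {UL, LL}"
    else:
        report["skipped"]["somatotopy_svm"] = "disabled in config"

    report["skipped"].setdefault(
        "searchlight", "trial-level data required; run searchlight module "
        "directly on per-trial images")
    return report


def _embed(pattern: VoxelPattern, mask: BrainMask) -> np.ndarray:
    """Weights of a pattern re-expressed over a reference mask (0 off-support)."""
    from . import imgio

    vol = imgio.unvectorize(pattern.weights, pattern.mask)
    return vol[mask.include]


def _site_forced_choice(table: pd.DataFrame) -> ForcedChoiceResult:
    """UL-vs-LL forced choice on per-subject mean decision values."""
    per = table.groupby(["subject", "site"])["decision"].mean().unstack("site")
    if per.isna().any().any():
        raise ValidationError("each subject needs both UL and LL images")
    return forced_choice(per["UL"].to_numpy(), per["LL"].to_numpy())


def report_to_json(report: dict, path=None) -> str:
    """Canonical (sorted, fixed-format) JSON; byte-identical across reruns."""
    text = json.dumps(report, sort_keys=True, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Signature application (external weight map → response table)


def apply_signature(pattern: VoxelPattern, dataset: StudyDataset,
                    compare: Optional[Tuple[str, str, str]] = None) -> dict:
    """Score a dataset with a supplied weight map.

    ``compare = (column, cond_a, cond_b)`` additionally runs a
    forced-choice test and paired t between the two conditions
    (``cond_a`` designated the higher-intensity one), on per-subject
    mean responses.
    """
    if dataset.n_images == 0:
        raise ValidationError("no images to score")
    table = score_dataset(pattern, dataset)
    out = {"responses": table}
    if compare is not None:
        col, a_val, b_val = compare
        per = (table[table[col].isin([a_val, b_val])]
               .groupby(["subject", col])["response"].mean().unstack(col))
        if a_val not in per.columns or b_val not in per.columns:
            raise ValidationError(f"conditions {a_val!r}/{b_val!r} not found "
                                  f"in column {col!r}")
        if per.isna().any().any():
            raise ValidationError("comparison requires both conditions for "
                                  "every subject")
        a, b = per[a_val].to_numpy(), per[b_val].to_numpy()
        fc = forced_choice(a, b)
        t, df, p = paired_t(a, b)
        out["forced_choice"] = fc
        out["paired_t"] = {"t": t, "df": df, "p": p}
    return out
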