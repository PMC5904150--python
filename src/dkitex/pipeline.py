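"""End-to-end experiment orchestration.

Feature extraction (MR8 + first-order statistics per subject), the three
texture tests per task (DKI / FLAIR / both modalities), the ANOVA-filtered
first-order experiment, RFE frequency voting with re-evaluation of the
selected biomarkers, and pairwise AUC comparisons — with reproducible
manifests and CSV/JSON reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import (
    VoiMask,
    biomarker_descriptor,
    extract_biomarkers,
    first_order_statistics,
)
from .classification import (
    CvRun,
    SvmConfig,
    anova_filtered_loocv,
    compare_auc_paired,
    nested_loocv,
)
from .dki import ScalarVolume
from .mr8 import Mr8FilterBank, apply_mr8, build_mr8_bank
from .rfe import evaluate_selected, select_by_frequency_voting
from .synthetic import SyntheticCohort

__all__ = [
    "ExperimentConfig",
    "extract_feature_table",
    "run_experiment",
    "run_full_study",
    "write_cohort",
    "load_cohort",
    "save_volume",
    "load_volume",
]

FEATURE_SETS = ("dki", "flair", "both", "selected")


@dataclass
class ExperimentConfig:
    """Configuration of one classification experiment."""

    task: str = "idh"
    feature_set: str = "dki"
    svm: SvmConfig = field(default_factory=SvmConfig)
    selection: list = None  # 0-based columns, required for "selected"
    seed: int = 0

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.feature_set == "selected" and not self.selection:
            raise ValueError("feature_set 'selected' requires a selection")


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O


def save_volume(volume, path, voxel_size=None):
    data = volume.data if isinstance(volume, ScalarVolume) else np.asarray(volume)
    vs = voxel_size or (volume.voxel_size if isinstance(volume, ScalarVolume) else (1, 1, 1))
    affine = np.diag(list(vs) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path, modality="MDK") -> ScalarVolume:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(np.asarray(img.dataobj, dtype=float), voxel_size=vs, modality=modality)


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a synthetic cohort as NIfTI volumes plus a cohort CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, mdk, flair, mask, lab in zip(
        cohort.subject_ids, cohort.mdk_volumes, cohort.flair_volumes, cohort.masks, cohort.labels
    ):
        paths = {
            "mdk_path": out / f"{sid}_mdk.nii.gz",
            "flair_path": out / f"{sid}_flair.nii.gz",
            "mask_path": out / f"{sid}_mask.nii.gz",
        }
        save_volume(mdk, paths["mdk_path"])
        save_volume(flair, paths["flair_path"])
        save_volume(mask.astype(np.float32), paths["mask_path"], voxel_size=cohort.spec.voxel_size)
        rows.append({"subject_id": sid, "label": int(lab), **{k: str(v) for k, v in paths.items()}})
    csv_path = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    (out / "phantom_spec.json").write_text(
        json.dumps({k: _jsonable(v) for k, v in asdict(cohort.spec).items()}, indent=2)
    )
    return csv_path


def load_cohort(csv_path):
    """Load a cohort CSV into per-subject volumes, masks and labels."""
    df = pd.read_csv(csv_path)
    required = {"subject_id", "label", "mdk_path", "flair_path", "mask_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort CSV must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("cohort CSV is empty")
    mdk, flair, masks = [], [], []
    for _, row in df.iterrows():
        for col in ("mdk_path", "flair_path", "mask_path"):
            if not Path(row[col]).exists():
                raise FileNotFoundError(f"{row['subject_id']}: missing {row[col]}")
        mdk.append(load_volume(row["mdk_path"], "MDK"))
        flair.append(load_volume(row["flair_path"], "FLAIR"))
        masks.append(np.asarray(nib.load(str(row["mask_path"])).dataobj) > 0.5)
    return df, mdk, flair, masks, df["label"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# Feature extraction


def _hash_inputs(volumes, masks, bank: Mr8FilterBank, abs_response: bool) -> str:
    h = hashlib.md5()
    for v in volumes:
        h.update(np.ascontiguousarray(v.data).tobytes())
    for m in masks:
        h.update(np.packbits(np.asarray(m, dtype=bool)).tobytes())
    h.update(repr((bank.orientations, bank.scales, bank.sigma_iso, abs_response)).encode())
    return h.hexdigest()


def extract_feature_table(
    cohort: SyntheticCohort = None,
    mdk_volumes=None,
    flair_volumes=None,
    masks=None,
    labels=None,
    subject_ids=None,
    bank: Mr8FilterBank = None,
    abs_response: bool = True,
    cache_dir=None,
) -> pd.DataFrame:
    """Extract the per-subject feature table.

    Columns: ``dki_1..dki_54``, ``flair_1..flair_54`` (the 1-based
    biomarker convention), the six first-order MDK statistics
    ``fo_mean..fo_p95`` plus ``fo_skewness``, and ``label``.  When
    ``cache_dir`` is given, the table is cached to CSV keyed by an MD5
    over volumes, masks and bank parameters.
    """
    if cohort is not None:
        mdk_volumes = cohort.mdk_volumes
        flair_volumes = cohort.flair_volumes
        masks = cohort.masks
        labels = cohort.labels
        subject_ids = cohort.subject_ids
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(labels))]
    bank = bank or build_mr8_bank()

    cache_path = None
    if cache_dir is not None:
        key = _hash_inputs(mdk_volumes + flair_volumes, masks, bank, abs_response)
        cache_path = Path(cache_dir) / f"features_{key}.csv"
        if cache_path.exists():
            return pd.read_csv(cache_path)

    rows = []
    for sid, mdk, flair, mask, lab in zip(subject_ids, mdk_volumes, flair_volumes, masks, labels):
        voi = VoiMask(mask, voxel_size=mdk.voxel_size)
        dki_vec = extract_biomarkers(apply_mr8(mdk, bank, abs_response), voi, modality="DKI")
        flair_vec = extract_biomarkers(apply_mr8(flair, bank, abs_response), voi, modality="FLAIR")
        fo = first_order_statistics(mdk, voi)
        row = {"subject_id": sid, "label": int(lab)}
        row.update({f"dki_{i+1}": v for i, v in enumerate(dki_vec.values)})
        row.update({f"flair_{i+1}": v for i, v in enumerate(flair_vec.values)})
        row.update(
            {
                "fo_mean": fo.mean,
                "fo_median": fo.median,
                "fo_sd": fo.sd,
                "fo_kurtosis": fo.kurtosis,
                "fo_p5": fo.p5,
                "fo_p95": fo.p95,
                "fo_skewness": fo.skewness,
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(cache_path, index=False)
    return table


def feature_matrix(table: pd.DataFrame, feature_set: str):
    """Select the feature columns for a test: 54 (dki/flair) or 108 (both)."""
    dki_cols = [f"dki_{i}" for i in range(1, 55)]
    flair_cols = [f"flair_{i}" for i in range(1, 55)]
    if feature_set == "dki":
        cols = dki_cols
    elif feature_set == "flair":
        cols = flair_cols
    elif feature_set in ("both", "selected"):
        cols = dki_cols + flair_cols
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    return table[cols].to_numpy(dtype=float), cols


def first_order_matrix(table: pd.DataFrame):
    cols = ["fo_mean", "fo_median", "fo_sd", "fo_kurtosis", "fo_p5", "fo_p95"]
    return table[cols].to_numpy(dtype=float), cols


# ---------------------------------------------------------------------------
# Experiments


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    return v


def cv_metrics(run: CvRun) -> dict:
    return {
        "n": run.n_folds,
        "accuracy": run.accuracy,
        "sensitivity": run.sensitivity,
        "specificity": run.specificity,
        "auc": run.auc,
        "confusion": run.confusion.tolist(),
    }


def _write_run(run: CvRun, out_dir: Path, name: str, config_dict: dict):
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = cv_metrics(run)
    (out_dir / f"{name}_metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    pd.DataFrame(
        {
            "subject_id": run.subject_ids,
            "y_true": run.y_true,
            "probability": run.probabilities,
            "decision_value": run.decision_values,
            "predicted": run.predicted,
            "C": [p[0] for p in run.params],
            "gamma": [p[1] for p in run.params],
        }
    ).to_csv(out_dir / f"{name}_predictions.csv", index=False)
    pd.DataFrame(
        {"threshold": run.roc.thresholds, "tpr": run.roc.tpr, "fpr": run.roc.fpr}
    ).to_csv(out_dir / f"{name}_roc.csv", index=False)
    manifest = {
        "name": name,
        "config": {k: _jsonable(v) for k, v in config_dict.items()},
        "config_hash": hashlib.md5(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "version": __version__,
    }
    (out_dir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_experiment(table: pd.DataFrame, config: ExperimentConfig, out_dir=None) -> CvRun:
    """One classification test on an extracted feature table."""
    y = table["label"].to_numpy(dtype=int)
    X, cols = feature_matrix(table, config.feature_set)
    subset = config.selection if config.feature_set == "selected" else None
    run = nested_loocv(
        X, y, config=config.svm, feature_subset=subset, subject_ids=list(table["subject_id"])
    )
    if out_dir is not None:
        name = f"{config.task}_{config.feature_set}"
        cfg = {
            "task": config.task,
            "feature_set": config.feature_set,
            "selection": config.selection,
            "seed": config.seed,
            "c_grid": list(config.svm.c_grid),
            "gamma_grid": list(config.svm.gamma_grid),
        }
        _write_run(run, Path(out_dir), name, cfg)
    return run


def run_full_study(
    table: pd.DataFrame,
    svm_config: SvmConfig = None,
    task: str = "idh",
    n_values=(4, 5, 6),
    out_dir=None,
) -> dict:
    """The full experiment suite on one task.

    Runs the ANOVA-filtered first-order experiment, the three texture
    tests (54 DKI / 54 FLAIR / 108 both), all pairwise AUC comparisons,
    RFE frequency voting on the DKI biomarkers, and the re-evaluation of
    the four selected biomarkers.  Returns a consolidated report dict.
    """
    svm_config = svm_config or SvmConfig()
    y = table["label"].to_numpy(dtype=int)
    if len(table) == 0:
        raise ValueError("empty cohort")

    report = {"task": task, "n_subjects": int(len(table))}

    X_fo, _ = first_order_matrix(table)
    fo_run, fo_selected, fo_consistent = anova_filtered_loocv(X_fo, y, svm_config)
    report["first_order"] = {
        **cv_metrics(fo_run),
        "consistently_selected": sorted(fo_consistent),
    }

    runs = {}
    for fs in ("dki", "flair", "both"):
        X, _ = feature_matrix(table, fs)
        runs[fs] = nested_loocv(X, y, config=svm_config, subject_ids=list(table["subject_id"]))
        report[fs] = cv_metrics(runs[fs])

    report["auc_comparisons"] = {}
    pairs = [("dki", "flair"), ("dki", "both"), ("flair", "both")]
    for a, b in pairs:
        cmp = compare_auc_paired(runs[a].probabilities, runs[b].probabilities, y)
        report["auc_comparisons"][f"{a}_vs_{b}"] = {
            "auc_a": cmp.auc_a,
            "auc_b": cmp.auc_b,
            "p_value": cmp.p_value,
        }

    X_dki, _ = feature_matrix(table, "dki")
    pool = select_by_frequency_voting(X_dki, y, config=svm_config, n_values=n_values)
    selected_biomarkers = [int(f) + 1 for f in pool.final_selection]  # 1-based
    sel_run = evaluate_selected(X_dki, y, config=svm_config, selection=pool.final_selection)
    report["rfe"] = {
        "selected_indices": selected_biomarkers,
        "selected_descriptors": [biomarker_descriptor(i) for i in selected_biomarkers],
        "selection_counts": pool.counts.tolist(),
        "selected_metrics": cv_metrics(sel_run),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{task}_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
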