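"""End-to-end orchestration: phantom → (optional signal fit) → split →
balance → train → evaluate, with per-run directories and a manifest.

A run is driven by a flat configuration dictionary (typically loaded
from YAML/JSON). Every stochastic stage derives its seed from the
single global seed, so a rerun with the same config reproduces every
artifact bit for bit (wall-clock metadata aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from dhikit import __version__
from dhikit.classifier import (
    LABEL_COLUMN,
    TrainConfig,
    predict,
    smote_balance,
    split_dataset,
    train,
)
from dhikit.dbsi_fit import FitConfig, fit_volume
from dhikit.evaluation import evaluate_multiclass
from dhikit.gradients import generate_scheme, load_scheme
from dhikit.phantom import (
    HistologyClass,
    build_signal_phantom,
    default_profiles,
    sample_feature_table,
    well_separated_profiles,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_end_to_end"]

DEFAULT_CONFIG: dict = {
    "mode": "features",            # "features" | "signal"
    "profiles": "default",         # "default" | "separated"
    "n_per_class": 600,
    "seed": 0,
    "ratios": [0.8, 0.1, 0.1],
    "stratified": True,
    "k_neighbors": 5,
    "bootstrap_reps": 10_000,
    "train": {},                   # TrainConfig overrides
    # signal mode only:
    "phantom_shape": [6, 6, 1],
    "snr": 50.0,
    "n_dirs": 99,
    "b_max": 3000.0,
    "dwi": None,                   # optional external NIfTI path
    "bval": None,
    "bvec": None,
}


def _merged(config: dict) -> dict:
    out = {**DEFAULT_CONFIG, **(config or {})}
    out["train"] = {**DEFAULT_CONFIG["train"], **(config.get("train") or {})}
    return out


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field checks; returns findings (empty = valid)."""
    findings: list[str] = []
    cfg = _merged(config)
    if cfg["mode"] not in ("features", "signal"):
        findings.append(f"unknown mode {cfg['mode']!r}")
    if cfg["profiles"] not in ("default", "separated"):
        findings.append(f"unknown profiles {cfg['profiles']!r}")
    ratios = cfg["ratios"]
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        findings.append("ratios must be three positive numbers")
    elif abs(sum(ratios) - 1.0) > 1e-9:
        findings.append("ratios do not sum to 1")
    if cfg["n_per_class"] < 1:
        findings.append("n_per_class must be >= 1")
    if cfg["k_neighbors"] < 1:
        findings.append("k_neighbors must be >= 1")
    if cfg["bootstrap_reps"] < 0:
        findings.append("bootstrap_reps must be >= 0")
    if cfg["mode"] == "signal":
        if cfg["dwi"] is not None:
            for key in ("bval", "bvec"):
                if not cfg[key]:
                    findings.append(f"signal mode with external dwi needs {key} path")
                elif not Path(cfg[key]).exists():
                    findings.append(f"{key} path {cfg[key]!r} not readable")
            if not Path(cfg["dwi"]).exists():
                findings.append(f"dwi path {cfg['dwi']!r} not readable")
        if cfg["snr"] is not None and cfg["snr"] <= 0:
            findings.append("snr must be positive (or null for noiseless)")
    try:
        TrainConfig(**cfg["train"])
    except (TypeError, ValueError) as exc:
        findings.append(f"train config: {exc}")
    return findings


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_table(table: pd.DataFrame) -> str:
    return hashlib.sha256(
        table.round(12).to_csv(index=False).encode()).hexdigest()


def run_end_to_end(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured pipeline, persisting intermediate
    artifacts, and return the evaluation report as a dictionary.

    The run directory receives a frozen copy of the config, the feature
    table, the split row ids, the evaluation report and a manifest with
    config hash, seeds and artifact hashes. Any stage error aborts with
    the stage name; artifacts from completed stages remain on disk.
    """
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    manifest: dict = {
        "config_hash": _hash_obj(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "artifacts": {},
    }
    stage = "init"
    try:
        stage = "profiles"
        profiles = (well_separated_profiles() if cfg["profiles"] == "separated"
                    else default_profiles())
        manifest["stages"].append(stage)

        stage = "features"
        if cfg["mode"] == "signal":
            table = _signal_mode_features(cfg, profiles, out, manifest)
        else:
            table = sample_feature_table(
                cfg["n_per_class"], profiles, seed=cfg["seed"])
        table.to_csv(out / "features.tsv", sep="\t", index=False)
        manifest["artifacts"]["features"] = _hash_table(table)
        manifest["stages"].append(stage)

        stage = "split"
        train_t, val_t, test_t = split_dataset(
            table, tuple(cfg["ratios"]), seed=cfg["seed"] + 1,
            stratified=cfg["stratified"])
        split_ids = {
            "train": train_t.index.tolist(),
            "val": val_t.index.tolist(),
            "test": test_t.index.tolist(),
        }
        (out / "split.json").write_text(json.dumps(split_ids))
        manifest["stages"].append(stage)

        stage = "balance"
        balanced = smote_balance(train_t, k_neighbors=cfg["k_neighbors"],
                                 seed=cfg["seed"] + 2)
        manifest["artifacts"]["balanced_train"] = _hash_table(balanced)
        manifest["stages"].append(stage)

        stage = "train"
        tc = TrainConfig(**{"seed": cfg["seed"] + 3, **cfg["train"]})
        model = train(balanced, val_t, tc)
        manifest["artifacts"]["final_val_loss"] = min(model.history["val_loss"])
        manifest["stages"].append(stage)

        stage = "evaluate"
        proba, labels = predict(model, test_t)
        report = evaluate_multiclass(
            test_t[LABEL_COLUMN].to_numpy(), proba,
            class_order=model.class_order, predicted_labels=labels,
            bootstrap_reps=cfg["bootstrap_reps"], seed=cfg["seed"] + 4)
        report_dict = report.to_dict()
        (out / "report.json").write_text(json.dumps(report_dict, indent=2))
        manifest["stages"].append(stage)
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.exception("pipeline aborted in stage %r", stage)
        raise
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report_dict


def _signal_mode_features(cfg, profiles, out: Path, manifest) -> pd.DataFrame:
    """Signal-level route: phantom DWI → voxel-wise fit → feature table."""
    from dhikit.dbsi_fit import AUX_METRICS, METRICS

    if cfg["dwi"] is not None:
        import nibabel as nib

        scheme = load_scheme(cfg["bval"], cfg["bvec"])
        dwi = np.asarray(nib.load(cfg["dwi"]).dataobj, dtype=float)
        labels = None
    else:
        scheme = generate_scheme(cfg["n_dirs"], cfg["b_max"], n_b0=1,
                                 seed=cfg["seed"])
        rng = np.random.default_rng(cfg["seed"] + 10)
        shape = tuple(cfg["phantom_shape"])
        label_map = rng.integers(0, len(HistologyClass), size=shape)
        dwi, truth = build_signal_phantom(
            label_map, profiles, scheme, snr=cfg["snr"], seed=cfg["seed"] + 11)
        labels = truth.labels
    maps = fit_volume(dwi, scheme, config=FitConfig())
    rows = []
    names = METRICS + AUX_METRICS
    for idx in np.ndindex(dwi.shape[:3]):
        row = {name: maps[name][idx] for name in names}
        if labels is not None:
            row[LABEL_COLUMN] = int(labels[idx])
        rows.append(row)
    table = pd.DataFrame(rows).dropna()
    table.insert(0, "voxel_id", np.arange(len(table)))
    manifest["artifacts"]["scheme_max_b"] = scheme.max_b
    return table.reset_index(drop=True)
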