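"""End-to-end orchestration: generate -> train inverse -> train
classifier -> report.

Two named presets: ``full`` pins the full-scale study settings
(cohort of 4137 healthy + 1958/1164/1400 AAA patients, 1400-epoch
inverse training) and ``desk`` a small deterministic configuration that
runs on a laptop.  Every stage derives its seed from the master seed by
a fixed counter scheme and writes its artifacts plus a manifest entry
under the run directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .classifier import (ClassifierConfig, TrainedClassifier,
                         evaluate_classifier, train_classifier_cv)
from .database import (WaveformDataset, generate_database, load_database,
                       save_database)
from .inverse import (InverseModelConfig, TrainedInverse, evaluate_inverse,
                      predict_waveforms, train_inverse)
from .network import load_default_network, load_network
from .solver import SolverConfig
from .waveforms import harmonic_energy_fraction

STAGE_INDEX = {"generate": 1, "inverse": 2, "classifier": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed (kept below 2^31)."""
    return (master_seed * 1009 + 7919 * STAGE_INDEX[stage]) % (2 ** 31)


@dataclass
class PipelineConfig:
    preset: str = "desk"
    master_seed: int = 0
    outdir: str = "runs/desk"
    network_path: str | None = None
    n_healthy: int = 18
    n_small: int = 14
    n_medium: int = 14
    n_large: int = 14
    n_samples: int = 200
    critical_fraction: float = 0.25
    periodicity_tol_mmhg: float = 0.2
    inverse: InverseModelConfig = field(default_factory=InverseModelConfig.desk)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig.desk)

    @classmethod
    def full(cls, master_seed: int = 0, outdir: str = "runs/full"):
        return cls(preset="full", master_seed=master_seed, outdir=outdir,
                   n_healthy=4137, n_small=1958, n_medium=1164, n_large=1400,
                   periodicity_tol_mmhg=0.1,
                   inverse=InverseModelConfig(),
                   classifier=ClassifierConfig())

    @classmethod
    def desk(cls, master_seed: int = 0, outdir: str = "runs/desk"):
        return cls(preset="desk", master_seed=master_seed, outdir=outdir)

    def base_network(self):
        if self.network_path:
            return load_network(self.network_path)
        return load_default_network()

    def to_dict(self) -> dict:
        return asdict(self)


def _update_manifest(outdir: Path, stage: str, payload: dict) -> None:
    path = outdir / "run_manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    payload = dict(payload)
    payload["completed_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest[stage] = payload
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(manifest, indent=1))
    tmp.replace(path)


def cmd_generate(config: PipelineConfig, progress: bool = False):
    """Simulate the cohort and write the database files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.master_seed, "generate")
    ds, manifest = generate_database(
        config.n_healthy,
        {"small": config.n_small, "medium": config.n_medium,
         "large": config.n_large},
        seed=seed, base_net=config.base_network(),
        solver_config=SolverConfig(
            periodicity_tol_mmhg=config.periodicity_tol_mmhg),
        n_samples=config.n_samples,
        critical_fraction=config.critical_fraction, progress=progress)
    save_database(ds, manifest, outdir / "database")
    _update_manifest(outdir, "generate", {
        "seed": seed, "n_patients": len(ds),
        "counts": ds.class_counts(),
        "rejections": len(manifest["rejections"]),
        "config_hash": manifest["config_hash"]})
    return ds, manifest


def cmd_train_inverse(config: PipelineConfig,
                      ds: WaveformDataset | None = None) -> TrainedInverse:
    """Fit the LSTM inverse model and write its evaluation report."""
    outdir = Path(config.outdir)
    if ds is None:
        ds, _ = load_database(outdir / "database")
    inv_cfg = config.inverse
    inv_cfg.seed = stage_seed(config.master_seed, "inverse")
    trained = train_inverse(ds, inv_cfg)
    reports = []
    summary = {}
    for split in ("train", "test"):
        rep, mn = evaluate_inverse(trained, ds, split)
        reports.append(rep)
        summary[f"min_site_accuracy_{split}_pct"] = mn
    import pandas as pd
    report = pd.concat(reports, ignore_index=True)
    report.to_csv(outdir / "inverse_report.csv", index=False)
    np.savez(outdir / "inverse_weights.npz",
             *[p for p in trained.model.params])
    _update_manifest(outdir, "inverse", {
        "seed": inv_cfg.seed, "epochs": inv_cfg.epochs,
        "final_loss": trained.history["loss"][-1], **summary})
    return trained


def cmd_train_classifier(config: PipelineConfig,
                         ds: WaveformDataset | None = None,
                         trained_inverse: TrainedInverse | None = None,
                         use_ground_truth: bool = False):
    """Train the CNN on the (inversely reconstructed) abdominal cycle.

    ``use_ground_truth=True`` is the ablation that trains on the
    simulator's own abdominal waveform instead of the inverse model's
    reconstruction; the report is labelled accordingly.
    """
    outdir = Path(config.outdir)
    if ds is None:
        ds, _ = load_database(outdir / "database")
    abd = list(ds.target_sites).index("abdominal_aorta")
    if use_ground_truth:
        cycles = ds.Y[:, :, abd]
        if trained_inverse is None:
            train_idx, test_idx = _default_split(config, ds)
        else:
            train_idx, test_idx = (trained_inverse.train_idx,
                                   trained_inverse.test_idx)
    else:
        if trained_inverse is None:
            raise ValueError("classifier needs the trained inverse model "
                             "(or use_ground_truth=True)")
        cycles = predict_waveforms(trained_inverse, ds.X)[:, :, abd]
        train_idx, test_idx = (trained_inverse.train_idx,
                               trained_inverse.test_idx)

    cls_cfg = config.classifier
    cls_cfg.seed = stage_seed(config.master_seed, "classifier")
    trained = train_classifier_cv(cycles[train_idx], ds.labels[train_idx],
                                  cls_cfg)
    results = {"ablation_ground_truth_input": bool(use_ground_truth),
               "cv_accuracy_pct": trained.cv_accuracy_pct,
               "fold_accuracies": trained.fold_accuracies}
    for split, idx in (("train", train_idx), ("test", test_idx),
                       ("all", np.arange(len(ds)))):
        conf, sev, det = evaluate_classifier(trained, cycles[idx],
                                             ds.labels[idx])
        results[f"severity_accuracy_{split}_pct"] = sev
        results[f"detection_accuracy_{split}_pct"] = det
        if split in ("test", "all"):
            np.savetxt(outdir / f"confusion_{split}.csv", conf,
                       fmt="%d", delimiter=",")
    (outdir / "classifier_report.json").write_text(
        json.dumps(results, indent=1))
    _update_manifest(outdir, "classifier", {
        "seed": cls_cfg.seed, **{k: v for k, v in results.items()
                                 if not isinstance(v, list)}})
    return trained, results


def _default_split(config: PipelineConfig, ds: WaveformDataset):
    from .inverse import split_by_patient
    return split_by_patient(len(ds), 0.8,
                            stage_seed(config.master_seed, "inverse"))


def cmd_report(outdir: str | Path) -> dict:
    """Consolidated headline metrics for a completed run; lists any
    missing stages instead of failing."""
    outdir = Path(outdir)
    path = outdir / "run_manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    missing = [s for s in STAGE_INDEX if s not in manifest]
    report = {"missing_stages": missing}
    if "inverse" in manifest:
        report["min_site_accuracy_train_pct"] = \
            manifest["inverse"]["min_site_accuracy_train_pct"]
        report["min_site_accuracy_test_pct"] = \
            manifest["inverse"]["min_site_accuracy_test_pct"]
    if "classifier" in manifest:
        for key in ("severity_accuracy_test_pct", "detection_accuracy_test_pct",
                    "severity_accuracy_all_pct", "detection_accuracy_all_pct",
                    "cv_accuracy_pct"):
            report[key] = manifest["classifier"][key]
    db = outdir / "database.h5"
    if db.exists():
        ds, _ = load_database(outdir / "database")
        healthy = np.flatnonzero(ds.labels == 0)
        if healthy.size:
            root = list(ds.target_sites).index("aortic_root")
            report["harmonic_energy_fraction_5"] = harmonic_energy_fraction(
                ds.Y[healthy[0], :, root], 5)
    (outdir / "summary_report.json").write_text(json.dumps(report, indent=1))
    return report


def run_pipeline(config: PipelineConfig, progress: bool = False) -> dict:
    """Run all stages in order and return the consolidated report."""
    ds, _ = cmd_generate(config, progress=progress)
    trained_inv = cmd_train_inverse(config, ds)
    cmd_train_classifier(config, ds, trained_inv)
    return cmd_report(config.outdir)
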