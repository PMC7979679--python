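"""Virtual-patient waveform database: generation, container and I/O.

The database stores, per patient, one fixed-length pressure cycle at
the three peripheral input sites (carotid, brachial, femoral) and at
the hidden target sites, plus the severity label, abdominal diameter
and profile.  Storage is HDF5 for the arrays, a JSON manifest for
provenance (profiles, aneurysm specs, rejections, seed) and a CSV
cohort summary.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .aneurysm import SeverityClass
from .network import NetworkTopology, load_default_network
from .patients import (CalibrationError, GenerationError, SamplerRanges,
                       VirtualPatient, build_patient, sample_profile)
from .solver import INPUT_SITES, TARGET_SITES, SolverConfig, \
    SolverDivergenceError
from .waveforms import DEFAULT_SAMPLES_PER_CYCLE

CLASS_NAMES = tuple(c.value for c in SeverityClass)


@dataclass
class WaveformDataset:
    """Fixed-length cycles for learning, one row per patient.

    ``X`` has shape (n, N, 3) — input sites in ``input_sites`` order —
    and ``Y`` shape (n, N, M) for the target sites; both in mmHg.
    """

    X: np.ndarray
    Y: np.ndarray
    labels: np.ndarray                  # class indices into CLASS_NAMES
    diameters_cm: np.ndarray
    pwv_m_s: np.ndarray
    periods_s: np.ndarray
    patient_ids: list[str]
    input_sites: tuple[str, ...] = INPUT_SITES
    target_sites: tuple[str, ...] = TARGET_SITES
    profiles: pd.DataFrame | None = None

    def __post_init__(self):
        n = self.X.shape[0]
        if not (self.Y.shape[0] == self.labels.shape[0] == n
                == len(self.patient_ids)):
            raise ValueError("inconsistent dataset row counts")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == i))
                for i, name in enumerate(CLASS_NAMES)}

    def subset(self, idx) -> "WaveformDataset":
        idx = np.asarray(idx)
        return WaveformDataset(
            X=self.X[idx], Y=self.Y[idx], labels=self.labels[idx],
            diameters_cm=self.diameters_cm[idx], pwv_m_s=self.pwv_m_s[idx],
            periods_s=self.periods_s[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            input_sites=self.input_sites, target_sites=self.target_sites,
            profiles=(self.profiles.iloc[idx].reset_index(drop=True)
                      if self.profiles is not None else None))


def _dataset_from_patients(patients: list[VirtualPatient],
                           n_samples: int) -> WaveformDataset:
    n = len(patients)
    X = np.zeros((n, n_samples, len(INPUT_SITES)), dtype=np.float64)
    Y = np.zeros((n, n_samples, len(TARGET_SITES)), dtype=np.float64)
    labels = np.zeros(n, dtype=np.int64)
    diam = np.zeros(n)
    pwv = np.zeros(n)
    periods = np.zeros(n)
    rows = []
    for i, p in enumerate(patients):
        for j, site in enumerate(INPUT_SITES):
            X[i, :, j] = p.cycles[site].pressure_mmhg
        for j, site in enumerate(TARGET_SITES):
            Y[i, :, j] = p.cycles[site].pressure_mmhg
        labels[i] = p.label.index
        diam[i] = p.abdominal_diameter_cm
        pwv[i] = p.pwv_m_s
        periods[i] = p.cycles[INPUT_SITES[0]].period
        rows.append(p.profile.to_dict())
    return WaveformDataset(
        X=X, Y=Y, labels=labels, diameters_cm=diam, pwv_m_s=pwv,
        periods_s=periods, patient_ids=[p.patient_id for p in patients],
        profiles=pd.DataFrame(rows))


def generate_database(n_healthy: int,
                      n_aaa_per_class: dict[str, int] | int,
                      seed: int,
                      base_net: NetworkTopology | None = None,
                      ranges: SamplerRanges | None = None,
                      solver_config: SolverConfig | None = None,
                      n_samples: int = DEFAULT_SAMPLES_PER_CYCLE,
                      critical_fraction: float = 0.25,
                      max_attempts: int = 8,
                      progress: bool = False):
    """Simulate a cohort to periodicity and assemble the dataset.

    ``n_aaa_per_class`` is either one count applied to each of
    small/medium/large or an explicit mapping.  Rejected patients
    (failed calibration, divergence, screening) are redrawn up to
    ``max_attempts`` times and logged in the manifest.  The numeric
    content is fully determined by ``(seed, configuration)``.
    """
    if base_net is None:
        base_net = load_default_network()
    if isinstance(n_aaa_per_class, int):
        n_aaa_per_class = {"small": n_aaa_per_class,
                           "medium": n_aaa_per_class,
                           "large": n_aaa_per_class}
    rng = np.random.default_rng(seed)
    plan: list[SeverityClass] = [SeverityClass.healthy] * n_healthy
    for name in ("small", "medium", "large"):
        plan += [SeverityClass(name)] * int(n_aaa_per_class.get(name, 0))

    patients: list[VirtualPatient] = []
    rejections: list[dict] = []
    for i, severity in enumerate(plan):
        pid = f"vp{i:05d}"
        built = None
        for attempt in range(max_attempts):
            profile = sample_profile(rng, ranges)
            try:
                built = build_patient(
                    profile, base_net, severity, rng,
                    solver_config=solver_config, n_samples=n_samples,
                    patient_id=pid, critical_fraction=critical_fraction)
                break
            except (GenerationError, CalibrationError,
                    SolverDivergenceError) as exc:
                rejections.append({"patient_id": pid, "attempt": attempt,
                                   "severity": severity.value,
                                   "reason": f"{type(exc).__name__}: {exc}"})
        if built is None:
            rejections.append({"patient_id": pid, "attempt": max_attempts,
                               "severity": severity.value,
                               "reason": "exhausted attempts; patient dropped"})
            continue
        patients.append(built)
        if progress:
            print(f"  [{len(patients)}/{len(plan)}] {pid} {severity.value}")

    ds = _dataset_from_patients(patients, n_samples)
    aaa_d = ds.diameters_cm[ds.labels > 0]
    wanted = np.round(np.arange(3.0, 6.95, 0.1), 1)
    present = set(np.round(aaa_d, 1))
    missing = [float(d) for d in wanted if d not in present]
    manifest = {
        "seed": seed,
        "n_samples": n_samples,
        "counts_requested": {"healthy": n_healthy, **n_aaa_per_class},
        "counts_generated": ds.class_counts(),
        "critical_fraction": critical_fraction,
        "input_sites": list(INPUT_SITES),
        "target_sites": list(TARGET_SITES),
        "rejections": rejections,
        "diameter_decimal_coverage": {
            "complete": len(missing) == 0, "missing": missing},
        "patients": [{
            "patient_id": p.patient_id,
            "label": p.label.value,
            "diameter_cm": p.abdominal_diameter_cm,
            "pwv_m_s": p.pwv_m_s,
            "converged": p.converged,
            "profile": p.profile.to_dict(),
            "aneurysm": p.aneurysm.to_dict() if p.aneurysm else None,
        } for p in patients],
    }
    manifest["config_hash"] = hashlib.sha256(json.dumps(
        {k: manifest[k] for k in ("seed", "n_samples", "counts_requested",
                                  "critical_fraction")},
        sort_keys=True).encode()).hexdigest()[:16]
    return ds, manifest


def save_database(ds: WaveformDataset, manifest: dict,
                  path: str | Path) -> None:
    """Write ``<path>.h5``, ``<path>.manifest.json`` and
    ``<path>.summary.csv``."""
    path = Path(path)
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        f.create_dataset("X", data=ds.X)
        f.create_dataset("Y", data=ds.Y)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("diameters_cm", data=ds.diameters_cm)
        f.create_dataset("pwv_m_s", data=ds.pwv_m_s)
        f.create_dataset("periods_s", data=ds.periods_s)
        f.create_dataset("patient_ids",
                         data=np.array(ds.patient_ids, dtype="S16"))
        f.attrs["input_sites"] = ",".join(ds.input_sites)
        f.attrs["target_sites"] = ",".join(ds.target_sites)
    path.with_suffix(".manifest.json").write_text(
        json.dumps(manifest, indent=1))
    summary_table(ds).to_csv(path.with_suffix(".summary.csv"))


def load_database(path: str | Path):
    path = Path(path)
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        ds = WaveformDataset(
            X=f["X"][:], Y=f["Y"][:], labels=f["labels"][:],
            diameters_cm=f["diameters_cm"][:], pwv_m_s=f["pwv_m_s"][:],
            periods_s=f["periods_s"][:],
            patient_ids=[s.decode() for s in f["patient_ids"][:]],
            input_sites=tuple(f.attrs["input_sites"].split(",")),
            target_sites=tuple(f.attrs["target_sites"].split(",")))
    manifest = json.loads(path.with_suffix(".manifest.json").read_text())
    ds.profiles = pd.DataFrame([p["profile"] for p in manifest["patients"]])
    return ds, manifest


def summary_table(ds: WaveformDataset) -> pd.DataFrame:
    """Cohort characteristics per severity class (Table-style means)."""
    if ds.profiles is None or len(ds) == 0:
        return pd.DataFrame()
    df = ds.profiles.copy()
    df["label"] = [CLASS_NAMES[i] for i in ds.labels]
    df["pwv_m_s"] = ds.pwv_m_s
    df["diameter_cm"] = ds.diameters_cm
    cols = ["age_years", "weight_kg", "height_cm", "ejection_fraction",
            "cardiac_output_l_min", "pulse_pressure_mmhg", "pwv_m_s",
            "diameter_cm"]
    return df.groupby("label")[cols].agg(["mean", "min", "max"])
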