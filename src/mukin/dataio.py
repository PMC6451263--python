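"""Session persistence: read/write and validate the on-disk artifacts.

Layout of a session directory:

* ``emg.dat``       raw EMG, little-endian float32, channel-major
* ``emg_header.txt`` sidecar: n_channels, n_samples, sample_rate, grid shape
* ``spikes.csv``    ``unit_id,sample_index`` (0-based)
* ``kinematics.csv`` ``sample_index,dof1_deg,dof2_deg,dof3_deg``
* ``segmentation.csv`` trial/ramp spans
* ``manifest.json`` seeds, config hash, provenance, file inventory

CSV files use a decimal point and comma separator with mandatory headers;
all sample indexing is 0-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorruptSessionError, InvalidInputError
from .types import (
    SEGMENTATION_COLUMNS,
    EMGRecording,
    KinematicsTrace,
    SpikeTrainSet,
    TrialSegmentation,
)

_HEADER_KEYS = ("n_channels", "n_samples", "sample_rate", "grid_rows", "grid_cols")


def write_session(
    path: str | Path,
    emg: EMGRecording,
    spikes: SpikeTrainSet,
    kinematics: KinematicsTrace,
    segmentation: TrialSegmentation,
    seeds: dict | None = None,
    extra_spikes: dict[str, SpikeTrainSet] | None = None,
) -> Path:
    """Write a session directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    raw = np.ascontiguousarray(emg.samples, dtype="<f4")
    (path / "emg.dat").write_bytes(raw.tobytes())
    header = {
        "n_channels": emg.n_channels,
        "n_samples": emg.n_samples,
        "sample_rate": emg.sample_rate,
        "grid_rows": emg.grid_shape[0],
        "grid_cols": emg.grid_shape[1],
    }
    (path / "emg_header.txt").write_text(
        "".join(f"{k}={header[k]}\n" for k in _HEADER_KEYS)
    )

    _write_spikes(path / "spikes.csv", spikes)
    for name, extra in (extra_spikes or {}).items():
        _write_spikes(path / f"spikes_{name}.csv", extra)

    kin = pd.DataFrame(
        {
            "sample_index": np.arange(kinematics.n_samples),
            "dof1_deg": kinematics.angles[0],
            "dof2_deg": kinematics.angles[1],
            "dof3_deg": kinematics.angles[2],
        }
    )
    kin.to_csv(path / "kinematics.csv", index=False)
    segmentation.records.to_csv(path / "segmentation.csv", index=False)

    manifest = {
        "format": "mukin-session-v1",
        "seeds": seeds or {},
        "spike_provenance": spikes.provenance,
        "kinematics_sample_rate": kinematics.sample_rate,
        "files": sorted(p.name for p in path.iterdir() if p.name != "manifest.json"),
        "emg_sha256": hashlib.sha256(raw.tobytes()).hexdigest(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def _write_spikes(file: Path, spikes: SpikeTrainSet) -> None:
    rows = [
        {"unit_id": uid, "sample_index": int(s)}
        for uid in spikes.unit_ids
        for s in spikes.trains[uid]
    ]
    pd.DataFrame(rows, columns=["unit_id", "sample_index"]).to_csv(file, index=False)


def read_session(
    path: str | Path,
) -> tuple[EMGRecording, SpikeTrainSet, KinematicsTrace, TrialSegmentation]:
    """Read and validate a session directory (lossless round-trip)."""
    path = Path(path)
    if not path.is_dir():
        raise CorruptSessionError(f"session directory not found: {path}")
    for name in ("manifest.json", "emg.dat", "emg_header.txt", "spikes.csv",
                 "kinematics.csv", "segmentation.csv"):
        if not (path / name).exists():
            raise CorruptSessionError(f"missing session file: {name}")

    manifest = json.loads((path / "manifest.json").read_text())

    header: dict[str, float] = {}
    for line in (path / "emg_header.txt").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            header[k.strip()] = float(v)
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise CorruptSessionError(f"EMG header missing keys: {missing}")
    n_channels = int(header["n_channels"])
    n_samples = int(header["n_samples"])

    raw = np.frombuffer((path / "emg.dat").read_bytes(), dtype="<f4")
    if raw.size != n_channels * n_samples:
        raise CorruptSessionError(
            f"EMG file holds {raw.size} samples, header promises {n_channels * n_samples}"
        )
    emg = EMGRecording(
        samples=raw.reshape(n_channels, n_samples).copy(),
        sample_rate=header["sample_rate"],
        grid_shape=(int(header["grid_rows"]), int(header["grid_cols"])),
    )

    sp = pd.read_csv(path / "spikes.csv")
    if list(sp.columns) != ["unit_id", "sample_index"]:
        raise CorruptSessionError("spikes.csv must have columns unit_id,sample_index")
    trains = {
        int(uid): np.sort(g["sample_index"].to_numpy(dtype=np.int64))
        for uid, g in sp.groupby("unit_id")
    }
    spikes = SpikeTrainSet(trains, provenance=manifest.get("spike_provenance", "external"))

    kin = pd.read_csv(path / "kinematics.csv")
    dof_cols = [c for c in kin.columns if c.endswith("_deg")]
    if len(dof_cols) != 3:
        raise CorruptSessionError(
            f"kinematics.csv must carry exactly 3 DoF columns, found {len(dof_cols)}"
        )
    kinematics = KinematicsTrace(
        angles=kin[dof_cols].to_numpy().T,
        sample_rate=float(manifest.get("kinematics_sample_rate", header["sample_rate"])),
    )

    seg = pd.read_csv(path / "segmentation.csv")
    if list(seg.columns) != SEGMENTATION_COLUMNS:
        raise CorruptSessionError("segmentation.csv has unexpected columns")
    segmentation = TrialSegmentation(seg)
    return emg, spikes, kinematics, segmentation


def validate_alignment(
    emg: EMGRecording, kinematics: KinematicsTrace
) -> tuple[KinematicsTrace, list[str]]:
    """Check EMG/kinematics alignment; resample kinematics if needed.

    Returns the kinematics on the EMG timebase plus a report of the
    discrepancies found (empty when nothing had to change). Kinematics at
    a different rate are linearly interpolated onto the EMG clock.
    """
    if emg.n_samples == 0 or kinematics.n_samples == 0:
        raise InvalidInputError("zero-length trace")
    report: list[str] = []
    if kinematics.sample_rate != emg.sample_rate:
        report.append(
            f"kinematics rate {kinematics.sample_rate} Hz != EMG rate {emg.sample_rate} Hz; resampled"
        )
    duration_kin = kinematics.n_samples / kinematics.sample_rate
    duration_emg = emg.n_samples / emg.sample_rate
    if abs(duration_kin - duration_emg) > 1.0 / min(emg.sample_rate, kinematics.sample_rate):
        report.append(
            f"duration mismatch: kinematics {duration_kin:.3f} s vs EMG {duration_emg:.3f} s"
        )
    if not report and kinematics.n_samples == emg.n_samples:
        return kinematics, report
    t_emg = np.arange(emg.n_samples) / emg.sample_rate
    t_kin = np.arange(kinematics.n_samples) / kinematics.sample_rate
    resampled = np.stack([np.interp(t_emg, t_kin, row) for row in kinematics.angles])
    if kinematics.n_samples != emg.n_samples and not report:
        report.append(
            f"length mismatch: kinematics {kinematics.n_samples} vs EMG {emg.n_samples}; resampled"
        )
    return KinematicsTrace(angles=resampled, sample_rate=emg.sample_rate), report
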