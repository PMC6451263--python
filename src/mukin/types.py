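"""Core in-memory containers shared by all pipeline stages.

The containers are deliberately thin wrappers around numpy arrays and a
pandas frame: an EMG recording (channels x samples), a set of motor-unit
spike trains (sorted discharge sample indices), a 3-DoF joint-angle trace,
the trial segmentation of a recording session, and a generic windowed
feature matrix. Validation happens at construction so downstream code can
rely on the invariants (sorted spikes, 3 kinematic rows, matching grid
geometry, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

N_DOFS = 3

SEGMENTATION_COLUMNS = [
    "trial_id",
    "dof",
    "direction",
    "start_sample",
    "end_sample",
    "ramp_duration_s",
]


@dataclass
class EMGRecording:
    """Multichannel surface EMG: ``samples`` is (n_channels, n_samples).

    ``grid_shape`` describes the electrode grid (rows, cols);
    ``bad_channel_mask`` marks channels excluded from analysis (True = bad).
    """

    samples: np.ndarray
    sample_rate: float
    grid_shape: tuple[int, int] = (8, 8)
    bad_channel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise InvalidInputError("EMG samples must be a 2-D (channels, time) array")
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")
        rows, cols = self.grid_shape
        if rows * cols != self.n_channels:
            raise InvalidInputError(
                f"grid shape {self.grid_shape} does not match {self.n_channels} channels"
            )
        if self.bad_channel_mask is None:
            self.bad_channel_mask = np.zeros(self.n_channels, dtype=bool)
        else:
            self.bad_channel_mask = np.asarray(self.bad_channel_mask, dtype=bool)
            if self.bad_channel_mask.shape != (self.n_channels,):
                raise InvalidInputError("bad_channel_mask length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def active_channels(self) -> np.ndarray:
        """Indices of channels not flagged as bad."""
        return np.flatnonzero(~self.bad_channel_mask)

    def with_samples(self, samples: np.ndarray) -> "EMGRecording":
        return EMGRecording(
            samples=samples,
            sample_rate=self.sample_rate,
            grid_shape=self.grid_shape,
            bad_channel_mask=self.bad_channel_mask.copy(),
        )


@dataclass
class SpikeTrainSet:
    """Per-unit sorted discharge sample indices.

    ``trains`` maps a unit id to a strictly increasing int array of
    discharge sample indices. ``provenance`` records whether the set is
    simulator ground truth, a corrupted ("decomposed") set, or external.
    """

    trains: dict[int, np.ndarray]
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for uid, idx in self.trains.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.ndim != 1:
                raise InvalidInputError(f"unit {uid}: spike indices must be 1-D")
            if idx.size and idx[0] < 0:
                raise InvalidInputError(f"unit {uid}: negative spike index")
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise InvalidInputError(f"unit {uid}: spike indices must be strictly increasing")
            clean[int(uid)] = idx
        self.trains = clean

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def restrict(self, spans: list[tuple[int, int]]) -> "SpikeTrainSet":
        """Keep only discharges falling inside the half-open sample spans."""
        out: dict[int, np.ndarray] = {}
        for uid, idx in self.trains.items():
            keep = np.zeros(idx.size, dtype=bool)
            for start, end in spans:
                keep |= (idx >= start) & (idx < end)
            out[uid] = idx[keep]
        return SpikeTrainSet(out, provenance=self.provenance)


@dataclass
class KinematicsTrace:
    """Per-sample wrist joint angles in degrees, one row per DoF (3 rows)."""

    angles: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[0] != N_DOFS:
            raise InvalidInputError("kinematics must have exactly 3 rows (DoFs)")
        if not np.all(np.isfinite(self.angles)):
            raise InvalidInputError("kinematics contains non-finite values")
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[1]


@dataclass
class TrialSegmentation:
    """Trial/ramp segmentation of a session.

    One record per direction episode: (trial_id, dof, direction,
    start_sample, end_sample, ramp_duration_s). Episodes are contiguous,
    non-overlapping spans that partition each DoF block (each span contains
    its leading rest plus the triangular ramp).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=SEGMENTATION_COLUMNS).copy()
        for col in ("trial_id", "dof", "direction", "start_sample", "end_sample"):
            df[col] = df[col].astype(int)
        df["ramp_duration_s"] = df["ramp_duration_s"].astype(float)
        if (df["end_sample"] <= df["start_sample"]).any():
            raise InvalidInputError("segmentation spans must satisfy end > start")
        spans = df.sort_values("start_sample")[["start_sample", "end_sample"]].to_numpy()
        if np.any(spans[1:, 0] < spans[:-1, 1]):
            raise InvalidInputError("segmentation spans overlap")
        self.records = df.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def trials(self) -> pd.DataFrame:
        """One row per (dof, trial_id) with the merged trial span."""
        g = self.records.groupby(["dof", "trial_id"], as_index=False).agg(
            start_sample=("start_sample", "min"),
            end_sample=("end_sample", "max"),
            ramp_duration_s=("ramp_duration_s", "first"),
        )
        return g.sort_values(["dof", "trial_id"]).reset_index(drop=True)

    def trial_spans(self, dof: int, trial_id: int) -> list[tuple[int, int]]:
        rows = self.records[(self.records.dof == dof) & (self.records.trial_id == trial_id)]
        return [(int(r.start_sample), int(r.end_sample)) for r in rows.itertuples()]


@dataclass
class FeatureMatrix:
    """Windowed features: ``values`` is (n_windows, n_features)."""

    values: np.ndarray
    window_end_sample: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_end_sample = np.asarray(self.window_end_sample, dtype=np.int64)
        if self.values.ndim != 2:
            raise InvalidInputError("feature values must be 2-D (windows, features)")
        if self.window_end_sample.shape != (self.values.shape[0],):
            raise InvalidInputError("window_end_sample length must match window count")
        if self.window_end_sample.size > 1 and np.any(np.diff(self.window_end_sample) <= 0):
            raise InvalidInputError("windows must be ordered by time")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("feature matrix contains non-finite values")
        if not self.labels:
            self.labels = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise InvalidInputError("label count must match feature count")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
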