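"""Synthetic motor-neuron-pool / surface-EMG session generator.

Emulates the experimental sessions the decoding pipeline expects: single-DoF
triangular joint-angle ramps at three speeds, a recruitment-ordered motor
neuron pool per DoF direction driven by the rectified normalized joint angle
(a common-drive proxy), multichannel biphasic MUAP templates on an electrode
grid, linear mixing into EMG with additive white noise at a configured SNR,
and an optional decomposition-error model (missed spikes, false positives,
partial unit detection biased toward high-threshold units).

All randomness flows from a single session seed through
``numpy.random.SeedSequence`` spawning, so identical seeds and configs yield
bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .mixing import superpose
from .types import (
    N_DOFS,
    EMGRecording,
    KinematicsTrace,
    SpikeTrainSet,
    TrialSegmentation,
)

# ---------------------------------------------------------------------------
# configuration types


@dataclass
class CueProfile:
    """Single-DoF triangular cue schedule.

    One trial = neutral -> +rom -> neutral, rest, neutral -> -rom -> neutral.
    ``rom`` is the half-range of motion in degrees per direction.
    """

    dof_index: int
    ramp_duration: float
    n_trials: int = 3
    rom: float = 60.0
    rest_duration: float = 2.0
    sample_rate: float = 2048.0

    def validate(self) -> None:
        if self.dof_index not in range(N_DOFS):
            raise InvalidConfigError(f"dof_index must be in 0..{N_DOFS - 1}")
        if self.ramp_duration <= 0:
            raise InvalidConfigError("ramp_duration must be positive")
        if self.sample_rate <= 0:
            raise InvalidConfigError("sample_rate must be positive")
        if self.n_trials < 0:
            raise InvalidConfigError("n_trials must be nonnegative")
        if self.rom <= 0:
            raise InvalidConfigError("rom must be positive")
        if self.rest_duration < 0:
            raise InvalidConfigError("rest_duration must be nonnegative")


@dataclass
class MotorUnitPool:
    """Recruitment-ordered pool of motor units for one DoF direction.

    Thresholds are fractions of maximal drive, strictly increasing;
    amplitude scales grow with recruitment threshold (larger units are
    recruited later).
    """

    recruitment_thresholds: np.ndarray
    min_rate: float = 8.0
    peak_rate: float = 35.0
    rate_gain: float = 40.0
    isi_cov: float = 0.15
    territory_centers: np.ndarray | None = None  # (n_units, 2) grid coords
    amplitude_scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.recruitment_thresholds = np.asarray(self.recruitment_thresholds, dtype=float)
        if self.recruitment_thresholds.ndim != 1 or self.recruitment_thresholds.size < 1:
            raise InvalidConfigError("need at least one recruitment threshold")
        if np.any(np.diff(self.recruitment_thresholds) <= 0):
            raise InvalidConfigError("recruitment thresholds must be strictly increasing")
        if not (0 < self.recruitment_thresholds[0] and self.recruitment_thresholds[-1] <= 1):
            raise InvalidConfigError("thresholds must lie in (0, 1]")
        if self.min_rate >= self.peak_rate:
            raise InvalidConfigError("min_rate must be below peak_rate")
        if self.isi_cov < 0:
            raise InvalidConfigError("isi_cov must be nonnegative")
        if self.amplitude_scales is None:
            # larger action potentials for higher-threshold units
            self.amplitude_scales = (
                self.recruitment_thresholds / self.recruitment_thresholds[-1]
            )
        else:
            self.amplitude_scales = np.asarray(self.amplitude_scales, dtype=float)

    @property
    def n_units(self) -> int:
        return self.recruitment_thresholds.size

    def rate_at(self, drive: np.ndarray | float, unit: int) -> np.ndarray | float:
        """Discharge rate (pps) of ``unit`` at the given drive level(s)."""
        thr = self.recruitment_thresholds[unit]
        return np.minimum(
            self.peak_rate, self.min_rate + self.rate_gain * (np.asarray(drive) - thr)
        )


@dataclass
class MUAPTemplateBank:
    """Per-unit multichannel MUAP waveforms, all of equal length.

    ``offset`` is the placement convention: a discharge at sample t places
    the template onset at t - offset (0 = onset-aligned).
    """

    templates: dict[int, np.ndarray]
    sample_rate: float
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.templates:
            raise InvalidInputError("template bank must contain at least one unit")
        lengths = {w.shape[1] for w in self.templates.values()}
        if len(lengths) != 1:
            raise InvalidInputError("all templates must have the same length")
        for uid, w in self.templates.items():
            if not np.any(np.abs(w) > 0):
                raise InvalidInputError(f"unit {uid}: template has zero energy")

    @property
    def template_length(self) -> int:
        return next(iter(self.templates.values())).shape[1]

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.templates)


@dataclass
class CorruptionSpec:
    """Decomposition-error model applied to ground-truth spike trains."""

    miss_rate: float = 0.0
    false_positive_rate: float = 0.0  # spurious events per second per unit
    detected_fraction: float = 1.0
    high_threshold_bias: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.miss_rate <= 1:
            raise InvalidConfigError("miss_rate must be in [0, 1]")
        if self.false_positive_rate < 0:
            raise InvalidConfigError("false_positive_rate must be nonnegative")
        if not 0 < self.detected_fraction <= 1:
            raise InvalidConfigError("detected_fraction must be in (0, 1]")
        if self.high_threshold_bias < 0:
            raise InvalidConfigError("high_threshold_bias must be nonnegative")


@dataclass
class GroundTruth:
    """Everything needed to reproduce a session bit-identically."""

    spikes: SpikeTrainSet
    bank: MUAPTemplateBank
    drives: dict[int, np.ndarray]  # pool index -> per-sample common drive
    seed: int


# ---------------------------------------------------------------------------
# cue generation


def _triangle(n_ramp: int, rom: float, direction: int) -> np.ndarray:
    """2*n_ramp samples of constant-slope triangle: 0 -> dir*rom -> 0."""
    up = rom * np.arange(1, n_ramp + 1) / n_ramp
    down = rom * np.arange(n_ramp - 1, -1, -1) / n_ramp
    return direction * np.concatenate([up, down])


def generate_cue(
    profile: CueProfile, seed: int | None = None
) -> tuple[KinematicsTrace, TrialSegmentation]:
    """Triangular single-DoF cue with trial segmentation.

    The cued DoF holds ``n_trials`` ramps per direction separated by rests;
    the other two DoFs are identically zero. The trace starts and ends at
    0 degrees and peaks at exactly +/- rom. ``seed`` is accepted for
    interface symmetry; the cue itself is deterministic.
    """
    profile.validate()
    fs = profile.sample_rate
    n_ramp = round(profile.ramp_duration * fs)
    n_rest = round(profile.rest_duration * fs)
    if n_ramp < 1:
        raise InvalidConfigError("ramp_duration too short for the sample rate")

    pieces: list[np.ndarray] = []
    records: list[dict] = []
    cursor = 0
    if profile.n_trials == 0:
        pieces.append(np.zeros(max(n_rest, 1)))
    for trial in range(profile.n_trials):
        for k, direction in enumerate((1, -1)):
            span_start = cursor
            pieces.append(np.zeros(n_rest))
            pieces.append(_triangle(n_ramp, profile.rom, direction))
            cursor += n_rest + 2 * n_ramp
            last = trial == profile.n_trials - 1 and direction == -1
            if last:  # trailing rest attached to the final episode
                pieces.append(np.zeros(n_rest))
                cursor += n_rest
            records.append(
                dict(
                    trial_id=trial,
                    dof=profile.dof_index,
                    direction=direction,
                    start_sample=span_start,
                    end_sample=cursor,
                    ramp_duration_s=profile.ramp_duration,
                )
            )
    cue = np.concatenate(pieces) if pieces else np.zeros(0)
    angles = np.zeros((N_DOFS, cue.size))
    angles[profile.dof_index] = cue
    trace = KinematicsTrace(angles=angles, sample_rate=fs)
    import pandas as pd

    seg = TrialSegmentation(pd.DataFrame(records)) if records else TrialSegmentation(
        pd.DataFrame(
            columns=[
                "trial_id",
                "dof",
                "direction",
                "start_sample",
                "end_sample",
                "ramp_duration_s",
            ]
        )
    )
    return trace, seg


# ---------------------------------------------------------------------------
# pool construction and spike sampling


def build_pool(
    n_units: int,
    recruitment_range: float,
    min_rate: float = 8.0,
    peak_rate: float = 35.0,
    rate_gain: float = 40.0,
    isi_cov: float = 0.15,
    max_threshold: float = 1.0,
    seed: int | None = None,
    grid_shape: tuple[int, int] = (8, 8),
    territory_center: tuple[float, float] | None = None,
    territory_spread: float = 1.2,
) -> MotorUnitPool:
    """Exponential recruitment-threshold ladder pool.

    Unit j (1-based) has threshold exp((j-1) ln(RR)/(n-1)) / RR scaled by
    ``max_threshold``, so the ladder spans [max_threshold/RR, max_threshold]
    and the largest/smallest ratio is exactly the recruitment range RR.
    Territory centers are scattered around ``territory_center`` (defaults to
    the grid center) on the electrode grid.
    """
    if n_units < 1:
        raise InvalidConfigError("n_units must be >= 1")
    if recruitment_range <= 1:
        raise InvalidConfigError("recruitment_range must exceed 1")
    if not 0 < max_threshold <= 1:
        raise InvalidConfigError("max_threshold must be in (0, 1]")
    if n_units == 1:
        thresholds = np.array([max_threshold])
    else:
        j = np.arange(n_units)
        thresholds = max_threshold * np.exp(
            j * math.log(recruitment_range) / (n_units - 1)
        ) / recruitment_range
        thresholds = np.minimum(thresholds, max_threshold)  # guard fp overshoot
    rng = np.random.default_rng(seed)
    if territory_center is None:
        territory_center = ((grid_shape[0] - 1) / 2, (grid_shape[1] - 1) / 2)
    centers = rng.normal(loc=territory_center, scale=territory_spread, size=(n_units, 2))
    centers[:, 0] = np.clip(centers[:, 0], 0, grid_shape[0] - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, grid_shape[1] - 1)
    return MotorUnitPool(
        recruitment_thresholds=thresholds,
        min_rate=min_rate,
        peak_rate=peak_rate,
        rate_gain=rate_gain,
        isi_cov=isi_cov,
        territory_centers=centers,
    )


def drive_from_kinematics(
    kinematics: KinematicsTrace, dof: int, direction: int, rom: float
) -> np.ndarray:
    """Rectified normalized joint angle as common drive in [0, 1]."""
    if dof not in range(N_DOFS):
        raise InvalidInputError(f"dof must be in 0..{N_DOFS - 1}")
    if direction not in (1, -1):
        raise InvalidInputError("direction must be +1 or -1")
    if rom <= 0:
        raise InvalidConfigError("rom must be positive")
    return np.clip(direction * kinematics.angles[dof] / rom, 0.0, 1.0)


def _sample_unit_spikes(
    threshold: float,
    drive: np.ndarray,
    fs: float,
    min_rate: float,
    peak_rate: float,
    rate_gain: float,
    isi_cov: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequential renewal process along a time-varying drive.

    A unit emits its first spike at the first suprathreshold sample
    (preserving recruitment order for monotone drive) and thereafter at
    Gaussian inter-spike intervals with mean 1/rate and CoV ``isi_cov``;
    intervals <= 1 ms are rejected (refractory safety). The unit never
    fires while the drive is below its threshold.
    """
    supra = np.flatnonzero(drive >= threshold)
    if supra.size == 0:
        return np.zeros(0, dtype=np.int64)
    spikes: list[int] = []
    t = int(supra[0])
    t_time = t / fs  # continuous spike time: ISIs accumulate fractionally
    n = drive.size
    while True:
        spikes.append(t)
        rate = min(peak_rate, min_rate + rate_gain * (drive[t] - threshold))
        mean_isi = 1.0 / rate
        if isi_cov == 0:
            isi = mean_isi
        else:
            isi = rng.normal(mean_isi, isi_cov * mean_isi)
            while isi <= 1e-3:
                isi = rng.normal(mean_isi, isi_cov * mean_isi)
        t_time += isi
        t_next = max(t + 1, round(t_time * fs))
        if t_next >= n:
            break
        if drive[t_next] >= threshold:
            t = t_next
        else:
            # de-recruited: wait for the next suprathreshold sample
            k = np.searchsorted(supra, t_next)
            if k == supra.size:
                break
            t = int(supra[k])
            t_time = t / fs
    return np.asarray(spikes, dtype=np.int64)


def sample_spike_trains(
    pool: MotorUnitPool,
    drive: np.ndarray,
    fs: float,
    seed: int | np.random.SeedSequence | None = None,
    unit_ids: list[int] | None = None,
) -> SpikeTrainSet:
    """Sample all pool units against a shared drive trace in [0, 1]."""
    if fs <= 0:
        raise InvalidConfigError("sample rate must be positive")
    drive = np.asarray(drive, dtype=float)
    if drive.ndim != 1:
        raise InvalidInputError("drive must be a 1-D trace")
    if drive.size and (drive.min() < 0 or drive.max() > 1):
        raise InvalidInputError("drive must lie in [0, 1]")
    if unit_ids is None:
        unit_ids = list(range(pool.n_units))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(pool.n_units)
    trains: dict[int, np.ndarray] = {}
    for j in range(pool.n_units):
        rng = np.random.default_rng(children[j])
        trains[unit_ids[j]] = _sample_unit_spikes(
            pool.recruitment_thresholds[j],
            drive,
            fs,
            pool.min_rate,
            pool.peak_rate,
            pool.rate_gain,
            pool.isi_cov,
            rng,
        )
    return SpikeTrainSet(trains, provenance="ground_truth")


# ---------------------------------------------------------------------------
# MUAP templates and EMG synthesis


def generate_templates(
    pool: MotorUnitPool,
    grid_shape: tuple[int, int] = (8, 8),
    template_length: int = 51,
    sample_rate: float = 2048.0,
    seed: int | np.random.SeedSequence | None = None,
    unit_ids: list[int] | None = None,
    decay_length: float = 1.5,
    base_amplitude: float = 1.0,
) -> MUAPTemplateBank:
    """Biphasic MUAP templates with spatial amplitude decay.

    Each unit's waveform is the first derivative of a Gaussian (width drawn
    per unit), identical across channels up to an amplitude factor that
    decays exponentially with grid distance from the unit's territory
    center. The maximal-channel peak amplitude is proportional to the
    unit's amplitude scale.
    """
    if pool.n_units < 1:
        raise InvalidInputError("empty pool")
    if template_length < 3:
        raise InvalidInputError("template_length must be >= 3 samples")
    if unit_ids is None:
        unit_ids = list(range(pool.n_units))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows, cols = grid_shape
    grid_r, grid_c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid_pos = np.stack([grid_r.ravel(), grid_c.ravel()], axis=1)  # (C, 2)

    centers = pool.territory_centers
    if centers is None:
        centers = np.tile([(rows - 1) / 2, (cols - 1) / 2], (pool.n_units, 1))

    t = np.arange(template_length) - (template_length - 1) / 2
    templates: dict[int, np.ndarray] = {}
    for j in range(pool.n_units):
        sigma_ms = rng.uniform(1.2, 2.4)  # per-unit waveform width
        sigma = sigma_ms * 1e-3 * sample_rate
        wave = -t * np.exp(-(t**2) / (2 * sigma**2))
        wave /= np.max(np.abs(wave))  # unit peak amplitude
        dist = np.linalg.norm(grid_pos - centers[j], axis=1)
        gain = base_amplitude * pool.amplitude_scales[j] * np.exp(-dist / decay_length)
        templates[unit_ids[j]] = gain[:, None] * wave[None, :]
    return MUAPTemplateBank(templates=templates, sample_rate=sample_rate, offset=0)


def synthesize_emg(
    spikes: SpikeTrainSet,
    bank: MUAPTemplateBank | None,
    n_samples: int,
    sample_rate: float = 2048.0,
    grid_shape: tuple[int, int] = (8, 8),
    noise_snr_db: float | None = None,
    absolute_noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> EMGRecording:
    """Mix MUAP templates at discharge times plus white Gaussian noise.

    The noise SD is chosen so the channel-mean SNR (10 log10 of signal
    power over noise power, signal power measured during activity) matches
    ``noise_snr_db``. With no units (or no discharges) the recording is
    pure noise at ``absolute_noise_sd``. ``noise_snr_db=None`` disables
    noise entirely.
    """
    n_channels = grid_shape[0] * grid_shape[1]
    if bank is not None and spikes.n_units:
        clean = superpose(spikes.trains, bank.templates, n_samples, offset=bank.offset)
        if clean.shape[0] != n_channels:
            raise InvalidInputError("template channel count does not match grid shape")
    else:
        clean = np.zeros((n_channels, n_samples))

    signal = clean.astype(np.float64)
    if noise_snr_db is not None:
        rng = np.random.default_rng(
            seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        )
        active = np.any(np.abs(clean) > 0, axis=0)
        if active.any():
            power = np.mean(clean[:, active] ** 2, axis=1)
            power = np.maximum(power, 1e-30)
            noise_db = np.mean(10 * np.log10(power)) - noise_snr_db
            noise_sd = math.sqrt(10 ** (noise_db / 10))
        else:
            noise_sd = absolute_noise_sd
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return EMGRecording(samples=signal, sample_rate=sample_rate, grid_shape=grid_shape)


# ---------------------------------------------------------------------------
# decomposition-error model


def corrupt_spike_trains(
    spikes: SpikeTrainSet,
    spec: CorruptionSpec,
    thresholds: dict[int, float],
    n_samples: int,
    sample_rate: float,
    seed: int | np.random.SeedSequence | None = None,
) -> SpikeTrainSet:
    """Apply the decomposition-error model to ground-truth spike trains.

    Keeps ceil(detected_fraction * n_units) units, sampled without
    replacement with probability weight threshold**high_threshold_bias
    (decomposition preferentially finds large, high-threshold units); each
    retained unit loses spikes independently at ``miss_rate`` and gains
    spurious discharges as a homogeneous process at ``false_positive_rate``
    events/s. Output trains are sorted and deduplicated.
    """
    spec.validate()
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    uids = spikes.unit_ids
    n_keep = math.ceil(spec.detected_fraction * len(uids))
    weights = np.array([max(thresholds.get(u, 1.0), 1e-12) for u in uids])
    weights = weights ** spec.high_threshold_bias
    weights = weights / weights.sum()
    kept = rng.choice(len(uids), size=n_keep, replace=False, p=weights)
    kept_ids = [uids[k] for k in sorted(kept)]

    duration = n_samples / sample_rate
    out: dict[int, np.ndarray] = {}
    for uid in kept_ids:
        idx = spikes.trains[uid]
        if spec.miss_rate > 0 and idx.size:
            idx = idx[rng.random(idx.size) >= spec.miss_rate]
        if spec.false_positive_rate > 0:
            n_fp = rng.poisson(spec.false_positive_rate * duration)
            fp = rng.integers(0, n_samples, size=n_fp)
            idx = np.concatenate([idx, fp])
        out[uid] = np.unique(idx)
    return SpikeTrainSet(out, provenance="corrupted")


# ---------------------------------------------------------------------------
# full-session assembly


@dataclass
class SessionConfig:
    """One recording session: 3 DoFs x n_trials at a single ramp speed."""

    ramp_duration: float = 1.0
    n_trials: int = 3
    rom_deg: float = 60.0
    rest_duration: float = 2.0
    sample_rate: float = 2048.0
    units_per_pool: int = 30
    pool_size_cv: float = 0.27  # per-pool unit-count dispersion (decomposition-like yields)
    recruitment_range: float = 30.0
    max_threshold: float = 0.8
    min_rate: float = 8.0
    peak_rate: float = 35.0
    rate_gain: float = 40.0
    isi_cov: float = 0.15
    shared_fraction: float = 0.05
    grid_shape: tuple[int, int] = (8, 8)
    template_length: int = 51
    snr_db: float | None = 15.0
    corruption: CorruptionSpec | None = None
    shuffle_dof_order: bool = True


# fixed territory loci for the six direction pools (dof*2 + dir_idx),
# spread over the 8x8 grid like distinct muscle territories
_POOL_CENTERS = [(1.5, 1.5), (5.5, 5.5), (1.5, 5.5), (5.5, 1.5), (3.5, 1.0), (3.5, 6.0)]


@dataclass
class Session:
    """A fully simulated recording session plus its ground truth."""

    emg: EMGRecording
    spikes: SpikeTrainSet  # the "decomposed" set seen by the pipeline
    kinematics: KinematicsTrace
    segmentation: TrialSegmentation
    ground_truth: GroundTruth
    config: SessionConfig
    unit_thresholds: dict[int, float] = field(default_factory=dict)
    unit_pool: dict[int, int] = field(default_factory=dict)


def simulate_session(config: SessionConfig, seed: int = 0) -> Session:
    """Generate one complete session at a single ramp speed.

    Six direction pools (two per DoF) are driven by the rectified
    normalized cue angle; a small fraction of units is shared between pools
    of different DoFs (multi-DoF units). EMG is the template mixture plus
    noise; if ``config.corruption`` is set, the session's spike set is the
    corrupted one (ground truth is kept alongside).
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    (
        ss_order,
        ss_pools,
        ss_templates,
        ss_spikes,
        ss_share,
        ss_noise,
        ss_corrupt,
    ) = ss.spawn(7)

    # --- cue assembly: one block per DoF, seeded order ------------------
    dof_order = list(range(N_DOFS))
    if config.shuffle_dof_order:
        dof_order = list(np.random.default_rng(ss_order).permutation(N_DOFS))
    blocks = []
    records = []
    cursor = 0
    for dof in dof_order:
        profile = CueProfile(
            dof_index=dof,
            ramp_duration=config.ramp_duration,
            n_trials=config.n_trials,
            rom=config.rom_deg,
            rest_duration=config.rest_duration,
            sample_rate=config.sample_rate,
        )
        trace, seg = generate_cue(profile)
        blocks.append(trace.angles)
        df = seg.records.copy()
        df["start_sample"] += cursor
        df["end_sample"] += cursor
        records.append(df)
        cursor += trace.n_samples
    angles = np.concatenate(blocks, axis=1)
    kinematics = KinematicsTrace(angles=angles, sample_rate=config.sample_rate)
    segmentation = TrialSegmentation(pd.concat(records, ignore_index=True))
    n_samples = kinematics.n_samples

    # --- pools, shared units, drives ------------------------------------
    pool_seeds = ss_pools.spawn(2 * N_DOFS)
    tmpl_seeds = ss_templates.spawn(2 * N_DOFS)
    spike_seeds = ss_spikes.spawn(2 * N_DOFS)
    share_rng = np.random.default_rng(ss_share)

    all_trains: dict[int, np.ndarray] = {}
    all_templates: dict[int, np.ndarray] = {}
    drives: dict[int, np.ndarray] = {}
    unit_thresholds: dict[int, float] = {}
    unit_pool: dict[int, int] = {}
    next_uid = 0
    pool_drive = {}
    for p in range(2 * N_DOFS):
        dof, dir_idx = divmod(p, 2)
        direction = 1 if dir_idx == 0 else -1
        pool_drive[p] = drive_from_kinematics(kinematics, dof, direction, config.rom_deg)
        drives[p] = pool_drive[p]

    # decomposition-style unit yields are heterogeneous across muscles:
    # draw per-pool counts around the configured mean
    size_rng = np.random.default_rng(ss_order.spawn(1)[0])
    pool_sizes = [
        max(4, int(round(size_rng.normal(config.units_per_pool,
                                         config.pool_size_cv * config.units_per_pool))))
        for _ in range(2 * N_DOFS)
    ]

    for p in range(2 * N_DOFS):
        dof = p // 2
        pool = build_pool(
            n_units=pool_sizes[p],
            recruitment_range=config.recruitment_range,
            min_rate=config.min_rate,
            peak_rate=config.peak_rate,
            rate_gain=config.rate_gain,
            isi_cov=config.isi_cov,
            max_threshold=config.max_threshold,
            seed=pool_seeds[p],
            grid_shape=config.grid_shape,
            territory_center=_POOL_CENTERS[p],
        )
        uids = list(range(next_uid, next_uid + pool.n_units))
        next_uid += pool.n_units

        # multi-DoF units: respond to the max of their own and a second
        # pool's drive (pools of a different DoF)
        drive = pool_drive[p]
        shared = share_rng.random(pool.n_units) < config.shared_fraction
        unit_drives = []
        for j in range(pool.n_units):
            if shared[j]:
                others = [q for q in range(2 * N_DOFS) if q // 2 != dof]
                q = int(share_rng.choice(others))
                unit_drives.append(np.maximum(drive, pool_drive[q]))
            else:
                unit_drives.append(drive)

        unit_seed_children = spike_seeds[p].spawn(pool.n_units)
        for j, uid in enumerate(uids):
            rng = np.random.default_rng(unit_seed_children[j])
            all_trains[uid] = _sample_unit_spikes(
                pool.recruitment_thresholds[j],
                unit_drives[j],
                config.sample_rate,
                pool.min_rate,
                pool.peak_rate,
                pool.rate_gain,
                pool.isi_cov,
                rng,
            )
            unit_thresholds[uid] = float(pool.recruitment_thresholds[j])
            unit_pool[uid] = p

        bank_p = generate_templates(
            pool,
            grid_shape=config.grid_shape,
            template_length=config.template_length,
            sample_rate=config.sample_rate,
            seed=tmpl_seeds[p],
            unit_ids=uids,
        )
        all_templates.update(bank_p.templates)

    spikes_truth = SpikeTrainSet(all_trains, provenance="ground_truth")
    bank = MUAPTemplateBank(
        templates=all_templates, sample_rate=config.sample_rate, offset=0
    )

    emg = synthesize_emg(
        spikes_truth,
        bank,
        n_samples=n_samples,
        sample_rate=config.sample_rate,
        grid_shape=config.grid_shape,
        noise_snr_db=config.snr_db,
        seed=ss_noise,
    )
    # sessions keep the storage dtype of the on-disk container
    emg = emg.with_samples(emg.samples.astype(np.float32))

    if config.corruption is not None:
        spikes = corrupt_spike_trains(
            spikes_truth,
            config.corruption,
            unit_thresholds,
            n_samples,
            config.sample_rate,
            seed=ss_corrupt,
        )
    else:
        spikes = SpikeTrainSet(
            {u: t.copy() for u, t in spikes_truth.trains.items()}, provenance="ground_truth"
        )

    ground_truth = GroundTruth(spikes=spikes_truth, bank=bank, drives=drives, seed=seed)
    return Session(
        emg=emg,
        spikes=spikes,
        kinematics=kinematics,
        segmentation=segmentation,
        ground_truth=ground_truth,
        config=config,
        unit_thresholds=unit_thresholds,
        unit_pool=unit_pool,
    )


def simulate_study(
    config: SessionConfig,
    seed: int = 0,
    ramp_durations: tuple[float, ...] = (5.0, 2.5, 1.0),
) -> dict[float, Session]:
    """Three runs at the three ramp speeds, one session each."""
    sessions = {}
    for k, d in enumerate(ramp_durations):
        sessions[d] = simulate_session(replace(config, ramp_duration=d), seed=seed + k)
    return sessions
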