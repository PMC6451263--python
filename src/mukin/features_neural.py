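"""Neural feature sets built from decomposed motor-unit spike trains.

Covers the decomposed spike count (DSC) matrix, cross-trial motor-unit
matching by template cross-correlation, spike-triggered-average (STA) MUAP
estimation, EMG reconstruction from spikes and templates, the residual EMG
(recorded minus reconstructed), and assembly of the comparison feature
sets: AM1 = [DSC || residual TD] -> PCA, AM2 = DSC -> PCA, and the raw DSC
fed to the model-based dimensionality reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    MissingTemplateError,
)
from .features_td import PCABasis, WindowSpec, apply_pca, fit_pca
from .mixing import superpose
from .simulator import MUAPTemplateBank
from .types import EMGRecording, FeatureMatrix, SpikeTrainSet


# ---------------------------------------------------------------------------
# decomposed spike counts


def spike_counts(
    spikes: SpikeTrainSet, spec: WindowSpec, n_samples: int, fs: float
) -> FeatureMatrix:
    """Windows x units matrix of discharge counts per half-open window."""
    from .features_td import segment

    intervals = segment(n_samples, spec, fs)
    uids = spikes.unit_ids
    counts = np.zeros((intervals.shape[0], len(uids)))
    for k, uid in enumerate(uids):
        idx = spikes.trains[uid]
        if idx.size and idx[-1] >= n_samples:
            raise InvalidInputError(f"unit {uid}: spike index beyond trace length")
        counts[:, k] = np.searchsorted(idx, intervals[:, 1]) - np.searchsorted(
            idx, intervals[:, 0]
        )
    return FeatureMatrix(
        values=counts,
        window_end_sample=intervals[:, 1],
        labels=[f"unit{uid}" for uid in uids],
    )


# ---------------------------------------------------------------------------
# spike-triggered averaging and reconstruction


def spike_triggered_average(
    emg: EMGRecording,
    spike_indices: np.ndarray,
    template_length: int,
    offset: int = 0,
    min_spikes: int = 10,
) -> np.ndarray:
    """Mean multichannel EMG segment aligned to discharges.

    The segment for a discharge at t spans [t-offset, t-offset+L);
    discharges without full support are skipped. Returns an
    (n_channels, L) template.
    """
    idx = np.asarray(spike_indices, dtype=np.int64)
    starts = idx - offset
    ok = (starts >= 0) & (starts + template_length <= emg.n_samples)
    starts = starts[ok]
    if starts.size < min_spikes:
        raise InsufficientDataError(
            f"{starts.size} usable discharges (< {min_spikes}) for STA"
        )
    gather = starts[:, None] + np.arange(template_length)[None, :]
    segments = emg.samples.astype(np.float64)[:, gather]  # (C, n, L)
    return segments.mean(axis=1)


def sta_template_bank(
    emg: EMGRecording,
    spikes: SpikeTrainSet,
    template_length: int = 51,
    offset: int = 0,
    min_spikes: int = 10,
) -> tuple[MUAPTemplateBank | None, list[int]]:
    """STA templates for every unit with enough usable discharges.

    Returns (bank, skipped_unit_ids); bank is None when no unit qualifies.
    """
    templates: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    for uid in spikes.unit_ids:
        try:
            w = spike_triggered_average(
                emg, spikes.trains[uid], template_length, offset, min_spikes
            )
        except InsufficientDataError:
            skipped.append(uid)
            continue
        if not np.any(np.abs(w) > 0):
            skipped.append(uid)
            continue
        templates[uid] = w
    if not templates:
        return None, skipped
    return (
        MUAPTemplateBank(templates=templates, sample_rate=emg.sample_rate, offset=offset),
        skipped,
    )


def reconstruct_emg(
    spikes: SpikeTrainSet, bank: MUAPTemplateBank, n_samples: int, emg_like: EMGRecording
) -> EMGRecording:
    """Superpose each unit's template at its discharge times."""
    missing = [u for u in spikes.unit_ids if u not in bank.templates]
    if missing:
        raise MissingTemplateError(f"no template for units {missing}")
    recon = superpose(spikes.trains, bank.templates, n_samples, offset=bank.offset)
    return emg_like.with_samples(recon.astype(np.float32))


def residual(emg: EMGRecording, reconstruction: EMGRecording) -> EMGRecording:
    """Recorded EMG minus the EMG explained by the decomposed spike trains."""
    if emg.samples.shape != reconstruction.samples.shape:
        raise InvalidInputError("EMG and reconstruction shapes differ")
    diff = emg.samples.astype(np.float64) - reconstruction.samples.astype(np.float64)
    return emg.with_samples(diff.astype(np.float32))


# ---------------------------------------------------------------------------
# cross-trial unit matching


@dataclass
class MatchPair:
    unit_a: int
    unit_b: int
    correlation: float
    channels: np.ndarray
    matched: bool
    reason: str = ""


@dataclass
class MatchResult:
    pairs: list[MatchPair]
    registry: dict[tuple[str, int], int] = field(default_factory=dict)


def _shift(w: np.ndarray, lag: int) -> np.ndarray:
    """Shift each channel's waveform by ``lag`` samples, zero-padded."""
    out = np.zeros_like(w)
    if lag >= 0:
        out[:, lag:] = w[:, : w.shape[1] - lag]
    else:
        out[:, :lag] = w[:, -lag:]
    return out


def _max_lag_correlation(
    wa: np.ndarray, wb: np.ndarray, max_lag: int
) -> float:
    """Normalized cross-correlation of the channel-concatenated waveforms
    at the lag of maximal magnitude; the signed value is returned."""
    na = np.linalg.norm(wa)
    best = 0.0
    for lag in range(-max_lag, max_lag + 1):
        shifted = _shift(wb, lag)
        nb = np.linalg.norm(shifted)
        if na == 0 or nb == 0:
            continue
        r = float(np.sum(wa * shifted) / (na * nb))
        if abs(r) > abs(best):
            best = r
    return best


def match_units(
    bank_a: MUAPTemplateBank,
    bank_b: MUAPTemplateBank,
    noise_sd: np.ndarray | float,
    match_threshold: float = 0.8,
    channel_rule: float = 1.25,
    max_lag: int | None = None,
) -> MatchResult:
    """Pairwise template comparison with the noise-gated channel rule.

    Channels enter the comparison when either waveform's peak absolute
    amplitude exceeds ``channel_rule`` times the baseline noise SD; the
    admissible channels' waveforms are concatenated and correlated at the
    best lag (searched over +/- half the template length by default). A
    pair is deemed the same motor unit when the correlation exceeds
    ``match_threshold``. The merged registry maps ("a", uid)/("b", uid) to
    a merged unit index via transitive closure, resolving conflicts by
    highest correlation first.
    """
    if bank_a.template_length != bank_b.template_length:
        raise InvalidInputError("template lengths differ between banks")
    length = bank_a.template_length
    n_channels = next(iter(bank_a.templates.values())).shape[0]
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_channels,))
    if max_lag is None:
        max_lag = length // 2

    pairs: list[MatchPair] = []
    for ua in bank_a.unit_ids:
        wa_full = bank_a.templates[ua]
        for ub in bank_b.unit_ids:
            wb_full = bank_b.templates[ub]
            peak = np.maximum(
                np.max(np.abs(wa_full), axis=1), np.max(np.abs(wb_full), axis=1)
            )
            channels = np.flatnonzero(peak > channel_rule * noise_sd)
            if channels.size == 0:
                pairs.append(
                    MatchPair(ua, ub, float("nan"), channels, False, "no admissible channels")
                )
                continue
            r = _max_lag_correlation(wa_full[channels], wb_full[channels], max_lag)
            pairs.append(MatchPair(ua, ub, r, channels, r > match_threshold))

    # transitive closure, best correlations first
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in sorted(
        (p for p in pairs if p.matched), key=lambda p: p.correlation, reverse=True
    ):
        ra, rb = find(("a", p.unit_a)), find(("b", p.unit_b))
        if ra != rb:
            parent[rb] = ra
    registry: dict[tuple[str, int], int] = {}
    roots: dict[tuple[str, int], int] = {}
    for side, bank in (("a", bank_a), ("b", bank_b)):
        for uid in bank.unit_ids:
            root = find((side, uid))
            registry[(side, uid)] = roots.setdefault(root, len(roots))
    return MatchResult(pairs=pairs, registry=registry)


# ---------------------------------------------------------------------------
# comparison feature sets


def assemble_feature_set(
    kind: str,
    dsc: FeatureMatrix,
    residual_td: FeatureMatrix | None = None,
    pca_variance: float = 0.98,
    train_rows: np.ndarray | None = None,
) -> tuple[FeatureMatrix, PCABasis | None]:
    """Build one of the comparison feature sets.

    AM1 = [DSC || residual TD] with a single joint PCA; AM2 = DSC with
    PCA; DSC_for_model = raw DSC (no PCA) for the activation model. The
    PCA basis is fit on ``train_rows`` only (all rows when None) and
    applied everywhere.
    """
    kind = kind.upper()
    if kind == "AM1":
        if residual_td is None:
            raise InvalidInputError("AM1 requires residual TD features")
        if not np.array_equal(dsc.window_end_sample, residual_td.window_end_sample):
            raise InvalidInputError("DSC and residual TD window axes differ")
        combined = FeatureMatrix(
            values=np.concatenate([dsc.values, residual_td.values], axis=1),
            window_end_sample=dsc.window_end_sample,
            labels=dsc.labels + residual_td.labels,
        )
    elif kind == "AM2":
        combined = dsc
    elif kind == "DSC_FOR_MODEL":
        return dsc, None
    else:
        raise InvalidInputError(f"unknown feature set kind {kind!r}")

    rows = train_rows if train_rows is not None else np.arange(combined.n_windows)
    train = FeatureMatrix(
        values=combined.values[rows],
        window_end_sample=combined.window_end_sample[rows],
        labels=combined.labels,
    )
    basis = fit_pca(train, variance=pca_variance)
    return apply_pca(basis, combined), basis
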