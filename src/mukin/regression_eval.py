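"""Linear regression to 3-DoF wrist angles, CV protocol and comparison.

Any feature set (TD, AM1, AM2 or the proposed activation-based set) is
mapped to the three joint angles by ordinary least squares with intercept;
the final estimate is the median of three consecutive regression outputs.
Performance is the per-DoF coefficient of determination R^2 on held-out
ramps, under repeated 3-fold leave-one-ramp-out cross-validation: in each
fold one trial of each DoF is held out and every stage parameter (channel
mask, noise thresholds, STA templates, PCA bases, DoF assignments,
g-functions, regression weights) is fit on the remaining trials only.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activation_model as am
from . import features_neural as fn
from . import features_td as ftd
from .errors import InvalidInputError, UnsupportedDesignError
from .types import N_DOFS, EMGRecording, FeatureMatrix, SpikeTrainSet
from .simulator import Session

FEATURE_KINDS = ("TD", "AM1", "AM2", "PROPOSED")


# ---------------------------------------------------------------------------
# regression primitives


@dataclass
class RegressionModel:
    """Fixed linear map: features (k) -> 3 DoF angles (degrees)."""

    weights: np.ndarray  # (k, 3)
    intercept: np.ndarray  # (3,)
    feature_kind: str = ""
    rank: int = -1


def fit(features: FeatureMatrix | np.ndarray, targets: np.ndarray, kind: str = "") -> RegressionModel:
    """Ordinary least squares per DoF with intercept.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("feature and target row counts differ")
    design = np.column_stack([np.ones(X.shape[0]), X])
    beta, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
    if rank < design.shape[1]:
        _warnings.warn(
            f"rank-deficient design ({rank} < {design.shape[1]}): minimum-norm fit",
            stacklevel=2,
        )
    return RegressionModel(weights=beta[1:], intercept=beta[0], feature_kind=kind, rank=int(rank))


def predict(model: RegressionModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Linear map plus intercept; no clipping."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    if X.shape[1] != model.weights.shape[0]:
        raise InvalidInputError("feature dimension does not match the model")
    return X @ model.weights + model.intercept


def median3(predictions: np.ndarray) -> np.ndarray:
    """Median of three consecutive outputs, per DoF independently.

    The first two outputs use the available prefix (median of one, then of
    two values).
    """
    P = np.asarray(predictions, dtype=float)
    squeeze = P.ndim == 1
    if squeeze:
        P = P[:, None]
    out = np.empty_like(P)
    if P.shape[0] >= 1:
        out[0] = P[0]
    if P.shape[0] >= 2:
        out[1] = np.median(P[:2], axis=0)
    if P.shape[0] >= 3:
        stacked = np.stack([P[:-2], P[1:-1], P[2:]])
        out[2:] = np.median(stacked, axis=0)
    return out[:, 0] if squeeze else out


def r_squared(estimates: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-DoF coefficient of determination and its mean over DoFs.

    R^2 = 1 - SS_res/SS_tot with SS_tot about the test-trace mean; a DoF
    with zero-variance truth is undefined (NaN) and excluded from the
    mean.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float).T).T
    tru = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    if est.shape != tru.shape:
        raise InvalidInputError("estimate and truth shapes differ")
    if est.shape[0] < 2:
        raise InvalidInputError("need at least 2 windows to score")
    ss_res = np.sum((tru - est) ** 2, axis=0)
    ss_tot = np.sum((tru - tru.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot > 0, r2, np.nan)
    mean = float(np.nanmean(r2)) if np.any(np.isfinite(r2)) else float("nan")
    return r2, mean


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CVPlan:
    """folds[repeat][fold] = list of held-out (dof, trial_id) pairs."""

    folds: list[list[list[tuple[int, int]]]]
    seed: int

    @property
    def repeats(self) -> int:
        return len(self.folds)


def make_cv_plan(segmentation, repeats: int = 10, seed: int = 0) -> CVPlan:
    """Random leave-one-ramp-per-DoF 3-fold plan, repeated.

    Requires exactly three trials per DoF (the experimental design); in
    each repeat a random bijection maps each DoF's trials onto the three
    folds, so every ramp is tested exactly once per repeat.
    """
    trials = segmentation.trials()
    per_dof: dict[int, list[int]] = {}
    for row in trials.itertuples():
        per_dof.setdefault(int(row.dof), []).append(int(row.trial_id))
    for dof, ids in per_dof.items():
        if len(ids) != 3:
            raise UnsupportedDesignError(
                f"DoF {dof} has {len(ids)} trials; the design requires exactly 3"
            )
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(repeats):
        assignment: list[list[tuple[int, int]]] = [[], [], []]
        for dof in sorted(per_dof):
            perm = rng.permutation(3)
            for fold, k in enumerate(perm):
                assignment[fold].append((dof, per_dof[dof][k]))
        folds.append(assignment)
    return CVPlan(folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# session artifacts shared across folds


@dataclass
class EvalConfig:
    window: ftd.WindowSpec = field(default_factory=ftd.WindowSpec)
    pca_variance: float = 0.98
    exclusion_factor: float = 5.0
    min_spikes: int = 10
    min_abs_corr: float = 0.2
    template_length: int = 51
    a0: float = 0.0


@dataclass
class SessionArtifacts:
    """Fold-independent, target-free precomputation for one session."""

    emg_filtered: EMGRecording
    spikes: SpikeTrainSet
    segmentation: object
    intervals: np.ndarray  # (R, 2) window sample spans
    targets: np.ndarray  # (3, R) mean angle per window
    window_trial: np.ndarray  # (R, 2) (dof, trial_id) per window
    rest_mask: np.ndarray  # per-sample rest indicator
    dsc: FeatureMatrix
    ramp_duration: float
    config: EvalConfig


def prepare_artifacts(session: Session, config: EvalConfig | None = None) -> SessionArtifacts:
    config = config or EvalConfig()
    filtered = ftd.bandpass(session.emg)
    n = filtered.n_samples
    fs = filtered.sample_rate
    intervals = ftd.segment(n, config.window, fs)
    if intervals.shape[0] < 2:
        raise InvalidInputError("session too short for the window schedule")

    angles = session.kinematics.angles
    cs = np.concatenate([np.zeros((N_DOFS, 1)), np.cumsum(angles, axis=1)], axis=1)
    w = intervals[0, 1] - intervals[0, 0]
    targets = (cs[:, intervals[:, 1]] - cs[:, intervals[:, 0]]) / w

    rest_mask = np.all(np.abs(angles) < 1e-9, axis=0)

    rec = session.segmentation.records.sort_values("start_sample").reset_index(drop=True)
    starts = rec["start_sample"].to_numpy()
    last = intervals[:, 1] - 1
    ridx = np.clip(np.searchsorted(starts, last, side="right") - 1, 0, len(rec) - 1)
    window_trial = np.stack(
        [rec["dof"].to_numpy()[ridx], rec["trial_id"].to_numpy()[ridx]], axis=1
    )

    dsc = fn.spike_counts(session.spikes, config.window, n, fs)
    return SessionArtifacts(
        emg_filtered=filtered,
        spikes=session.spikes,
        segmentation=session.segmentation,
        intervals=intervals,
        targets=targets,
        window_trial=window_trial,
        rest_mask=rest_mask,
        dsc=dsc,
        ramp_duration=session.config.ramp_duration,
        config=config,
    )


def fold_rows(art: SessionArtifacts, held_out: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """(train_rows, test_rows) window indices for one fold."""
    held = set(held_out)
    is_test = np.array(
        [(int(d), int(t)) in held for d, t in art.window_trial], dtype=bool
    )
    return np.flatnonzero(~is_test), np.flatnonzero(is_test)


def _train_spans(art: SessionArtifacts, held_out: list[tuple[int, int]]) -> list[tuple[int, int]]:
    held = set(held_out)
    spans = []
    for row in art.segmentation.records.itertuples():
        if (int(row.dof), int(row.trial_id)) not in held:
            spans.append((int(row.start_sample), int(row.end_sample)))
    return spans


def _span_mask(n: int, spans: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in spans:
        mask[s:e] = True
    return mask


# ---------------------------------------------------------------------------
# per-fold model fitting (all stage parameters from training ramps only)


@dataclass
class FoldModel:
    """Everything fit on one training fold, for one feature kind."""

    kind: str
    channel_mask: np.ndarray
    zc_thresholds: np.ndarray
    ssc_thresholds: np.ndarray
    pca: ftd.PCABasis | None
    assignment: am.DoFAssignment | None
    g_functions: dict[int, am.GFunction] | None
    regression: RegressionModel
    features: FeatureMatrix  # full-session features under this fold's model
    notes: list[str] = field(default_factory=list)


def fit_fold(
    art: SessionArtifacts,
    kind: str,
    held_out: list[tuple[int, int]],
    targets: np.ndarray | None = None,
    _ctx: dict | None = None,
) -> FoldModel:
    """Fit one feature kind on the training ramps of one fold.

    ``targets`` defaults to the artifact's windowed angles; it is a
    parameter so the no-leakage property (test-window targets never touch
    training) is directly testable. ``_ctx`` optionally shares the heavy
    fold-level intermediates (channel mask, thresholds, residual TD)
    across kinds evaluated on the same fold.
    """
    kind = kind.upper()
    if kind not in FEATURE_KINDS:
        raise InvalidInputError(f"unknown feature kind {kind!r}")
    cfg = art.config
    if targets is None:
        targets = art.targets
    train_rows, _ = fold_rows(art, held_out)
    spans = _train_spans(art, held_out)
    ctx = _ctx if _ctx is not None else {}
    notes: list[str] = []

    if "channel_mask" not in ctx:
        train_mask = _span_mask(art.emg_filtered.n_samples, spans)
        train_emg = art.emg_filtered.with_samples(art.emg_filtered.samples[:, train_mask])
        masked = ftd.exclude_channels(train_emg, factor=cfg.exclusion_factor)
        ctx["channel_mask"] = masked.bad_channel_mask
        rest_train = art.rest_mask & train_mask
        full_scale = float(np.max(np.abs(art.emg_filtered.samples[:, train_mask]))) or 1.0
        zc, ssc = ftd.rest_noise_thresholds(
            art.emg_filtered, rest_train, full_scale=full_scale
        )
        ctx["zc"], ctx["ssc"] = zc, ssc
    channel_mask = ctx["channel_mask"]
    zc, ssc = ctx["zc"], ctx["ssc"]

    def td_of(recording: EMGRecording) -> FeatureMatrix:
        rec = recording.with_samples(recording.samples)
        rec.bad_channel_mask = channel_mask.copy()
        return ftd.extract_td(
            rec, cfg.window, ftd.TDFeatureConfig(zc_threshold=zc, ssc_threshold=ssc)
        )

    pca = None
    assignment = None
    g_functions = None

    if kind == "TD":
        if "td_features" not in ctx:
            ctx["td_features"] = td_of(art.emg_filtered)
        raw = ctx["td_features"]
        pca = ftd.fit_pca(
            FeatureMatrix(raw.values[train_rows], raw.window_end_sample[train_rows], raw.labels),
            variance=cfg.pca_variance,
        )
        features = ftd.apply_pca(pca, raw)
    else:
        if kind in ("AM1", "PROPOSED") and "residual_td" not in ctx:
            train_spikes = art.spikes.restrict(spans)
            bank, skipped = fn.sta_template_bank(
                art.emg_filtered,
                train_spikes,
                template_length=cfg.template_length,
                min_spikes=cfg.min_spikes,
            )
            if bank is None:
                raise InvalidInputError("no unit has enough training discharges for STA")
            if skipped:
                notes.append(f"STA skipped units {skipped}")
            covered = SpikeTrainSet(
                {u: art.spikes.trains[u] for u in bank.unit_ids},
                provenance=art.spikes.provenance,
            )
            recon = fn.reconstruct_emg(
                covered, bank, art.emg_filtered.n_samples, art.emg_filtered
            )
            ctx["residual_td"] = td_of(fn.residual(art.emg_filtered, recon))

        if kind == "AM2":
            features, pca = fn.assemble_feature_set(
                "AM2", art.dsc, pca_variance=cfg.pca_variance, train_rows=train_rows
            )
        elif kind == "AM1":
            features, pca = fn.assemble_feature_set(
                "AM1",
                art.dsc,
                residual_td=ctx["residual_td"],
                pca_variance=cfg.pca_variance,
                train_rows=train_rows,
            )
        else:  # PROPOSED
            assignment = am.assign_dof(
                FeatureMatrix(
                    art.dsc.values[train_rows],
                    art.dsc.window_end_sample[train_rows],
                    art.dsc.labels,
                ),
                targets[:, train_rows],
                min_abs_corr=cfg.min_abs_corr,
            )
            g_functions = {}
            col = {int(l.removeprefix("unit")): k for k, l in enumerate(art.dsc.labels)}
            for uid, (dof, _) in list(assignment.assignments.items()):
                try:
                    g_functions[uid] = am.fit_g(
                        art.dsc.values[train_rows, col[uid]],
                        targets[dof, train_rows],
                        unit_id=uid,
                    )
                except (am.DegenerateInputError, am.InsufficientDataError) as exc:
                    assignment.excluded[uid] = str(exc)
                    del assignment.assignments[uid]
            activations, warn = am.compute_activations(
                art.dsc, assignment, g_functions, a0=cfg.a0
            )
            notes.extend(warn)
            res_raw = ctx["residual_td"]
            pca = ftd.fit_pca(
                FeatureMatrix(
                    res_raw.values[train_rows],
                    res_raw.window_end_sample[train_rows],
                    res_raw.labels,
                ),
                variance=cfg.pca_variance,
            )
            res_proj = ftd.apply_pca(pca, res_raw)
            features = am.neural_feature_matrix(activations, res_proj)

    regression = fit(
        FeatureMatrix(
            features.values[train_rows], features.window_end_sample[train_rows], features.labels
        ),
        targets[:, train_rows].T,
        kind=kind,
    )
    return FoldModel(
        kind=kind,
        channel_mask=channel_mask,
        zc_thresholds=zc,
        ssc_thresholds=ssc,
        pca=pca,
        assignment=assignment,
        g_functions=g_functions,
        regression=regression,
        features=features,
        notes=notes,
    )


def score_fold(
    model: FoldModel, art: SessionArtifacts, held_out: list[tuple[int, int]]
) -> tuple[np.ndarray, float]:
    """Held-out R^2 per DoF after median-of-three smoothing.

    Smoothing runs within each contiguous held-out window run (strict
    online semantics: only past regression outputs enter the median).
    """
    _, test_rows = fold_rows(art, held_out)
    if test_rows.size < 2:
        raise InvalidInputError("held-out set has fewer than 2 windows")
    preds = predict(model.regression, model.features)
    smoothed = []
    breaks = np.flatnonzero(np.diff(test_rows) > 1) + 1
    for run in np.split(test_rows, breaks):
        smoothed.append(median3(preds[run]))
    est = np.concatenate(smoothed, axis=0)
    truth = art.targets[:, test_rows].T
    return r_squared(est, truth)


# ---------------------------------------------------------------------------
# full comparison


@dataclass
class EvaluationReport:
    """Per-cell R^2 plus aggregation helpers.

    ``cells`` columns: kind, ramp_duration_s, repeat, fold, dof, r2.
    """

    cells: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def aggregate(self, by: tuple[str, ...] = ("kind", "ramp_duration_s")) -> pd.DataFrame:
        g = self.cells.dropna(subset=["r2"]).groupby(list(by))["r2"]
        out = g.agg(mean_r2="mean", sd_r2="std", n_cells="count").reset_index()
        return out

    def mean_r2(self, kind: str) -> float:
        sel = self.cells[self.cells.kind == kind.upper()]["r2"]
        return float(sel.dropna().mean())


def run_comparison(
    session: Session,
    kinds: tuple[str, ...] = FEATURE_KINDS,
    plan: CVPlan | None = None,
    config: EvalConfig | None = None,
    repeats: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated 3-fold leave-one-ramp-out comparison of feature sets.

    For each repeat x fold, every stage parameter is fit on the training
    ramps only and R^2 is measured on the held-out ramps after smoothing.
    Stage failures are recorded per cell (NaN) rather than aborting the
    run.
    """
    config = config or EvalConfig(template_length=session.config.template_length)
    art = prepare_artifacts(session, config)
    if plan is None:
        plan = make_cv_plan(session.segmentation, repeats=repeats, seed=seed)
    kinds = tuple(k.upper() for k in kinds)

    rows = []
    notes: list[str] = []
    for rep, fold_list in enumerate(plan.folds):
        for fold, held_out in enumerate(fold_list):
            ctx: dict = {}
            for kind in kinds:
                try:
                    model = fit_fold(art, kind, held_out, _ctx=ctx)
                    per_dof, _ = score_fold(model, art, held_out)
                    notes.extend(f"[{kind} r{rep} f{fold}] {n}" for n in model.notes)
                except Exception as exc:  # recorded, not fatal
                    notes.append(f"[{kind} r{rep} f{fold}] failed: {exc}")
                    per_dof = np.full(N_DOFS, np.nan)
                for dof in range(N_DOFS):
                    rows.append(
                        dict(
                            kind=kind,
                            ramp_duration_s=art.ramp_duration,
                            repeat=rep,
                            fold=fold,
                            dof=dof,
                            r2=per_dof[dof],
                        )
                    )
    return EvaluationReport(cells=pd.DataFrame(rows), notes=notes)


def concat_reports(reports: list[EvaluationReport]) -> EvaluationReport:
    return EvaluationReport(
        cells=pd.concat([r.cells for r in reports], ignore_index=True),
        notes=[n for r in reports for n in r.notes],
    )
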