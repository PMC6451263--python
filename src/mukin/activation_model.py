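"""Model-based dimensionality reduction of motor-unit spike trains.

Motor neurons of a pool share a large part of their synaptic input, so
each unit's discharge pattern is an independent, noisy view of one common
drive. The model inverts this: for each unit j assigned to DoF i, a linear
map g_ij from the unit's windowed spike counts x_ij to the joint angle is
estimated by robust regression (iteratively reweighted least squares with
the Tukey bisquare weight), giving a per-window synaptic-input proxy
alpha_ij = g_ij(x_ij). Units are assigned to the DoF whose angle series
correlates most strongly (in magnitude) with their count series. The pool
activation is the recursive median

    a_i[r] = median(alpha_i1[r], ..., alpha_in[r], a_i[r-1])

which is robust to up to floor((n-1)/2) corrupted unit estimates per
window and, through the a_i[r-1] term, smooth over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    EmptyPoolError,
    InsufficientDataError,
    InvalidInputError,
)
from .types import N_DOFS, FeatureMatrix

BISQUARE_C = 4.685  # 95% Gaussian efficiency


@dataclass
class GFunction:
    """Linear spike-count -> joint-angle map for one unit."""

    unit_id: int
    slope: float  # degrees per (spikes/window)
    intercept: float  # degrees
    iterations: int = 0
    converged: bool = True

    def __call__(self, counts: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(counts, dtype=float) + self.intercept


@dataclass
class DoFAssignment:
    """unit_id -> (dof_index, signed Pearson correlation)."""

    assignments: dict[int, tuple[int, float]]
    excluded: dict[int, str] = field(default_factory=dict)

    def units_for_dof(self, dof: int) -> list[int]:
        return sorted(u for u, (d, _) in self.assignments.items() if d == dof)


@dataclass
class PoolActivation:
    """Per-window pool activation a_i[r] for one DoF (degrees)."""

    dof: int
    values: np.ndarray
    a0: float = 0.0
    empty_pool: bool = False


# ---------------------------------------------------------------------------
# DoF assignment


def assign_dof(
    dsc: FeatureMatrix,
    window_angles: np.ndarray,
    min_abs_corr: float = 0.2,
) -> DoFAssignment:
    """Associate each unit to the DoF with the highest |correlation|.

    ``window_angles`` is (n_dofs, n_windows), aligned to the DSC windows.
    Units with a zero-variance count series, or whose best correlation
    magnitude falls below ``min_abs_corr``, are flagged unassignable.
    """
    window_angles = np.asarray(window_angles, dtype=float)
    if window_angles.ndim != 2 or window_angles.shape[0] != N_DOFS:
        raise InvalidInputError("window_angles must be (3, n_windows)")
    if window_angles.shape[1] != dsc.n_windows:
        raise InvalidInputError("kinematics windows do not align with DSC windows")
    if dsc.n_windows < 2:
        raise InvalidInputError("need at least 2 windows for correlation")

    assignments: dict[int, tuple[int, float]] = {}
    excluded: dict[int, str] = {}
    ang = window_angles - window_angles.mean(axis=1, keepdims=True)
    ang_norm = np.linalg.norm(ang, axis=1)
    for k, label in enumerate(dsc.labels):
        uid = int(label.removeprefix("unit")) if label.startswith("unit") else k
        x = dsc.values[:, k]
        xc = x - x.mean()
        xn = np.linalg.norm(xc)
        if xn == 0:
            excluded[uid] = "zero-variance count series"
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (ang @ xc) / (ang_norm * xn)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        best = int(np.argmax(np.abs(corr)))
        if abs(corr[best]) < min_abs_corr:
            excluded[uid] = f"max |correlation| {abs(corr[best]):.3f} below {min_abs_corr}"
            continue
        assignments[uid] = (best, float(corr[best]))
    return DoFAssignment(assignments=assignments, excluded=excluded)


# ---------------------------------------------------------------------------
# robust linear fit


def _bisquare_weights(resid: np.ndarray, scale: float, c: float = BISQUARE_C) -> np.ndarray:
    u = resid / (c * scale)
    w = np.zeros_like(u)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    return w


def fit_g(
    counts: np.ndarray,
    angles: np.ndarray,
    unit_id: int = -1,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> GFunction:
    """Robust linear regression of joint angle on windowed spike counts.

    Iteratively reweighted least squares with the Tukey bisquare weight
    (tuning constant 4.685 x robust scale, scale = MAD/0.6745 of the
    residuals), at most ``max_iter`` iterations, relative parameter
    tolerance ``tol``. Initialization is ordinary least squares.
    """
    x = np.asarray(counts, dtype=float)
    y = np.asarray(angles, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("counts and angles must be equal-length 1-D series")
    if x.size < 10:
        raise InsufficientDataError("need at least 10 windows to fit g")
    if np.unique(x).size < 2:
        raise DegenerateInputError("constant count series: g is unidentifiable")

    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        resid = y - X @ beta
        # MAD about zero (residuals are nominally centered): robust to an
        # initial fit displaced by gross outliers
        scale = np.median(np.abs(resid)) / 0.6745
        if scale <= np.finfo(float).tiny:
            converged = True  # (near-)exact fit
            break
        w = _bisquare_weights(resid, scale)
        if np.unique(x[w > 0]).size < 2:
            break  # surviving weights cannot identify a line; keep estimate
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) <= tol * max(1.0, np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return GFunction(
        unit_id=unit_id,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        iterations=iterations,
        converged=converged,
    )


def estimate_alpha(g: GFunction, counts: np.ndarray) -> np.ndarray:
    """Per-window synaptic-input proxy alpha = g(counts), in degrees."""
    return g(counts)


# ---------------------------------------------------------------------------
# median pooling


def combine_median(alphas: np.ndarray, a0: float = 0.0) -> np.ndarray:
    """Recursive median pooling of n unit series.

    ``alphas`` is (n_units, n_windows); the output at window r is the
    median of the n alpha values and the previous output (a0 before the
    first window). Even-cardinality medians are the mean of the two
    central order statistics.
    """
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    if alphas.shape[0] == 0:
        raise EmptyPoolError("no unit series to combine")
    n, r_total = alphas.shape
    out = np.empty(r_total)
    prev = float(a0)
    buf = np.empty(n + 1)
    for r in range(r_total):
        buf[:n] = alphas[:, r]
        buf[n] = prev
        prev = float(np.median(buf))
        out[r] = prev
    return out


def compute_activations(
    dsc: FeatureMatrix,
    assignment: DoFAssignment,
    g_functions: dict[int, GFunction],
    a0: float = 0.0,
) -> tuple[list[PoolActivation], list[str]]:
    """Per-DoF activation series from the fitted unit models.

    Units are pooled by assigned DoF; a DoF with an empty pool emits the
    constant ``a0`` with a warning flag.
    """
    col_of_unit = {}
    for k, label in enumerate(dsc.labels):
        uid = int(label.removeprefix("unit")) if label.startswith("unit") else k
        col_of_unit[uid] = k

    warnings: list[str] = []
    activations: list[PoolActivation] = []
    any_pool = False
    for dof in range(N_DOFS):
        uids = [
            u
            for u in assignment.units_for_dof(dof)
            if u in g_functions and u in col_of_unit
        ]
        if not uids:
            warnings.append(f"DoF {dof}: empty pool, emitting constant a0={a0}")
            activations.append(
                PoolActivation(
                    dof=dof,
                    values=np.full(dsc.n_windows, float(a0)),
                    a0=a0,
                    empty_pool=True,
                )
            )
            continue
        any_pool = True
        alphas = np.stack(
            [estimate_alpha(g_functions[u], dsc.values[:, col_of_unit[u]]) for u in uids]
        )
        activations.append(
            PoolActivation(dof=dof, values=combine_median(alphas, a0=a0), a0=a0)
        )
    if not any_pool:
        raise EmptyPoolError("all DoF pools are empty")
    return activations, warnings


def neural_feature_matrix(
    activations: list[PoolActivation], residual_td: FeatureMatrix
) -> FeatureMatrix:
    """The proposed feature set: [a_1, a_2, a_3 || residual TD (after PCA)]."""
    if len(activations) != N_DOFS:
        raise InvalidInputError("need one activation series per DoF")
    r = residual_td.n_windows
    for act in activations:
        if act.values.size != r:
            raise InvalidInputError("activation windows do not align with residual TD")
    act_block = np.stack([a.values for a in sorted(activations, key=lambda a: a.dof)], axis=1)
    return FeatureMatrix(
        values=np.concatenate([act_block, residual_td.values], axis=1),
        window_end_sample=residual_td.window_end_sample,
        labels=[f"activation_dof{d + 1}" for d in range(N_DOFS)] + residual_td.labels,
    )
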