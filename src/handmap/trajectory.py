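"""Trajectory-matching templates, trial validation, and motor-error scoring.

Templates are curves x = alpha*y + beta*sin(pi*y) with y in [0, 1],
where one unit of y spans 211 mm of workspace depth; alpha sets the
overall direction of the movement and |beta| its curvature.  A movement
trace is scored against its template by interpolating the trace's
x-position at the 30 evenly spaced depth cut points y_k = k/30
(k = 1..30) and taking the square root of the SUM of squared horizontal
deviations — the motor-error score is deliberately the unnormalized
root-sum-square, in cm; a root-mean-square variant is available behind
``normalized=True``.

The module also computes trajectory-specific localization errors from a
subject's error map: on each grid row, the two column-targets whose x
positions laterally "sandwich" the template at that row's depth (ten
targets per trajectory), or just the two far-row targets bracketing the
movement endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import TargetGrid, make_target_grid

__all__ = [
    "TrajectoryTemplate",
    "TrajectoryScore",
    "make_template",
    "default_template_set",
    "validate_trial",
    "trajectory_rmse",
    "endpoint_error",
    "sandwich_targets",
    "local_localization_error",
    "endpoint_localization_error",
    "score_trials",
    "subject_dummy_regression",
    "motor_vs_localization_correlation",
]

N_SEGMENTS = 30
MIN_SPEED_MM_S = 165.0
MM_PER_CM = 10.0


@dataclass(frozen=True)
class TrajectoryTemplate:
    """Target curve x(y) = alpha*y + beta*sin(pi*y), y in unit depth."""

    alpha: float
    beta: float
    scale: float = 211.0  # mm of workspace depth per unit y

    def __call__(self, y_unit: np.ndarray | float) -> np.ndarray | float:
        """Template x-position in mm at unit depth(s) y."""
        y = np.asarray(y_unit, dtype=float)
        x = (self.alpha * y + self.beta * np.sin(np.pi * y)) * self.scale
        return float(x) if np.isscalar(y_unit) else x

    @property
    def curvature(self) -> float:
        return abs(self.beta)


def make_template(alpha: float, beta: float, scale: float = 211.0) -> TrajectoryTemplate:
    """Build a template curve; x(0)=0 and x(1)=alpha*scale always."""
    return TrajectoryTemplate(alpha=alpha, beta=beta, scale=scale)


def default_template_set() -> list[TrajectoryTemplate]:
    """The 15-template set of the formal task.

    Fifteen (alpha, beta) pairs spanning alpha in [-1, 1] and beta in
    [-0.9, 0.8].  The individual pairs are a regular 5 x 3 grid over
    those ranges — a documented stand-in, since only the ranges and the
    count are prescribed.  The familiarization pair (0, 0.1) is not in
    the set.
    """
    alphas = [-1.0, -0.5, 0.0, 0.5, 1.0]
    betas = [-0.9, -0.05, 0.8]
    return [make_template(a, b) for a in alphas for b in betas]


@dataclass(frozen=True)
class TrajectoryScore:
    """Motor-error scores of one trial (cm) and its validity verdict."""

    rmse: float
    endpoint_error: float
    valid: bool
    reasons: tuple[str, ...] = ()


def validate_trial(
    trace: pd.DataFrame, min_speed: float = MIN_SPEED_MM_S
) -> tuple[bool, list[str]]:
    """Apply the task's validity rules to one movement trace.

    A trial is invalid if the mean movement speed (path length over
    duration) is below ``min_speed`` mm/s, if the depth coordinate ever
    decreases (backward movement), or if movement starts before the go
    cue (samples at t < 0 with depth displacement).  Returns the verdict
    and the list of reason codes among {"slow", "backward", "early-start"}.
    """
    if len(trace) < 2:
        raise ValueError("trace must contain at least two samples")
    t = trace["t_s"].to_numpy(dtype=float)
    x = trace["x_mm"].to_numpy(dtype=float)
    y = trace["y_mm"].to_numpy(dtype=float)
    reasons = []
    pre = t < 0
    if pre.any() and np.ptp(y[pre]) > 0:
        reasons.append("early-start")
    move = ~pre
    dt = t[move][-1] - t[move][0]
    path = np.hypot(np.diff(x[move]), np.diff(y[move])).sum()
    if dt <= 0 or path / dt < min_speed:
        reasons.append("slow")
    if np.any(np.diff(y[move]) < 0):
        reasons.append("backward")
    return (not reasons), reasons


def _cut_point_x(trace: pd.DataFrame, scale: float) -> np.ndarray:
    """x (mm) linearly interpolated at the 30 depth cut points.

    Cut points sit at y = k/30 for k = 1..30: the start point, where all
    curves coincide at x = 0, carries no information and is excluded,
    while the endpoint is included.
    """
    y = trace["y_mm"].to_numpy(dtype=float) / scale
    x = trace["x_mm"].to_numpy(dtype=float)
    cuts = np.arange(1, N_SEGMENTS + 1) / N_SEGMENTS
    if y[-1] < cuts[-1] - 1e-9:
        raise ValueError(
            f"trace ends at unit depth {y[-1]:.3f}, before the final cut point"
        )
    # np.interp needs increasing y; validity filtering guarantees monotone depth
    return np.interp(cuts, y, x)


def trajectory_rmse(
    trace: pd.DataFrame,
    template: TrajectoryTemplate,
    normalized: bool = False,
) -> float:
    """Motor error of one trace against its template, cm.

    Root of the sum of squared horizontal deviations at the 30 cut
    points (root-mean-square with ``normalized=True``).  A constant
    offset of d cm at every cut point therefore scores d*sqrt(30).
    """
    cuts = np.arange(1, N_SEGMENTS + 1) / N_SEGMENTS
    dx_cm = (_cut_point_x(trace, template.scale) - template(cuts)) / MM_PER_CM
    ss = float((dx_cm**2).sum())
    return np.sqrt(ss / N_SEGMENTS) if normalized else float(np.sqrt(ss))


def endpoint_error(trace: pd.DataFrame, template: TrajectoryTemplate) -> float:
    """Absolute horizontal deviation at the final cut point (y = 1), cm.

    Because sin(pi) = 0, the endpoint is immune to the template's beta:
    only deviations from the alpha-determined endpoint register.
    """
    x_end = _cut_point_x(trace, template.scale)[-1]
    return float(abs(x_end - template(1.0)) / MM_PER_CM)


def sandwich_targets(
    template: TrajectoryTemplate, grid: TargetGrid | None = None
) -> list[tuple[int, int]]:
    """The ten (row, col) 0-based targets sandwiching a template.

    On each grid row the template's x at that row's depth is bracketed
    by the two nearest column-targets on either side; when the template
    runs laterally outside the grid, the two nearest columns on that
    side are used instead.
    """
    g = grid or make_target_grid()
    out: list[tuple[int, int]] = []
    n_cols = g.geometry.n_cols
    for i, y_mm in enumerate(g.y):
        y_unit = (y_mm - g.geometry.body_offset) / template.scale
        x_t = template(float(np.clip(y_unit, 0.0, 1.0)))
        right = int(np.searchsorted(g.x, x_t))
        if right == 0:
            lo, hi = 0, 1  # template left of the grid: clamp
        elif right >= n_cols:
            lo, hi = n_cols - 2, n_cols - 1  # right of the grid: clamp
        else:
            lo, hi = right - 1, right
        out.extend([(i, lo), (i, hi)])
    return out


def local_localization_error(
    error_map, template: TrajectoryTemplate, grid: TargetGrid | None = None
) -> float:
    """Mean error magnitude (cm) at the 10 targets sandwiching a template."""
    mags = error_map.magnitudes
    sel = sandwich_targets(template, grid)
    return float(np.mean([mags[r, c] for r, c in sel]))


def endpoint_localization_error(
    error_map, template: TrajectoryTemplate, grid: TargetGrid | None = None
) -> float:
    """Mean error magnitude (cm) at the two far-row targets bracketing
    the template endpoint."""
    g = grid or make_target_grid()
    mags = error_map.magnitudes
    far_row = g.geometry.n_rows - 1
    x_end = template(1.0)
    n_cols = g.geometry.n_cols
    right = int(np.searchsorted(g.x, x_end))
    if right == 0:
        lo, hi = 0, 1
    elif right >= n_cols:
        lo, hi = n_cols - 2, n_cols - 1
    else:
        lo, hi = right - 1, right
    return float((mags[far_row, lo] + mags[far_row, hi]) / 2.0)


def score_trials(
    trials: pd.DataFrame,
    templates: Sequence[TrajectoryTemplate] | None = None,
    min_speed: float = MIN_SPEED_MM_S,
) -> pd.DataFrame:
    """Validate and score every trial in a long-format trajectory table.

    Returns one row per (subject_id, session, trial_index) with alpha,
    beta, validity verdict and reasons, and — for valid trials — the
    rmse and endpoint error in cm.
    """
    tpl_index: dict[tuple[float, float], TrajectoryTemplate] = {}
    for tpl in templates or default_template_set():
        tpl_index[(tpl.alpha, tpl.beta)] = tpl
    rows = []
    for (sid, ses, tri), trace in trials.groupby(
        ["subject_id", "session", "trial_index"], sort=True
    ):
        a, b = float(trace["alpha"].iloc[0]), float(trace["beta"].iloc[0])
        tpl = tpl_index.get((a, b)) or make_template(a, b)
        ok, reasons = validate_trial(trace, min_speed)
        rec = {
            "subject_id": sid,
            "session": ses,
            "trial_index": tri,
            "alpha": a,
            "beta": b,
            "valid": ok,
            "reasons": ";".join(reasons),
            "rmse_cm": np.nan,
            "endpoint_error_cm": np.nan,
        }
        if ok:
            rec["rmse_cm"] = trajectory_rmse(trace, tpl)
            rec["endpoint_error_cm"] = endpoint_error(trace, tpl)
        rows.append(rec)
    return pd.DataFrame(rows)


def subject_dummy_regression(
    y: np.ndarray, x: np.ndarray, subject_ids: np.ndarray
) -> dict:
    """Fixed-slope regression of motor error on localization error with
    per-subject intercepts.

    Fits ``y = slope * x + intercept_s`` by least squares with dummy-coded
    subjects; the slope is the fixed effect of interest.  Returns slope,
    its standard error, 95% CI, t and two-sided p with
    df = N - n_subjects - 1.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    subject_ids = np.asarray(subject_ids)
    subjects, idx = np.unique(subject_ids, return_inverse=True)
    n, k = len(y), len(subjects)
    if k < 2:
        raise ValueError("need at least 2 subjects")
    dummies = np.zeros((n, k))
    dummies[np.arange(n), idx] = 1.0
    design = np.column_stack([x, dummies])
    if np.linalg.matrix_rank(design) < k + 1:
        raise ValueError("degenerate design (collinear predictors)")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough observations for inference")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(max(sigma2 * xtx_inv[0, 0], 0.0)))
    slope = float(coef[0])
    if se == 0:
        tval, pval, ci = np.inf if slope else 0.0, 0.0 if slope else 1.0, (slope, slope)
    else:
        tval = slope / se
        pval = float(2 * stats.t.sf(abs(tval), df))
        tcrit = stats.t.ppf(0.975, df)
        ci = (slope - tcrit * se, slope + tcrit * se)
    return {
        "slope": slope,
        "se": se,
        "ci95": (float(ci[0]), float(ci[1])),
        "t": float(tval),
        "p": float(pval),
        "df": int(df),
        "n_subjects": int(k),
    }


def motor_vs_localization_correlation(
    motor: np.ndarray, localization: np.ndarray, method: str = "auto"
) -> dict:
    """Across-subject correlation of mean motor error with mean
    localization error.

    Pearson by default; with ``method='auto'`` a Shapiro normality
    pre-check on both variables switches to Spearman when either fails
    at alpha = 0.05.
    """
    motor = np.asarray(motor, dtype=float)
    localization = np.asarray(localization, dtype=float)
    if len(motor) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(motor) == 0 or np.ptp(localization) == 0:
        raise ValueError("correlation undefined for a constant vector")
    use = method
    if method == "auto":
        normal = (
            stats.shapiro(motor).pvalue >= 0.05
            and stats.shapiro(localization).pvalue >= 0.05
        )
        use = "pearson" if normal else "spearman"
    if use == "pearson":
        r, p = stats.pearsonr(motor, localization)
    elif use == "spearman":
        r, p = stats.spearmanr(motor, localization)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "method": use, "n": len(motor)}
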