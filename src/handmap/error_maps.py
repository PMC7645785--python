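"""Hand-localization error maps and their summary statistics.

An error map collects, for one subject and one measurement session, the
2-D localization error vector at each of the 100 grid targets: the
difference between where the unseen hand actually was and where the
visual target was.  The map is stored as a 2 x n_rows x n_cols array
whose first axis holds the mediolateral (x_e) and depth (y_e) error
components, in cm.  Trial tables arrive in mm; the single mm -> cm
conversion happens here, at the map boundary.

Sign convention: error = hand - target, i.e. the vector's tail sits at
the target and its head at the registered hand position.  A positive
x_e is a rightward localization bias, a positive y_e an overshoot away
from the body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import TargetGrid, make_target_grid

__all__ = [
    "ErrorMap",
    "RegionalSummary",
    "IncompleteMapError",
    "build_error_map",
    "build_all_maps",
    "mean_error_magnitude",
    "regional_errors",
    "error_reduction",
    "average_subject_map",
    "direction_bias_test",
    "binomial_critical_counts",
    "maps_to_frame",
    "frame_to_maps",
]

MM_PER_CM = 10.0


class IncompleteMapError(ValueError):
    """A subject-session block does not contain exactly one trial per target."""


@dataclass
class ErrorMap:
    """Per-subject, per-session matrix of localization error vectors (cm)."""

    errors: np.ndarray  # (2, n_rows, n_cols), cm; [0]=x_e, [1]=y_e
    subject_id: str | int = ""
    session: str | int = ""

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        if self.errors.ndim != 3 or self.errors.shape[0] != 2:
            raise ValueError(
                f"error map must have shape (2, n_rows, n_cols), got {self.errors.shape}"
            )
        if not np.all(np.isfinite(self.errors)):
            raise ValueError("error map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.errors.shape

    @property
    def magnitudes(self) -> np.ndarray:
        """Per-target error-vector magnitude, cm; shape (n_rows, n_cols)."""
        return np.hypot(self.errors[0], self.errors[1])

    def flatten(self) -> np.ndarray:
        """All error components as one vector (x components then y)."""
        return self.errors.reshape(-1)


@dataclass(frozen=True)
class RegionalSummary:
    """Mean error magnitudes (cm) in the canonical workspace regions.

    Left/right split the columns 10/10 at the vertical midline; near
    covers the three rows closest to the body, far the remaining two.
    """

    left: float
    right: float
    near: float
    far: float
    overall: float


def build_error_map(
    trials: pd.DataFrame,
    grid: TargetGrid | None = None,
    *,
    subject_id: str | int | None = None,
    session: str | int | None = None,
) -> ErrorMap:
    """Assemble one subject-session error map from matching trials.

    ``trials`` must hold exactly one row per grid target with columns
    target_row, target_col (1-based), target_x_mm, target_y_mm,
    hand_x_mm, hand_y_mm.  Errors are hand - target, converted to cm.

    Raises
    ------
    IncompleteMapError
        If any target is missing or duplicated; the message names the
        offending (row, col).
    """
    geom = (grid or make_target_grid()).geometry
    n_rows, n_cols = geom.n_rows, geom.n_cols

    counts = np.zeros((n_rows, n_cols), dtype=int)
    errors = np.zeros((2, n_rows, n_cols))
    for rec in trials.itertuples(index=False):
        r, c = int(rec.target_row), int(rec.target_col)
        if not (1 <= r <= n_rows and 1 <= c <= n_cols):
            raise IncompleteMapError(f"target (row={r}, col={c}) outside the grid")
        if counts[r - 1, c - 1]:
            raise IncompleteMapError(f"duplicate trial for target (row={r}, col={c})")
        counts[r - 1, c - 1] = 1
        errors[0, r - 1, c - 1] = (rec.hand_x_mm - rec.target_x_mm) / MM_PER_CM
        errors[1, r - 1, c - 1] = (rec.hand_y_mm - rec.target_y_mm) / MM_PER_CM
    if counts.sum() != n_rows * n_cols:
        r, c = np.argwhere(counts == 0)[0]
        raise IncompleteMapError(f"missing trial for target (row={r + 1}, col={c + 1})")

    sid = subject_id if subject_id is not None else _single_value(trials, "subject_id")
    ses = session if session is not None else _single_value(trials, "session")
    return ErrorMap(errors=errors, subject_id=sid, session=ses)


def _single_value(trials: pd.DataFrame, column: str):
    if column not in trials.columns:
        return ""
    vals = trials[column].unique()
    if len(vals) > 1:
        raise ValueError(f"trials mix several values of {column}: {vals!r}")
    return vals[0]


def build_all_maps(
    trials: pd.DataFrame, grid: TargetGrid | None = None
) -> dict[tuple, ErrorMap]:
    """Build every (subject, session) error map found in a trial table."""
    maps: dict[tuple, ErrorMap] = {}
    for (sid, ses), block in trials.groupby(["subject_id", "session"], sort=True):
        maps[(sid, ses)] = build_error_map(block, grid, subject_id=sid, session=ses)
    return maps


def mean_error_magnitude(error_map: ErrorMap) -> float:
    """Mean over all targets of the error-vector magnitude, cm."""
    return float(error_map.magnitudes.mean())


def regional_errors(error_map: ErrorMap) -> RegionalSummary:
    """Mean error magnitude in the left/right and near/far workspace halves.

    Row 1 is nearest the body: near = rows 1-3, far = rows 4-5.  With a
    20-column grid left = columns 1-10, right = columns 11-20.
    """
    mags = error_map.magnitudes
    n_rows, n_cols = mags.shape
    half = n_cols // 2
    near_rows = int(np.ceil(n_rows * 3 / 5))  # 3 of 5 rows on the default grid
    return RegionalSummary(
        left=float(mags[:, :half].mean()),
        right=float(mags[:, half:].mean()),
        near=float(mags[:near_rows, :].mean()),
        far=float(mags[near_rows:, :].mean()),
        overall=float(mags.mean()),
    )


def error_reduction(error_1: float, error_i: float) -> float:
    """Percentage improvement of session i relative to session 1.

    ``100 * (error_1 - error_i) / error_1``; positive means the later
    session was more accurate.
    """
    if error_1 <= 0:
        raise ValueError("session-1 error must be positive")
    return 100.0 * (error_1 - error_i) / error_1


def average_subject_map(maps: Sequence[ErrorMap]) -> ErrorMap:
    """Component-wise mean of one subject's maps across sessions."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    subjects = {m.subject_id for m in maps}
    if len(subjects) > 1:
        raise ValueError(f"maps mix subjects: {sorted(map(str, subjects))}")
    stacked = np.stack([m.errors for m in maps])
    return ErrorMap(
        errors=stacked.mean(axis=0),
        subject_id=maps[0].subject_id,
        session="mean",
    )


def binomial_critical_counts(
    n: int, p0: float = 0.5, alpha: float = 0.05
) -> tuple[int | None, int | None]:
    """Critical counts of an exact one-tailed binomial test at each tail.

    Returns ``(lower, upper)`` where ``upper`` is the smallest k with
    P(X >= k | Binomial(n, p0)) < alpha and ``lower`` the largest k with
    P(X <= k) < alpha.  For n=26 at p0=0.5 this gives (8, 18): 18 or
    more (or 8 or fewer) subjects biased the same way is significant.
    A tail that cannot attain alpha for any k returns None.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = np.arange(n + 1)
    upper_tail = stats.binom.sf(k - 1, n, p0)  # P(X >= k)
    lower_tail = stats.binom.cdf(k, n, p0)  # P(X <= k)
    upper_ok = np.flatnonzero(upper_tail < alpha)
    lower_ok = np.flatnonzero(lower_tail < alpha)
    upper = int(upper_ok[0]) if upper_ok.size else None
    lower = int(lower_ok[-1]) if lower_ok.size else None
    return lower, upper


def direction_bias_test(
    averaged_maps: Iterable[ErrorMap],
    component: str = "x",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group-level test for a consistent error direction at each target.

    For each target, counts the subjects whose (session-averaged) error
    component is positive and flags targets where that count reaches the
    exact one-tailed binomial criticals against p0=0.5 at either tail.
    A component exactly 0 counts as not-positive (measure zero with
    continuous data).

    Returns a tidy frame with one row per target: row, col, n_subjects,
    n_positive, fraction_positive, significant.
    """
    comp = {"x": 0, "y": 1}.get(component)
    if comp is None:
        raise ValueError("component must be 'x' or 'y'")
    maps = list(averaged_maps)
    if len(maps) < 2:
        raise ValueError("need at least two subjects")
    stacked = np.stack([m.errors[comp] for m in maps])  # (n_subj, rows, cols)
    n = stacked.shape[0]
    n_pos = (stacked > 0).sum(axis=0)
    lower, upper = binomial_critical_counts(n, 0.5, alpha)
    sig = np.zeros_like(n_pos, dtype=bool)
    if upper is not None:
        sig |= n_pos >= upper
    if lower is not None:
        sig |= n_pos <= lower
    rows, cols = np.indices(n_pos.shape)
    return pd.DataFrame(
        {
            "row": rows.ravel() + 1,
            "col": cols.ravel() + 1,
            "n_subjects": n,
            "n_positive": n_pos.ravel(),
            "fraction_positive": n_pos.ravel() / n,
            "significant": sig.ravel(),
        }
    )


def maps_to_frame(maps: Iterable[ErrorMap]) -> pd.DataFrame:
    """Serialize maps to long form (subject_id, session, row, col, x_e_cm, y_e_cm)."""
    records = []
    for m in maps:
        n_rows, n_cols = m.errors.shape[1:]
        rows, cols = np.indices((n_rows, n_cols))
        records.append(
            pd.DataFrame(
                {
                    "subject_id": m.subject_id,
                    "session": m.session,
                    "row": rows.ravel() + 1,
                    "col": cols.ravel() + 1,
                    "x_e_cm": m.errors[0].ravel(),
                    "y_e_cm": m.errors[1].ravel(),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def frame_to_maps(frame: pd.DataFrame) -> dict[tuple, ErrorMap]:
    """Inverse of :func:`maps_to_frame`."""
    maps: dict[tuple, ErrorMap] = {}
    for (sid, ses), block in frame.groupby(["subject_id", "session"], sort=True):
        n_rows = int(block["row"].max())
        n_cols = int(block["col"].max())
        errors = np.zeros((2, n_rows, n_cols))
        r = block["row"].to_numpy() - 1
        c = block["col"].to_numpy() - 1
        errors[0, r, c] = block["x_e_cm"].to_numpy()
        errors[1, r, c] = block["y_e_cm"].to_numpy()
        maps[(sid, ses)] = ErrorMap(errors=errors, subject_id=sid, session=ses)
    return maps
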