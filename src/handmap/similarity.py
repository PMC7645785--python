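"""Within- vs between-subject similarity of hand-localization maps.

The idiosyncrasy question — is a subject's error map more like their own
map in another session than like anybody else's? — is answered by
comparing two pools of similarity values for every session pair (A, B):

* *within*: one value per subject, map(subject, A) vs map(subject, B);
* *between*: all n*(n-1) ordered cross-subject values, map(i, A) vs
  map(j, B) for i != j.

Similarity is either the Pearson correlation over the 200 jointly
flattened error components (x and y concatenated), or the Euclidean
distance between the two 200-component vectors divided by 100 — the
latter implemented exactly as that printed rule, which is a scaled norm
rather than a literal per-target average.

Correlations are Fisher-Z transformed before the within/between Welch
t-test by default; distances are compared with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import stats

from .error_maps import ErrorMap

__all__ = [
    "SessionPairResult",
    "map_correlation",
    "map_distance",
    "within_between_sets",
    "compare_within_between",
    "fisher_z",
    "kendalls_w",
    "distance_trend",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined because a map has zero variance."""


def map_correlation(map_a: ErrorMap, map_b: ErrorMap) -> float:
    """Pearson r between two maps over their 200 flattened components."""
    a, b = map_a.flatten(), map_b.flatten()
    if a.shape != b.shape:
        raise ValueError("maps have different grids")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero-variance error map")
    return float(stats.pearsonr(a, b).statistic)


def map_distance(map_a: ErrorMap, map_b: ErrorMap) -> float:
    """Scaled Euclidean distance between two maps, cm.

    L2 norm of the 200-component difference divided by 100 (the number
    of targets), per the study's stated normalization.
    """
    a, b = map_a.flatten(), map_b.flatten()
    if a.shape != b.shape:
        raise ValueError("maps have different grids")
    n_targets = a.size // 2
    return float(np.linalg.norm(a - b) / n_targets)


@dataclass
class SessionPairResult:
    """Within- and between-subject similarity pools for one session pair."""

    session_a: object
    session_b: object
    metric: str
    within: np.ndarray  # one value per subject
    between: np.ndarray  # n*(n-1) ordered cross-subject values
    subjects: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "session_a": self.session_a,
            "session_b": self.session_b,
            "metric": self.metric,
            "within": [float(v) for v in self.within],
            "between": [float(v) for v in self.between],
            "subjects": [str(s) for s in self.subjects],
        }


_METRICS = {"correlation": map_correlation, "distance": map_distance}


def within_between_sets(
    maps: dict[tuple, ErrorMap],
    session_a,
    session_b,
    metric: str = "correlation",
) -> SessionPairResult:
    """All pairwise similarities between two sessions of a cohort.

    ``maps`` is keyed by (subject_id, session).  Subjects missing either
    session are dropped with a warning.  For n retained subjects the
    result holds n within values and n*(n-1) between values — every
    ordered pairing of distinct subjects (for symmetric metrics the two
    orders coincide in value but both are kept, matching the full
    pairing-matrix construction: within + between = n^2 values).
    """
    func = _METRICS.get(metric)
    if func is None:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    subjects_a = {sid for sid, ses in maps if ses == session_a}
    subjects_b = {sid for sid, ses in maps if ses == session_b}
    subjects = sorted(subjects_a & subjects_b, key=str)
    dropped = (subjects_a | subjects_b) - set(subjects)
    if dropped:
        warnings.warn(
            f"dropping subjects missing a session: {sorted(map(str, dropped))}",
            stacklevel=2,
        )
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects present in both sessions")
    within, between = [], []
    for i in subjects:
        for j in subjects:
            v = func(maps[(i, session_a)], maps[(j, session_b)])
            (within if i == j else between).append(v)
    return SessionPairResult(
        session_a=session_a,
        session_b=session_b,
        metric=metric,
        within=np.asarray(within),
        between=np.asarray(between),
        subjects=subjects,
    )


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's variance-stabilizing transform z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def compare_within_between(
    result: SessionPairResult,
    method: str = "auto",
    transform: bool = True,
) -> dict:
    """Test whether within-subject similarity exceeds between-subject.

    For correlations the default is Welch's unequal-variance t-test on
    Fisher-Z transformed coefficients; for distances a Wilcoxon rank-sum
    test (the sign of a significant result then means within < between).
    ``method`` may force 'welch' or 'wilcoxon'.
    """
    if len(result.within) == 0 or len(result.between) == 0:
        raise ValueError("both similarity pools must be nonempty")
    w, b = np.asarray(result.within, float), np.asarray(result.between, float)
    use = method
    if method == "auto":
        use = "welch" if result.metric == "correlation" else "wilcoxon"
    if result.metric == "correlation" and transform:
        w, b = fisher_z(w), fisher_z(b)
    if use == "welch":
        if np.ptp(w) == 0 and np.ptp(b) == 0:
            raise ValueError("degenerate variance in both pools")
        res = stats.ttest_ind(w, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        dof = float(res.df)
    elif use == "wilcoxon":
        stat, p = stats.ranksums(w, b)
        stat, p, dof = float(stat), float(p), np.nan
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "metric": result.metric,
        "method": use,
        "statistic": stat,
        "df": dof,
        "p": p,
        "within_mean": float(np.mean(result.within)),
        "between_mean": float(np.mean(result.between)),
        "n_within": int(len(w)),
        "n_between": int(len(b)),
    }


def kendalls_w(data: np.ndarray) -> tuple[float, float, float]:
    """Kendall's coefficient of concordance over (raters x conditions).

    Rows are the repeated units (e.g. subject pairs), columns the
    conditions (sessions); W measures agreement of the within-row
    rankings, with the standard tie correction.  Returns (W, chi2, p)
    using the chi-square approximation with k-1 df.
    """
    data = np.asarray(data, dtype=float)
    m, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    ranks = stats.rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    s = float(((col_sums - col_sums.mean()) ** 2).sum())
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (k**3 - k) - m * ties
    if denom <= 0:
        raise ValueError("degenerate ranking (all values tied)")
    w = 12.0 * s / denom
    chi2 = m * (k - 1) * w
    p = float(stats.chi2.sf(chi2, k - 1))
    return w, chi2, p


def distance_trend(
    maps: dict[tuple, ErrorMap], sessions: list, alpha: float = 0.05
) -> dict:
    """Trend of within-session between-subject map distances over sessions.

    For each session, the distance between every unordered pair of
    subjects is computed; Kendall's W tests the concordance of the
    session ranking across pairs, followed by Bonferroni-corrected
    pairwise Wilcoxon signed-rank tests between successive-session
    (and all other) session pairs.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    subjects = sorted({sid for sid, _ in maps}, key=str)
    for ses in sessions:
        missing = [s for s in subjects if (s, ses) not in maps]
        if missing:
            raise ValueError(f"session {ses!r} missing for subjects {missing}")
    pairs = [
        (subjects[i], subjects[j])
        for i in range(len(subjects))
        for j in range(i + 1, len(subjects))
    ]
    dist = np.array(
        [
            [map_distance(maps[(a, ses)], maps[(b, ses)]) for ses in sessions]
            for a, b in pairs
        ]
    )
    w, chi2, p = kendalls_w(dist)
    n_tests = len(sessions) * (len(sessions) - 1) // 2
    posthoc = []
    for i in range(len(sessions)):
        for j in range(i + 1, len(sessions)):
            res = stats.wilcoxon(dist[:, i], dist[:, j])
            posthoc.append(
                {
                    "session_a": sessions[i],
                    "session_b": sessions[j],
                    "statistic": float(res.statistic),
                    "p_raw": float(res.pvalue),
                    "p_bonferroni": float(min(1.0, res.pvalue * n_tests)),
                }
            )
    return {
        "kendalls_w": float(w),
        "chi2": float(chi2),
        "p": float(p),
        "session_means": {str(s): float(m) for s, m in zip(sessions, dist.mean(axis=0))},
        "posthoc": posthoc,
        "n_pairs": len(pairs),
    }
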