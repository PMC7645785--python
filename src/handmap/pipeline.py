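"""End-to-end analysis pipeline: simulate -> maps -> similarity ->
identification -> trajectory scoring -> report.

A single seeded :class:`RunConfig` drives every stage; the numeric
payload of the resulting :class:`ReportBundle` is a deterministic
function of the config, and every artifact (trial tables, maps, result
JSON, markdown report) can be written to an output directory.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import error_maps as em
from . import io as hio
from . import similarity as sim
from . import trajectory as traj
from .error_maps import ErrorMap, build_all_maps
from .geometry import make_target_grid
from .identification import identification_protocol
from .synthetic import CohortConfig, GroupBias, generate_cohort, generate_trajectory_trials

logger = logging.getLogger("handmap")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_report", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    classifier: dict = field(default_factory=dict)  # ErrorMapClassifier overrides
    protocols: list[tuple[tuple, object]] = field(
        default_factory=lambda: [((1, 2), 3)]
    )  # (train_sessions, test_session)
    alpha: float = 0.05
    output_dir: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        labels = set(self.cohort.session_labels)
        for train, test in self.protocols:
            referenced = set(train) | {test}
            missing = referenced - labels
            if missing:
                raise ValueError(
                    f"protocol references sessions absent from cohort: {sorted(map(str, missing))}"
                )


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) file mirroring the dataclasses."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cohort_raw = dict(raw.get("cohort", {}))
    if "sessions" in cohort_raw:
        cohort_raw["sessions"] = {
            _coerce_label(k): float(v) for k, v in cohort_raw["sessions"].items()
        }
    if "group_bias" in cohort_raw:
        cohort_raw["group_bias"] = GroupBias(**cohort_raw["group_bias"])
    cohort = CohortConfig(**cohort_raw)
    protocols = [
        (tuple(_coerce_label(s) for s in train), _coerce_label(test))
        for train, test in raw.get("protocols", [[[1, 2], 3]])
    ]
    return RunConfig(
        cohort=cohort,
        classifier=raw.get("classifier", {}),
        protocols=protocols,
        alpha=float(raw.get("alpha", 0.05)),
        output_dir=raw.get("output_dir"),
        log_level=raw.get("log_level", "INFO"),
    )


def _coerce_label(label):
    try:
        return int(label)
    except (TypeError, ValueError):
        return label


@dataclass
class ReportBundle:
    """All pipeline results, JSON-serializable via :meth:`to_dict`."""

    session_summaries: dict = field(default_factory=dict)
    regional: dict = field(default_factory=dict)
    error_reductions: dict = field(default_factory=dict)
    direction_bias: dict = field(default_factory=dict)
    session_pairs: list = field(default_factory=list)
    distance_trend: dict = field(default_factory=dict)
    identification: list = field(default_factory=list)
    trajectory: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self.__dict__, default=_jsonify))

    def payload_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _mean_ci(values: np.ndarray, level: float = 0.95) -> dict:
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if len(values) < 2:
        return {"mean": m, "ci_low": m, "ci_high": m}
    sem = stats.sem(values)
    lo, hi = stats.t.interval(level, len(values) - 1, loc=m, scale=sem) if sem > 0 else (m, m)
    return {"mean": m, "ci_low": float(lo), "ci_high": float(hi)}


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every analysis stage on a freshly simulated cohort."""
    t0 = time.time()
    grid = make_target_grid()
    bundle = ReportBundle(config={"cohort": config.cohort.to_dict(),
                                  "classifier": dict(config.classifier),
                                  "protocols": [[list(tr), te] for tr, te in config.protocols],
                                  "alpha": config.alpha},
                          seed=config.cohort.seed)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ------------------------------------------------------
    logger.info("simulating cohort (seed=%d)", config.cohort.seed)
    trials = generate_cohort(config.cohort, grid)
    traj_trials = generate_trajectory_trials(config.cohort, grid=grid)
    if outdir:
        hio.write_matching_trials(trials, outdir / "matching_trials.csv")
        hio.write_trajectory_trials(traj_trials, outdir / "trajectory_trials.csv")

    # --- maps ------------------------------------------------------------
    maps = build_all_maps(trials, grid)
    if outdir:
        hio.write_error_maps(maps, outdir / "error_maps.csv")
    sessions = config.cohort.session_labels
    subjects = sorted({sid for sid, _ in maps})

    per_session = {
        ses: np.array([em.mean_error_magnitude(maps[(s, ses)]) for s in subjects])
        for ses in sessions
    }
    bundle.session_summaries = {
        str(ses): _mean_ci(vals) for ses, vals in per_session.items()
    }
    bundle.regional = {
        str(ses): {
            k: float(np.mean(v))
            for k, v in pd.DataFrame(
                [em.regional_errors(maps[(s, ses)]).__dict__ for s in subjects]
            ).items()
        }
        for ses in sessions
    }
    e1 = per_session[sessions[0]]
    bundle.error_reductions = {
        str(ses): _mean_ci(
            [em.error_reduction(a, b) for a, b in zip(e1, per_session[ses])]
        )
        for ses in sessions[1:]
    }

    averaged = [
        em.average_subject_map([maps[(s, ses)] for ses in sessions]) for s in subjects
    ]
    bundle.direction_bias = {
        comp: em.direction_bias_test(averaged, comp, config.alpha) for comp in ("x", "y")
    }

    # --- similarity ------------------------------------------------------
    pair_results = []
    for a, b in itertools.combinations(sessions, 2):
        for metric in ("correlation", "distance"):
            res = sim.within_between_sets(maps, a, b, metric)
            test = sim.compare_within_between(res)
            pair_results.append({"pair": [str(a), str(b)], **test})
    bundle.session_pairs = pair_results
    bundle.distance_trend = sim.distance_trend(maps, sessions, config.alpha)

    # --- identification ---------------------------------------------------
    ident = []
    for train, test in config.protocols:
        res = identification_protocol(
            maps, train, test, seed=config.cohort.seed, **config.classifier
        )
        ident.append(res.to_dict())
    bundle.identification = ident

    # --- trajectory -------------------------------------------------------
    scores = traj.score_trials(traj_trials)
    valid = scores[scores["valid"]]
    first = sessions[0]
    per_subj_rmse = valid.groupby("subject_id")["rmse_cm"].mean()
    per_subj_loc = pd.Series(
        {s: em.mean_error_magnitude(maps[(s, first)]) for s in subjects}
    )
    common = per_subj_rmse.index.intersection(per_subj_loc.index)
    corr = traj.motor_vs_localization_correlation(
        per_subj_rmse.loc[common].to_numpy(), per_subj_loc.loc[common].to_numpy()
    )

    # per-trajectory local localization error vs motor error, subject dummies
    tpl_cache: dict[tuple, traj.TrajectoryTemplate] = {}
    loc_err, end_loc_err = [], []
    for rec in valid.itertuples(index=False):
        key = (rec.alpha, rec.beta)
        tpl = tpl_cache.setdefault(key, traj.make_template(*key))
        m = maps[(rec.subject_id, first)]
        loc_err.append(traj.local_localization_error(m, tpl, grid))
        end_loc_err.append(traj.endpoint_localization_error(m, tpl, grid))
    reg_local = traj.subject_dummy_regression(
        valid["rmse_cm"].to_numpy(), np.array(loc_err), valid["subject_id"].to_numpy()
    )
    reg_endpoint = traj.subject_dummy_regression(
        valid["endpoint_error_cm"].to_numpy(),
        np.array(end_loc_err),
        valid["subject_id"].to_numpy(),
    )
    curv = valid.groupby(valid["beta"].abs())["rmse_cm"].mean()
    curvature_r = float(stats.pearsonr(curv.index.to_numpy(), curv.to_numpy()).statistic)
    bundle.trajectory = {
        "n_trials": int(len(scores)),
        "n_valid": int(len(valid)),
        "mean_rmse_cm": float(valid["rmse_cm"].mean()),
        "mean_endpoint_error_cm": float(valid["endpoint_error_cm"].mean()),
        "rmse_curvature_correlation": curvature_r,
        "motor_vs_localization": corr,
        "regression_local": reg_local,
        "regression_endpoint": reg_endpoint,
    }
    if outdir:
        scores.to_csv(outdir / "trajectory_scores.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(bundle.to_dict(), indent=2, sort_keys=True)
        )
        (outdir / "report.md").write_text(render_report(bundle, "markdown"))
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return bundle


def _fmt_ci(d: dict) -> str:
    return f"{d['mean']:.3f} (95% CI {d['ci_low']:.3f}–{d['ci_high']:.3f})"


def render_report(bundle: ReportBundle, fmt: str = "json") -> str:
    """Serialize a bundle as JSON or as a human-readable markdown report."""
    if fmt == "json":
        return json.dumps(bundle.to_dict(), indent=2, sort_keys=True)
    if fmt != "markdown":
        raise ValueError("format must be 'json' or 'markdown'")
    lines = ["# Hand-localization analysis report", ""]
    lines.append(f"Seed: {bundle.seed}")
    lines.append("")
    lines.append("## Mean localization error by session (cm)")
    lines.append("")
    lines.append("| session | mean error |")
    lines.append("|---|---|")
    for ses, d in bundle.session_summaries.items():
        lines.append(f"| {ses} | {_fmt_ci(d)} |")
    if bundle.error_reductions:
        lines.append("")
        lines.append("## Error reduction vs session 1 (%)")
        lines.append("")
        for ses, d in bundle.error_reductions.items():
            lines.append(f"- session {ses}: {_fmt_ci(d)}")
    if bundle.session_pairs:
        lines.append("")
        lines.append("## Within- vs between-subject similarity")
        lines.append("")
        lines.append("| pair | metric | within mean | between mean | stat | p |")
        lines.append("|---|---|---|---|---|---|")
        for r in bundle.session_pairs:
            lines.append(
                f"| {r['pair'][0]}-{r['pair'][1]} | {r['metric']} "
                f"| {r['within_mean']:.3f} | {r['between_mean']:.3f} "
                f"| {r['statistic']:.2f} | {r['p']:.2g} |"
            )
    lines.append("")
    lines.append("## Person identification")
    lines.append("")
    if not bundle.identification:
        lines.append("No identification protocols were configured for this run.")
    else:
        for r in bundle.identification:
            train = "+".join(r["train_sessions"])
            lines.append(
                f"- train {train} → test {r['test_session']}: "
                f"accuracy {100 * r['accuracy']:.2f}% "
                f"({r['n_correct']}/{r['n_test']})"
            )
    if bundle.trajectory:
        t = bundle.trajectory
        lines.append("")
        lines.append("## Trajectory matching")
        lines.append("")
        lines.append(f"- valid trials: {t['n_valid']}/{t['n_trials']}")
        lines.append(f"- mean motor error (RMSE): {t['mean_rmse_cm']:.3f} cm")
        mv = t["motor_vs_localization"]
        lines.append(
            f"- motor vs localization error ({mv['method']}): "
            f"r = {mv['r']:.3f}, p = {mv['p']:.3f}"
        )
        rl = t["regression_local"]
        lines.append(
            f"- local-error regression slope: {rl['slope']:.3f} "
            f"(95% CI {rl['ci95'][0]:.3f}–{rl['ci95'][1]:.3f}), "
            f"t({rl['df']}) = {rl['t']:.2f}, p = {rl['p']:.3g}"
        )
    lines.append("")
    return "\n".join(lines)
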