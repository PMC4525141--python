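"""End-to-end orchestration: per-fish metrics -> group tables -> inference.

``run_analysis`` turns a set of trajectories grouped by treatment into the
full report bundle (per-fish metrics, group mean +/- SEM tables, circular
summaries with Moore's test and a bootstrap CI, omnibus + post-hoc tests on
the scalar read-outs, binned temporal dynamics, occupancy heatmaps, run log).
``run_prepost`` compares ROI occupancy in the windows flanking an event
(e.g. a fight resolution) with the mixed pre/post ANOVA.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular import bootstrap_direction_ci, group_mean_vector, moores_rayleigh_test
from .errors import ValidationError
from .inference import (
    GroupSummary,
    games_howell_summary,
    mixed_prepost_anova,
    oneway_anova_summary,
    tukey_hsd_summary,
    welch_anova_summary,
)
from .metrics import (
    aggregate_binned,
    binned_series,
    fish_metrics,
    group_aggregate,
    occupancy_heatmap,
    time_in_roi,
)
from .trajectory import ArenaGeometry, TrackedTrajectory, detected_fraction, read_trajectory


@dataclass
class ExperimentConfig:
    """Inputs for a full analysis run.

    ``treatments`` maps a treatment label to the list of trajectory CSVs of
    its fish (every fish belongs to exactly one treatment).
    """

    treatments: dict[str, list[str]]
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    bin_s: float = 30.0
    seed: int = 0
    outdir: str = "fishgaze_report"

    def load(self) -> dict[str, list[TrackedTrajectory]]:
        out: dict[str, list[TrackedTrajectory]] = {}
        for label, paths in self.treatments.items():
            out[label] = []
            for i, p in enumerate(paths):
                if not Path(p).exists():
                    raise IOError(f"missing input for treatment {label}: {p}")
                out[label].append(
                    read_trajectory(p, self.arena, subject_id=f"{label}_{i:02d}", treatment=label)
                )
        return out


def _scalar_tests(groups_by_metric: dict[str, list[GroupSummary]]) -> dict:
    """Both omnibus variants plus both post-hoc families per metric; the
    caller chooses which to report, as the assumptions dictate."""
    out = {}
    for metric, summaries in groups_by_metric.items():
        if len(summaries) < 2:
            continue
        entry = {}
        welch = welch_anova_summary(summaries)
        oneway = oneway_anova_summary(summaries)
        entry["welch"] = {"F": welch.statistic, "df": list(welch.df), "p": welch.p}
        entry["oneway"] = {"F": oneway.statistic, "df": list(oneway.df), "p": oneway.p}
        entry["games_howell"] = [
            {"pair": f"{r.group_a} vs {r.group_b}", "q": r.statistic, "df": r.df, "p": r.p}
            for r in games_howell_summary(summaries)
        ]
        entry["tukey"] = [
            {"pair": f"{r.group_a} vs {r.group_b}", "q": r.statistic, "df": r.df, "p": r.p}
            for r in tukey_hsd_summary(summaries)
        ]
        out[metric] = entry
    return out


def run_analysis(
    cfg: ExperimentConfig,
    trajectories: dict[str, list[TrackedTrajectory]] | None = None,
) -> dict:
    """Run the four attention read-outs and group inference; write the bundle.

    Returns the report dict; files are written under ``cfg.outdir``.
    Outputs are a pure function of (inputs, config, seed).
    """
    t0 = time.perf_counter()
    trajs = cfg.load() if trajectories is None else trajectories
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = {label: [fish_metrics(t) for t in ts] for label, ts in trajs.items()}
    rows = []
    for label, recs in records.items():
        for r in recs:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "treatment": label,
                    "time_in_roi_pct": r.time_in_roi_pct,
                    "total_distance_m": r.total_distance_m,
                    "mean_speed_roi_m_s": r.mean_speed_roi_m_s,
                    "alpha_deg": r.rv.alpha,
                    "R": r.rv.R,
                    "r_proj": r.r_proj,
                }
            )
    metrics_df = pd.DataFrame(rows)
    metrics_df.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")

    group_tables = {}
    circular = {}
    for label, recs in records.items():
        if len(recs) >= 2:
            group_tables[label] = group_aggregate(recs)
            group_tables[label].to_csv(outdir / f"group_{label}.csv", float_format="%.6f")
        members = [r.rv for r in recs]
        entry: dict = {"n_fish": len(recs)}
        gv = group_mean_vector(members)
        entry["alpha_g"] = gv.alpha_g
        entry["R_g"] = gv.R_g
        if len(members) >= 4:
            moore = moores_rayleigh_test(members, seed=cfg.seed)
            entry["moore_R_star"] = moore.R_star
            entry["moore_p"] = moore.p
        if len(members) >= 5 and gv.defined:
            lo, hi = bootstrap_direction_ci(members, seed=cfg.seed)
            entry["ci_low"], entry["ci_high"] = lo, hi
        circular[label] = entry
    with open(outdir / "circular.json", "w") as fh:
        json.dump(circular, fh, indent=2)

    groups_by_metric: dict[str, list[GroupSummary]] = {}
    for metric in ("time_in_roi_pct", "r_proj", "total_distance_m", "mean_speed_roi_m_s"):
        summaries = []
        for label, recs in records.items():
            vals = [getattr(r, metric) for r in recs]
            vals = [v for v in vals if v is not None]
            if len(vals) >= 2 and float(np.std(vals, ddof=1)) > 0:
                summaries.append(GroupSummary.from_raw(label, vals))
        groups_by_metric[metric] = summaries
    stats = _scalar_tests(groups_by_metric)
    stats_available = bool(stats)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2)

    for metric in ("roi_occupancy", "r_proj"):
        for label, ts in trajs.items():
            series = [binned_series(t, metric, bin_s=cfg.bin_s) for t in ts]
            if len(series) >= 2:
                agg = aggregate_binned(series)
                agg.to_csv(outdir / f"binned_{metric}_{label}.csv", index=False, float_format="%.6f")

    for label, ts in trajs.items():
        for t in ts:
            hm = occupancy_heatmap(t)
            np.savetxt(outdir / f"heatmap_{t.subject_id}.csv", hm.counts, fmt="%d", delimiter=",")

    run_log = {
        "version": __version__,
        "seed": cfg.seed,
        "bin_s": cfg.bin_s,
        "arena": dataclasses.asdict(cfg.arena),
        "group_stats_available": stats_available,
        "detected_fraction": {
            label: [detected_fraction(t) for t in ts] for label, ts in trajs.items()
        },
        "elapsed_s": time.perf_counter() - t0,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)

    return {
        "metrics": metrics_df,
        "group_tables": group_tables,
        "circular": circular,
        "stats": stats,
        "run_log": run_log,
    }


def run_prepost(
    trajectories: dict[str, list[TrackedTrajectory]],
    resolution_time_s: float,
    delta_s: float | None = None,
) -> dict:
    """Pre/post-event ROI occupancy and the mixed ANOVA on it.

    Per fish, percent time in the ROI over [t_res - delta, t_res) and
    [t_res, t_res + delta); delta defaults to the resolution time itself
    (equal flanking windows).  Returns the per-fish table and the
    MixedPrePostResult.
    """
    if delta_s is None:
        delta_s = resolution_time_s
    if delta_s <= 0:
        raise ValidationError("window must be positive")
    pre_vals, post_vals, labels, subjects = [], [], [], []
    for label, ts in trajectories.items():
        for t in ts:
            if resolution_time_s - delta_s < 0 or resolution_time_s + delta_s > t.duration_s + 1e-9:
                raise ValidationError("pre/post windows exceed the session")
            pre_vals.append(time_in_roi(t.slice_time(resolution_time_s - delta_s, resolution_time_s)))
            post_vals.append(time_in_roi(t.slice_time(resolution_time_s, resolution_time_s + delta_s)))
            labels.append(label)
            subjects.append(t.subject_id)
    table = pd.DataFrame(
        {"subject_id": subjects, "treatment": labels, "pre": pre_vals, "post": post_vals}
    )
    anova = mixed_prepost_anova(pre_vals, post_vals, labels)
    return {"table": table, "anova": anova}
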