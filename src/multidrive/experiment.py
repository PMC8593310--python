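"""The 2x2 evaluation protocol and behavior-metric pipeline.

The study design crosses driving speed (60 vs 120 km/h) with the number of
search items per display (6 vs 9). Policies are trained separately for
each condition; each simulated participant then runs 24 trials per
condition (12 target-present, 12 foil, order shuffled). From every trial
trace we extract five behavior metrics:

* trial time (s),
* SD of lateral offset from the lane center (m),
* number of lane deviations (maximal excursions beyond the half-lane
  bound, counted once at onset),
* number of in-car glances,
* mean in-car glance duration (s).

An in-car glance spans from the start of the switch toward the display to
the start of the switch back to the road — the eyes are off the road for
the whole span.

Metrics are aggregated within participants first, then across
participants. Fit indices against a human summary table report, per
metric: mean absolute error across condition cells, that error relative
to the human mean, the error in human-SD units, and the R-squared of an
ordinary least-squares regression of the human observations on the model
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .driving import ConfigurationError, DrivingEnv, learn_transition_model
from .rl import train_policy
from .search import SearchEnv
from .supervisory import (
    MultitaskConfig,
    TrainedPolicies,
    TrialTrace,
    new_session_state,
    run_trial,
    train_supervisory,
)

__all__ = [
    "Condition",
    "TrialMetrics",
    "conditions",
    "train_condition",
    "run_condition",
    "extract_glances",
    "compute_metrics",
    "aggregate",
    "compute_fit_indices",
    "load_human_summary",
    "synthetic_human_summary_path",
]

METRIC_NAMES = (
    "trial_time",
    "offset_sd",
    "n_lane_deviations",
    "n_incar_glances",
    "mean_incar_glance_duration",
)


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2 design."""

    speed_kmh: float
    n_items: int

    def __post_init__(self) -> None:
        if self.speed_kmh not in (60.0, 120.0) or self.n_items not in (6, 9):
            raise ConfigurationError(
                "conditions are the 2x2 crossing of speed {60, 120} km/h "
                "and items {6, 9}"
            )

    @property
    def label(self) -> str:
        return f"{int(self.speed_kmh)}kmh_{self.n_items}items"


def conditions() -> list[Condition]:
    """The four cells of the design, in a fixed order."""
    return [
        Condition(speed, items)
        for speed in (60.0, 120.0)
        for items in (6, 9)
    ]


@dataclass
class TrialMetrics:
    """The five behavior metrics of one trial."""

    trial_time: float
    offset_sd: float
    n_lane_deviations: int
    n_incar_glances: int
    mean_incar_glance_duration: float
    trial_type: str  # "target" | "foil"
    aborted: bool = False


# ---------------------------------------------------------------------------
# training pipeline
# ---------------------------------------------------------------------------


def train_condition(
    condition: Condition,
    profile: str = "fast",
    seed: int = 0,
    config: MultitaskConfig | None = None,
) -> TrainedPolicies:
    """Train everything for one condition, in order: transition model,
    driving policy, search policy, supervisory policy."""
    if config is None:
        config = MultitaskConfig.for_condition(
            speed_kmh=condition.speed_kmh,
            n_items=condition.n_items,
            profile=profile,
            seed=seed,
        )
    policies = TrainedPolicies(config=config)
    rng = np.random.default_rng(config.drive_learning.seed)
    policies.tau = learn_transition_model(
        config.driving, config.tau_rollout_steps, rng
    )
    drive_env = DrivingEnv(
        config.driving,
        policies.tau,
        episode_steps=config.drive_episode_steps,
        n_entropy_bins=config.n_entropy_bins,
        obs_burst_prob=config.obs_burst_prob,
        obs_burst_mean_steps=config.obs_burst_mean_steps,
        start_offset_sd_m=config.start_offset_sd_m,
    )
    policies.q_drive, drive_log = train_policy(drive_env, config.drive_learning, rng)
    search_env = SearchEnv(
        config.search, interruption_prob=config.search_interruption_prob
    )
    policies.q_search, search_log = train_policy(
        search_env, config.search_learning, np.random.default_rng(config.search_learning.seed)
    )
    policies.logs["drive_returns"] = drive_log
    policies.logs["search_returns"] = search_log
    train_supervisory(
        policies, config, np.random.default_rng(config.supervisory_learning.seed)
    )
    return policies


# ---------------------------------------------------------------------------
# metric extraction
# ---------------------------------------------------------------------------


def extract_glances(trace: TrialTrace) -> list[tuple[str, float]]:
    """Partition the trial timeline into maximal road / in-car spans.

    An in-car span opens at the start of a switch toward the display and
    closes at the start of the switch back (or at trial end). Span
    durations sum exactly to the trial time. Traces taken mid-session may
    open with the eyes already on the display.
    """
    if not trace.events:
        return []
    first = trace.events[0]
    if first.kind == "switch":
        current_kind = "incar" if first.detail.get("from") == "search" else "road"
    else:
        current_kind = "incar" if first.focus == "search" else "road"
    glances: list[tuple[str, float]] = []
    span_start = first.t_start
    for event in trace.events:
        if event.kind == "switch":
            to = event.detail.get("to")
            new_kind = "incar" if to == "search" else "road"
            if new_kind != current_kind:
                if event.t_start > span_start:
                    glances.append((current_kind, event.t_start - span_start))
                current_kind = new_kind
                span_start = event.t_start
    t_end = trace.events[-1].t_end
    if t_end > span_start:
        glances.append((current_kind, t_end - span_start))
    return glances


def compute_metrics(trace: TrialTrace, deviation_bound: float = 0.85) -> TrialMetrics:
    """Reduce one trace to the five behavior metrics.

    ``deviation_bound`` is the center-line offset at which the car body
    leaves the lane (lane width minus car width, halved).
    """
    if not trace.events:
        raise ConfigurationError("cannot compute metrics for an empty trace")
    offsets = np.array(
        [o for e in trace.events for (_, o) in e.offset_samples]
    )
    offset_sd = float(np.std(offsets, ddof=1)) if offsets.size > 1 else 0.0
    # lane deviations: maximal contiguous excursions, counted at onset
    out = np.abs(offsets) > deviation_bound
    n_dev = int(np.sum(out[1:] & ~out[:-1]) + (1 if out.size and out[0] else 0))
    glances = extract_glances(trace)
    incar = [d for kind, d in glances if kind == "incar"]
    return TrialMetrics(
        trial_time=trace.trial_time,
        offset_sd=offset_sd,
        n_lane_deviations=n_dev,
        n_incar_glances=len(incar),
        mean_incar_glance_duration=float(np.mean(incar)) if incar else 0.0,
        trial_type="target" if trace.target_present else "foil",
        aborted=trace.aborted,
    )


# ---------------------------------------------------------------------------
# condition simulation
# ---------------------------------------------------------------------------


def run_condition(
    condition: Condition,
    policies: TrainedPolicies,
    n_participants: int,
    master_seed: int = 0,
    n_trials: int = 24,
) -> pd.DataFrame:
    """Simulate the trial protocol for one condition.

    Each simulated participant is an independent evaluation seed over the
    shared trained policies and runs ``n_trials`` trials, half foil and
    half target-present, in shuffled order.
    """
    policies.require("tau", "q_drive", "q_search", "q_supervisory")
    rows = []
    for participant in range(n_participants):
        rng = np.random.default_rng([master_seed, int(condition.speed_kmh),
                                     condition.n_items, participant])
        trial_types = [True] * (n_trials // 2) + [False] * (n_trials - n_trials // 2)
        rng.shuffle(trial_types)
        # one continuous driving session per participant: the car, belief
        # and attention carry over from trial to trial
        joint = new_session_state(policies.config, rng)
        for trial_index, target_present in enumerate(trial_types):
            trace = run_trial(
                policies, policies.config, target_present, rng, joint=joint
            )
            metrics = compute_metrics(
                trace, deviation_bound=policies.config.driving.deviation_bound
            )
            rows.append(
                {
                    "participant": participant,
                    "speed_kmh": condition.speed_kmh,
                    "n_items": condition.n_items,
                    "trial_index": trial_index,
                    "trial_type": metrics.trial_type,
                    "trial_time": metrics.trial_time,
                    "offset_sd": metrics.offset_sd,
                    "n_lane_deviations": metrics.n_lane_deviations,
                    "n_incar_glances": metrics.n_incar_glances,
                    "mean_incar_glance_duration": metrics.mean_incar_glance_duration,
                    "aborted": metrics.aborted,
                }
            )
    return pd.DataFrame(rows)


def aggregate(trial_table: pd.DataFrame, pool_trial_types: bool = False) -> pd.DataFrame:
    """Two-stage aggregation: participant means first, then across
    participants (mean, SD, and standard error with n = participants)."""
    group_cols = ["speed_kmh", "n_items"] + (
        [] if pool_trial_types else ["trial_type"]
    )
    per_participant = (
        trial_table.groupby(group_cols + ["participant"], as_index=False)[
            list(METRIC_NAMES)
        ].mean()
    )
    records = []
    for keys, grp in per_participant.groupby(group_cols):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(grp)
        rec = dict(zip(group_cols, keys))
        rec["n_participants"] = n
        for m in METRIC_NAMES:
            vals = grp[m].to_numpy(dtype=float)
            rec[f"{m}_mean"] = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            rec[f"{m}_sd"] = sd
            rec[f"{m}_se"] = sd / np.sqrt(n) if n > 1 else 0.0
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def _summary_to_cells(summary: pd.DataFrame, pool_trial_types: bool) -> pd.DataFrame:
    cols = ["speed_kmh", "n_items"] + ([] if pool_trial_types else ["trial_type"])
    return summary.set_index(cols).sort_index()


def compute_fit_indices(
    model_summary: pd.DataFrame,
    human_summary: pd.DataFrame,
    pool_trial_types: bool = False,
) -> pd.DataFrame:
    """Model-vs-human fit per behavior metric across condition cells.

    Both inputs are ``aggregate``-style tables with ``<metric>_mean`` (and
    for the human table ``<metric>_sd``) columns over the same condition x
    trial-type cells. Returns absolute error, error relative to the human
    mean, error in human-SD units, and OLS R-squared of the human cell
    means regressed on the model's.
    """
    m = _summary_to_cells(model_summary, pool_trial_types)
    h = _summary_to_cells(human_summary, pool_trial_types)
    if not m.index.equals(h.index):
        raise ConfigurationError(
            "model and human summaries cover different condition cells"
        )
    rows = []
    for metric in METRIC_NAMES:
        mv = m[f"{metric}_mean"].to_numpy(dtype=float)
        hv = h[f"{metric}_mean"].to_numpy(dtype=float)
        abs_err = float(np.mean(np.abs(mv - hv)))
        human_mean = float(np.mean(hv))
        rel_err = abs_err / abs(human_mean) if human_mean != 0 else np.nan
        sd_col = f"{metric}_sd"
        if sd_col in h.columns and np.all(np.isfinite(h[sd_col])):
            human_sd = float(np.mean(h[sd_col].to_numpy(dtype=float)))
        else:
            human_sd = float(np.std(hv, ddof=1))
        err_sd = abs_err / human_sd if human_sd > 0 else np.nan
        if np.ptp(mv) > 0:
            lin = stats.linregress(mv, hv)
            r2 = float(lin.rvalue**2)
        else:
            r2 = np.nan
        rows.append(
            {
                "metric": metric,
                "absolute_error": abs_err,
                "relative_error": rel_err,
                "error_in_sd_units": err_sd,
                "r_squared": r2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# human-summary I/O
# ---------------------------------------------------------------------------


def load_human_summary(path) -> pd.DataFrame:
    """Load a per-participant human summary CSV and aggregate it.

    Expected long-format columns: participant, speed_kmh, n_items,
    trial_type, metric, value — one row per participant x condition x
    trial-type x metric.
    """
    df = pd.read_csv(path)
    required = {"participant", "speed_kmh", "n_items", "trial_type", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"human summary missing columns: {sorted(missing)}")
    wide = df.pivot_table(
        index=["speed_kmh", "n_items", "trial_type", "participant"],
        columns="metric",
        values="value",
    ).reset_index()
    records = []
    for keys, grp in wide.groupby(["speed_kmh", "n_items", "trial_type"]):
        rec = dict(zip(["speed_kmh", "n_items", "trial_type"], keys))
        rec["n_participants"] = len(grp)
        for m in METRIC_NAMES:
            vals = grp[m].to_numpy(dtype=float)
            rec[f"{m}_mean"] = float(np.mean(vals))
            rec[f"{m}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rec[f"{m}_se"] = (
                rec[f"{m}_sd"] / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
        records.append(rec)
    return pd.DataFrame(records)


def synthetic_human_summary_path():
    """Path to the bundled synthetic stand-in human summary (the real
    study's participant data is not distributed with this package)."""
    return resources.files("multidrive.data") / "synthetic_human_summary.csv"
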