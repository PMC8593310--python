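"""Supervisory attention allocation between driving and in-car search.

The top level of the hierarchy is itself a POMDP. Its observation is the
pair of best-available-action utilities reported by the two trained
subtask policies — max Q over the lane-keeping policy's current belief
state and max Q over the search policy's current belief state — together
with which task currently holds visual attention. It applies two actions,
*drive* and *search*:

* drive: the driving model runs one cycle of constant time ``dt_drive_s``
  while allowed to observe its lane position;
* search: the search model is iterated once (one EMMA encode) and driving
  is simulated forward *without attention* for the duration of the eye
  movement — prediction-only belief updates, though the driver can still
  steer on the propagated belief.

Changing focus costs a task switch: attention downtime equal to the
road-display saccade duration (34 degrees of separation at the default
geometry), during which neither task progresses and driving runs blind
with steering held. Returning to the display also resets the search
fixation to the display entry point.

The supervisory policy is trained with the same SARSA machinery as the
subtasks, after both of them, to maximize the joint reward R_d + R_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Hashable

import numpy as np
import pandas as pd

from . import driving as drv
from . import search as srch
from .driving import ConfigurationError, DrivingParams, DrivingState, TransitionModel
from .rl import LearningParams, QTable, max_q, select_action, train_policy
from .search import SearchParams, SearchEnv

__all__ = [
    "DRIVE",
    "SEARCH",
    "MultitaskConfig",
    "QCalibration",
    "TrialEvent",
    "TrialTrace",
    "JointState",
    "TrainedPolicies",
    "SupervisoryEnv",
    "supervisory_step",
    "train_supervisory",
    "run_trial",
    "new_session_state",
    "install_search_task",
    "always_drive_policy",
    "strict_alternation_policy",
]

DRIVE, SEARCH = 0, 1
_ACTION_NAMES = {DRIVE: "drive", SEARCH: "search"}


@dataclass
class MultitaskConfig:
    """Full configuration for one task condition.

    ``switch_cost_s = None`` derives the cost from the saccade-duration
    law at the road-display visual separation (34 degrees by default,
    0.273 s at the oculomotor defaults).
    """

    driving: DrivingParams = field(default_factory=DrivingParams)
    search: SearchParams = field(default_factory=SearchParams)
    drive_learning: LearningParams = field(
        default_factory=lambda: LearningParams(n_episodes=2000, seed=1)
    )
    search_learning: LearningParams = field(
        default_factory=lambda: LearningParams(n_episodes=500, seed=2)
    )
    supervisory_learning: LearningParams = field(
        default_factory=lambda: LearningParams(n_episodes=2000, seed=3)
    )
    switch_cost_s: float | None = None
    display_separation_deg: float = 34.0
    q_bins: int = 12
    search_reward_weight: float = 1.0
    n_entropy_bins: int = 8
    trial_time_limit_s: float = 60.0
    # evaluation keeps the mild stochasticity of the final training
    # temperature: SARSA's values describe the softmax policy at that
    # temperature, so evaluating colder would execute a policy the values
    # never supported
    # supervisory training episodes are continuing multi-task sessions:
    # driving never pauses, and a fresh search screen replaces a completed
    # one immediately, as in the experimental procedure
    session_time_limit_s: float = 30.0
    eval_tau: float = 0.2
    obs_burst_prob: float = 0.1
    obs_burst_mean_steps: float = 8.0
    start_offset_sd_m: float = 0.5
    drive_episode_steps: int = 120
    tau_rollout_steps: int = 60_000
    search_interruption_prob: float = 0.0
    n_warmup_trials: int = 40
    # SARSA on the coarse supervisory observation is restart-sensitive
    # (attractor basins of few long glances vs several short ones); train
    # independent restarts and keep the table with the best joint-reward
    # rate on held-out training-distribution trials. warm_start_sessions
    # > 0 seeds odd restarts by policy-evaluating naive alternation first.
    supervisory_restarts: int = 3
    selection_trials: int = 24
    warm_start_sessions: int = 0

    def __post_init__(self) -> None:
        if self.switch_cost_s is not None and self.switch_cost_s < 0:
            raise ConfigurationError("switch_cost_s must be >= 0")
        if self.q_bins < 2:
            raise ConfigurationError("q_bins must be >= 2")

    @property
    def switch_cost(self) -> float:
        if self.switch_cost_s is not None:
            return self.switch_cost_s
        return srch.saccade_time(self.display_separation_deg, self.search)

    @classmethod
    def for_condition(
        cls,
        speed_kmh: float = 60.0,
        n_items: int = 6,
        profile: str = "fast",
        seed: int = 0,
        **overrides,
    ) -> "MultitaskConfig":
        """Condition-specific configuration at a training-size profile.

        ``profile='full'`` uses the full episode budgets (driving 20k
        episodes, search 20k episodes, supervisory 5k half-minute
        sessions of roughly eight tasks each); ``'fast'`` scales them
        down for quick runs.
        """
        if profile not in ("full", "fast"):
            raise ConfigurationError("profile must be 'full' or 'fast'")
        full = profile == "full"
        kwargs = dict(
            driving=DrivingParams(speed_kmh=speed_kmh),
            search=SearchParams(n_items=n_items),
            drive_learning=LearningParams(
                n_episodes=20_000 if full else 4_000, seed=seed * 7 + 1
            ),
            # search episodes are cheap and state coverage matters: the
            # supervisor reads max-Q off this table for every layout
            search_learning=LearningParams(
                n_episodes=20_000 if full else 6_000,
                seed=seed * 7 + 2,
                alpha=0.3,
                tau_sm=2.0,
                tau_sm_final=0.1,
            ),
            # the supervisory task is continuing (tasks follow each other
            # during uninterrupted driving), so it is learned with
            # differential SARSA: Q values are advantages relative to the
            # estimated reward rate
            supervisory_learning=LearningParams(
                n_episodes=5_000 if full else 1_500,
                seed=seed * 7 + 3,
                alpha=0.05,
                tau_sm=2.0,
                tau_sm_final=0.2,
                average_reward=True,
            ),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class QCalibration:
    """Quantile bin edges for the supervisory max-Q observations,
    calibrated from a random-policy warm-up phase.

    Quantile (rather than equal-width) bins matter here: the warm-up
    range of max q_drive is dominated by rare catastrophic values, and
    equal-width bins would compress the operationally relevant gradient —
    the slow decline of q_drive as blind-driving uncertainty accumulates —
    into a single bin, blinding the supervisor to glance age.
    """

    q_drive_edges: list[float]
    q_search_edges: list[float]

    @staticmethod
    def from_samples(
        qd_vals: list[float], qs_vals: list[float], n_bins: int
    ) -> "QCalibration":
        probs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
        return QCalibration(
            q_drive_edges=sorted(set(np.quantile(qd_vals, probs).tolist())),
            q_search_edges=sorted(set(np.quantile(qs_vals, probs).tolist())),
        )

    def observe(self, q_d: float, q_s: float, n_bins: int = 0) -> tuple[int, int]:
        return (
            int(np.searchsorted(self.q_drive_edges, q_d, side="right")),
            int(np.searchsorted(self.q_search_edges, q_s, side="right")),
        )


@dataclass
class TrialEvent:
    """One contiguous span of trial time.

    kind is ``drive_cycle`` (one attended driving cycle),
    ``search_encode`` (one EMMA encode with driving blind underneath) or
    ``switch`` (attention downtime). ``offset_samples`` holds the lateral
    offset at each driving sub-step boundary inside the event, sampled
    every ``dt_drive_s``.
    """

    t_start: float
    t_end: float
    kind: str
    focus: str
    lateral_offset_m: float
    r_drive: float
    r_search: float
    offset_samples: list[tuple[float, float]] = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class TrialTrace:
    """Timestamped event log of one multitasking trial."""

    events: list[TrialEvent]
    target_present: bool
    completed: bool
    aborted: bool = False

    @property
    def trial_time(self) -> float:
        """Trial duration: traces from an ongoing session need not start
        at t = 0."""
        if not self.events:
            return 0.0
        return self.events[-1].t_end - self.events[0].t_start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_start": e.t_start,
                    "t_end": e.t_end,
                    "kind": e.kind,
                    "focus": e.focus,
                    "lateral_offset_m": e.lateral_offset_m,
                    "r_drive": e.r_drive,
                    "r_search": e.r_search,
                }
                for e in self.events
            ]
        )

    def to_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for e in self.events:
                fh.write(
                    json.dumps(
                        {
                            "t_start": e.t_start,
                            "t_end": e.t_end,
                            "kind": e.kind,
                            "focus": e.focus,
                            "lateral_offset_m": e.lateral_offset_m,
                            "r_drive": e.r_drive,
                            "r_search": e.r_search,
                            "detail": e.detail,
                        }
                    )
                    + "\n"
                )


@dataclass
class JointState:
    """Mutable joint state of one trial."""

    drive_state: DrivingState
    drive_belief: np.ndarray
    search_env: SearchEnv  # holds SearchState + SearchBelief + cell machinery
    focus: int = DRIVE
    t: float = 0.0


@dataclass
class TrainedPolicies:
    """Everything learned for one condition, in training order."""

    config: MultitaskConfig
    tau: TransitionModel | None = None
    q_drive: QTable | None = None
    q_search: QTable | None = None
    q_supervisory: QTable | None = None
    calibration: QCalibration | None = None
    logs: dict = field(default_factory=dict)

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ConfigurationError(
                    f"{name} has not been trained yet; training order is "
                    "transition model -> driving -> search -> supervisory"
                )

    # -- serialization ----------------------------------------------------

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.tau is not None:
            self.tau.to_csv(d / "transition_model.csv")
        for name in ("q_drive", "q_search", "q_supervisory"):
            qt = getattr(self, name)
            if qt is not None:
                qt.to_csv(d / f"{name}.csv")
        manifest = {
            "speed_kmh": self.config.driving.speed_kmh,
            "n_items": self.config.search.n_items,
            "calibration": (
                vars(self.calibration) if self.calibration is not None else None
            ),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory, config: MultitaskConfig) -> "TrainedPolicies":
        import json
        from pathlib import Path

        d = Path(directory)
        pol = cls(config=config)
        if (d / "transition_model.csv").exists():
            pol.tau = TransitionModel.from_csv(
                d / "transition_model.csv", config.driving
            )
        for name in ("q_drive", "q_search", "q_supervisory"):
            p = d / f"{name}.csv"
            if p.exists():
                setattr(pol, name, QTable.from_csv(p))
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest.get("calibration"):
            pol.calibration = QCalibration(**manifest["calibration"])
        return pol


# ---------------------------------------------------------------------------
# step mechanics
# ---------------------------------------------------------------------------


def _drive_key(joint: JointState, config: MultitaskConfig) -> Hashable:
    return drv.belief_state_key(
        joint.drive_belief, config.driving, config.n_entropy_bins
    )


def _blind_drive(
    joint: JointState,
    policies: TrainedPolicies,
    config: MultitaskConfig,
    duration: float,
    steer: bool,
    rng: np.random.Generator,
    samples: list[tuple[float, float]],
) -> float:
    """Advance true driving and prediction-only belief for ``duration``
    seconds in dt_drive sub-steps (last one partial); returns accrued R_d.

    Partial sub-steps scale the true dynamics by the sub-step length and
    interpolate the belief between identity and the one-step transition
    map, keeping it a proper distribution.
    """
    p = config.driving
    r_d = 0.0
    remaining = duration
    while remaining > 1e-12:
        h = min(p.dt_drive_s, remaining)
        if steer:
            a_idx = select_action(
                policies.q_drive, _drive_key(joint, config), config.eval_tau, rng
            )
        else:
            # attention is on neither task: the wheel stays where the
            # driver left it
            a_idx = p.action_index(joint.drive_state.steering)
        joint.drive_state = drv.simulate_step(
            joint.drive_state, p.action_set[a_idx], p, rng, duration=h
        )
        pushed = drv.belief_predict(joint.drive_belief, a_idx, policies.tau)
        lam = h / p.dt_drive_s
        joint.drive_belief = (
            pushed if lam >= 1.0 - 1e-12 else (1 - lam) * joint.drive_belief + lam * pushed
        )
        r_d += drv.driving_reward(joint.drive_state, p, h)
        joint.t += h
        samples.append((joint.t, joint.drive_state.lateral_offset_m))
        remaining -= h
    return r_d


def supervisory_step(
    action: int,
    joint: JointState,
    policies: TrainedPolicies,
    config: MultitaskConfig,
    rng: np.random.Generator,
) -> tuple[list[TrialEvent], float, JointState]:
    """Execute one supervisory decision; returns (events, joint reward, state').

    A focus change first emits a ``switch`` event of duration
    ``switch_cost`` with blind, steering-held driving underneath. Then the
    chosen task runs: one observed driving cycle, or one search encode
    with blind (but steered) driving underneath.
    """
    if action not in (DRIVE, SEARCH):
        raise ConfigurationError("supervisory action must be DRIVE or SEARCH")
    policies.require("tau", "q_drive", "q_search")
    p = config.driving
    events: list[TrialEvent] = []
    r_drive_total = 0.0
    r_search_total = 0.0

    if action != joint.focus:
        t0 = joint.t
        samples: list[tuple[float, float]] = []
        r_d = _blind_drive(
            joint, policies, config, config.switch_cost, steer=False, rng=rng,
            samples=samples,
        )
        r_drive_total += r_d
        events.append(
            TrialEvent(
                t_start=t0,
                t_end=joint.t,
                kind="switch",
                focus=_ACTION_NAMES[action],
                lateral_offset_m=joint.drive_state.lateral_offset_m,
                r_drive=r_d,
                r_search=0.0,
                offset_samples=samples,
                detail={
                    "from": _ACTION_NAMES[joint.focus],
                    "to": _ACTION_NAMES[action],
                },
            )
        )
        # on a switch back to the display the return saccade (whose travel
        # time is the switch cost) lands at the previously fixated locus:
        # visual short-term memory lets the searcher resume where they
        # left off, so the fixation persists across road glances
        joint.focus = action

    if action == DRIVE:
        t0 = joint.t
        a_idx = select_action(
            policies.q_drive, _drive_key(joint, config), config.eval_tau, rng
        )
        joint.drive_state = drv.simulate_step(
            joint.drive_state, p.action_set[a_idx], p, rng
        )
        joint.drive_belief = drv.belief_predict(
            joint.drive_belief, a_idx, policies.tau
        )
        obs = drv.sample_observation(joint.drive_state, p, rng)
        joint.drive_belief = drv.belief_correct(joint.drive_belief, obs, p)
        r_d = drv.driving_reward(joint.drive_state, p, p.dt_drive_s)
        r_drive_total += r_d
        joint.t += p.dt_drive_s
        events.append(
            TrialEvent(
                t_start=t0,
                t_end=joint.t,
                kind="drive_cycle",
                focus="drive",
                lateral_offset_m=joint.drive_state.lateral_offset_m,
                r_drive=r_d,
                r_search=0.0,
                offset_samples=[(joint.t, joint.drive_state.lateral_offset_m)],
                detail={"steering_action": p.action_set[a_idx]},
            )
        )
    else:
        t0 = joint.t
        senv = joint.search_env
        cell = select_action(
            policies.q_search,
            senv.state_key(),
            config.eval_tau,
            rng,
            valid=senv.valid_actions(),
        )
        elapsed, done = senv.apply_action(cell)
        r_s = srch.search_reward(
            elapsed, done, config.search, foil=senv.state.target_index is None
        )
        r_search_total += r_s
        samples = []
        r_d = _blind_drive(
            joint, policies, config, elapsed, steer=True, rng=rng, samples=samples
        )
        r_drive_total += r_d
        events.append(
            TrialEvent(
                t_start=t0,
                t_end=joint.t,
                kind="search_encode",
                focus="search",
                lateral_offset_m=joint.drive_state.lateral_offset_m,
                r_drive=r_d,
                r_search=r_s,
                offset_samples=samples,
                detail={
                    "cell": cell,
                    "elapsed": elapsed,
                    "done": done,
                    "n_encoded": senv.belief.n_encoded,
                },
            )
        )

    reward = r_drive_total + config.search_reward_weight * r_search_total
    return events, reward, joint


def _new_joint_state(
    policies: TrainedPolicies,
    config: MultitaskConfig,
    target_present: bool,
    rng: np.random.Generator,
) -> JointState:
    senv = SearchEnv(config.search)
    senv.reset(rng, target_present=target_present)
    # sessions happen during continuous driving: the car starts wherever
    # the ongoing lane-keeping left it, not at a pristine lane center
    offset = float(np.clip(rng.normal(0.0, config.start_offset_sd_m), -1.5, 1.5))
    return JointState(
        drive_state=DrivingState(
            lateral_offset_m=offset,
            steering=0.0,
            speed_kmh=config.driving.speed_kmh,
        ),
        drive_belief=drv.initial_belief(
            config.driving, config.driving.discretize(offset)
        ),
        search_env=senv,
        focus=DRIVE,
        t=0.0,
    )


def new_session_state(
    config: MultitaskConfig, rng: np.random.Generator, target_present: bool = True
) -> JointState:
    """Fresh joint state for the start of a continuous driving session."""
    return _new_joint_state(None, config, target_present, rng)


def install_search_task(
    joint: JointState,
    config: MultitaskConfig,
    target_present: bool,
    rng: np.random.Generator,
) -> None:
    """Replace the display contents with a fresh search task.

    Driving state, belief, time and attention focus carry over; the eyes
    stay where they are if already on the display, otherwise the next
    switch toward the display lands at the entry point.
    """
    fixation = (
        joint.search_env.belief.fixation
        if joint.focus == SEARCH
        else config.search.entry_point
    )
    layout = srch.generate_layout(config.search, target_present, rng)
    joint.search_env.state = layout
    joint.search_env.belief = srch.SearchBelief(
        encoded=[None] * config.search.n_items, fixation=fixation
    )


def _observe(
    joint: JointState, policies: TrainedPolicies, config: MultitaskConfig
) -> tuple[float, float]:
    q_d = max_q(policies.q_drive, _drive_key(joint, config))
    q_s = max_q(policies.q_search, joint.search_env.state_key())
    return q_d, q_s


def _obs_key(
    joint: JointState, policies: TrainedPolicies, config: MultitaskConfig
) -> Hashable:
    q_d, q_s = _observe(joint, policies, config)
    if policies.calibration is None:
        raise ConfigurationError("supervisory q-bin calibration missing")
    qd_bin, qs_bin = policies.calibration.observe(q_d, q_s, config.q_bins)
    return (qd_bin, qs_bin, joint.focus)


class SupervisoryEnv:
    """rl-protocol wrapper so ``train_policy`` can train the supervisor.

    Episodes are continuing multi-task sessions: when a search task
    completes (its reward already includes the completion bonus), a fresh
    layout immediately replaces it and driving carries on, exactly as the
    experimenter switched tasks in the study. Episodes end only by the
    session time limit (truncation, so SARSA bootstraps across it).
    """

    n_actions = 2

    def __init__(self, policies: TrainedPolicies, config: MultitaskConfig):
        policies.require("tau", "q_drive", "q_search")
        if policies.calibration is None:
            raise ConfigurationError("calibrate q-bins before supervisory training")
        self.policies = policies
        self.config = config
        self.joint: JointState | None = None
        self.tasks_completed = 0
        # supervisory decisions span variable time; train_policy compounds
        # the discount over this duration (in driving-cycle units)
        self.last_step_duration = 1.0

    def reset(self, rng: np.random.Generator) -> Hashable:
        target_present = bool(rng.random() < 0.5)
        self.joint = _new_joint_state(self.policies, self.config, target_present, rng)
        self.tasks_completed = 0
        return _obs_key(self.joint, self.policies, self.config)

    def step(
        self, action: int, rng: np.random.Generator
    ) -> tuple[Hashable, float, bool, bool]:
        t_before = self.joint.t
        _, reward, self.joint = supervisory_step(
            action, self.joint, self.policies, self.config, rng
        )
        self.last_step_duration = (
            self.joint.t - t_before
        ) / self.config.driving.dt_drive_s
        senv = self.joint.search_env
        if srch.is_trial_complete(senv.state, senv.belief):
            self.tasks_completed += 1
            install_search_task(
                self.joint, self.config, bool(rng.random() < 0.5), rng
            )
        truncated = self.joint.t >= self.config.session_time_limit_s
        key = _obs_key(self.joint, self.policies, self.config)
        return key, reward, truncated, False


def calibrate_q_bins(
    policies: TrainedPolicies,
    config: MultitaskConfig,
    rng: np.random.Generator,
) -> QCalibration:
    """Warm-up phase: run random-attention trials and record the observed
    range of (max q_drive, max q_search) to fix the equal-width bins."""
    policies.require("tau", "q_drive", "q_search")
    qd_vals: list[float] = []
    qs_vals: list[float] = []
    # sticky random attention with a mixture of switch rates: short,
    # medium and very long glances, so the warm-up samples span the whole
    # observation region from crisp safety to deep blind-driving risk
    switch_probs = (0.25, 0.1, 0.033)
    for i in range(config.n_warmup_trials):
        joint = _new_joint_state(policies, config, target_present=i % 2 == 0, rng=rng)
        p_switch = switch_probs[i % len(switch_probs)]
        action = DRIVE
        while True:
            q_d, q_s = _observe(joint, policies, config)
            qd_vals.append(q_d)
            qs_vals.append(q_s)
            if rng.random() < p_switch:
                action = SEARCH if action == DRIVE else DRIVE
            _, _, joint = supervisory_step(action, joint, policies, config, rng)
            senv = joint.search_env
            if (
                srch.is_trial_complete(senv.state, senv.belief)
                or joint.t >= config.trial_time_limit_s
            ):
                break
    return QCalibration.from_samples(qd_vals, qs_vals, config.q_bins)


def train_supervisory(
    policies: TrainedPolicies,
    config: MultitaskConfig,
    rng: np.random.Generator | None = None,
) -> TrainedPolicies:
    """Train the attention-allocation policy on top of the trained subtasks.

    Runs the q-bin calibration warm-up first if needed, then SARSA over
    continuing sessions. Several independent restarts are trained and the
    Q-table with the highest joint-reward *rate* on held-out
    training-distribution trials is kept (reward rate is the quantity the
    differential learner optimizes). Mutates and returns ``policies``.
    """
    policies.require("tau", "q_drive", "q_search")
    params = config.supervisory_learning
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if policies.calibration is None:
        policies.calibration = calibrate_q_bins(policies, config, rng)
    best: tuple[float, QTable, list[float]] | None = None
    n_restarts = max(1, config.supervisory_restarts)
    for restart in range(n_restarts):
        env = SupervisoryEnv(policies, config)
        run_rng = np.random.default_rng([params.seed, restart, 71])
        initial_q = None
        if restart % 2 == 1 and config.warm_start_sessions > 0:
            # seed the other attractor basin: policy-evaluate naive strict
            # alternation before softmax improvement takes over
            warm_params = replace(
                params, n_episodes=config.warm_start_sessions, alpha=0.1
            )
            initial_q, _ = train_policy(
                env,
                warm_params,
                rng=np.random.default_rng([params.seed, restart, 13]),
                behavior=lambda i, r: SEARCH if i % 2 == 0 else DRIVE,
            )
        qtable, returns = train_policy(
            env, params, rng=run_rng, initial_q=initial_q
        )
        if n_restarts == 1:
            score = 0.0
        else:
            policies.q_supervisory = qtable
            sel_rng = np.random.default_rng([params.seed, restart, 997])
            joint = _new_joint_state(policies, config, True, sel_rng)
            total_reward = 0.0
            for i in range(config.selection_trials):
                trace = run_trial(
                    policies, config, target_present=i % 2 == 0, rng=sel_rng,
                    joint=joint,
                )
                total_reward += trial_joint_reward(trace, config)
            score = total_reward / max(joint.t, 1e-9)
        if best is None or score > best[0]:
            best = (score, qtable, returns)
    policies.q_supervisory = best[1]
    policies.logs["supervisory_returns"] = best[2]
    return policies


# ---------------------------------------------------------------------------
# trial rollout
# ---------------------------------------------------------------------------

SupervisoryPolicy = Callable[[Hashable, JointState, np.random.Generator, int], int]


def always_drive_policy(obs_key, joint, rng, step_index) -> int:
    """Baseline: never look at the display."""
    return DRIVE


def strict_alternation_policy(obs_key, joint, rng, step_index) -> int:
    """Baseline: alternate drive / search every supervisory decision."""
    return SEARCH if step_index % 2 == 0 else DRIVE


def run_trial(
    policies: TrainedPolicies,
    config: MultitaskConfig,
    target_present: bool,
    rng: np.random.Generator,
    supervisory_policy: SupervisoryPolicy | None = None,
    joint: JointState | None = None,
) -> TrialTrace:
    """Simulate one full trial; returns its complete event trace.

    With no explicit ``supervisory_policy`` the trained supervisory
    Q-table selects actions by softmax at the evaluation temperature.
    Passing a ``joint`` state continues an ongoing driving session: a
    fresh search task is installed on the display and the trial runs from
    wherever the car, belief and attention currently are (the caller's
    joint state is mutated, so consecutive calls chain into the continuous
    24-task protocol of the study). Trials that exceed the per-trial time
    limit are flagged ``aborted``.
    """
    if supervisory_policy is None:
        policies.require("tau", "q_drive", "q_search", "q_supervisory")
    else:
        policies.require("tau", "q_drive", "q_search")
    if joint is None:
        joint = _new_joint_state(policies, config, target_present, rng)
    else:
        install_search_task(joint, config, target_present, rng)
    t_origin = joint.t
    events: list[TrialEvent] = []
    step_index = 0
    completed = False
    aborted = False
    while True:
        if supervisory_policy is None:
            key = _obs_key(joint, policies, config)
            action = select_action(
                policies.q_supervisory, key, config.eval_tau, rng
            )
        else:
            key = (
                _obs_key(joint, policies, config)
                if policies.calibration is not None
                else None
            )
            action = supervisory_policy(key, joint, rng, step_index)
        new_events, _, joint = supervisory_step(action, joint, policies, config, rng)
        events.extend(new_events)
        step_index += 1
        senv = joint.search_env
        if srch.is_trial_complete(senv.state, senv.belief):
            completed = True
            break
        if joint.t - t_origin >= config.trial_time_limit_s:
            aborted = True
            break
    return TrialTrace(
        events=events,
        target_present=target_present,
        completed=completed,
        aborted=aborted,
    )


def trial_joint_reward(trace: TrialTrace, config: MultitaskConfig) -> float:
    """Total R_d + weighted R_s accumulated over a trace."""
    return sum(
        e.r_drive + config.search_reward_weight * e.r_search for e in trace.events
    )
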