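"""Lane-keeping POMDP: dynamics, learned transition model, belief filter.

The vehicle drives a slightly leftward-bending highway lane at fixed speed.
The hidden state is the continuous lateral offset from the lane center; the
agent acts by setting the steering wheel to one of a small set of discrete
positions, held for one driving cycle. Together the fixed speed, the chosen
wheel position and the previous lane position determine the next lane
position:

    offset' = offset + v * dt * a + drift * dt + v * dt * N(0, sigma_d)

where ``a`` is the wheel position and the noise term is steering-execution
noise — its lateral effect scales with speed, which is the mechanical
reason faster driving is less stable. The road is bounded: beyond
``offset_range_m`` (the outer edge of the three-lane carriageway) the car
rides the edge.

The agent never sees the continuous state: it tracks a belief over
discretized lane positions with a Bayes filter whose prediction step uses
a *learned* stochastic transition model (empirical next-bin frequencies
from fully observed random-action steps) and whose correction step uses a
bin-confusion observation channel (the true bin is reported with
probability ``p_obs_correct``, otherwise a uniformly random other bin).

For tabular learning the belief is compressed to a sufficient statistic:
its most likely position (argmax) and its Shannon entropy.

Reward is 0 while the car body is within the lane bounds and a negative
penalty proportional to time spent beyond them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable

import numpy as np
import pandas as pd
from scipy.special import xlogy as _xlogy

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "DrivingParams",
    "DrivingState",
    "TransitionModel",
    "BeliefSummary",
    "simulate_step",
    "learn_transition_model",
    "belief_predict",
    "belief_correct",
    "belief_summary",
    "driving_reward",
    "entropy_bin",
    "belief_state_key",
    "sample_observation",
    "initial_belief",
    "DrivingEnv",
]


class ConfigurationError(ValueError):
    """Raised when a parameter set or action is inconsistent."""


@dataclass
class DrivingParams:
    """Driving task parameters.

    speed_kmh : condition value, 60 or 120 in the study design (any
        positive value is accepted).
    lane_width_m : lane width; with ``car_width_m`` it sets the deviation
        threshold (lane deviation = the car body crossing the lane edge).
    car_width_m : vehicle width; 0 restores the point-car convention with
        its ±lane_width/2 threshold.
    n_position_bins : odd number of discretization bins for the lateral
        offset over [-offset_range_m, +offset_range_m].
    action_set : ordered absolute steering-wheel positions
        (dimensionless); must contain 0 (wheel centered). The resulting
        lateral velocity is speed * position.
    sigma_d : SD of steering-execution noise per driving cycle
        (dimensionless, in wheel-position units); lateral effect
        speed * dt * sigma_d.
    p_obs_correct : probability an observation reports the true bin.
    dt_drive_s : seconds per driving cycle.
    curvature_drift_mps : constant lateral drift (m/s) emulating the
        slightly leftward-bending road; 0 disables it.
    penalty_rate : out-of-lane penalty per second, sized so that a typical
        deviation wipes out a large share of one search task's gain —
        keeping the driving objective (cumulative R_d near 0) binding.
    """

    speed_kmh: float = 60.0
    lane_width_m: float = 3.5
    car_width_m: float = 1.8
    n_position_bins: int = 21
    offset_range_m: float = 3.5
    action_set: tuple[float, ...] = (-0.1, -0.03, -0.01, 0.0, 0.01, 0.03, 0.1)
    sigma_d: float = 0.03
    p_obs_correct: float = 0.9
    dt_drive_s: float = 0.25
    curvature_drift_mps: float = 0.02
    penalty_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.n_position_bins < 1 or self.n_position_bins % 2 == 0:
            raise ConfigurationError("n_position_bins must be odd and positive")
        if not (0.0 < self.p_obs_correct <= 1.0):
            raise ConfigurationError("p_obs_correct must be in (0, 1]")
        if self.dt_drive_s <= 0:
            raise ConfigurationError("dt_drive_s must be > 0")
        if 0.0 not in self.action_set:
            raise ConfigurationError("action_set must contain the centered wheel 0")
        if self.speed_kmh <= 0:
            raise ConfigurationError("speed_kmh must be > 0")
        if self.car_width_m >= self.lane_width_m:
            raise ConfigurationError("car wider than lane")

    @property
    def speed_mps(self) -> float:
        return self.speed_kmh / 3.6

    @property
    def lane_half_bound(self) -> float:
        return self.lane_width_m / 2.0

    @property
    def deviation_bound(self) -> float:
        """Offset beyond which the car body is outside the lane."""
        return (self.lane_width_m - self.car_width_m) / 2.0

    @property
    def n_actions(self) -> int:
        return len(self.action_set)

    @property
    def bin_width(self) -> float:
        return 2.0 * self.offset_range_m / self.n_position_bins

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.linspace(
            -self.offset_range_m, self.offset_range_m, self.n_position_bins + 1
        )
        return 0.5 * (edges[:-1] + edges[1:])

    def discretize(self, offset: float) -> int:
        """Bin index of a lateral offset; out-of-range clamps to edge bins."""
        idx = int(np.floor((offset + self.offset_range_m) / self.bin_width))
        return int(np.clip(idx, 0, self.n_position_bins - 1))

    def action_index(self, action: float) -> int:
        for i, a in enumerate(self.action_set):
            if abs(a - action) < 1e-12:
                return i
        raise ConfigurationError(f"action {action!r} not in action_set")


@dataclass
class DrivingState:
    """True (hidden) driving state; ``steering`` is the current wheel
    position, i.e. the last action applied (held between decisions)."""

    lateral_offset_m: float = 0.0
    steering: float = 0.0
    speed_kmh: float = 60.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lateral_offset_m):
            raise ConfigurationError("lateral_offset_m must be finite")


@dataclass(frozen=True)
class BeliefSummary:
    """Sufficient statistic of the driving belief: (argmax bin, entropy)."""

    map_position: int
    entropy: float


def simulate_step(
    state: DrivingState,
    action: float,
    params: DrivingParams,
    rng: np.random.Generator,
    duration: float | None = None,
) -> DrivingState:
    """Advance the true dynamics one driving cycle.

    ``action`` is the absolute wheel position for the cycle. ``duration``
    defaults to ``dt_drive_s``; a shorter value scales the deterministic
    terms linearly and the noise SD by sqrt(duration/dt), so composing two
    half-cycles matches one full cycle in distribution.
    """
    params.action_index(action)  # raises ConfigurationError if invalid
    dt = params.dt_drive_s if duration is None else float(duration)
    if dt <= 0:
        raise ConfigurationError("duration must be > 0")
    noise_sd = (
        params.speed_mps
        * params.dt_drive_s
        * params.sigma_d
        * np.sqrt(dt / params.dt_drive_s)
    )
    offset = (
        state.lateral_offset_m
        + params.speed_mps * dt * action
        + params.curvature_drift_mps * dt
        + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    )
    # the road is not unbounded: +-offset_range_m is the outer edge of the
    # three-lane carriageway (also the belief's support); the car rides
    # the edge beyond it, still accruing out-of-lane penalties
    offset = float(np.clip(offset, -params.offset_range_m, params.offset_range_m))
    return DrivingState(
        lateral_offset_m=offset, steering=float(action), speed_kmh=state.speed_kmh
    )


class TransitionModel:
    """Learned stochastic model tau_d of the driving physics.

    Stores visit counts per (from_bin, action, to_bin); conditional
    distributions are normalized on query. Rows never visited fall back to
    an identity-plus-diffusion prior (stay with probability 1-2*eps, move
    to each neighbor with eps; edge bins keep the lost mass), which
    prevents zero-probability traps early in learning.
    """

    FALLBACK_EPS = 0.05

    def __init__(self, params: DrivingParams):
        self.params = params
        n = params.n_position_bins
        self.counts = np.zeros((n, params.n_actions, n))
        self._matrices: dict[int, np.ndarray] | None = None

    def record(self, from_bin: int, action_index: int, to_bin: int) -> None:
        self.counts[from_bin, action_index, to_bin] += 1
        self._matrices = None

    def fallback_row(self, from_bin: int) -> np.ndarray:
        n = self.params.n_position_bins
        eps = self.FALLBACK_EPS
        row = np.zeros(n)
        row[from_bin] = 1.0 - 2.0 * eps
        for nb in (from_bin - 1, from_bin + 1):
            if 0 <= nb < n:
                row[nb] += eps
            else:
                row[from_bin] += eps  # reflect lost mass back: keeps row stochastic
        return row

    def prob(self, from_bin: int, action_index: int) -> np.ndarray:
        """Conditional distribution over next bins; sums to 1."""
        return self.matrix(action_index)[from_bin]

    def matrix(self, action_index: int) -> np.ndarray:
        """Row-stochastic transition matrix P[i, j] = p(j | i, a)."""
        if self._matrices is None:
            self._matrices = {}
        mat = self._matrices.get(action_index)
        if mat is None:
            c = self.counts[:, action_index, :]
            totals = c.sum(axis=1)
            mat = np.empty_like(c)
            for i in range(c.shape[0]):
                if totals[i] > 0:
                    mat[i] = c[i] / totals[i]
                else:
                    mat[i] = self.fallback_row(i)
            self._matrices[action_index] = mat
        return mat

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in range(self.params.n_actions):
            mat = self.matrix(a)
            for i in range(self.params.n_position_bins):
                for j in np.nonzero(mat[i])[0]:
                    rows.append((i, a, int(j), float(mat[i, j])))
        return pd.DataFrame(
            rows, columns=["from_bin", "action_index", "to_bin", "probability"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: DrivingParams) -> "TransitionModel":
        df = pd.read_csv(path)
        model = cls(params)
        matrices = {
            a: np.zeros((params.n_position_bins, params.n_position_bins))
            for a in range(params.n_actions)
        }
        for row in df.itertuples(index=False):
            matrices[int(row.action_index)][int(row.from_bin), int(row.to_bin)] = (
                row.probability
            )
        # loaded probabilities stand in directly; counts stay empty
        model._matrices = matrices
        return model


def learn_transition_model(
    params: DrivingParams,
    n_rollout_steps: int,
    rng: np.random.Generator,
) -> TransitionModel:
    """Learn tau_d from fully observed random-action transitions.

    Each sampled step starts at a uniformly random bin center, applies a
    random wheel position, and records the observed (bin, action,
    next-bin) transition.
    """
    if n_rollout_steps < 1:
        raise ConfigurationError("n_rollout_steps must be >= 1")
    model = TransitionModel(params)
    centers = params.bin_centers
    n = params.n_position_bins
    for _ in range(n_rollout_steps):
        from_bin = int(rng.integers(n))
        state = DrivingState(
            lateral_offset_m=float(centers[from_bin]),
            steering=0.0,
            speed_kmh=params.speed_kmh,
        )
        a_idx = int(rng.integers(params.n_actions))
        nxt = simulate_step(state, params.action_set[a_idx], params, rng)
        model.record(from_bin, a_idx, params.discretize(nxt.lateral_offset_m))
    return model


def initial_belief(params: DrivingParams, at_bin: int | None = None) -> np.ndarray:
    """Point-mass belief at a bin (default: the center bin)."""
    b = np.zeros(params.n_position_bins)
    b[at_bin if at_bin is not None else params.n_position_bins // 2] = 1.0
    return b


def belief_predict(
    belief: np.ndarray, action_index: int, tau: TransitionModel
) -> np.ndarray:
    """Prediction step of the Bayes filter: push the belief through tau_d
    for the chosen action.

    This is the update used alone while "driving blind" with attention on
    the in-car task.
    """
    pred = belief @ tau.matrix(action_index)
    s = pred.sum()
    return pred / s if s > 0 else pred


def belief_correct(
    predicted: np.ndarray, observation: int, params: DrivingParams
) -> np.ndarray:
    """Correction step: Bayes posterior under the bin-confusion channel.

    The likelihood puts ``p_obs_correct`` on the observed bin and spreads
    the remainder uniformly over the other bins. A zero normalizer (an
    observation impossible under a degenerate belief) resets the belief to
    the normalized likelihood itself.
    """
    n = params.n_position_bins
    if not (0 <= observation < n):
        raise ConfigurationError("observation bin out of range")
    if n == 1:
        return np.ones(1)
    lik = np.full(n, (1.0 - params.p_obs_correct) / (n - 1))
    lik[observation] = params.p_obs_correct
    post = lik * predicted
    z = post.sum()
    if z <= 0.0:
        logger.warning(
            "belief_correct: zero normalizer for observation %d; "
            "resetting belief to the likelihood",
            observation,
        )
        return lik / lik.sum()
    return post / z


def belief_summary(belief: np.ndarray) -> BeliefSummary:
    """(argmax position, entropy in nats); ties break to the lowest index."""
    ent = float(-_xlogy(belief, belief).sum())  # nats, 0*log0 == 0
    return BeliefSummary(map_position=int(np.argmax(belief)), entropy=max(ent, 0.0))


def entropy_bin(ent: float, params: DrivingParams, n_entropy_bins: int = 8) -> int:
    """Equal-width bin of a belief entropy over [0, log(n_position_bins)]."""
    max_ent = np.log(params.n_position_bins)
    if max_ent <= 0:
        return 0
    idx = int(ent / max_ent * n_entropy_bins)
    return int(np.clip(idx, 0, n_entropy_bins - 1))


def belief_state_key(
    belief: np.ndarray, params: DrivingParams, n_entropy_bins: int = 8
) -> tuple[int, int]:
    """Discretized policy state: (argmax bin, entropy bin)."""
    s = belief_summary(belief)
    return (s.map_position, entropy_bin(s.entropy, params, n_entropy_bins))


def driving_reward(
    state: DrivingState, params: DrivingParams, duration: float
) -> float:
    """0 while the car is within the lane bounds (closed interval), else
    -penalty_rate * duration. The bound accounts for the car's width; set
    ``car_width_m = 0`` for the point-car convention."""
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    if abs(state.lateral_offset_m) <= params.deviation_bound:
        return 0.0
    return -params.penalty_rate * duration


def sample_observation(
    state: DrivingState, params: DrivingParams, rng: np.random.Generator
) -> int:
    """Draw an observed bin from the bin-confusion observation channel."""
    true_bin = params.discretize(state.lateral_offset_m)
    n = params.n_position_bins
    if n == 1 or rng.random() < params.p_obs_correct:
        return true_bin
    other = int(rng.integers(n - 1))
    return other + (other >= true_bin)


class DrivingEnv:
    """Training environment for the lane-keeping policy.

    State key is the belief's sufficient statistic: (argmax bin, entropy
    bin). Each step the policy sets the wheel, the true state advances,
    and the belief runs a predict step followed by a correction with a
    fresh observation — except during blind *bursts*: occlusion intervals
    of geometric length (occasionally much longer) that mimic the
    glance-shaped observation gaps the policy will face under the
    supervisory model. Episodes also use belief exploring-starts — some
    begin already uncertain, with the truth sampled from a random-width
    belief — so every entropy bin of the policy key is trained. Episodes
    are fixed length (time-limit truncation; SARSA bootstraps across the
    boundary).
    """

    def __init__(
        self,
        params: DrivingParams,
        tau: TransitionModel,
        episode_steps: int = 120,
        n_entropy_bins: int = 8,
        obs_burst_prob: float = 0.1,
        obs_burst_mean_steps: float = 8.0,
        exploring_start_prob: float = 0.2,
        start_offset_sd_m: float = 0.5,
    ):
        self.params = params
        self.tau = tau
        self.episode_steps = episode_steps
        self.n_entropy_bins = n_entropy_bins
        self.obs_burst_prob = obs_burst_prob
        self.obs_burst_mean_steps = obs_burst_mean_steps
        self.exploring_start_prob = exploring_start_prob
        self.start_offset_sd_m = start_offset_sd_m
        self.n_actions = params.n_actions
        self.state: DrivingState | None = None
        self.belief: np.ndarray | None = None
        self._steps = 0
        self._blind_remaining = 0

    def state_key(self) -> Hashable:
        return belief_state_key(self.belief, self.params, self.n_entropy_bins)

    def reset(self, rng: np.random.Generator) -> Hashable:
        p = self.params
        if rng.random() < self.exploring_start_prob:
            center = float(rng.uniform(-p.offset_range_m, p.offset_range_m))
        else:
            center = float(np.clip(rng.normal(0.0, self.start_offset_sd_m), -1.5, 1.5))
        # belief exploring-start: begin some episodes already uncertain;
        # occasionally fully lost (near-uniform belief) so the deepest
        # entropy bins are trained too, not just reachable
        if rng.random() < 0.1:
            self.belief = np.full(p.n_position_bins, 1.0 / p.n_position_bins)
            start = float(rng.uniform(-p.offset_range_m, p.offset_range_m))
        else:
            spread = float(rng.uniform(0.0, 1.2))  # meters
            if spread < p.bin_width / 2:
                start = center
                self.belief = initial_belief(p, p.discretize(center))
            else:
                pdf = np.exp(-0.5 * ((p.bin_centers - center) / spread) ** 2)
                self.belief = pdf / pdf.sum()
                start = float(
                    np.clip(
                        rng.normal(center, spread),
                        -p.offset_range_m,
                        p.offset_range_m,
                    )
                )
        self.state = DrivingState(
            lateral_offset_m=start, steering=0.0, speed_kmh=p.speed_kmh
        )
        self._steps = 0
        self._blind_remaining = 0
        return self.state_key()

    def step(
        self, action: int, rng: np.random.Generator
    ) -> tuple[Hashable, float, bool, bool]:
        p = self.params
        self.state = simulate_step(self.state, p.action_set[action], p, rng)
        self.belief = belief_predict(self.belief, action, self.tau)
        if self._blind_remaining > 0:
            self._blind_remaining -= 1
        else:
            if self.obs_burst_prob > 0 and rng.random() < self.obs_burst_prob:
                # occlusion burst; mostly glance-length, occasionally much
                # longer so deep-blindness states are also covered
                mean = self.obs_burst_mean_steps * (1.0 if rng.random() < 0.7 else 3.0)
                self._blind_remaining = int(rng.geometric(1.0 / mean))
            else:
                obs = sample_observation(self.state, p, rng)
                self.belief = belief_correct(self.belief, obs, p)
        r = driving_reward(self.state, p, p.dt_drive_s)
        self._steps += 1
        done = self._steps >= self.episode_steps
        return self.state_key(), r, done, False  # truncation, never terminal
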