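"""Tabular SARSA learning and softmax action selection.

All three policies in the hierarchy (lane keeping, visual search, supervisory
attention allocation) are learned with the same on-policy machinery: a
Q-table over discretized state keys, the SARSA temporal-difference update

    Q(s,a) <- Q(s,a) + alpha * [r + gamma * Q(s',a') - Q(s,a)]

and softmax (Boltzmann) action selection with temperature ``tau_sm``,

    p(a) = exp(Q(s,a)/tau_sm) / sum_i exp(Q(s,i)/tau_sm).

The softmax temperature is annealed linearly over training episodes;
post-training simulation keeps a small non-zero temperature so behavior
stays mildly stochastic, like human behavior, rather than greedy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Hashable, Protocol

import numpy as np
import pandas as pd

__all__ = [
    "QTable",
    "LearningParams",
    "sarsa_update",
    "softmax_probs",
    "select_action",
    "train_policy",
    "max_q",
]


class Environment(Protocol):
    """Contract an environment must satisfy for :func:`train_policy`.

    ``reset`` starts an episode and returns the initial state key;
    ``step`` applies an action index and returns
    ``(next_state_key, reward, done, terminal)`` where ``done`` ends the
    episode and ``terminal`` distinguishes true task completion (no
    bootstrapping) from a time-limit truncation (bootstrap continues).
    """

    n_actions: int

    def reset(self, rng: np.random.Generator) -> Hashable: ...

    def step(
        self, action: int, rng: np.random.Generator
    ) -> tuple[Hashable, float, bool, bool]: ...


class QTable:
    """State-key -> action-utility vector map with a zero default.

    Unseen states resolve to the zero vector, which under softmax selection
    yields uniform exploration.
    """

    def __init__(self, n_actions: int):
        if n_actions < 1:
            raise ValueError("n_actions must be >= 1")
        self.n_actions = int(n_actions)
        self._table: dict[Hashable, np.ndarray] = {}

    def get(self, state_key: Hashable) -> np.ndarray:
        """Q vector for a state; zeros if never visited (read-only view)."""
        q = self._table.get(state_key)
        if q is None:
            return np.zeros(self.n_actions)
        return q

    def ensure(self, state_key: Hashable) -> np.ndarray:
        """Q vector for a state, inserting a zero vector if absent."""
        q = self._table.get(state_key)
        if q is None:
            q = np.zeros(self.n_actions)
            self._table[state_key] = q
        return q

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, state_key: Hashable) -> bool:
        return state_key in self._table

    def items(self):
        return self._table.items()

    def copy(self) -> "QTable":
        new = QTable(self.n_actions)
        new._table = {k: v.copy() for k, v in self._table.items()}
        return new

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (repr(key), a, float(q[a]))
            for key, q in self._table.items()
            for a in range(self.n_actions)
        ]
        return pd.DataFrame(rows, columns=["state_key", "action_index", "q_value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "QTable":
        import ast

        df = pd.read_csv(path)
        n_actions = int(df["action_index"].max()) + 1
        qt = cls(n_actions)
        for state_repr, group in df.groupby("state_key", sort=False):
            key = ast.literal_eval(state_repr)
            if isinstance(key, list):
                key = tuple(key)
            vec = np.zeros(n_actions)
            vec[group["action_index"].to_numpy()] = group["q_value"].to_numpy()
            qt._table[key] = vec
        return qt


@dataclass
class LearningParams:
    """SARSA hyperparameters.

    alpha : learning rate in (0, 1].
    gamma : discount factor in [0, 1].
    tau_sm : softmax temperature at the start of training (> 0). The
        environment-dynamics model tau_d is a different object entirely;
        the suffix keeps them apart.
    tau_sm_final : temperature at the end of the linear anneal; also the
        default evaluation temperature.
    n_episodes : training episodes.
    seed : base seed for the training RNG.
    """

    alpha: float = 0.1
    alpha_final: float | None = None
    # count-adaptive step size: alpha_eff = max(alpha, 1/(1+n_visits)).
    # The first update of a (state, action) pair jumps to its bootstrapped
    # target instead of creeping up from 0, so rarely tried actions are
    # not systematically underestimated in continuing tasks
    count_adaptive_alpha: bool = True
    # differential (average-reward) mode for continuing tasks: the update
    # target uses r - rho*duration with no discounting, where rho is the
    # learned reward rate per base-cycle; Q values become relative
    # advantages, which keeps them small and comparable across actions
    average_reward: bool = False
    rho_lr: float = 0.01
    # scale-free exploration floor: with probability epsilon a uniform
    # action is taken regardless of Q gaps, so no action's estimate ever
    # goes permanently stale (softmax alone stops sampling an action once
    # its gap exceeds a few temperatures)
    epsilon: float = 0.0
    gamma: float = 0.95
    tau_sm: float = 1.0
    tau_sm_final: float = 0.05
    n_episodes: int = 1000
    seed: int = 0
    max_steps_per_episode: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.alpha_final is not None and not (0.0 < self.alpha_final <= 1.0):
            raise ValueError("alpha_final must be in (0, 1]")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.tau_sm <= 0 or self.tau_sm_final <= 0:
            raise ValueError("softmax temperatures must be > 0")
        if self.n_episodes < 0:
            raise ValueError("n_episodes must be >= 0")

    def temperature(self, episode: int) -> float:
        """Linearly annealed temperature for a given episode index."""
        if self.n_episodes <= 1:
            return self.tau_sm
        frac = episode / (self.n_episodes - 1)
        return self.tau_sm + frac * (self.tau_sm_final - self.tau_sm)

    def learning_rate(self, episode: int) -> float:
        """Linearly annealed step size (constant if alpha_final unset):
        late-training averaging damps the variance of noisy returns."""
        if self.alpha_final is None or self.n_episodes <= 1:
            return self.alpha
        frac = episode / (self.n_episodes - 1)
        return self.alpha + frac * (self.alpha_final - self.alpha)


def sarsa_update(
    q_sa: float, r: float, q_next: float, alpha: float, gamma: float
) -> float:
    """One SARSA temporal-difference update; returns the new Q(s,a)."""
    if not (
        math.isfinite(q_sa) and math.isfinite(r) and math.isfinite(q_next)
    ):
        raise ValueError("non-finite input to sarsa_update")
    return q_sa + alpha * (r + gamma * q_next - q_sa)


def softmax_probs(q_values: np.ndarray, tau_sm: float) -> np.ndarray:
    """Boltzmann action probabilities.

    Computed with max-subtraction for overflow safety; by shift invariance
    of the softmax this is numerically identical to the plain form.
    """
    if tau_sm <= 0:
        raise ValueError("softmax temperature must be > 0")
    q = np.asarray(q_values, dtype=float)
    z = (q - q.max()) / tau_sm
    e = np.exp(z)
    return e / e.sum()


def select_action(
    qtable: QTable,
    state_key: Hashable,
    tau_sm: float,
    rng: np.random.Generator,
    valid: "list[int] | np.ndarray | None" = None,
) -> int:
    """Sample an action index from the softmax over a state's Q vector.

    ``valid`` restricts the choice to a subset of action indices
    (action-space pruning for states where some actions are provably
    wasted); the returned index is always in the full action space.
    """
    q = qtable.get(state_key)
    if valid is not None:
        valid = np.asarray(valid)
        probs = softmax_probs(q[valid], tau_sm)
        pick = int(np.searchsorted(np.cumsum(probs), rng.random()))
        return int(valid[min(pick, len(valid) - 1)])
    probs = softmax_probs(q, tau_sm)
    # inverse-CDF sampling; rng.choice is an order of magnitude slower
    return int(np.searchsorted(np.cumsum(probs), rng.random()))


def max_q(qtable: QTable, state_key: Hashable) -> float:
    """Best available action utility for a state; 0 for unseen states."""
    return float(qtable.get(state_key).max())


def train_policy(
    env: Environment,
    params: LearningParams,
    rng: np.random.Generator | None = None,
    callback: Callable[[int, float], None] | None = None,
    initial_q: QTable | None = None,
    behavior: Callable[[int, np.random.Generator], int] | None = None,
) -> tuple[QTable, list[float]]:
    """Run SARSA with annealed softmax selection on an environment.

    ``initial_q`` warm-starts the table (it is trained in place);
    ``behavior`` replaces softmax selection with a fixed behavior policy
    mapping (step index, rng) to an action — on-policy evaluation of that
    behavior. Returns the learned Q-table and the per-episode return log.
    Raises ``RuntimeError`` if a Q-value diverges (becomes non-finite).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    qtable = initial_q if initial_q is not None else QTable(env.n_actions)
    returns: list[float] = []
    visit_counts: dict[tuple[Hashable, int], int] = {}
    get_valid = getattr(env, "valid_actions", None)
    rho = 0.0  # average reward per base cycle (differential mode only)
    step_index = 0
    for episode in range(params.n_episodes):
        tau = params.temperature(episode)
        alpha = params.learning_rate(episode)
        s = env.reset(rng)
        def _select(state_key):
            valid = get_valid() if get_valid else None
            if params.epsilon > 0 and rng.random() < params.epsilon:
                pool = valid if valid is not None else range(env.n_actions)
                pool = list(pool)
                return int(pool[rng.integers(len(pool))])
            return select_action(qtable, state_key, tau, rng, valid=valid)

        if behavior is not None:
            a = behavior(step_index, rng)
        else:
            a = _select(s)
        total = 0.0
        for _ in range(params.max_steps_per_episode):
            step_index += 1
            s2, r, done, terminal = env.step(a, rng)
            total += r
            q_s = qtable.ensure(s)
            # semi-Markov discounting: environments whose steps span
            # variable amounts of time report the duration (in base-cycle
            # units) and the discount compounds over it
            dur = getattr(env, "last_step_duration", 1.0)
            gamma_eff = 1.0 if params.average_reward else params.gamma**dur
            if done and terminal:
                target_next = 0.0
                a2 = 0
            else:
                if behavior is not None:
                    a2 = behavior(step_index, rng)
                else:
                    a2 = _select(s2)
                target_next = float(qtable.get(s2)[a2])
            if params.count_adaptive_alpha:
                n_sa = visit_counts.get((s, a), 0)
                visit_counts[(s, a)] = n_sa + 1
                alpha_eff = max(alpha, 1.0 / (1.0 + n_sa))
            else:
                alpha_eff = alpha
            r_eff = r - rho * dur if params.average_reward else r
            q_old = float(q_s[a])
            q_s[a] = sarsa_update(q_old, r_eff, target_next, alpha_eff, gamma_eff)
            if params.average_reward:
                # R-learning: track the reward rate from the TD error
                delta = r_eff + target_next - q_old
                rho += params.rho_lr * delta / max(dur, 1e-9)
            if not math.isfinite(q_s[a]):
                raise RuntimeError(
                    f"SARSA diverged at episode {episode}: Q became non-finite"
                )
            if done:
                break
            s, a = s2, a2
        returns.append(total)
        if callback is not None:
            callback(episode, total)
    return qtable, returns


def training_log_frame(returns: list[float]) -> pd.DataFrame:
    return pd.DataFrame({"episode": range(len(returns)), "return": returns})
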