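"""In-car visual-search POMDP with EMMA oculomotor timing.

The driver searches a small dashboard display for a target among randomly
placed three-letter items. Items are points in degrees of visual angle on
the display plane, separated by at least ``min_separation`` so each needs
its own fixation. The model's belief starts as an empty grid that fills
with encoded items; it also carries the eyes' fixation location.

Timing follows the EMMA eye-movement model. Encoding a visual object of
frequency ``f`` at eccentricity ``ecc`` (degrees from fixation) takes

    T_e = K * (-log f) * exp(k * ecc)

and a saccade covering distance D degrees takes

    T_s = t_prep + t_exec + D * t_sacc.

If T_e < t_prep the object is encoded without the eyes moving; otherwise a
saccade brings fixation to the object and the remaining fraction of the
encoding (restarted at zero eccentricity) completes afterwards.

Each encoding costs its elapsed time as negative reward; finding the
target — or, on a foil trial, encoding every item — ends the trial with a
large positive reward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
import pandas as pd

from .driving import ConfigurationError

__all__ = [
    "SearchParams",
    "SearchState",
    "SearchBelief",
    "generate_layout",
    "encoding_time",
    "saccade_time",
    "encode_action",
    "search_reward",
    "is_trial_complete",
    "SearchEnv",
    "layout_to_frame",
]


@dataclass
class SearchParams:
    """Search task and oculomotor parameters.

    n_items : items on the display (6 or 9 in the study design).
    extent_x_deg, extent_y_deg : display span in degrees of visual angle
        (a dashboard display of roughly 10 x 6 degrees).
    min_separation_deg : minimum pairwise item distance (2 degrees, so
        every item requires its own fixation).
    item_frequency : EMMA object frequency f in (0, 1]. The default 1e-5
        (novel trigram stimuli) makes the covert-encoding radius — the
        eccentricity below which T_e < t_prep and no saccade fires —
        about 1.7 degrees, so items separated by the 2-degree minimum
        each demand their own fixation, as the display design intends.
    encoding_constant_s : EMMA K, seconds.
    eccentricity_constant : EMMA k, per degree.
    t_prep_s, t_exec_s : saccade preparation and execution times, seconds.
    t_sacc_s_per_deg : incremental saccade time per degree.
    reward_found : positive reward when the target is found.
    reward_foil_complete : reward for exhausting a foil display; defaults
        to the same value, set 0 to reward only target detection.
    """

    n_items: int = 6
    extent_x_deg: float = 10.0
    extent_y_deg: float = 6.0
    min_separation_deg: float = 2.0
    item_frequency: float = 1e-5
    encoding_constant_s: float = 0.006
    eccentricity_constant: float = 0.4
    t_prep_s: float = 0.135
    t_exec_s: float = 0.070
    t_sacc_s_per_deg: float = 0.002
    reward_found: float = 10.0
    reward_foil_complete: float = 10.0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigurationError("n_items must be >= 1")
        if self.min_separation_deg <= 0:
            raise ConfigurationError("min_separation_deg must be > 0")
        if not (0.0 < self.item_frequency <= 1.0):
            raise ConfigurationError("item_frequency must be in (0, 1]")
        for name in ("encoding_constant_s", "t_prep_s", "t_exec_s", "t_sacc_s_per_deg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def entry_point(self) -> tuple[float, float]:
        """Display entry fixation: top-center, where the eyes land when
        arriving from the road above."""
        return (0.0, self.extent_y_deg / 2.0)


@dataclass
class SearchState:
    """Physical display state plus current eye fixation."""

    item_positions: np.ndarray  # (n_items, 2) in degrees
    target_index: int | None
    fixation: tuple[float, float]


@dataclass
class SearchBelief:
    """Initially empty grid of encoded items, plus the fixation location.

    ``encoded[i]`` is None until item i has been encoded, then True/False
    for target/non-target identity.
    """

    encoded: list[bool | None]
    fixation: tuple[float, float]

    @classmethod
    def empty(cls, params: SearchParams) -> "SearchBelief":
        return cls(encoded=[None] * params.n_items, fixation=params.entry_point)

    @property
    def n_encoded(self) -> int:
        return sum(1 for e in self.encoded if e is not None)

    def target_found(self) -> bool:
        return any(e is True for e in self.encoded)


def generate_layout(
    params: SearchParams, target_present: bool, rng: np.random.Generator
) -> SearchState:
    """Rejection-sample a random item layout honoring the separation rule."""
    half_x = params.extent_x_deg / 2.0
    half_y = params.extent_y_deg / 2.0
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < params.n_items:
        if attempts >= 10_000:
            raise ConfigurationError(
                "could not place items at the required separation; display too small"
            )
        attempts += 1
        cand = np.array(
            [rng.uniform(-half_x, half_x), rng.uniform(-half_y, half_y)]
        )
        if all(
            np.linalg.norm(cand - p) >= params.min_separation_deg for p in positions
        ):
            positions.append(cand)
    target_index = int(rng.integers(params.n_items)) if target_present else None
    return SearchState(
        item_positions=np.array(positions),
        target_index=target_index,
        fixation=params.entry_point,
    )


def encoding_time(f: float, eccentricity: float, params: SearchParams) -> float:
    """EMMA encoding time K * (-log f) * exp(k * eccentricity), seconds."""
    if f <= 0 or f > 1:
        raise ConfigurationError("object frequency f must be in (0, 1]")
    if eccentricity < 0:
        raise ConfigurationError("eccentricity must be >= 0")
    return (
        params.encoding_constant_s
        * (-math.log(f))
        * math.exp(params.eccentricity_constant * eccentricity)
    )


def saccade_time(distance: float, params: SearchParams) -> float:
    """Saccade duration t_prep + t_exec + D * t_sacc, seconds."""
    if distance < 0:
        raise ConfigurationError("saccade distance must be >= 0")
    return params.t_prep_s + params.t_exec_s + distance * params.t_sacc_s_per_deg


def encode_action(
    state: SearchState,
    belief: SearchBelief,
    item: int,
    params: SearchParams,
) -> tuple[SearchBelief, float]:
    """Encode one item, returning the updated belief and elapsed seconds.

    If the encoding completes faster than saccade preparation
    (T_e < t_prep), the item is encoded covertly and fixation stays put.
    Otherwise a saccade moves fixation to the item; the fraction of
    encoding finished during the saccade carries over, and the remainder
    is re-done at zero eccentricity.

    Re-encoding an already-encoded item is allowed (it wastes time;
    policies learn to avoid it).
    """
    if not (0 <= item < len(belief.encoded)):
        raise ConfigurationError("item index out of range")
    pos = state.item_positions[item]
    ecc = float(np.linalg.norm(np.asarray(belief.fixation) - pos))
    t_enc = encoding_time(params.item_frequency, ecc, params)
    new_encoded = list(belief.encoded)
    new_encoded[item] = item == state.target_index
    if t_enc < params.t_prep_s:
        return SearchBelief(encoded=new_encoded, fixation=belief.fixation), t_enc
    t_sac = saccade_time(ecc, params)
    completed_fraction = min(1.0, t_sac / t_enc)
    residual = (1.0 - completed_fraction) * encoding_time(
        params.item_frequency, 0.0, params
    )
    new_fix = (float(pos[0]), float(pos[1]))
    return SearchBelief(encoded=new_encoded, fixation=new_fix), t_sac + residual


def search_reward(elapsed: float, trial_done: bool, params: SearchParams,
                  foil: bool = False) -> float:
    """Negative encoding time, plus the completion reward when done."""
    if elapsed < 0:
        raise ConfigurationError("elapsed must be >= 0")
    r = -elapsed
    if trial_done:
        r += params.reward_foil_complete if foil else params.reward_found
    return r


def is_trial_complete(state: SearchState, belief: SearchBelief) -> bool:
    """Target encoded (target-present) or every item encoded (foil)."""
    if state.target_index is not None:
        return belief.encoded[state.target_index] is not None
    return all(e is not None for e in belief.encoded)


def layout_to_frame(state: SearchState) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_index": range(len(state.item_positions)),
            "x_deg": state.item_positions[:, 0],
            "y_deg": state.item_positions[:, 1],
            "is_target": [
                i == state.target_index for i in range(len(state.item_positions))
            ],
        }
    )


class SearchEnv:
    """Training environment for the search policy.

    The policy state is coarse, keeping the Q-table tractable: the display
    is partitioned into 3x3 cells, and the key is (fixation cell, 9-bit
    mask of cells that still contain at least one unencoded item). Actions
    name a cell; acting on a cell encodes its nearest unencoded item (or
    re-encodes its nearest item if all are done — a pure waste the policy
    learns to avoid); acting on an empty cell just saccades to its center.

    ``interruption_prob`` teleports the fixation back to the display entry
    point before a step, emulating the road glances that interrupt search
    in the multitask setting, so the policy also learns the re-entry
    states it will face there.
    """

    N_CELLS_X = 3
    N_CELLS_Y = 3

    def __init__(self, params: SearchParams, max_actions: int = 100,
                 p_target_present: float = 0.5, interruption_prob: float = 0.0):
        self.params = params
        self.max_actions = max_actions
        self.p_target_present = p_target_present
        self.interruption_prob = interruption_prob
        self.n_actions = self.N_CELLS_X * self.N_CELLS_Y
        self.state: SearchState | None = None
        self.belief: SearchBelief | None = None
        self._steps = 0

    def cell_of(self, xy) -> int:
        p = self.params
        cx = int(
            np.clip(
                (xy[0] + p.extent_x_deg / 2) / p.extent_x_deg * self.N_CELLS_X,
                0,
                self.N_CELLS_X - 1,
            )
        )
        cy = int(
            np.clip(
                (xy[1] + p.extent_y_deg / 2) / p.extent_y_deg * self.N_CELLS_Y,
                0,
                self.N_CELLS_Y - 1,
            )
        )
        return cy * self.N_CELLS_X + cx

    def cell_center(self, cell: int) -> tuple[float, float]:
        p = self.params
        cy, cx = divmod(cell, self.N_CELLS_X)
        x = (cx + 0.5) / self.N_CELLS_X * p.extent_x_deg - p.extent_x_deg / 2
        y = (cy + 0.5) / self.N_CELLS_Y * p.extent_y_deg - p.extent_y_deg / 2
        return (x, y)

    def state_key(self) -> Hashable:
        mask = 0
        for i, e in enumerate(self.belief.encoded):
            if e is None:
                mask |= 1 << self.cell_of(self.state.item_positions[i])
        return (self.cell_of(self.belief.fixation), mask)

    def valid_actions(self) -> list[int]:
        """Cells still holding unencoded items; saccading anywhere else is
        provably wasted time, so the policy never selects it."""
        cells = {
            self.cell_of(self.state.item_positions[i])
            for i, e in enumerate(self.belief.encoded)
            if e is None
        }
        if not cells:
            return list(range(self.n_actions))
        return sorted(cells)

    def reset(
        self,
        rng: np.random.Generator,
        target_present: bool | None = None,
        state: SearchState | None = None,
    ) -> Hashable:
        if state is None:
            if target_present is None:
                target_present = bool(rng.random() < self.p_target_present)
            state = generate_layout(self.params, target_present, rng)
        self.state = state
        self.belief = SearchBelief.empty(self.params)
        self._steps = 0
        return self.state_key()

    def apply_action(self, cell: int) -> tuple[float, bool]:
        """Execute a cell-directed encode; returns (elapsed, done)."""
        fix = np.asarray(self.belief.fixation)
        in_cell = [
            i
            for i in range(self.params.n_items)
            if self.cell_of(self.state.item_positions[i]) == cell
        ]
        if in_cell:
            unencoded = [i for i in in_cell if self.belief.encoded[i] is None]
            pool = unencoded if unencoded else in_cell
            dists = [
                float(np.linalg.norm(fix - self.state.item_positions[i]))
                for i in pool
            ]
            item = pool[int(np.argmin(dists))]
            self.belief, elapsed = encode_action(
                self.state, self.belief, item, self.params
            )
        else:
            # nothing there: saccade to the cell center, encode nothing
            center = self.cell_center(cell)
            dist = float(np.linalg.norm(fix - np.asarray(center)))
            elapsed = saccade_time(dist, self.params)
            self.belief = SearchBelief(
                encoded=list(self.belief.encoded), fixation=center
            )
        return elapsed, is_trial_complete(self.state, self.belief)

    def step(
        self, action: int, rng: np.random.Generator
    ) -> tuple[Hashable, float, bool, bool]:
        if self.interruption_prob > 0 and rng.random() < self.interruption_prob:
            self.belief = SearchBelief(
                encoded=list(self.belief.encoded), fixation=self.params.entry_point
            )
        elapsed, done = self.apply_action(action)
        r = search_reward(
            elapsed, done, self.params, foil=self.state.target_index is None
        )
        self._steps += 1
        truncated = self._steps >= self.max_actions
        return self.state_key(), r, done or truncated, done
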