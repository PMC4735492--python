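"""Intervention regimes: attitude bias at initialization and control nodes.

Two levers are modeled.  A population-level one — the attitude bias
``alpha`` bounding initial non-leader strategies — and an individual-level
one: "saint" nodes that never join when asked and "devil" nodes that always
do, placed either uniformly at random or on the highest-degree nodes.
Controls are always drawn from non-leader nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, ParameterError
from .network import SocialNetwork, top_degree_nodes
from .simcore import AgentPopulation, REGULAR, RANDOM, TOP_DEGREE, PLACEMENT_MODES

__all__ = ["ControlAssignment", "place_controls", "alpha_bound_strategies", "build_controls"]


@dataclass(frozen=True)
class ControlAssignment:
    """Saint and devil node sets plus the placement mode that produced them."""

    saints: frozenset[int] = frozenset()
    devils: frozenset[int] = frozenset()
    placement_mode: str = RANDOM

    def __post_init__(self):
        if self.saints & self.devils:
            raise ConfigurationError("a node cannot be both saint and devil")

    def validate_against(self, leaders: Iterable[int]) -> None:
        leaders = frozenset(leaders)
        if self.saints & leaders or self.devils & leaders:
            raise ConfigurationError("control nodes must not overlap the leader set")

    def merged_with(self, other: "ControlAssignment") -> "ControlAssignment":
        return ControlAssignment(
            saints=self.saints | other.saints,
            devils=self.devils | other.devils,
            placement_mode=self.placement_mode,
        )

    def to_roles(self) -> dict[int, str]:
        roles = {v: "saint" for v in self.saints}
        roles.update({v: "devil" for v in self.devils})
        return roles


def place_controls(
    net: SocialNetwork,
    role: str,
    count: int,
    mode: str,
    leaders: Iterable[int],
    rng: np.random.Generator | None = None,
) -> ControlAssignment:
    """Choose ``count`` control nodes of the given role among non-leaders.

    ``random`` mode samples uniformly without replacement; ``top_degree``
    takes the highest-degree non-leader nodes (ties by ascending id).
    Deterministic given the generator state.
    """
    if role not in ("saint", "devil"):
        raise ParameterError(f"role must be 'saint' or 'devil', got {role!r}")
    if mode not in PLACEMENT_MODES:
        raise ParameterError(f"mode must be one of {PLACEMENT_MODES}, got {mode!r}")
    leaders = frozenset(int(v) for v in leaders)
    count = int(count)
    if count < 0:
        raise ConfigurationError(f"count must be >= 0, got {count}")
    available = net.n - len(leaders)
    if count > available:
        raise ConfigurationError(
            f"cannot place {count} controls: only {available} non-leader nodes"
        )
    if count == 0:
        chosen: list[int] = []
    elif mode == TOP_DEGREE:
        chosen = top_degree_nodes(net, count, exclude=leaders)
    else:
        rng = np.random.default_rng() if rng is None else rng
        pool = np.array([v for v in range(net.n) if v not in leaders], dtype=np.int64)
        chosen = rng.choice(pool, size=count, replace=False).tolist()
    nodes = frozenset(int(v) for v in chosen)
    if role == "saint":
        return ControlAssignment(saints=nodes, placement_mode=mode)
    return ControlAssignment(devils=nodes, placement_mode=mode)


def build_controls(
    net: SocialNetwork,
    saints: int,
    devils: int,
    mode: str,
    leaders: Iterable[int],
    rng: np.random.Generator,
) -> ControlAssignment:
    """Place saints then devils with a shared mode, keeping the sets disjoint."""
    leaders = frozenset(int(v) for v in leaders)
    saint_assign = place_controls(net, "saint", saints, mode, leaders, rng)
    # devils are placed after saints so top-degree saints claim the best nodes
    devil_assign = place_controls(
        net, "devil", devils, mode, leaders | saint_assign.saints, rng
    )
    return ControlAssignment(
        saints=saint_assign.saints, devils=devil_assign.devils, placement_mode=mode
    )


def alpha_bound_strategies(
    pop: AgentPopulation, alpha: float, rng: np.random.Generator | None = None
) -> AgentPopulation:
    """Redraw regular-agent initial strategies as Uniform[0, alpha].

    Leaders, saints, and devils are untouched.  ``alpha`` applies at
    initialization only; learning may later carry strategies above it.
    """
    if not (0.0 < alpha <= 1.0):
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    rng = np.random.default_rng() if rng is None else rng
    regular = pop.role == REGULAR
    pop.strategy[regular] = rng.uniform(0.0, alpha, size=int(regular.sum()))
    return pop
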