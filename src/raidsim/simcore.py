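"""One full game: initialization, the per-generation recruitment round
(nucleation, expansion, resolution, payoffs), population-wide pairwise
imitation, and convergence detection.

Model summary
-------------
Each agent ``j`` carries a strategy ``s_j`` in [0, 1]: the probability of
joining a collective "raid" when asked.  Every generation one leader is
picked uniformly at random and invites ``n`` agents sampled uniformly from
within hop distance ``r`` of itself (nucleation).  Acceptors form the
nucleus; each nucleus member then asks its direct friends, every invitee
getting exactly one independent join draw at its own probability
(expansion).  The raid occurs iff at least ``m`` agents joined in total.
Joiners are rewarded and asked refusers penalized when it occurs, and vice
versa when it fails; everyone not asked scores zero.  After payoffs, every
regular agent compares against one uniformly chosen regular peer and adopts
the peer's (pre-update) strategy iff the peer's payoff is strictly higher.
Leaders, saints (never join), and devils (always join) never learn and are
never imitated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ParameterError
from .network import SocialNetwork

__all__ = [
    "REGULAR",
    "LEADER",
    "SAINT",
    "DEVIL",
    "ROLE_NAMES",
    "AgentPopulation",
    "SimulationConfig",
    "RaidRecord",
    "RunResult",
    "init_population",
    "nucleate",
    "expand",
    "assign_payoffs",
    "update_strategies",
    "play_round",
    "run_generation",
    "run_simulation",
]

# role codes (stored in a compact int8 array)
REGULAR, LEADER, SAINT, DEVIL = 0, 1, 2, 3
ROLE_NAMES = {REGULAR: "regular", LEADER: "leader", SAINT: "saint", DEVIL: "devil"}
ROLE_CODES = {v: k for k, v in ROLE_NAMES.items()}

RANDOM = "random"
TOP_DEGREE = "top_degree"
PLACEMENT_MODES = (RANDOM, TOP_DEGREE)


@dataclass
class SimulationConfig:
    """All model and experiment parameters.

    ``n`` (nucleus invitation count) and ``m`` (raid threshold) have no
    canonical values; the shipped defaults come from the baseline
    calibration procedure in :mod:`raidsim.experiments` (mean MRR close to
    one at ``r=1`` on the 91-node fixture).
    """

    n: int = 5  # nucleus invitation count (calibrated default, 91-node fixture)
    m: int = 9  # raid threshold: minimum joiners (calibrated default, 91-node fixture)
    r: int = 1  # recruitment radius in hops
    alpha: float = 1.0  # upper bound on initial non-leader strategies
    reward: float = 1.0  # payoff magnitude for successful coordination
    cost: float = 1.0  # payoff magnitude for failed coordination
    leader_strategy_low: float = 0.5
    leader_strategy_high: float = 1.0
    leaders: int | None = None  # leader count; None -> round(0.05 N), min 1
    saints: int = 0
    devils: int = 0
    placement: str = RANDOM
    replicates: int = 1000
    max_generations: int = 5000
    stall_window: int = 100
    seed: int = 0

    def validate(self, n_nodes: int | None = None) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if self.m < 1:
            raise ConfigurationError(f"m must be >= 1, got {self.m}")
        if self.r < 1:
            raise ConfigurationError(f"r must be >= 1, got {self.r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.reward <= 0 or self.cost <= 0:
            raise ConfigurationError("reward and cost must be positive")
        if not (0.0 <= self.leader_strategy_low <= self.leader_strategy_high <= 1.0):
            raise ConfigurationError("leader strategy bounds must satisfy 0 <= low <= high <= 1")
        if self.saints < 0 or self.devils < 0:
            raise ConfigurationError("saint and devil counts must be >= 0")
        if self.placement not in PLACEMENT_MODES:
            raise ConfigurationError(
                f"placement must be one of {PLACEMENT_MODES}, got {self.placement!r}"
            )
        if self.max_generations < 1 or self.stall_window < 1:
            raise ConfigurationError("max_generations and stall_window must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if n_nodes is not None:
            L = self.leader_count(n_nodes)
            if L + self.saints + self.devils > n_nodes:
                raise ConfigurationError(
                    f"leaders + saints + devils ({L}+{self.saints}+{self.devils}) "
                    f"exceed population size {n_nodes}"
                )

    def leader_count(self, n_nodes: int) -> int:
        """Configured leader count, defaulting to round(0.05 N) with a floor of 1."""
        if self.leaders is not None:
            return int(self.leaders)
        return max(1, round(0.05 * n_nodes))

    def evolve(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


class AgentPopulation:
    """Per-node strategy, role, and per-round payoff.

    Saints have effective join probability 0 and devils 1 regardless of the
    stored strategy; roles are fixed for the lifetime of a run.
    """

    __slots__ = ("strategy", "role", "payoff")

    def __init__(self, strategy: np.ndarray, role: np.ndarray):
        strategy = np.asarray(strategy, dtype=np.float64)
        role = np.asarray(role, dtype=np.int8)
        if strategy.shape != role.shape or strategy.ndim != 1:
            raise ConfigurationError("strategy and role must be 1-D arrays of equal length")
        if np.any((strategy < 0) | (strategy > 1)):
            raise ConfigurationError("strategies must lie in [0, 1]")
        self.strategy = strategy
        self.role = role
        self.payoff = np.zeros(strategy.shape[0], dtype=np.float64)

    @property
    def n(self) -> int:
        return self.strategy.shape[0]

    def indices_of(self, role: int) -> np.ndarray:
        return np.flatnonzero(self.role == role)

    @property
    def regular_indices(self) -> np.ndarray:
        return self.indices_of(REGULAR)

    def effective_join_prob(self, nodes: np.ndarray) -> np.ndarray:
        """Join probability when asked: 0 for saints, 1 for devils, s_j otherwise."""
        p = self.strategy[nodes].copy()
        roles = self.role[nodes]
        p[roles == SAINT] = 0.0
        p[roles == DEVIL] = 1.0
        return p

    def mean_strategy(self) -> float:
        return float(self.strategy.mean())

    def copy(self) -> "AgentPopulation":
        out = AgentPopulation(self.strategy.copy(), self.role.copy())
        out.payoff = self.payoff.copy()
        return out


def init_population(
    net: SocialNetwork,
    cfg: SimulationConfig,
    leaders: Iterable[int],
    controls=None,
    rng: np.random.Generator | None = None,
) -> AgentPopulation:
    """Initialize strategies and roles.

    Leader strategies ~ Uniform[leader bounds] (default [0.5, 1]); regular
    strategies ~ Uniform[0, alpha]; saints get strategy 0, devils 1.  All
    payoffs start at zero.  Leader/saint/devil sets must be disjoint.
    """
    cfg.validate(net.n)
    rng = np.random.default_rng() if rng is None else rng
    leaders = frozenset(int(v) for v in leaders)
    saints = frozenset(int(v) for v in getattr(controls, "saints", ()) or ())
    devils = frozenset(int(v) for v in getattr(controls, "devils", ()) or ())
    for name, group in (("leaders", leaders), ("saints", saints), ("devils", devils)):
        for v in group:
            if v not in net:
                raise ConfigurationError(f"{name} contains unknown node {v}")
    if (leaders & saints) or (leaders & devils) or (saints & devils):
        raise ConfigurationError("leader, saint, and devil sets must be disjoint")

    role = np.full(net.n, REGULAR, dtype=np.int8)
    role[list(leaders)] = LEADER
    role[list(saints)] = SAINT
    role[list(devils)] = DEVIL

    strategy = np.empty(net.n, dtype=np.float64)
    regular = role == REGULAR
    # draw order is fixed (regulars then leaders) so runs are reproducible
    strategy[regular] = rng.uniform(0.0, cfg.alpha, size=int(regular.sum()))
    lead_idx = np.flatnonzero(role == LEADER)
    strategy[lead_idx] = rng.uniform(
        cfg.leader_strategy_low, cfg.leader_strategy_high, size=lead_idx.size
    )
    strategy[role == SAINT] = 0.0
    strategy[role == DEVIL] = 1.0
    return AgentPopulation(strategy, role)


@dataclass(frozen=True)
class RaidRecord:
    """One round of recruitment: who nucleated, who was asked, who joined."""

    leader: int
    nucleus_invited: frozenset[int]
    nucleus_joined: frozenset[int]
    expansion_invited: frozenset[int]
    expansion_joined: frozenset[int]
    occurred: bool

    @property
    def asked(self) -> frozenset[int]:
        return self.nucleus_invited | self.expansion_invited

    @property
    def joined(self) -> frozenset[int]:
        return self.nucleus_joined | self.expansion_joined

    def to_dict(self) -> dict:
        return {
            "leader": self.leader,
            "nucleus_invited": sorted(self.nucleus_invited),
            "nucleus_joined": sorted(self.nucleus_joined),
            "expansion_invited": sorted(self.expansion_invited),
            "expansion_joined": sorted(self.expansion_joined),
            "asked": sorted(self.asked),
            "joined": sorted(self.joined),
            "occurred": self.occurred,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def nucleate(
    net: SocialNetwork,
    pop: AgentPopulation,
    leader: int,
    n: int,
    r: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """First recruitment stage.

    Invites ``min(n, |neighborhood(leader, r)|)`` nodes sampled uniformly
    without replacement from within hop distance ``r`` of the leader; each
    invitee independently joins with its effective join probability.
    Returns ``(invited, nucleus)`` as sorted index arrays.
    """
    if pop.role[leader] != LEADER:
        raise ParameterError(f"node {leader} does not have the leader role")
    pool = net.neighborhood(leader, r)
    if pool.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    k = min(int(n), pool.size)
    invited = pool if k == pool.size else rng.choice(pool, size=k, replace=False)
    invited = np.sort(invited)
    joins = rng.random(invited.size) < pop.effective_join_prob(invited)
    return invited, invited[joins]


def expand(
    net: SocialNetwork,
    pop: AgentPopulation,
    nucleus: np.ndarray,
    already_asked: np.ndarray,
    leader: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Second recruitment stage.

    Every direct friend of a nucleus member — excluding the nucleus, the
    leader, and anyone already asked — receives exactly ONE independent join
    draw at its effective probability, no matter how many nucleus members it
    is adjacent to.  Returns ``(invited, joiners)``.
    """
    nucleus = np.asarray(nucleus, dtype=np.int64)
    if nucleus.size == 0:
        raise ParameterError("expand requires a nonempty nucleus")
    mask = np.zeros(net.n, dtype=bool)
    for v in nucleus:
        mask[net.neighbors(int(v))] = True
    mask[nucleus] = False
    mask[int(leader)] = False
    mask[np.asarray(already_asked, dtype=np.int64)] = False
    invited = np.flatnonzero(mask).astype(np.int64)
    if invited.size == 0:
        return invited, invited
    joins = rng.random(invited.size) < pop.effective_join_prob(invited)
    return invited, invited[joins]


def assign_payoffs(
    pop: AgentPopulation,
    asked: np.ndarray,
    joined: np.ndarray,
    occurred: bool,
    reward: float,
    cost: float,
) -> np.ndarray:
    """Coordination payoffs for one round, written into ``pop.payoff``.

    If the raid occurred: joiners get ``+reward`` and asked refusers
    ``-cost``.  If it did not: joiners get ``-cost`` and asked refusers
    ``+reward``.  Everyone not asked (including the leader) scores 0.
    """
    pop.payoff[:] = 0.0
    asked = np.asarray(asked, dtype=np.int64)
    joined = np.asarray(joined, dtype=np.int64)
    if asked.size == 0:
        return pop.payoff
    if occurred:
        pop.payoff[asked] = -cost
        pop.payoff[joined] = reward
    else:
        pop.payoff[asked] = reward
        pop.payoff[joined] = -cost
    return pop.payoff


def update_strategies(pop: AgentPopulation, rng: np.random.Generator) -> AgentPopulation:
    """Population-wide synchronous pairwise imitation.

    Every regular agent picks one peer uniformly at random from the other
    regular agents and adopts the peer's pre-update strategy iff the peer's
    payoff is strictly greater.  Leaders, saints, and devils neither learn
    nor serve as models.  A no-op with fewer than two regular agents.
    """
    reg = pop.regular_indices
    k = reg.size
    if k < 2:
        return pop
    payoffs = pop.payoff[reg]
    snapshot = pop.strategy[reg].copy()
    # uniform peer excluding self: draw in [0, k-2], shift past own position
    peers = rng.integers(0, k - 1, size=k)
    peers += peers >= np.arange(k)
    adopt = payoffs[peers] > payoffs
    pop.strategy[reg[adopt]] = snapshot[peers[adopt]]
    return pop


def play_round(
    net: SocialNetwork,
    pop: AgentPopulation,
    cfg: SimulationConfig,
    leaders: np.ndarray,
    rng: np.random.Generator,
) -> RaidRecord:
    """Run one recruitment round (no learning): nucleation, expansion,
    resolution, and payoff assignment.  Returns the round's RaidRecord."""
    leader = int(leaders[rng.integers(leaders.size)])
    nuc_invited, nucleus = nucleate(net, pop, leader, cfg.n, cfg.r, rng)
    if nucleus.size > 0:
        exp_invited, exp_joined = expand(net, pop, nucleus, nuc_invited, leader, rng)
    else:
        exp_invited = exp_joined = np.empty(0, dtype=np.int64)
    joined_count = nucleus.size + exp_joined.size
    occurred = joined_count >= cfg.m
    asked = np.concatenate([nuc_invited, exp_invited])
    joined = np.concatenate([nucleus, exp_joined])
    assign_payoffs(pop, asked, joined, occurred, cfg.reward, cfg.cost)
    return RaidRecord(
        leader=leader,
        nucleus_invited=frozenset(nuc_invited.tolist()),
        nucleus_joined=frozenset(nucleus.tolist()),
        expansion_invited=frozenset(exp_invited.tolist()),
        expansion_joined=frozenset(exp_joined.tolist()),
        occurred=bool(occurred),
    )


def run_generation(
    net: SocialNetwork,
    pop: AgentPopulation,
    cfg: SimulationConfig,
    leaders: np.ndarray,
    rng: np.random.Generator,
) -> tuple[RaidRecord, AgentPopulation]:
    """One full generation: recruitment round, imitation update, payoff reset."""
    record = play_round(net, pop, cfg, leaders, rng)
    update_strategies(pop, rng)
    pop.payoff[:] = 0.0
    return record, pop


@dataclass
class RunResult:
    """Outcome of a single simulation run."""

    initial_mean_strategy: float
    final_mean_strategy: float
    mrr: float
    generations: int
    converged: bool
    trajectory: list[float] | None = None
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "initial_mean_strategy": self.initial_mean_strategy,
            "final_mean_strategy": self.final_mean_strategy,
            "mrr": self.mrr,
            "generations": self.generations,
            "converged": self.converged,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def run_simulation(
    net: SocialNetwork,
    cfg: SimulationConfig,
    leaders: Iterable[int],
    controls=None,
    seed: int | np.random.SeedSequence = 0,
    record_trajectory: bool = False,
    snapshot_generations: Sequence[int] = (),
) -> RunResult:
    """Run one game to convergence (or ``max_generations``).

    Convergence: the strategies of all regular agents are unchanged for
    ``stall_window`` consecutive generations, or all regular agents share a
    single strategy value (vacuously true with < 2 regular agents).  The
    Mean Risk-taking Ratio (MRR) is the mean over all N strategies at the
    end divided by the initial mean.  Identical seeds give identical runs.
    """
    rng = np.random.default_rng(seed)
    pop = init_population(net, cfg, leaders, controls, rng)
    leader_arr = np.asarray(sorted(int(v) for v in leaders), dtype=np.int64)
    if leader_arr.size == 0:
        raise ConfigurationError("at least one leader is required")

    initial_mean = pop.mean_strategy()
    reg = pop.regular_indices
    snapshot_set = set(int(g) for g in snapshot_generations)
    trajectory = [initial_mean] if record_trajectory else None
    snapshots: dict[int, np.ndarray] = {}
    if 0 in snapshot_set:
        snapshots[0] = pop.strategy.copy()

    def _settled() -> bool:
        if reg.size == 0:
            return True
        s = pop.strategy[reg]
        return bool(np.all(s == s[0]))

    converged = _settled()
    generations = 0
    stall = 0
    prev = pop.strategy[reg].copy()
    while not converged and generations < cfg.max_generations:
        run_generation(net, pop, cfg, leader_arr, rng)
        generations += 1
        if record_trajectory:
            trajectory.append(pop.mean_strategy())
        if generations in snapshot_set:
            snapshots[generations] = pop.strategy.copy()
        cur = pop.strategy[reg]
        if np.array_equal(cur, prev):
            stall += 1
        else:
            stall = 0
            prev = cur.copy()
        converged = stall >= cfg.stall_window or _settled()

    final_mean = pop.mean_strategy()
    mrr = final_mean / initial_mean if initial_mean > 0 else float("nan")
    return RunResult(
        initial_mean_strategy=initial_mean,
        final_mean_strategy=final_mean,
        mrr=mrr,
        generations=generations,
        converged=converged,
        trajectory=trajectory,
        snapshots=snapshots,
    )
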