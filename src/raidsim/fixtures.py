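"""Seeded synthetic fixtures: named (network, leader set) pairs.

Every fixture is a connected Watts-Strogatz graph with a 6-neighbor initial
lattice and rewiring rate 0.75, with round(0.05 N) leaders (minimum 1)
sampled uniformly at random.  A fixture spec fully determines its network
and leader set bit-exactly, so experiments need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .network import SocialNetwork, generate_ws_network

__all__ = ["FixtureSpec", "FIXTURES", "make_fixture", "get_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    n_nodes: int
    neighbors: int = 6
    rewire_rate: float = 0.75
    network_seed: int = 0
    leader_count: int = 1
    leader_seed: int = 0


def _spec(name: str, n_nodes: int, network_seed: int, leader_seed: int) -> FixtureSpec:
    return FixtureSpec(
        name=name,
        n_nodes=n_nodes,
        network_seed=network_seed,
        leader_count=max(1, round(0.05 * n_nodes)),
        leader_seed=leader_seed,
    )


#: shipped fixtures, one per studied network size
FIXTURES: dict[str, FixtureSpec] = {
    "ws91": _spec("ws91", 91, network_seed=9101, leader_seed=9102),
    "ws200": _spec("ws200", 200, network_seed=20001, leader_seed=20002),
    "ws300": _spec("ws300", 300, network_seed=30001, leader_seed=30002),
    "ws400": _spec("ws400", 400, network_seed=40001, leader_seed=40002),
    "ws500": _spec("ws500", 500, network_seed=50001, leader_seed=50002),
}


def make_fixture(spec: FixtureSpec) -> tuple[SocialNetwork, frozenset[int]]:
    """Build the (network, leader set) pair a spec describes."""
    net = generate_ws_network(
        spec.n_nodes, spec.neighbors, spec.rewire_rate, spec.network_seed
    )
    rng = np.random.default_rng(spec.leader_seed)
    leaders = rng.choice(net.n, size=spec.leader_count, replace=False)
    return net, frozenset(int(v) for v in leaders)


def get_fixture(name: str) -> tuple[SocialNetwork, frozenset[int]]:
    """Look up a shipped fixture by name and build it."""
    try:
        spec = FIXTURES[name]
    except KeyError:
        raise ParameterError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return make_fixture(spec)
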