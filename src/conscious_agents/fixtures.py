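"""Built-in fixtures: canonical worked examples and seeded generators.

``identity_pair`` is the minimal two-agent system — binary percept and
action spaces, all four kernels 2x2 identities — whose 16-state joint
dynamics decomposes into six absorbing sets with periods (1, 1, 2, 4, 4,
4).  ``swap_d1_pair`` changes only D1 to the swap matrix ((0,1),(1,0)),
which fuses the state space into two period-8 cycles and creates 2 bits
of integrated information across the agent bipartition.

The seeded generators produce random agents, adjacent pairs, and
band-fitness worlds for property tests and games.  Identical
(name, params, seed) always yield identical objects.
"""

from __future__ import annotations

import numpy as np

from .agents import ConsciousAgent
from .evogames import WorldModel, gaussian_band_fitness
from .kernels import (
    MarkovKernel,
    StateSpace,
    binary_space,
    identity_kernel,
    random_kernel,
    swap2,
)

__all__ = ["make_fixture", "FIXTURE_NAMES"]


def _binary_agent(name: str, D: MarkovKernel | None = None) -> ConsciousAgent:
    b = binary_space()
    ident = identity_kernel(b)
    return ConsciousAgent(
        name=name, X=b, G=b, P=ident, D=D if D is not None else ident, A=ident, N=0
    )


def _identity_pair(params, seed):
    return (_binary_agent("C1"), _binary_agent("C2"))


def _swap_d1_pair(params, seed):
    return (_binary_agent("C1", D=swap2()), _binary_agent("C2"))


def _random_agent(params, seed):
    params = params or {}
    nx = int(params.get("nx", 2))
    ng = int(params.get("ng", 2))
    n_in = int(params.get("n_in", ng))
    n_out = int(params.get("n_out", nx))
    rng = np.random.default_rng(seed)
    X = StateSpace(tuple(f"x{i}" for i in range(nx)))
    G = StateSpace(tuple(f"g{i}" for i in range(ng)))
    Win = StateSpace(tuple(f"w{i}" for i in range(n_in)))
    Wout = StateSpace(tuple(f"v{i}" for i in range(n_out)))
    return ConsciousAgent(
        name=params.get("name", f"random_agent_{seed}"),
        X=X,
        G=G,
        P=random_kernel(Win, X, rng, name="P"),
        D=random_kernel(X, G, rng, name="D"),
        A=random_kernel(G, Wout, rng, name="A"),
        N=int(params.get("N", 0)),
    )


def _random_adjacent_pair(params, seed):
    """Two adjacent agents with seeded random kernels.

    Adjacency pins P1 = A2 and P2 = A1, so only four kernels are free:
    D1, D2, and the two cross channels.
    """
    params = params or {}
    n1x = int(params.get("n1x", 2))
    n1g = int(params.get("n1g", 2))
    n2x = int(params.get("n2x", 2))
    n2g = int(params.get("n2g", 2))
    rng = np.random.default_rng(seed)
    X1 = StateSpace(tuple(f"a{i}" for i in range(n1x)))
    G1 = StateSpace(tuple(f"b{i}" for i in range(n1g)))
    X2 = StateSpace(tuple(f"c{i}" for i in range(n2x)))
    G2 = StateSpace(tuple(f"d{i}" for i in range(n2g)))
    chan21 = random_kernel(G2, X1, rng, name="A2")  # C2 acts -> C1 perceives
    chan12 = random_kernel(G1, X2, rng, name="A1")  # C1 acts -> C2 perceives
    D1 = random_kernel(X1, G1, rng, name="D1")
    D2 = random_kernel(X2, G2, rng, name="D2")
    c1 = ConsciousAgent(name="R1", X=X1, G=G1, P=chan21, D=D1, A=chan12, N=0)
    c2 = ConsciousAgent(name="R2", X=X2, G=G2, P=chan12, D=D2, A=chan21, N=0)
    return (c1, c2)


def _band_fitness_world(params, seed):
    """An ordered world with a goldilocks (interior-peak) fitness band.

    Defaults: 10 ordered states, uniform prior, Gaussian fitness peaked
    at state index 4.5 with width 1.5 — fit states sit in the middle of
    the order, so no prefix cut of the order isolates them.
    """
    params = params or {}
    size = int(params.get("size", 10))
    peak = float(params.get("peak", (size - 1) / 2.0))
    width = float(params.get("width", 1.5))
    W = StateSpace(tuple(f"w{i:02d}" for i in range(size)))
    prior = params.get("prior")
    m = np.full(size, 1.0 / size) if prior is None else np.asarray(prior, float)
    world = WorldModel(W=W, m=m)
    f = gaussian_band_fitness(world, peak=peak, width=width)
    return (world, f)


_REGISTRY = {
    "identity_pair": _identity_pair,
    "swap_d1_pair": _swap_d1_pair,
    "random_agent": _random_agent,
    "random_adjacent_pair": _random_adjacent_pair,
    "band_fitness_world": _band_fitness_world,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str, params: dict | None = None, seed: int | None = None):
    """Build a named fixture; deterministic given (name, params, seed)."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder(params, seed)
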