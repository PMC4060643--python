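"""Conscious agents, adjacency, and the join constructions.

A conscious agent is a six-tuple C = (X, G, P, D, A, N): a percept space
X, an action space G, three Markovian kernels — perception P (world to
X), decision D (X to G), action A (G to world) — and an integer counter N
that ticks once per perceive-decide-act cycle.

Two agents are *adjacent* when each one's perception channel is the
other's action channel (P1 = A2, P2 = A1) and their counters agree.
Adjacent agents can be combined: the *undirected join* tensors the
component kernels into an agent on the product spaces, and the *directed
join* composes D1 A1 D2 into a single decision kernel.  Both
constructions return a bona fide agent — combination is closed.

Networks of more than two agents factor each agent's perception and
action kernels into per-neighbor tensor factors; ``build_network`` wires
and validates such a graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kernels import (
    MarkovKernel,
    StateSpace,
    ValidationReport,
    product_space,
    tensor,
    validate_kernel,
)

__all__ = [
    "ConsciousAgent",
    "AdjacencyReport",
    "check_adjacency",
    "undirected_join",
    "directed_join",
    "NetworkAgent",
    "AgentNetwork",
    "build_network",
    "JoinError",
]

KERNEL_ATOL = 1e-12


class JoinError(ValueError):
    """A join was requested on agents that do not satisfy its preconditions."""


@dataclass(frozen=True)
class ConsciousAgent:
    """The six-tuple (X, G, P, D, A, N).

    ``P.source`` is the agent's incoming world alphabet and ``A.target``
    its outgoing one; under conscious realism those are other agents'
    action/percept spaces, never a free-standing world.
    """

    name: str
    X: StateSpace
    G: StateSpace
    P: MarkovKernel
    D: MarkovKernel
    A: MarkovKernel
    N: int = 0

    def __post_init__(self):
        if not self.P.target.same_labels(self.X):
            raise ValueError(f"agent {self.name!r}: P.target must equal X")
        if not self.D.source.same_labels(self.X):
            raise ValueError(f"agent {self.name!r}: D.source must equal X")
        if not self.D.target.same_labels(self.G):
            raise ValueError(f"agent {self.name!r}: D.target must equal G")
        if not self.A.source.same_labels(self.G):
            raise ValueError(f"agent {self.name!r}: A.source must equal G")
        if self.N < 0:
            raise ValueError(f"agent {self.name!r}: counter N must be >= 0")

    def validate(self) -> ValidationReport:
        violations = []
        for label, k in (("P", self.P), ("D", self.D), ("A", self.A)):
            rep = validate_kernel(k)
            violations.extend(f"{label}: {v}" for v in rep.violations)
        return ValidationReport(ok=not violations, violations=tuple(violations))

    def with_counter(self, n: int) -> "ConsciousAgent":
        return replace(self, N=n)


@dataclass(frozen=True)
class AdjacencyReport:
    adjacent: bool
    failed_conditions: tuple = ()

    def __bool__(self) -> bool:
        return self.adjacent


def _kernels_equal(k1: MarkovKernel, k2: MarkovKernel) -> bool:
    return k1.shape == k2.shape and bool(
        np.allclose(k1.matrix, k2.matrix, rtol=0.0, atol=KERNEL_ATOL)
    )


def check_adjacency(c1: ConsciousAgent, c2: ConsciousAgent) -> AdjacencyReport:
    """Check the compatibility conditions P1 = A2, P2 = A1, N1 = N2.

    Shape mismatches are reported as failures of the corresponding
    condition, never raised: adjacency is a query, not an assertion.
    """
    failed = []
    if not _kernels_equal(c1.P, c2.A):
        failed.append("P1=A2")
    if not _kernels_equal(c2.P, c1.A):
        failed.append("P2=A1")
    if c1.N != c2.N:
        failed.append("N1=N2")
    return AdjacencyReport(adjacent=not failed, failed_conditions=tuple(failed))


def undirected_join(c1: ConsciousAgent, c2: ConsciousAgent, name: str = "") -> ConsciousAgent:
    """Combine two adjacent agents into one agent on the product spaces.

    The joint percept space is X1 x X2 and action space G1 x G2.  The
    joint perception kernel reads its input transposed — entry
    P((g2, g1), (x1, x2)) = P1(g2, x1) P2(g1, x2) — because agent 1
    perceives what agent 2 does and vice versa; symmetrically the joint
    action kernel writes its output transposed,
    A((g1, g2), (x2, x1)) = A1(g1, x2) A2(g2, x1).  The joint decision
    kernel is the plain tensor D1 (x) D2.
    """
    rep = check_adjacency(c1, c2)
    if not rep.adjacent:
        raise JoinError(
            f"cannot join {c1.name!r} and {c2.name!r}: "
            f"failed conditions {', '.join(rep.failed_conditions)}"
        )
    X = product_space(c1.X, c2.X)
    G = product_space(c1.G, c2.G)
    # P1 reads G2 and P2 reads G1 (adjacency), so the plain tensor already
    # has the transposed input tuple (g2, g1); likewise A1 writes X2 and A2
    # writes X1, giving the transposed output (x2, x1).
    P = tensor(c1.P, c2.P)
    D = tensor(c1.D, c2.D)
    A = tensor(c1.A, c2.A)
    return ConsciousAgent(
        name=name or f"({c1.name}+{c2.name})", X=X, G=G, P=P, D=D, A=A, N=c1.N
    )


def directed_join(c1: ConsciousAgent, c2: ConsciousAgent, name: str = "") -> ConsciousAgent:
    """Combine C1 -> C2 into one agent perceiving as C1 and acting as C2.

    The combined decision kernel is the three-fold composition D1 A1 D2,
    which integrates over C1's action space and C2's percept space; those
    experiences become internal to the combined agent's decision process.
    """
    if c1.N != c2.N:
        raise JoinError(
            f"cannot join {c1.name!r} -> {c2.name!r}: counters differ ({c1.N} != {c2.N})"
        )
    # The channel C1 -> C2 is the single kernel A1 = P2: G1 -> X2, so the
    # combined decision kernel is the matrix product D1 A1 D2: X1 -> G2.
    if c1.D.target.size != c1.A.source.size:
        raise JoinError(
            f"cannot join {c1.name!r} -> {c2.name!r}: stage D1->A1 shape mismatch"
        )
    if c1.A.target.size != c2.D.source.size:
        raise JoinError(
            f"cannot join {c1.name!r} -> {c2.name!r}: stage A1->D2, A1 emits "
            f"{c1.A.target.size} symbols but D2 reads {c2.D.source.size}"
        )
    D = MarkovKernel(c1.X, c2.G, c1.D.matrix @ c1.A.matrix @ c2.D.matrix)
    return ConsciousAgent(
        name=name or f"({c1.name}>{c2.name})",
        X=c1.X,
        G=c2.G,
        P=c1.P,
        D=D,
        A=c2.A,
        N=c1.N,
    )


# ---------------------------------------------------------------------------
# Networks


@dataclass(frozen=True)
class NetworkAgent:
    """An agent inside a network, with per-neighbor kernel factors.

    ``percept_factors[j]`` is the kernel through which this agent
    perceives neighbor ``j`` (source: j's action factor toward us,
    target: our percept factor X_ij), and ``action_factors[j]`` the
    kernel through which it acts on ``j``.  The agent's full P and A are
    tensor products of the factors, expressing probabilistic independence
    of the per-neighbor channels; D acts on the full product percept
    space.
    """

    name: str
    percept_factors: tuple  # ((neighbor_name, MarkovKernel), ...) in canonical order
    action_factors: tuple  # ((neighbor_name, MarkovKernel), ...)
    D: MarkovKernel
    N: int = 0

    @property
    def in_neighbors(self) -> tuple:
        return tuple(n for n, _ in self.percept_factors)

    @property
    def out_neighbors(self) -> tuple:
        return tuple(n for n, _ in self.action_factors)

    @property
    def X(self) -> StateSpace:
        if not self.percept_factors:  # isolated agent: no incoming channels
            return self.D.source
        if len(self.percept_factors) == 1:
            return self.percept_factors[0][1].target
        return product_space(*(k.target for _, k in self.percept_factors))

    @property
    def G(self) -> StateSpace:
        if not self.action_factors:
            return self.D.target
        if len(self.action_factors) == 1:
            return self.action_factors[0][1].source
        return product_space(*(k.source for _, k in self.action_factors))

    def full_P(self) -> MarkovKernel:
        kernels = [k for _, k in self.percept_factors]
        out = kernels[0]
        for k in kernels[1:]:
            out = tensor(out, k)
        return out

    def full_A(self) -> MarkovKernel:
        kernels = [k for _, k in self.action_factors]
        out = kernels[0]
        for k in kernels[1:]:
            out = tensor(out, k)
        return out

    def as_agent(self) -> ConsciousAgent:
        return ConsciousAgent(
            name=self.name, X=self.X, G=self.G, P=self.full_P(), D=self.D,
            A=self.full_A(), N=self.N,
        )


@dataclass(frozen=True)
class AgentNetwork:
    """A validated multi-graph of network agents.

    Every undirected edge (i, j) satisfies the adjacency conditions at
    the factor level (P_ij = A_ji and P_ji = A_ij); a directed edge
    i -> j requires only A_ij = P_ji.  All counters are equal.
    """

    agents: tuple  # of NetworkAgent
    edges: tuple  # of (name_i, name_j, kind)

    def agent(self, name: str) -> NetworkAgent:
        for a in self.agents:
            if a.name == name:
                return a
        raise KeyError(f"no agent named {name!r}")

    @property
    def names(self) -> tuple:
        return tuple(a.name for a in self.agents)


def _factor(pairs, neighbor):
    for n, k in pairs:
        if n == neighbor:
            return k
    return None


def build_network(agents, edges) -> AgentNetwork:
    """Wire and validate an agent network.

    ``agents`` is an iterable of NetworkAgent; ``edges`` of
    (name_i, name_j, kind) with kind "undirected" or "directed"
    (directed means i -> j).  Raises ValueError naming the first
    violation: dangling endpoints, missing factors, factor-space
    mismatches, failed adjacency, or unequal counters.
    """
    agents = tuple(agents)
    edges = tuple(tuple(e) for e in edges)
    by_name = {}
    for a in agents:
        if a.name in by_name:
            raise ValueError(f"duplicate agent name {a.name!r}")
        by_name[a.name] = a

    counters = {a.N for a in agents}
    if len(counters) > 1:
        raise ValueError(f"agent counters are not synchronized: {sorted(counters)}")

    # which channels (j -> i percept factors) each edge requires
    required_in = {a.name: set() for a in agents}  # feeding neighbor names
    required_out = {a.name: set() for a in agents}
    for i, j, kind in edges:
        for end in (i, j):
            if end not in by_name:
                raise ValueError(f"edge ({i!r}, {j!r}) references unknown agent {end!r}")
        if kind == "undirected":
            required_in[i].add(j)
            required_in[j].add(i)
            required_out[i].add(j)
            required_out[j].add(i)
        elif kind == "directed":
            required_out[i].add(j)
            required_in[j].add(i)
        else:
            raise ValueError(f"unknown edge kind {kind!r}")

    for a in agents:
        if set(a.in_neighbors) != required_in[a.name]:
            raise ValueError(
                f"agent {a.name!r}: percept factors for {sorted(a.in_neighbors)} "
                f"but edges require {sorted(required_in[a.name])}"
            )
        if set(a.out_neighbors) != required_out[a.name]:
            raise ValueError(
                f"agent {a.name!r}: action factors for {sorted(a.out_neighbors)} "
                f"but edges require {sorted(required_out[a.name])}"
            )
        if not a.D.source.same_labels(a.X):
            raise ValueError(f"agent {a.name!r}: D.source must equal the product percept space")
        if not a.D.target.same_labels(a.G):
            raise ValueError(f"agent {a.name!r}: D.target must equal the product action space")

    def _check_channel(i, j):
        """Channel i -> j: i's action factor toward j must be j's percept factor from i."""
        a_ij = _factor(by_name[i].action_factors, j)
        p_ji = _factor(by_name[j].percept_factors, i)
        if a_ij.shape != p_ji.shape or not np.allclose(
            a_ij.matrix, p_ji.matrix, rtol=0.0, atol=KERNEL_ATOL
        ):
            raise ValueError(
                f"channel {i!r}->{j!r}: action factor A_{i}{j} differs from "
                f"percept factor P_{j}{i}"
            )
        if not a_ij.source.same_labels(_action_source(by_name[i], j)):
            raise ValueError(f"channel {i!r}->{j!r}: action factor source mismatch")

    def _action_source(agent, neighbor):
        return _factor(agent.action_factors, neighbor).source

    for i, j, kind in edges:
        if kind == "undirected":
            _check_channel(i, j)
            _check_channel(j, i)
        else:
            _check_channel(i, j)

    return AgentNetwork(agents=agents, edges=edges)
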