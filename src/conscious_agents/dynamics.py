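"""Joint dynamics of interacting agents.

Two adjacent agents form a Markov chain on E = X1 x G1 x X2 x G2.  At
every step four transitions fire simultaneously and independently: each
agent decides its next action from its current percept (D), and each
agent's current action becomes the other's next percept (A).  The joint
transition kernel is therefore a product of four kernel values, not a
composition:

    L(e, e') = A2(g2, x1') D1(x1, g1') A1(g1, x2') D2(x2, g2')

for e = (x1, g1, x2, g2).  ``network_chain`` generalizes the same
simultaneous-independent-update pattern to explicit multi-agent graphs:
every percept factor is fed by exactly one action channel, and every
agent's next action tuple is drawn from its decision kernel.

Joint states carry Dirac labels |x1 g1 x2 g2> with the leftmost digit the
state of X1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import AgentNetwork, ConsciousAgent, check_adjacency, JoinError
from .kernels import MarkovKernel, StateSpace, product_space

__all__ = [
    "JointState",
    "DynamicsChain",
    "two_agent_chain",
    "network_chain",
    "simulate",
    "Trajectory",
]

#: above this joint-space size the dense transition matrix is not built
DENSE_LIMIT = 4096


def dirac_label(components: tuple) -> str:
    """Format a component tuple as a Dirac ket.

    Single-character labels are concatenated ("|0001>"); longer labels are
    space-separated so the label still round-trips.
    """
    parts = [str(c) for c in components]
    sep = "" if all(len(p) == 1 for p in parts) else " "
    return "|" + sep.join(parts) + ">"


def parse_dirac(label: str, spaces: tuple) -> tuple:
    """Parse a Dirac label back to a component tuple, given component spaces.

    Accepts ASCII ``|...>`` and the typographic ``|...⟩`` closer, with or
    without spaces between components (spaces required when any label has
    more than one character).
    """
    s = label.strip()
    for opener in ("|",):
        if s.startswith(opener):
            s = s[len(opener):]
    for closer in (">", "⟩", "〉"):
        if s.endswith(closer):
            s = s[: -len(closer)]
    s = s.strip()
    if " " in s:
        parts = s.split()
    else:
        if not all(all(len(str(l)) == 1 for l in sp.labels) for sp in spaces):
            raise ValueError(
                f"cannot parse {label!r}: multi-character state labels need spaces"
            )
        if len(s) != len(spaces):
            raise ValueError(
                f"cannot parse {label!r}: expected {len(spaces)} components, got {len(s)}"
            )
        parts = list(s)
    components = tuple(parts)
    for comp, sp in zip(components, spaces):
        if comp not in sp:
            raise ValueError(f"component {comp!r} of {label!r} not in space {sp.labels!r}")
    return components


@dataclass(frozen=True)
class JointState:
    """A joint state of the coupled dynamics: one component per channel."""

    components: tuple

    @property
    def dirac_label(self) -> str:
        return dirac_label(self.components)

    @classmethod
    def from_dirac(cls, label: str, spaces: tuple) -> "JointState":
        return cls(parse_dirac(label, spaces))


@dataclass(frozen=True)
class _UpdateRule:
    """One independent draw of the simultaneous update.

    Draws output components ``out_idx`` (a contiguous block for decision
    kernels, a single index for percept channels) from ``kernel`` applied
    to the current components ``in_idx``.
    """

    kernel: MarkovKernel
    in_idx: tuple
    out_idx: tuple


@dataclass
class DynamicsChain:
    """A Markov chain on the joint state space of an agent system.

    ``component_spaces`` are the per-channel state spaces in enumeration
    order; E enumerates their product row-major (last component fastest),
    matching the |0000>, |0001>, ... |1111> convention.  The dense matrix
    ``L`` is built only when |E| <= DENSE_LIMIT; ``row`` always works.
    """

    E: StateSpace
    component_spaces: tuple
    rules: tuple  # of _UpdateRule, ordered by first output component
    t: int = 0
    provenance: tuple = ()
    _L: MarkovKernel | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.E.size

    @property
    def L(self) -> MarkovKernel:
        if self._L is None:
            if self.n_states > DENSE_LIMIT:
                raise ValueError(
                    f"joint space has {self.n_states} states; the dense kernel "
                    f"is only materialized up to {DENSE_LIMIT} (use .row instead)"
                )
            m = np.empty((self.n_states, self.n_states))
            for i, e in enumerate(self.E.labels):
                m[i] = self.row(e)
            self._L = MarkovKernel(self.E, self.E, m, name="L")
        return self._L

    def components_of(self, e) -> tuple:
        """Normalize a state (tuple, plain label, or Dirac string) to components."""
        if isinstance(e, tuple):
            return e
        if len(self.component_spaces) == 1 and e in self.component_spaces[0]:
            return (e,)
        return parse_dirac(str(e), self.component_spaces)

    def joint_label(self, comps: tuple):
        """The E-label for a component tuple (plain for one component)."""
        return comps[0] if len(self.component_spaces) == 1 else tuple(comps)

    def row(self, e) -> np.ndarray:
        """Transition distribution out of joint state ``e`` (a label tuple)."""
        comps = self.components_of(e)
        # per-component next-state marginals / blocks, then outer product
        out = np.ones(1)
        # rules are ordered by first output component and tile the components
        for rule in self.rules:
            src = tuple(comps[i] for i in rule.in_idx)
            src_label = src[0] if len(src) == 1 else src
            block = rule.kernel.row(src_label)
            out = np.kron(out, block)
        return out

    def probability(self, e, e_next) -> float:
        """L(e, e'): probability of a single joint transition."""
        r = self.row(e)
        return float(r[self.E.index(self.joint_label(self.components_of(e_next)))])

    def successor(self, e) -> tuple:
        """Deterministic successor; raises if the row is not a point mass."""
        r = self.row(e)
        idx = np.argmax(r)
        if not np.isclose(r[idx], 1.0, rtol=0.0, atol=1e-12):
            raise ValueError(f"state {e!r} has a non-deterministic transition row")
        return self.E.labels[idx]

    def is_deterministic(self) -> bool:
        return all(rule.kernel.is_deterministic() for rule in self.rules)


def two_agent_chain(c1: ConsciousAgent, c2: ConsciousAgent) -> DynamicsChain:
    """The joint chain of two adjacent agents on E = X1 x G1 x X2 x G2."""
    rep = check_adjacency(c1, c2)
    if not rep.adjacent:
        raise JoinError(
            f"cannot build joint dynamics for {c1.name!r}, {c2.name!r}: "
            f"failed conditions {', '.join(rep.failed_conditions)}"
        )
    spaces = (c1.X, c1.G, c2.X, c2.G)
    E = product_space(*spaces, name="E")
    # simultaneous independent draws, in component order (x1', g1', x2', g2'):
    #   x1' ~ A2(g2, .), g1' ~ D1(x1, .), x2' ~ A1(g1, .), g2' ~ D2(x2, .)
    a2 = MarkovKernel(c2.G, c1.X, c2.A.matrix, name="A2")
    a1 = MarkovKernel(c1.G, c2.X, c1.A.matrix, name="A1")
    rules = (
        _UpdateRule(a2, in_idx=(3,), out_idx=(0,)),
        _UpdateRule(c1.D, in_idx=(0,), out_idx=(1,)),
        _UpdateRule(a1, in_idx=(1,), out_idx=(2,)),
        _UpdateRule(c2.D, in_idx=(2,), out_idx=(3,)),
    )
    return DynamicsChain(
        E=E, component_spaces=spaces, rules=rules, provenance=(c1, c2)
    )


def network_chain(net: AgentNetwork) -> DynamicsChain:
    """Joint chain of an agent network under lock-step independent updates.

    The joint state concatenates, agent by agent, each agent's percept
    factors (one per incoming channel, in factor order) then its action
    factors.  Each next-percept factor is drawn from the feeding agent's
    action-factor kernel applied to that agent's current action factor;
    each agent's next action tuple is drawn from its decision kernel
    applied to its current percept tuple.  All draws are independent, so
    L is the product of the per-rule kernel values.
    """
    # component layout
    comp_spaces = []
    comp_index = {}  # (agent, "x"/"g", neighbor) -> component position
    for a in net.agents:
        for n, k in a.percept_factors:
            comp_index[(a.name, "x", n)] = len(comp_spaces)
            comp_spaces.append(k.target)
        for n, k in a.action_factors:
            comp_index[(a.name, "g", n)] = len(comp_spaces)
            comp_spaces.append(k.source)
    comp_spaces = tuple(comp_spaces)

    rules = []
    for a in net.agents:
        # percept updates: channel j -> a
        for j, _pk in a.percept_factors:
            feeder = net.agent(j)
            a_ji = None
            for n, k in feeder.action_factors:
                if n == a.name:
                    a_ji = k
            if a_ji is None:
                raise ValueError(
                    f"percept factor of {a.name!r} from {j!r} has no feeding "
                    f"action factor"
                )
            rules.append(
                _UpdateRule(
                    a_ji,
                    in_idx=(comp_index[(j, "g", a.name)],),
                    out_idx=(comp_index[(a.name, "x", j)],),
                )
            )
        # decision update: the whole action tuple in one block
        in_idx = tuple(comp_index[(a.name, "x", n)] for n, _ in a.percept_factors)
        out_idx = tuple(comp_index[(a.name, "g", n)] for n, _ in a.action_factors)
        rules.append(_UpdateRule(a.D, in_idx=in_idx, out_idx=out_idx))

    rules.sort(key=lambda r: r.out_idx[0])
    # rules must tile the components contiguously for the kron assembly
    pos = 0
    for r in rules:
        if r.out_idx[0] != pos:
            raise ValueError(
                "decision kernels must cover contiguous action components; "
                "declare action factors in network layout order"
            )
        pos += len(r.out_idx)
    E = product_space(*comp_spaces, name="E")
    return DynamicsChain(
        E=E,
        component_spaces=comp_spaces,
        rules=tuple(rules),
        provenance=tuple(net.agents),
    )


@dataclass
class Trajectory:
    """A simulated path through the joint state space."""

    states: list  # of component tuples
    chain: DynamicsChain
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i) -> tuple:
        return self.states[i]

    @property
    def dirac_labels(self) -> list:
        return [dirac_label(s) for s in self.states]

    def to_tsv(self) -> str:
        names = [f"c{i}" for i in range(len(self.chain.component_spaces))]
        lines = ["\t".join(["step", "dirac_label"] + names)]
        for step, s in enumerate(self.states):
            lines.append("\t".join([str(step), dirac_label(s)] + [str(c) for c in s]))
        return "\n".join(lines) + "\n"


def simulate(
    chain: DynamicsChain,
    initial,
    n_steps: int,
    seed: int | None = None,
) -> Trajectory:
    """Run the chain for ``n_steps`` lock-step updates.

    ``initial`` is a component tuple, a Dirac label, or a JointState.
    Draws consume the random stream in component order — one draw per
    update rule per step — so identical seeds give identical trajectories
    on every platform.  Deterministic chains ignore the seed's values (the
    draws are forced).  The provenance agents' counters advance by
    ``n_steps``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if isinstance(initial, JointState):
        comps = initial.components
    else:
        comps = chain.components_of(initial)
    comps = tuple(str(c) for c in comps)
    if chain.joint_label(comps) not in chain.E:
        raise ValueError(f"unknown initial state {dirac_label(comps)}")

    rng = np.random.default_rng(seed)
    states = [comps]
    cur = comps
    for _ in range(n_steps):
        nxt = list(cur)
        for rule in chain.rules:
            src = tuple(cur[i] for i in rule.in_idx)
            src_label = src[0] if len(src) == 1 else src
            p = rule.kernel.row(src_label)
            j = int(rng.choice(len(p), p=p))
            out_label = rule.kernel.target.labels[j]
            if len(rule.out_idx) == 1:
                nxt[rule.out_idx[0]] = out_label
            else:
                for pos, lab in zip(rule.out_idx, out_label):
                    nxt[pos] = lab
        cur = tuple(nxt)
        states.append(cur)
    chain.t += n_steps
    new_prov = tuple(a.with_counter(a.N + n_steps) for a in chain.provenance)
    chain.provenance = new_prov
    return Trajectory(states=states, chain=chain, seed=seed)
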