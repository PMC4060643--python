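"""Asymptotic structure of finite chains: absorbing sets, periods,
cyclic classes, and the associated spectral and harmonic objects.

A finite Markov chain decomposes into closed communicating classes
("absorbing sets": once entered, never left) plus transient states.
Each closed class rho has a period d_rho and splits into d_rho cyclic
classes ("asymptotic events") U_{rho,1}, ..., U_{rho,d_rho}; the
dynamics maps each cyclic class wholly onto the next, cyclically.

On top of that combinatorial skeleton sit the spectral objects: for
every class rho and integer k mod d_rho, the unit-modulus eigenvalue
lambda_{rho,k} = exp(2 i pi k / d_rho) with eigenfunction

    f_{rho,k} = sum_delta lambda_{rho,k}^delta U_{rho,delta},

satisfying L f = lambda f exactly; and for the space-time chain Q (which
advances the step counter by one while moving the state by L), the
Q-harmonic functions g_{rho,k}(., n) = lambda^{-n} f_{rho,k}.  Those
harmonic functions have the algebraic form of free-particle plane waves
on the cyclic classes — the bridge exploited in :mod:`.observables`.

Enumeration convention (fixed, and relied on by the rest of the
package): classes are ordered by period ascending, then by smallest
state index; within a class, delta = 1 is the cyclic class containing
the smallest state index and delta advances with the dynamics.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dynamics import DynamicsChain
from .kernels import MarkovKernel

__all__ = [
    "AbsorbingClass",
    "AbsorbingStructure",
    "SpectralObject",
    "SpaceTimeChain",
    "find_absorbing_structure",
    "indicator",
    "eigenvalue",
    "eigenfunction",
    "spacetime_kernel",
    "harmonic_function",
]

SUPPORT_TOL = 1e-15  # entries at or below this count as structural zeros


@dataclass(frozen=True)
class AbsorbingClass:
    """One closed communicating class with its cyclic decomposition."""

    index: int  # rho, 1-based
    states: tuple  # all labels, concatenation of cyclic classes in delta order
    period: int  # d_rho
    cyclic_classes: tuple  # tuple of tuples of labels, delta = 1 .. d_rho

    def delta_of(self, label) -> int:
        """1-based cyclic-class index of a state in this class."""
        for d, cc in enumerate(self.cyclic_classes, start=1):
            if label in cc:
                return d
        raise KeyError(f"state {label!r} not in class {self.index}")


@dataclass(frozen=True)
class AbsorbingStructure:
    """All closed classes of a chain, plus its transient states."""

    classes: tuple  # of AbsorbingClass, ordered per the module convention
    transient_states: tuple
    state_labels: tuple  # full enumeration of E, fixing vector indexing
    L: MarkovKernel  # the generating kernel (dense)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def cls(self, rho: int) -> AbsorbingClass:
        if not 1 <= rho <= len(self.classes):
            raise IndexError(f"class index rho={rho} out of range 1..{len(self.classes)}")
        return self.classes[rho - 1]

    def summary_rows(self):
        """(rho, period, states-in-delta-order) rows for tabular display."""
        return [(c.index, c.period, list(c.states)) for c in self.classes]


def _class_period_and_cyclic(L: np.ndarray, members: list, labels: tuple):
    """Period and delta-ordered cyclic classes of one closed class.

    Standard BFS level algorithm: root at the member with the smallest
    state index, assign BFS levels, and take the gcd of
    (level(u) + 1 - level(v)) over all support edges u -> v inside the
    class.  States then partition by level mod period; the root's cyclic
    class is delta = 1 and delta advances with the dynamics.
    """
    members = sorted(members)  # by state index
    root = members[0]
    member_set = set(members)
    level = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.nonzero(L[u] > SUPPORT_TOL)[0]:
                v = int(v)
                if v in member_set and v not in level:
                    level[v] = level[u] + 1
                    nxt.append(v)
        frontier = nxt
    g = 0
    for u in members:
        for v in np.nonzero(L[u] > SUPPORT_TOL)[0]:
            v = int(v)
            if v in member_set:
                g = math.gcd(g, level[u] + 1 - level[v])
    d = abs(g) if g != 0 else 1
    cyclic = [[] for _ in range(d)]
    for u in members:
        cyclic[level[u] % d].append(u)
    # delta = 1 at the root (level 0), advancing with the dynamics
    classes = tuple(tuple(labels[i] for i in sorted(cc)) for cc in cyclic)
    return d, classes


def find_absorbing_structure(chain: DynamicsChain) -> AbsorbingStructure:
    """Locate all closed communicating classes and their cyclic structure.

    Classes are the strongly connected components of the support digraph
    of L that have no outgoing support edge; everything else is
    transient.
    """
    L = chain.L
    m = L.matrix
    n = m.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    src, dst = np.nonzero(m > SUPPORT_TOL)
    g.add_edges_from(zip(src.tolist(), dst.tolist()))

    closed = []
    transient = []
    for scc in nx.strongly_connected_components(g):
        scc = set(scc)
        leaves = any(
            (v not in scc) for u in scc for v in g.successors(u)
        )
        if leaves:
            transient.extend(scc)
        else:
            closed.append(sorted(scc))

    labels = L.source.labels
    built = []
    for members in closed:
        d, cyclic = _class_period_and_cyclic(m, members, labels)
        states = tuple(lab for cc in cyclic for lab in cc)
        built.append((d, min(members), states, cyclic))
    built.sort(key=lambda t: (t[0], t[1]))
    classes = tuple(
        AbsorbingClass(index=i, states=states, period=d, cyclic_classes=cyclic)
        for i, (d, _, states, cyclic) in enumerate(built, start=1)
    )
    transient_labels = tuple(labels[i] for i in sorted(transient))
    return AbsorbingStructure(
        classes=classes, transient_states=transient_labels, state_labels=labels, L=L
    )


def indicator(struct: AbsorbingStructure, rho: int, delta: int) -> np.ndarray:
    """0/1 vector over E: the indicator of asymptotic event (rho, delta)."""
    cls = struct.cls(rho)
    if not 1 <= delta <= cls.period:
        raise IndexError(f"delta={delta} out of range 1..{cls.period} for class {rho}")
    members = set(cls.cyclic_classes[delta - 1])
    return np.array([1.0 if lab in members else 0.0 for lab in struct.state_labels])


def eigenvalue(struct: AbsorbingStructure, rho: int, k: int) -> complex:
    """lambda_{rho,k} = exp(2 i pi k / d_rho); k is reduced mod d_rho."""
    d = struct.cls(rho).period
    return cmath.exp(2j * cmath.pi * (k % d) / d)


@dataclass(frozen=True)
class SpectralObject:
    """Eigenpair of L attached to class rho and mode k."""

    rho: int
    k: int
    period: int  # d_rho
    eigenvalue: complex
    vector: np.ndarray  # f_{rho,k} over E, complex

    @property
    def d_rho_k(self):
        """d_rho / k — the wavelength/period of the associated plane wave.

        Undefined at k = 0 (no spatial variation); callers wanting wave
        parameters must use a nonzero mode.
        """
        from fractions import Fraction

        k = self.k % self.period
        if k == 0:
            raise ZeroDivisionError("d_rho_k is undefined for the k = 0 mode")
        return Fraction(self.period, k)


def eigenfunction(struct: AbsorbingStructure, rho: int, k: int) -> SpectralObject:
    """f_{rho,k} = sum_delta lambda^delta U_{rho,delta}.

    Supported only on class rho; satisfies L f = lambda f because the
    dynamics sends cyclic class delta wholly into delta + 1.
    """
    cls = struct.cls(rho)
    lam = eigenvalue(struct, rho, k)
    f = np.zeros(len(struct.state_labels), dtype=complex)
    for delta in range(1, cls.period + 1):
        f += (lam ** delta) * indicator(struct, rho, delta)
    return SpectralObject(
        rho=rho, k=k % cls.period, period=cls.period, eigenvalue=lam, vector=f
    )


@dataclass(frozen=True)
class SpaceTimeChain:
    """The kernel Q on (state, step) pairs: step -> step + 1, state by L.

    Represented as an operator on functions h(state_label, n), never as a
    stored matrix (the step axis is unbounded).
    """

    chain: DynamicsChain

    def apply(self, h):
        """Return Qh, with (Qh)(e, n) = sum_e' L(e, e') h(e', n + 1)."""
        L = self.chain.L

        def qh(e, n):
            row = L.row(e)
            return sum(
                row[j] * h(L.target.labels[j], n + 1)
                for j in np.nonzero(row)[0]
            )

        return qh

    def probability(self, e, n, e_next, m) -> float:
        """Q((e, n), {e'} x {m}): L(e, e') if m = n + 1, else 0."""
        if m != n + 1:
            return 0.0
        return self.chain.probability(e, e_next)


def spacetime_kernel(chain: DynamicsChain) -> SpaceTimeChain:
    return SpaceTimeChain(chain)


def harmonic_function(
    struct: AbsorbingStructure, rho: int, k: int, n: int
) -> np.ndarray:
    """g_{rho,k}(., n) = lambda_{rho,k}^(-n) f_{rho,k} over E.

    Q-harmonic: applying the space-time kernel reproduces the function,
    sum_e' L(e, e') g(e', n + 1) = g(e, n).
    """
    if n < 0:
        raise IndexError("step index n must be >= 0")
    spec = eigenfunction(struct, rho, k)
    return spec.eigenvalue ** (-n) * spec.vector
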