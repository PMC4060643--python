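"""Physical observables read off the asymptotic structure.

Two constructions live here.

**Plane-wave identification.**  The Q-harmonic function of class rho and
mode k, restricted to the cyclic classes and written per asymptotic
event delta, is

    g(delta, n) = cis(2 pi delta / d_rho_k  -  2 pi n / d_rho_k),

with d_rho_k = d_rho / k.  This is the free-particle wavefunction
psi(x, t) = A sum_x cis(2 pi x / lambda - 2 pi t / T) |x> under the
identifications A -> 1, |x> -> U_{rho,delta}, x -> delta, t -> n and
lambda = T = d_rho_k.  The momentum is p = h / d_rho_k and the energy
E = h c / d_rho_k; since wavelength equals period, the wave speed is 1
in lattice units.  h and c default to 1 — the identification is
structural, not dimensional.

**Integrated information.**  For a bipartition of the joint-state
components into blocks B1, B2, perturb the whole system into a uniform
joint state at time t, update once by L, and measure the two directed
effective informations: the mutual information between B1 at t and B2
at t + 1, and symmetrically.  Phi is their sum (in bits).  This measure
is fully determined by L, needs no search over partitions, and vanishes
exactly when L factorizes as a tensor product across the partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .asymptotics import AbsorbingStructure
from .dynamics import DynamicsChain

__all__ = [
    "WaveParams",
    "wave_params",
    "wavefunction",
    "PhiResult",
    "integrated_information",
]


@dataclass(frozen=True)
class WaveParams:
    """Free-particle parameters of mode (rho, k)."""

    rho: int
    k: int
    d_rho_k: Fraction
    wavelength: Fraction  # lattice units
    period: Fraction  # step units
    momentum: float  # p = h / d_rho_k
    energy: float  # E = h c / d_rho_k
    h: float = 1.0
    c: float = 1.0


def wave_params(
    struct: AbsorbingStructure, rho: int, k: int, h: float = 1.0, c: float = 1.0
) -> WaveParams:
    """Extract wavelength, period, momentum and energy for mode (rho, k).

    The k = 0 mode is the constant class indicator: it carries no spatial
    variation, so no wavelength is defined and the call is refused.
    """
    cls = struct.cls(rho)
    k_red = k % cls.period
    if k_red == 0:
        raise ValueError(
            f"mode k={k} is 0 mod d_rho={cls.period}: the constant mode has no "
            f"wave parameters"
        )
    d_rho_k = Fraction(cls.period, k_red)
    return WaveParams(
        rho=rho,
        k=k_red,
        d_rho_k=d_rho_k,
        wavelength=d_rho_k,
        period=d_rho_k,
        momentum=h / float(d_rho_k),
        energy=h * c / float(d_rho_k),
        h=h,
        c=c,
    )


def wavefunction(struct: AbsorbingStructure, rho: int, k: int, n: int) -> np.ndarray:
    """Complex amplitude per asymptotic event delta = 1 .. d_rho at step n.

    amplitude(delta) = cis(2 pi delta / d_rho_k - 2 pi n / d_rho_k), unit
    modulus everywhere on the class.  Equals the harmonic function
    aggregated per cyclic class (the harmonic function is constant on
    each cyclic class).
    """
    cls = struct.cls(rho)
    params = wave_params(struct, rho, k)  # validates k != 0
    d = float(params.d_rho_k)
    deltas = np.arange(1, cls.period + 1)
    phase = 2.0 * np.pi * deltas / d - 2.0 * np.pi * n / d
    return np.exp(1j * phase)


@dataclass(frozen=True)
class PhiResult:
    """Bipartition integrated information, in bits."""

    block1: tuple  # component indices
    block2: tuple
    ei_forward: float  # MI(block1_t ; block2_{t+1})
    ei_backward: float  # MI(block2_t ; block1_{t+1})

    @property
    def phi(self) -> float:
        return self.ei_forward + self.ei_backward


def _mutual_information_from_joint(joint: np.ndarray) -> float:
    """MI in bits of a joint probability table (rows: first variable)."""
    p1 = joint.sum(axis=1)
    p2 = joint.sum(axis=0)
    mi = 0.0
    for i, j in zip(*np.nonzero(joint)):
        p = joint[i, j]
        mi += p * math.log2(p / (p1[i] * p2[j]))
    return max(mi, 0.0)


def integrated_information(
    chain: DynamicsChain, block1, block2=None
) -> PhiResult:
    """Phi across a bipartition of the joint-state components.

    ``block1``/``block2`` are component index tuples; ``block2`` defaults
    to the complement of ``block1``.  The joint state at time t is
    uniformly distributed (a maximum-entropy perturbation of the whole
    system) and updated once by L.  Deterministic chains reduce to exact
    integer contingency counts, so dyadic distributions give bit-exact
    values.
    """
    n_comp = len(chain.component_spaces)
    block1 = tuple(sorted(block1))
    if block2 is None:
        block2 = tuple(i for i in range(n_comp) if i not in block1)
    else:
        block2 = tuple(sorted(block2))
    if set(block1) & set(block2):
        raise ValueError(f"blocks overlap: {block1} and {block2}")
    if set(block1) | set(block2) != set(range(n_comp)):
        missing = set(range(n_comp)) - set(block1) - set(block2)
        raise ValueError(f"blocks do not cover all components; missing {sorted(missing)}")
    if chain.n_states > 4096:
        raise ValueError("exact enumeration requires at most 4096 joint states")

    labels = chain.E.labels
    n = len(labels)

    def project(state, block):
        return tuple(state[i] for i in block)

    b1_vals = sorted({project(s, block1) for s in labels})
    b2_vals = sorted({project(s, block2) for s in labels})
    b1_idx = {v: i for i, v in enumerate(b1_vals)}
    b2_idx = {v: i for i, v in enumerate(b2_vals)}

    fwd = np.zeros((len(b1_vals), len(b2_vals)))  # (B1_t, B2_{t+1})
    bwd = np.zeros((len(b2_vals), len(b1_vals)))  # (B2_t, B1_{t+1})
    for e in labels:
        row = chain.row(e)
        i1 = b1_idx[project(e, block1)]
        i2 = b2_idx[project(e, block2)]
        for j in np.nonzero(row)[0]:
            e_next = labels[int(j)]
            p = row[int(j)] / n
            fwd[i1, b2_idx[project(e_next, block2)]] += p
            bwd[i2, b1_idx[project(e_next, block1)]] += p

    return PhiResult(
        block1=block1,
        block2=block2,
        ei_forward=_mutual_information_from_joint(fwd),
        ei_backward=_mutual_information_from_joint(bwd),
    )
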