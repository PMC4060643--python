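# conscious-agents

A simulator and analysis toolkit for networks of *conscious agents*:
finite probabilistic agents defined entirely by Markovian kernels, whose
coupled perceive–decide–act dynamics generates Markov chains with rich
asymptotic structure.

## The formalism

An agent is a six-tuple **C = (X, G, P, D, A, N)**: a finite percept
space *X*, a finite action space *G*, three row-stochastic kernels —
perception *P: W → X*, decision *D: X → G*, action *A: G → W* — and an
integer counter *N* that ticks once per perceive–decide–act cycle.  Two
agents are *adjacent* when each one's perception channel is the other's
action channel (*P₁ = A₂*, *P₂ = A₁*, *N₁ = N₂*).  Adjacent agents can
be combined into a new agent, either by an **undirected join** (tensor
products of kernels on the product spaces) or a **directed join**
(kernel composition *D₁A₁D₂*), and the package proves both closures by
construction and property tests.

A joined pair evolves on the 16-state joint space
*E = X₁ × G₁ × X₂ × G₂* under the lock-step kernel

    L(e, e′) = A₂(g₂, x₁′) · D₁(x₁, g₁′) · A₁(g₁, x₂′) · D₂(x₂, g₂′),

a product of four simultaneous independent draws, not a composition.
The toolkit computes the chain's absorbing sets ρ with periods *d_ρ* and
cyclic classes *U_{ρ,δ}*, the unit-modulus eigenpairs
*λ_{ρ,k} = exp(2πik/d_ρ)*, *f_{ρ,k} = Σ_δ λ^δ U_{ρ,δ}* of *L*, and the
harmonic functions *g_{ρ,k}(·,n) = λ^{−n} f_{ρ,k}* of the space-time
chain.  Those harmonic functions have exactly the plane-wave form
*ψ(x,t) = Σ_x cis(2πx/λ − 2πt/T)* with wavelength = period = *d_ρ/k*,
which the `observables` layer exposes as momentum *p = h/d_{ρ,k}* and
energy *E = hc/d_{ρ,k}*.  It also measures bipartition **integrated
information**: the sum of the two directed block-to-block mutual
informations under a uniform perturbation of the joint state.

A separate layer implements the evolutionary-game side of the theory:
worlds with priors *m*, fitness functions *f: W → [0,1]*, the fitness
measure *m_f ∝ f·m*, the four-tier perceptual-strategy hierarchy (naive
realist → strong critical → weak critical → interface), mutual-information
tuning comparisons, a seeded territory-choice game with information
costs, and replicator dynamics.

## Worked example

Two binary agents with all-identity kernels:

```sh
$ cagents asymptotics --fixture identity_pair
rho	period	states (delta order)
1	1	|0000>
2	1	|1111>
3	2	|0101> |1010>
4	4	|0001> |1000> |0100> |0010>
5	4	|0011> |1001> |1100> |0110>
6	4	|0111> |1011> |1101> |1110>
transient	-	(none)
```

The 16-state chain splits into six absorbing sets: two fixed points, one
2-cycle, and three 4-cycles listed in their cycle order (|0001⟩ → |1000⟩
→ |0100⟩ → |0010⟩ → …).  Changing only *D₁* to the swap matrix
((0,1),(1,0)) fuses the space into two period-8 cycles, and the combined
agent carries information not reducible to its parts:

```sh
$ cagents phi --fixture swap_d1_pair --block1 x1,g1
block1=x1,g1	block2=x2,g2
ei_forward_bits	1
ei_backward_bits	1
phi_bits	2
```

Each direction of influence across the agent bipartition carries exactly
one bit, for 2 bits of integrated information.  The period-4 class of
the identity system carries a plane-wave mode:

```sh
$ cagents wavefunction --fixture identity_pair --rho 4 --k 1 | head -3
# rho=4 k=1 d_rho_k=4 wavelength=4 period=4 p=0.25 E=0.25 (h=1.0, c=1.0)
delta	n	re	im
1	0	6.12323399574e-17	1
```

Wavelength and period both equal *d_{ρ,k}* = 4, so the wave speed is 1
in lattice units and *p = h/4* with *h* = 1.

The same operations are available as a library:

```python
from conscious_agents import (make_fixture, two_agent_chain,
                              find_absorbing_structure, integrated_information)

chain = two_agent_chain(*make_fixture("swap_d1_pair"))
struct = find_absorbing_structure(chain)
print([c.period for c in struct.classes])       # [8, 8]
print(integrated_information(chain, (0, 1)).phi)  # 2.0
```

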