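# Methods

## Scope and model assumptions

Everything in this package is finite.  State spaces are ordered finite
label sets carrying the full power-set σ-algebra, so all
measure-theoretic statements about kernels reduce to finite sums, every
event is a union of singletons, and the quasi-compactness condition
behind the asymptotic decomposition holds automatically.  Continuous or
countably infinite spaces are out of scope.

Agents interact in lock step: at each tick every decision kernel and
every action channel fires simultaneously and independently, and all
counters advance together.  The joint transition kernel is therefore a
*product* of kernel values (one per update rule), never a composition.
There is no free-standing world state: an agent's "world" is the tuple
of its neighbors' action/percept factors.

## Numerical conventions

* Row-stochasticity tolerance: 1e-12 absolute per row.  Kernels read
  from text files are renormalized if the row sum is within 1e-9 of 1
  (decimal round-trip noise) and rejected otherwise, so genuinely
  malformed specs fail loudly.
* Support threshold for graph analysis: entries ≤ 1e-15 are structural
  zeros.  Probabilities that small cannot arise from the fixtures or
  generators used here, so support detection is unambiguous.
* Product spaces enumerate row-major over factors in declared order
  (last factor fastest); Dirac labels |x₁g₁x₂g₂⟩ concatenate factor
  labels left-to-right in that order, which reproduces the |0000⟩ …
  |1111⟩ enumeration of the worked examples.
* Dense transition matrices are materialized only for |E| ≤ 4096.
  Larger chains expose lazily computed rows assembled from the factored
  update rules; simulation works at any size, absorbing-structure
  analysis requires the dense form.
* Simulation consumes one RNG draw per update rule per step, in
  component order, from a `numpy` Generator seeded per call —
  trajectories are bit-reproducible across platforms.  Deterministic
  (0/1-kernel) chains produce seed-independent trajectories.

## Absorbing structure

Closed classes are the strongly connected components of the support
digraph of L with no outgoing support edge (networkx SCCs); remaining
states are transient and reported separately — the "union of asymptotic
events exhausts E" property is asserted only for chains without
transients, which includes both canonical examples.  The period of a
class is the gcd of (level(u) + 1 − level(v)) over support edges inside
the class, with BFS levels rooted at the class member with the smallest
state index — the standard exact-integer algorithm.  Cyclic classes are
the residue classes of the BFS level mod the period.

Enumeration order is a package-wide convention: classes sort by (period
ascending, smallest state index ascending), and within a class δ = 1 is
the cyclic class containing the smallest state index, with δ advancing
along the dynamics.  This is the unique simple rule consistent with the
canonical examples' listed order (six classes with periods 1, 1, 2, 4,
4, 4, and U₅,₃ supported on |1100⟩).

The eigenfunction f_{ρ,k} takes the value λ_{ρ,k}^δ on cyclic class δ
and 0 off the class.  The eigen-relation L f = λ f and the
Q-harmonicity of g_{ρ,k}(·,n) = λ^{−n} f_{ρ,k} are statements about the
chain restricted to its recurrent part: a transient state feeding class
ρ picks up mass from f while f vanishes there, so the property tests
assert the relations in max norm over recurrent states (globally, and
exactly, for the canonical examples, which have no transients).  The
space-time kernel Q is represented as an operator on functions of
(state, step) — the step axis is unbounded, so it is never stored as a
matrix.

The independent cross-check for class detection is a Cesàro oracle: for
chains with ≤ 8 states, the averaged powers (1/N)·Σ Lⁿ are computed
after a long burn-in (2¹⁵ steps, averaging window 840 — a multiple of
every period ≤ 8), and class supports are read off the limit rows.  The
burn-in length matters: transient mass decays geometrically but the
rate can be slow when the transient set is nearly closed, so the
support threshold (1e-6) must sit far above the residual.

## Wave parameters and integrated information

Wave-parameter extraction maps mode (ρ, k ≠ 0) to d_{ρ,k} = d_ρ/k
(kept as an exact rational), wavelength = period = d_{ρ,k}, momentum
p = h/d_{ρ,k} and energy E = hc/d_{ρ,k}.  The constants h and c default
to 1: the identification is structural, and physical values are
accepted for display only since nothing fixes what one lattice step
means dimensionally.  The k = 0 mode is the constant class indicator
and carries no wavelength; extraction refuses it rather than divide by
zero.

Integrated information across a bipartition (B₁, B₂) of the joint-state
components is the sum of two directed effective informations: with the
joint state uniformly distributed at time t (an independent
maximum-entropy perturbation of the whole system) and updated once by
L, φ = MI(B₁_t ; B₂_{t+1}) + MI(B₂_t ; B₁_{t+1}) in bits.  This measure
was chosen because it is fully determined by L, requires no search over
partitions, vanishes exactly when L factorizes as a tensor product
across the partition, and yields the 2-bit value on the swap-D1 system.
Other measures from the integrated-information literature may share
these properties; no claim is made that this φ equals any specific
published variant.  On deterministic chains the contingency tables are
exact integer counts; mutual information is evaluated with `log2` in
double precision, which is exact for the dyadic ratios deterministic
chains produce (a fully symbolic logarithm is impossible: log₂ of a
non-power-of-two rational is irrational).

## Evolutionary games

"Structure" on a world is a total order on its labels, and
"structure-preserving" means order-preserving — the minimal structure
that expresses the monotone-versus-band fitness distinction (too much
salt or too little is devastating; the fit band is interior to the
order).  Only deterministic strategies are classified into the realist
tiers; stochastic strategies are interface by definition, since the
hierarchy is defined through structure-preserving *functions*.

The territory-choice game is this package's own concrete instantiation
of the no-free-information principles: each round, territories are
drawn i.i.d. from the world prior; each strategy perceives every
territory through its kernel, values percepts by the exact posterior
mean of fitness given the percept under (m, p), picks the best territory
(ties to the lowest index), and pays an information cost proportional
to log₂|X|.  All strategies face the same territory stream; each
strategy's percept noise uses its own derived substream so results are
seed-stable under strategy-list changes.  Default study conditions,
fixed in the `band_fitness_world` fixture: 10 ordered world states,
uniform prior, Gaussian band fitness peaked at index 4.5 with width
1.5, 2 territories, 10⁴ rounds, seed 1, zero information cost (both
competing strategies have two percepts, so costs cancel anyway);
replicator runs use 500 generations from equal frequencies.  These are
round numbers typical of seeded evolutionary-game demonstrations at
desk scale; conclusions asserted in tests are qualitative directions
(which strategy wins, fixation), never quantitative results of external
simulation studies.

The genericity probe draws 1000 random fitness functions (i.i.d.
uniform values) on a uniform 8-state ordered world and compares the
best deterministic 2-percept strategies with and without the
order-preserving restriction, in MI with m_f.  For deterministic
strategies MI(W; X) = H(X), so the comparison reduces to binary
entropies of subset masses versus prefix masses — exhaustive and exact.
The asserted direction (unrestricted strictly better more than half the
time) is deliberately weak; the fraction observed is far higher, but
"almost surely" claims about external simulations are not asserted.

## What the generators do and do not emulate

The synthetic generators produce Dirichlet(1) random kernels, random
adjacent pairs (adjacency pins the two cross channels, leaving four
free kernels), sparse random chains with 1–3 support entries per row
(so transient states actually occur), and band-fitness worlds.  They
cover the combinatorial range the theory quantifies over — they are not
calibrated to any empirical perceptual or neural data, so passing tests
demonstrate the mathematics of the formalism, not claims about human
vision or any measured organism.

## Known limitations

* Networks require an explicit per-neighbor factorization of each
  agent's kernels; automatic discovery of factorizations, and
  combination of arbitrary non-adjacent subsets of a pseudograph, are
  not implemented.
* Absorbing-structure analysis is dense-only (|E| ≤ 4096); spectral
  objects are not computed for transient parts.
* The relativistic/geometric-algebra extension of the wave
  identification is not modeled.
* Integrated information is computed for a given bipartition; there is
  no minimum-information-partition search.
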