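"""Perceptual strategies, fitness measures, and evolutionary games.

The setting: a finite world W with a "true" prior m over its states and
a total order on its labels (the structure realist strategies may
preserve).  A fitness function f: W -> [0, 1] reweights the prior into
the *fitness measure* m_f(w) = f(w) m(w) / sum f m.  A perceptual
strategy is a Markovian kernel p: W -> X from world states to percepts.

Strategies form a nested hierarchy (most to least committed to truth):

* naive realist — X = W and p an order-isomorphism: sees all the truth;
* strong critical realist — X a subset of W's labels, p order-preserving
  onto it: sees some of the truth;
* weak critical realist — X arbitrary but p order-preserving: sees true
  relationships, not true states;
* interface — no constraint: tuned to whatever pays, typically fitness.

A strategy tuned to maximize mutual information with m ("truth") does
not in general maximize mutual information with m_f ("fitness"): when f
is non-monotone in the world order — too much salt or too little is
devastating — order-preserving percepts cannot isolate the fit band,
and interface strategies win.  ``play_game`` makes that concrete as a
seeded territory-choice game with information costs, and
``replicator_dynamics`` lets strategy frequencies evolve under the
resulting payoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kernels import MarkovKernel, StateSpace, validate_kernel

__all__ = [
    "WorldModel",
    "FitnessFunction",
    "PerceptualStrategy",
    "fitness_measure",
    "classify_strategy",
    "mutual_info",
    "tuning_gap",
    "play_game",
    "replicator_dynamics",
    "threshold_strategy",
    "band_strategy",
    "best_two_percept_entropies",
    "gaussian_band_fitness",
]

PROB_ATOL = 1e-12


@dataclass(frozen=True)
class WorldModel:
    """A finite world with a prior and a total order on its states.

    The order is the canonical label order of ``W``; ``m`` holds the true
    probabilities of the world states.
    """

    W: StateSpace
    m: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        if m.shape != (self.W.size,):
            raise ValueError(f"prior shape {m.shape} does not match |W| = {self.W.size}")
        if np.any(m < 0.0):
            raise ValueError("prior entries must be non-negative")
        if abs(m.sum() - 1.0) > PROB_ATOL:
            raise ValueError(f"prior sums to {m.sum()!r}, not 1")
        m = m.copy()
        m.setflags(write=False)
        object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class FitnessFunction:
    """f: W -> [0, 1], for a fixed (organism, state, action) context.

    The general signature makes fitness a function of the world *and* of
    the organism, its state, and its action; fixing those three yields
    the per-world payoff map used here.  The context identifiers are
    carried for bookkeeping only.
    """

    values: np.ndarray
    organism: str = "organism"
    state: str = "state"
    action: str = "action"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("fitness values must be a vector over W")
        if np.any((v < 0.0) | (v > 1.0)):
            raise ValueError("fitness values must lie in [0, 1]")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PerceptualStrategy:
    """A perceptual kernel p: W -> X with an optional category tag."""

    name: str
    X: StateSpace
    p: MarkovKernel
    declared_category: str | None = None

    def __post_init__(self):
        if not self.p.target.same_labels(self.X):
            raise ValueError(f"strategy {self.name!r}: p.target must equal X")
        rep = validate_kernel(self.p)
        if not rep.ok:
            raise ValueError(f"strategy {self.name!r}: {'; '.join(rep.violations)}")

    def is_deterministic(self) -> bool:
        return self.p.is_deterministic()

    def mapping(self) -> list:
        """World-index -> percept-index map (deterministic strategies only)."""
        if not self.is_deterministic():
            raise ValueError(f"strategy {self.name!r} is stochastic")
        return [int(np.argmax(row)) for row in self.p.matrix]


def fitness_measure(world: WorldModel, f: FitnessFunction) -> np.ndarray:
    """m_f(w) = f(w) m(w), normalized so m_f(W) = 1."""
    fm = f.values * world.m
    total = fm.sum()
    if total <= 0.0:
        raise ValueError("fitness measure undefined: f has zero mass under m")
    return fm / total


def classify_strategy(s: PerceptualStrategy, world: WorldModel) -> str:
    """Most specific tier of the realist-to-interface hierarchy.

    Only deterministic strategies can occupy the realist tiers;
    stochastic strategies classify as interface.  Order preservation is
    with respect to the worlds' and percepts' canonical label orders.
    """
    if not s.is_deterministic():
        return "interface"
    mapping = s.mapping()  # world index -> percept index
    n_w = world.W.size

    order_preserving = all(
        mapping[i] <= mapping[i + 1] for i in range(n_w - 1)
    )
    if not order_preserving:
        return "interface"

    x_labels = s.X.labels
    w_labels = world.W.labels
    onto = set(mapping) == set(range(s.X.size))

    if x_labels == w_labels:
        bijective = len(set(mapping)) == n_w
        strictly_increasing = all(mapping[i] < mapping[i + 1] for i in range(n_w - 1))
        if bijective and strictly_increasing:
            return "naive_realist"
    if set(x_labels) <= set(w_labels) and onto:
        return "strong_critical"
    return "weak_critical"


def mutual_info(s: PerceptualStrategy, measure: np.ndarray) -> float:
    """Mutual information (bits) of (w, x) with w ~ measure, x ~ p(w, .)."""
    measure = np.asarray(measure, dtype=float)
    if measure.shape != (s.p.source.size,):
        raise ValueError(
            f"measure has {measure.shape[0] if measure.ndim else 0} entries, "
            f"strategy reads {s.p.source.size} world states"
        )
    if abs(measure.sum() - 1.0) > 1e-9:
        raise ValueError("measure must sum to 1")
    joint = measure[:, None] * s.p.matrix
    pw = joint.sum(axis=1)
    px = joint.sum(axis=0)
    mi = 0.0
    for i, j in zip(*np.nonzero(joint)):
        q = joint[i, j]
        mi += q * math.log2(q / (pw[i] * px[j]))
    return max(mi, 0.0)


def tuning_gap(s: PerceptualStrategy, world: WorldModel, f: FitnessFunction) -> dict:
    """MI with truth (m) versus MI with fitness (m_f), in bits."""
    return {
        "mi_truth": mutual_info(s, world.m),
        "mi_fitness": mutual_info(s, fitness_measure(world, f)),
    }


# ---------------------------------------------------------------------------
# Games


def _percept_posterior_fitness(world: WorldModel, f: FitnessFunction, s: PerceptualStrategy):
    """E[f | percept] under (m, p): the strategy's internal value of each percept."""
    joint = world.m[:, None] * s.p.matrix  # (w, x)
    px = joint.sum(axis=0)
    vals = np.full(s.X.size, -np.inf)
    reachable = px > 0.0
    vals[reachable] = (f.values[:, None] * joint).sum(axis=0)[reachable] / px[reachable]
    return vals


def play_game(
    world: WorldModel,
    f: FitnessFunction,
    strategies,
    n_territories: int = 2,
    cost_per_percept_bit: float = 0.0,
    n_rounds: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Seeded territory-choice game; returns mean payoff per strategy.

    Each round, ``n_territories`` world states are drawn i.i.d. from m.
    Every strategy perceives each territory through its kernel, picks the
    territory whose percept carries the highest internal expected fitness
    (posterior mean of f given the percept; ties to the lowest territory
    index), and earns f(w_chosen) minus an information cost of
    ``cost_per_percept_bit * log2 |X|``.  There is no free information:
    richer percept alphabets pay for their resolution.

    All strategies face the same territory stream; each strategy's
    percept noise uses its own substream, so adding a strategy never
    changes the others' draws.
    """
    strategies = list(strategies)
    if not strategies:
        raise ValueError("need at least one strategy")
    if n_territories < 2:
        raise ValueError("need at least two territories to choose between")
    if cost_per_percept_bit < 0:
        raise ValueError("information cost must be >= 0")

    world_rng = np.random.default_rng(seed)
    w_draws = world_rng.choice(world.W.size, size=(n_rounds, n_territories), p=world.m)

    payoffs = {}
    for s_i, strat in enumerate(strategies):
        rng = np.random.default_rng(None if seed is None else (seed, s_i))
        values = _percept_posterior_fitness(world, f, strat)
        if strat.is_deterministic():
            mapping = np.array(strat.mapping())
            percepts = mapping[w_draws]
        else:
            cum = np.cumsum(strat.p.matrix, axis=1)
            u = rng.random(size=w_draws.shape)
            percepts = (u[..., None] > cum[w_draws]).sum(axis=-1)
        internal = values[percepts]  # (rounds, territories)
        choice = np.argmax(internal, axis=1)  # first max -> lowest index
        chosen_w = w_draws[np.arange(n_rounds), choice]
        gross = f.values[chosen_w].mean()
        cost = cost_per_percept_bit * math.log2(strat.X.size)
        payoffs[strat.name] = float(gross - cost)
    return payoffs


def replicator_dynamics(payoffs, init_freqs, n_generations: int) -> np.ndarray:
    """Discrete replicator update: freq_i' = freq_i * payoff_i / mean payoff.

    ``payoffs`` is either a fixed payoff vector or a callable
    freqs -> payoff vector (frequency-dependent games).  Returns the
    frequency trajectory, shape (n_generations + 1, n_strategies);
    frequencies stay non-negative and sum to 1 throughout.
    """
    freqs = np.asarray(init_freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > PROB_ATOL or np.any(freqs < 0):
        raise ValueError("initial frequencies must be a probability vector")
    payoff_fn = payoffs if callable(payoffs) else (lambda _freqs: np.asarray(payoffs, float))
    traj = [freqs.copy()]
    for _ in range(n_generations):
        pay = np.asarray(payoff_fn(freqs), dtype=float)
        mean = float(freqs @ pay)
        if mean == 0.0:
            raise ZeroDivisionError("mean payoff is zero; replicator update undefined")
        freqs = freqs * pay / mean
        freqs = freqs / freqs.sum()  # renormalize away rounding drift
        traj.append(freqs.copy())
    return np.vstack(traj)


# ---------------------------------------------------------------------------
# Strategy and fitness constructors


def threshold_strategy(world: WorldModel, cut: int, name: str = "") -> PerceptualStrategy:
    """Order-preserving two-percept strategy: "lo" below ``cut``, "hi" at/above."""
    if not 1 <= cut <= world.W.size - 1:
        raise ValueError(f"cut must be in 1..{world.W.size - 1}")
    X = StateSpace(("lo", "hi"))
    m = np.zeros((world.W.size, 2))
    m[:cut, 0] = 1.0
    m[cut:, 1] = 1.0
    return PerceptualStrategy(
        name=name or f"threshold@{cut}", X=X,
        p=MarkovKernel(world.W, X, m), declared_category="weak_critical",
    )


def band_strategy(
    world: WorldModel, f: FitnessFunction, threshold: float = 0.5, name: str = ""
) -> PerceptualStrategy:
    """Interface two-percept strategy: "fit" where f >= threshold, else "unfit".

    Colors the world by fitness bands, ignoring the world order entirely.
    """
    X = StateSpace(("unfit", "fit"))
    m = np.zeros((world.W.size, 2))
    in_band = f.values >= threshold
    m[in_band, 1] = 1.0
    m[~in_band, 0] = 1.0
    return PerceptualStrategy(
        name=name or "band", X=X, p=MarkovKernel(world.W, X, m),
        declared_category="interface",
    )


def gaussian_band_fitness(
    world: WorldModel, peak: float, width: float
) -> FitnessFunction:
    """Non-monotone goldilocks fitness: a Gaussian bump over the world order."""
    idx = np.arange(world.W.size, dtype=float)
    vals = np.exp(-0.5 * ((idx - peak) / width) ** 2)
    return FitnessFunction(values=vals)


def best_two_percept_entropies(measure: np.ndarray) -> dict:
    """Best achievable MI with a measure for deterministic 2-percept strategies.

    For a deterministic strategy MI(w; x) = H(x), the binary entropy of
    the percept split, so the best unrestricted 2-percept strategy
    maximizes H over all non-trivial subsets of W, while the best
    order-preserving one maximizes over prefix cuts only.  Exhaustive:
    meant for small worlds (|W| <= 20).
    """
    measure = np.asarray(measure, dtype=float)
    n = measure.size
    if n > 20:
        raise ValueError("exhaustive subset search limited to |W| <= 20")

    def h2(q):
        if q <= 0.0 or q >= 1.0:
            return 0.0
        return -q * math.log2(q) - (1 - q) * math.log2(1 - q)

    prefix = np.cumsum(measure)[:-1]
    best_ordered = max(h2(q) for q in prefix)
    masks = np.arange(1, 2**n - 1)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(float)
    subset_mass = bits @ measure
    best_any = max(h2(q) for q in subset_mass)
    return {"best_order_preserving": best_ordered, "best_unrestricted": best_any}
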