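"""Finite state spaces and Markovian kernels.

A Markovian kernel between two finite state spaces is a row-stochastic
matrix: row ``s`` is the probability distribution over target states given
source state ``s``.  Kernels model communication channels (perception,
decision, action) throughout this package, and the two algebraic
operations on them — composition and tensor product — are the building
blocks of every multi-agent construction.

All measurable-space language in the underlying formalism reduces here to
finite sets carrying the full power-set sigma-algebra, so every integral
is a finite sum and every event is a union of singleton states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateSpace",
    "MarkovKernel",
    "ValidationReport",
    "validate_kernel",
    "compose",
    "tensor",
    "identity_kernel",
    "swap2",
    "product_space",
    "random_kernel",
]

#: absolute tolerance on each row sum
ROW_SUM_ATOL = 1e-12
#: rows read from text are renormalized if off by at most this, else rejected
RENORM_ATOL = 1e-9


@dataclass(frozen=True)
class StateSpace:
    """An ordered finite set of distinct state labels.

    Label order is canonical: it fixes matrix row/column order, product
    enumeration order, and serialization order.
    """

    labels: tuple
    name: str = ""

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"state labels must be distinct, got {labels!r}")
        if len(labels) == 0:
            raise ValueError("state space must be non-empty")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r} in space {self.name or self.labels!r}")

    def __contains__(self, label) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def same_labels(self, other: "StateSpace") -> bool:
        return self.labels == other.labels


def binary_space(name: str = "") -> StateSpace:
    """The two-state space {0, 1} with labels "0", "1"."""
    return StateSpace(("0", "1"), name=name)


def product_space(*spaces: StateSpace, name: str = "") -> StateSpace:
    """Cartesian product; labels are tuples in declared factor order.

    Enumeration is row-major over the factors: the last factor varies
    fastest.  Nested tuples from repeated products are flattened so that a
    product of products has flat component tuples.
    """
    import itertools

    def _flat(label):
        if isinstance(label, tuple):
            out = []
            for part in label:
                out.extend(_flat(part))
            return out
        return [label]

    labels = tuple(
        tuple(x for lab in combo for x in _flat(lab))
        for combo in itertools.product(*(s.labels for s in spaces))
    )
    return StateSpace(labels, name=name)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple = ()

    def __bool__(self) -> bool:
        return self.ok


@dataclass(frozen=True)
class MarkovKernel:
    """Row-stochastic matrix from ``source`` to ``target`` labels.

    ``matrix[i, j]`` is the probability of target state ``j`` given source
    state ``i``.  Rows must sum to 1 within ``ROW_SUM_ATOL``; use
    ``validate_kernel`` for a non-raising check.
    """

    source: StateSpace
    target: StateSpace
    matrix: np.ndarray
    name: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError(f"kernel matrix must be 2-d, got shape {m.shape}")
        if m.shape != (self.source.size, self.target.size):
            raise ValueError(
                f"kernel matrix shape {m.shape} does not match "
                f"(source={self.source.size}, target={self.target.size})"
            )
        m = m.copy()
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def __call__(self, s_label, t_label) -> float:
        return float(self.matrix[self.source.index(s_label), self.target.index(t_label)])

    def row(self, s_label) -> np.ndarray:
        return self.matrix[self.source.index(s_label)]

    @property
    def shape(self):
        return self.matrix.shape

    def allclose(self, other: "MarkovKernel", atol: float = ROW_SUM_ATOL) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.matrix, other.matrix, rtol=0.0, atol=atol)
        )

    def is_deterministic(self) -> bool:
        """True when every entry is exactly 0 or 1."""
        return bool(np.all((self.matrix == 0.0) | (self.matrix == 1.0)))


def validate_kernel(kernel: MarkovKernel, atol: float = ROW_SUM_ATOL) -> ValidationReport:
    """Check the Markov-kernel invariants and report each violation.

    Violations name the offending row or entry.  A non-rectangular entry
    table never reaches this point: ``MarkovKernel`` construction raises a
    structural ``ValueError`` first.
    """
    m = kernel.matrix
    violations = []
    neg = np.argwhere(m < 0.0)
    for i, j in neg:
        violations.append(
            f"negative entry {m[i, j]!r} at ({kernel.source.labels[i]!r}, "
            f"{kernel.target.labels[j]!r})"
        )
    over = np.argwhere(m > 1.0)
    for i, j in over:
        violations.append(
            f"entry {m[i, j]!r} exceeds 1 at ({kernel.source.labels[i]!r}, "
            f"{kernel.target.labels[j]!r})"
        )
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if abs(s - 1.0) > atol:
            violations.append(f"row {i} ({kernel.source.labels[i]!r}) sums to {s!r}")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def compose(k1: MarkovKernel, k2: MarkovKernel, name: str = "") -> MarkovKernel:
    """Kernel composition (k1 then k2): ordinary stochastic matrix product.

    entry(s, u) = sum_t k1(s, t) * k2(t, u).
    """
    if not k1.target.same_labels(k2.source):
        raise ValueError(
            f"cannot compose: first kernel's target {k1.target.labels!r} "
            f"differs from second kernel's source {k2.source.labels!r}"
        )
    return MarkovKernel(k1.source, k2.target, k1.matrix @ k2.matrix, name=name)


def tensor(
    k1: MarkovKernel,
    k2: MarkovKernel,
    input_order: tuple = (0, 1),
    output_order: tuple = (0, 1),
    name: str = "",
) -> MarkovKernel:
    """Tensor product of two kernels on the product spaces.

    With the default orders the result maps (a, b) -> (c, d) with
    entry((a, b), (c, d)) = k1(a, c) * k2(b, d): the two factors act
    independently.  ``input_order=(1, 0)`` presents the source as
    k2.source x k1.source (the input tuple is read transposed), and
    ``output_order=(1, 0)`` likewise transposes the target product.  The
    transposed variants are needed because the undirected-join
    construction wires the joint perception kernel with inputs (g2, g1)
    and the joint action kernel with outputs (x2, x1).
    """
    for order in (input_order, output_order):
        if tuple(sorted(order)) != (0, 1):
            raise ValueError(f"order must be a permutation of (0, 1), got {order!r}")
    in_spaces = [k1.source, k2.source]
    out_spaces = [k1.target, k2.target]
    src = product_space(*(in_spaces[i] for i in input_order))
    tgt = product_space(*(out_spaces[i] for i in output_order))
    # outer product, then axis permutation to the declared orders
    t = np.einsum("ac,bd->abcd", k1.matrix, k2.matrix)
    # axes 0,1 are inputs (k1, k2); axes 2,3 outputs (k1, k2)
    perm_in = [input_order[0], input_order[1]]
    perm_out = [2 + output_order[0], 2 + output_order[1]]
    t = np.transpose(t, perm_in + perm_out)
    m = t.reshape(src.size, tgt.size)
    return MarkovKernel(src, tgt, m, name=name)


def identity_kernel(space: StateSpace, name: str = "") -> MarkovKernel:
    return MarkovKernel(space, space, np.eye(space.size), name=name)


def swap2(space: StateSpace | None = None, name: str = "swap") -> MarkovKernel:
    """The 2x2 swap (NOT) kernel ((0,1),(1,0)) on a binary space."""
    if space is None:
        space = binary_space()
    if space.size != 2:
        raise ValueError("swap2 requires a two-state space")
    return MarkovKernel(space, space, np.array([[0.0, 1.0], [1.0, 0.0]]), name=name)


def random_kernel(
    source: StateSpace,
    target: StateSpace,
    rng: np.random.Generator,
    concentration: float = 1.0,
    name: str = "",
) -> MarkovKernel:
    """Random kernel with independent Dirichlet(concentration) rows."""
    m = rng.dirichlet(np.full(target.size, concentration), size=source.size)
    # guard against numerical drift beyond the row-sum tolerance
    m = m / m.sum(axis=1, keepdims=True)
    return MarkovKernel(source, target, m, name=name)
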