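"""Serialization: agent spec files (YAML) and kernel matrices (CSV).

Formats are plain text and bit-exact on round-trip: floats are written
with shortest round-trip representations (YAML) or 17 significant digits
(CSV).  Kernels are validated on load; rows whose sums are off by more
than 1e-9 are rejected with the offending row named, rows within 1e-9
are renormalized (decimal round-trip noise), and anything inside the
1e-12 row-sum tolerance is taken as-is.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from .agents import ConsciousAgent
from .kernels import RENORM_ATOL, ROW_SUM_ATOL, MarkovKernel, StateSpace

__all__ = [
    "save_matrix_csv",
    "load_matrix_csv",
    "save_agent",
    "load_agent",
    "agent_to_dict",
    "agent_from_dict",
]

FORMAT_VERSION = 1


def _clean_rows(matrix: np.ndarray, context: str) -> np.ndarray:
    """Apply the load-time renormalization policy."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"{context}: matrix must be rectangular (2-d)")
    if np.any(m < 0.0):
        i, j = np.argwhere(m < 0.0)[0]
        raise ValueError(f"{context}: negative entry {m[i, j]!r} at row {i}, column {j}")
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if abs(s - 1.0) > RENORM_ATOL:
            raise ValueError(f"{context}: row {i} sums to {s!r} (beyond 1e-9 tolerance)")
    bad = np.abs(sums - 1.0) > ROW_SUM_ATOL
    if np.any(bad):
        m = m.copy()
        m[bad] = m[bad] / sums[bad, None]
    return m


def save_matrix_csv(kernel: MarkovKernel, path) -> None:
    """Header row = target labels, first column = source labels."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + [str(l) for l in kernel.target.labels])
        for i, s in enumerate(kernel.source.labels):
            w.writerow([str(s)] + [f"{x:.17g}" for x in kernel.matrix[i]])


def load_matrix_csv(path) -> MarkovKernel:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise ValueError(f"{path}: not a kernel CSV (missing header)")
    target = StateSpace(tuple(rows[0][1:]))
    src_labels = []
    data = []
    for r_i, row in enumerate(rows[1:], start=2):
        if len(row) != target.size + 1:
            raise ValueError(f"{path}: line {r_i} has {len(row)} cells, expected {target.size + 1}")
        src_labels.append(row[0])
        data.append([float(x) for x in row[1:]])
    source = StateSpace(tuple(src_labels))
    m = _clean_rows(np.array(data), context=str(path))
    return MarkovKernel(source, target, m)


def _matrix_to_lists(matrix: np.ndarray) -> list:
    return [[float(x) for x in row] for row in matrix]


def agent_to_dict(agent: ConsciousAgent) -> dict:
    return {
        "format": FORMAT_VERSION,
        "name": agent.name,
        "percepts": [str(l) for l in agent.X.labels],
        "actions": [str(l) for l in agent.G.labels],
        "world_in": [str(l) for l in agent.P.source.labels],
        "world_out": [str(l) for l in agent.A.target.labels],
        "kernels": {
            "P": _matrix_to_lists(agent.P.matrix),
            "D": _matrix_to_lists(agent.D.matrix),
            "A": _matrix_to_lists(agent.A.matrix),
        },
        "counter": int(agent.N),
    }


def agent_from_dict(spec: dict, base_dir: Path | None = None, context: str = "<dict>") -> ConsciousAgent:
    try:
        version = spec["format"]
        name = spec["name"]
        X = StateSpace(tuple(spec["percepts"]))
        G = StateSpace(tuple(spec["actions"]))
        world_in = StateSpace(tuple(spec["world_in"]))
        world_out = StateSpace(tuple(spec["world_out"]))
        kernels = spec["kernels"]
        counter = int(spec.get("counter", 0))
    except KeyError as exc:
        raise ValueError(f"{context}: missing field {exc.args[0]!r}") from None
    if version != FORMAT_VERSION:
        raise ValueError(f"{context}: unsupported format version {version!r}")

    def build(key: str, source: StateSpace, target: StateSpace) -> MarkovKernel:
        entry = kernels.get(key)
        if entry is None:
            raise ValueError(f"{context}: kernel {key!r} missing")
        if isinstance(entry, str):  # external CSV path, relative to the spec file
            path = (base_dir / entry) if base_dir is not None else Path(entry)
            k = load_matrix_csv(path)
            if k.shape != (source.size, target.size):
                raise ValueError(
                    f"{context}: kernel {key!r} from {path} has shape {k.shape}, "
                    f"expected ({source.size}, {target.size})"
                )
            return MarkovKernel(source, target, k.matrix, name=key)
        m = _clean_rows(np.array(entry, dtype=float), context=f"{context}: kernel {key!r}")
        return MarkovKernel(source, target, m, name=key)

    agent = ConsciousAgent(
        name=name,
        X=X,
        G=G,
        P=build("P", world_in, X),
        D=build("D", X, G),
        A=build("A", G, world_out),
        N=counter,
    )
    rep = agent.validate()
    if not rep.ok:
        raise ValueError(f"{context}: {'; '.join(rep.violations)}")
    return agent


def save_agent(agent: ConsciousAgent, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(agent_to_dict(agent), fh, sort_keys=False)


def load_agent(path) -> ConsciousAgent:
    path = Path(path)
    with open(path) as fh:
        try:
            spec = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"{path}: parse error: {exc}") from None
    if not isinstance(spec, dict):
        raise ValueError(f"{path}: agent spec must be a mapping")
    return agent_from_dict(spec, base_dir=path.parent, context=str(path))
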