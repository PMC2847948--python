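"""Deterministic threshold dynamics of gene regulatory networks.

The genotype is a signed interaction matrix ``w`` over ``N`` genes:
``w[i, j] = +1`` means gene ``j`` activates gene ``i``, ``-1`` that it
represses it, and ``0`` that it has no direct effect.  The phenotype is the
trajectory of binary gene-activity states under the synchronous update rule

    s_i(t+1) = +1   if  sum_j w[i, j] * s_j(t) > 0
             = -1   otherwise,

with activity encoded internally as +1 (active) / -1 (inactive).  A tied
regulatory sum of exactly zero therefore maps to *inactive*.  Because the
state space is finite (2^N states) and the dynamics deterministic, every
initial state reaches an attractor: a fixed point or a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ACTIVE: int = 1
INACTIVE: int = -1

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "GeneNetwork",
    "AttractorResult",
    "as_pattern",
    "pattern_from_bits",
    "pattern_to_bits",
    "update_state",
    "hamming_distance",
    "find_attractor",
]


@dataclass
class GeneNetwork:
    """Signed interaction matrix of a gene regulatory network.

    ``interactions[i, j]`` is the regulatory effect of gene ``j`` on gene
    ``i`` (row = regulated gene, column = regulator).  Entries are
    restricted to {-1, 0, +1}: the mutation operator only ever adds or
    removes interactions, it does not evolve magnitudes.
    """

    interactions: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.interactions)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"interaction matrix must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise ValueError("network needs at least one gene")
        if not np.isin(w, (-1, 0, 1)).all():
            bad = w[~np.isin(w, (-1, 0, 1))][0]
            raise ValueError(f"interaction entries must be in {{-1, 0, +1}}, got {bad}")
        self.interactions = w.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return self.interactions.shape[0]

    @property
    def n_interactions(self) -> int:
        """Number of nonzero entries of the interaction matrix."""
        return int(np.count_nonzero(self.interactions))

    def regulators_of(self, gene: int) -> np.ndarray:
        """Indices of genes with a nonzero effect on ``gene``."""
        return np.flatnonzero(self.interactions[gene]).astype(np.int64)

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self.interactions.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return np.array_equal(self.interactions, other.interactions)


def as_pattern(states, n_genes: Optional[int] = None) -> np.ndarray:
    """Validate and coerce a gene-activity pattern to an int8 ±1 vector."""
    s = np.asarray(states)
    if s.ndim != 1:
        raise ValueError(f"activity pattern must be one-dimensional, got shape {s.shape}")
    if not np.isin(s, (-1, 1)).all():
        raise ValueError("activity states must be +1 (active) or -1 (inactive)")
    if n_genes is not None and s.shape[0] != n_genes:
        raise ValueError(f"pattern has {s.shape[0]} genes, expected {n_genes}")
    return s.astype(np.int8)


def pattern_from_bits(bits: str) -> np.ndarray:
    """Parse a 0/1 bit-string (gene 0 leftmost; 1 = active) into a ±1 pattern."""
    if not bits or any(c not in "01" for c in bits):
        raise ValueError(f"pattern bit-string must be nonempty over 0/1, got {bits!r}")
    return np.array([1 if c == "1" else -1 for c in bits], dtype=np.int8)


def pattern_to_bits(pattern) -> str:
    """Serialize a ±1 pattern to a 0/1 bit-string, gene 0 leftmost."""
    p = as_pattern(pattern)
    return "".join("1" if x > 0 else "0" for x in p)


def update_state(network: GeneNetwork, state) -> np.ndarray:
    """One synchronous update step of the threshold dynamics.

    Gene ``i`` becomes active iff its signed regulatory input
    ``sum_j w[i, j] * s_j`` is strictly positive; ties at zero and negative
    sums both map to inactive.  The input state is not modified.
    """
    s = as_pattern(state, network.n_genes)
    total = network.interactions.astype(np.int64) @ s.astype(np.int64)
    return np.where(total > 0, ACTIVE, INACTIVE).astype(np.int8)


def hamming_distance(a, b) -> int:
    """Number of genes at which two activity patterns differ."""
    pa, pb = as_pattern(a), as_pattern(b)
    if pa.shape[0] != pb.shape[0]:
        raise ValueError(f"pattern lengths differ: {pa.shape[0]} vs {pb.shape[0]}")
    return int(np.count_nonzero(pa != pb))


@dataclass
class AttractorResult:
    """Attractor reached from one initial condition.

    ``steps_to_attractor`` counts update steps until the first state that
    belongs to the attractor; ``cycle_length`` is 1 for fixed points.
    ``fixed_state`` is present only for fixed points.
    """

    kind: str
    steps_to_attractor: int
    cycle_length: int
    fixed_state: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_point", "cycle"):
            raise ValueError(f"unknown attractor kind {self.kind!r}")
        if (self.kind == "fixed_point") != (self.fixed_state is not None):
            raise ValueError("fixed_state must be present iff kind is fixed_point")


def find_attractor(network: GeneNetwork, initial, max_steps: Optional[int] = None) -> AttractorResult:
    """Iterate the dynamics from ``initial`` until the attractor is identified.

    The state space is finite, so with the default cap of ``2**N`` steps an
    attractor is always found.  Detection records every visited state; the
    first revisited state marks the attractor entry point.
    """
    n = network.n_genes
    if max_steps is None:
        max_steps = 2 ** n
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = as_pattern(initial, n)
    seen = {state.tobytes(): 0}
    trajectory = [state]
    for step in range(1, max_steps + 1):
        state = update_state(network, state)
        key = state.tobytes()
        if key in seen:
            entry = seen[key]
            cycle_length = step - entry
            if cycle_length == 1:
                return AttractorResult(
                    kind="fixed_point",
                    steps_to_attractor=entry,
                    cycle_length=1,
                    fixed_state=trajectory[entry].copy(),
                )
            return AttractorResult(kind="cycle", steps_to_attractor=entry, cycle_length=cycle_length)
        seen[key] = step
        trajectory.append(state)
    raise RuntimeError(f"no attractor found within {max_steps} steps (increase max_steps)")
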