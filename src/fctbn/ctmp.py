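"""Finite-state continuous-time Markov process primitives.

A homogeneous Markov process on a finite state space is parameterized by an
intensity matrix Q whose off-diagonal entry q_ij is the instantaneous rate of
jumping from state i to state j and whose rows sum to zero.  Sojourn times in
state i are exponential with parameter q_i = -Q_ii, and the closed-form
maximum-likelihood estimate of each rate is the transition count divided by
the exposure time, q̂ = M / T.

This module is deliberately general (arbitrary finite state spaces); the
network model built on top of it restricts nodes to binary states.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, SchemaError

__all__ = [
    "IntensityMatrix",
    "ConditionalIntensityMatrix",
    "SufficientStats",
    "RateEstimate",
    "ValidationReport",
    "sojourn_law",
    "validate_intensity",
    "sufficient_stats",
    "mle_intensities",
    "enumerate_joint_states",
]

#: tolerance for the row-sum-zero invariant of intensity matrices
ROW_SUM_TOL = 1e-9


def sojourn_law(rate: float, t: float) -> tuple[float, float]:
    """Density and CDF of the exponential sojourn law with the given rate.

    The holding time in a state with total exit rate ``q`` is exponential:
    ``f(t) = q e^{-qt}``, ``F(t) = 1 - e^{-qt}``.

    Raises
    ------
    ValueError
        If ``rate <= 0`` or ``t < 0``.
    """
    if rate <= 0:
        raise ValueError(f"sojourn rate must be positive, got {rate}")
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    density = rate * math.exp(-rate * t)
    cdf = 1.0 - math.exp(-rate * t)
    return density, cdf


@dataclass
class IntensityMatrix:
    """Transition intensity matrix over an ordered list of state labels."""

    states: list
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2 or self.rates.shape[0] != self.rates.shape[1]:
            raise SchemaError(f"intensity matrix must be square, got shape {self.rates.shape}")
        if len(self.states) != self.rates.shape[0]:
            raise SchemaError("state labels and matrix dimension disagree")


@dataclass
class ConditionalIntensityMatrix:
    """A node's intensity matrix for one complete parent configuration."""

    node: str
    parent_config: tuple  # tuple of (parent, state), in declared parent order
    matrix: IntensityMatrix


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)


def validate_intensity(matrix) -> ValidationReport:
    """Check row-sums-zero and off-diagonal nonnegativity of an intensity matrix.

    Accepts an :class:`IntensityMatrix` or a raw square array.  A non-square
    input raises; invariant violations are *reported*, not raised.
    """
    rates = matrix.rates if isinstance(matrix, IntensityMatrix) else np.asarray(matrix, dtype=float)
    if rates.ndim != 2 or rates.shape[0] != rates.shape[1]:
        raise SchemaError(f"intensity matrix must be square, got shape {rates.shape}")
    violations: list[str] = []
    row_sums = rates.sum(axis=1)
    for i, s in enumerate(row_sums):
        if abs(s) > ROW_SUM_TOL:
            violations.append(f"row {i} sums to {s:.3e}, expected 0")
    off = rates - np.diag(np.diag(rates))
    bad = np.argwhere(off < 0)
    for i, j in bad:
        if i != j:
            violations.append(f"off-diagonal entry ({i},{j}) = {rates[i, j]:.3e} is negative")
    return ValidationReport(ok=not violations, violations=violations)


@dataclass
class SufficientStats:
    """Transition counts M and exposure times T per (node, state, parent_config).

    ``parent_config`` is a tuple of ``(parent, state)`` pairs in the child's
    declared parent order.  Censored sojourns contribute exposure only.
    """

    M: dict = field(default_factory=dict)
    T: dict = field(default_factory=dict)

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        M = dict(self.M)
        T = dict(self.T)
        for k, v in other.M.items():
            M[k] = M.get(k, 0) + v
        for k, v in other.T.items():
            T[k] = T.get(k, 0.0) + v
        return SufficientStats(M, T)

    def total_exposure(self, node: str) -> float:
        return sum(v for (n, _s, _u), v in self.T.items() if n == node)


def sufficient_stats(dataset, structure) -> SufficientStats:
    """Tally M[x|u] and T[x|u] over every sojourn of every subject.

    For each record, every node accrues exposure at its interval-start state
    under its interval-start parent configuration; the transitioning node of a
    non-censored record additionally counts one transition out of its state.
    """
    stats = SufficientStats()
    node_idx = {n: i for i, n in enumerate(dataset.nodes)}
    for node in structure.nodes:
        if node not in node_idx:
            raise SchemaError(f"structure node {node!r} absent from dataset")
    for subject in dataset.subjects:
        for rec in subject.records:
            for node in structure.nodes:
                state = int(rec.states[node_idx[node]])
                config = tuple(
                    (p, int(rec.states[node_idx[p]])) for p in structure.parents.get(node, ())
                )
                key = (node, state, config)
                stats.T[key] = stats.T.get(key, 0.0) + rec.duration
                if not rec.censored and rec.node == node:
                    stats.M[key] = stats.M.get(key, 0) + 1
    return stats


@dataclass
class RateEstimate:
    rate: float
    inestimable: bool = False


def mle_intensities(stats: SufficientStats) -> dict:
    """Closed-form MLE q̂ = M/T per (node, state, parent_config).

    Cells with zero exposure are flagged inestimable (rate NaN) rather than
    raised; cells with exposure but no transitions estimate to 0.
    """
    out: dict = {}
    for key, t in stats.T.items():
        m = stats.M.get(key, 0)
        if t <= 0:
            out[key] = RateEstimate(float("nan"), inestimable=True)
        else:
            out[key] = RateEstimate(m / t, inestimable=False)
    # count-only keys with no exposure record are inestimable too
    for key in stats.M:
        if key not in out:
            out[key] = RateEstimate(float("nan"), inestimable=True)
    return out


def enumerate_joint_states(nodes, cap: int = 2**16) -> list[tuple]:
    """Enumerate joint configurations of a set of finite-state variables.

    ``nodes`` may be a mapping name -> state count, a sequence of
    ``(name, count)`` pairs, or a sequence of counts.  Ordering is
    lexicographic in node declaration order (last node varies fastest),
    matching nested-loop enumeration.  A set of n binary variables yields
    2^n configurations.
    """
    if isinstance(nodes, Mapping):
        counts = [int(v) for v in nodes.values()]
    else:
        nodes = list(nodes)
        if not nodes:
            raise SchemaError("at least one node is required")
        if isinstance(nodes[0], (tuple, list)):
            counts = [int(c) for _name, c in nodes]
        else:
            counts = [int(c) for c in nodes]
    if not counts:
        raise SchemaError("at least one node is required")
    for c in counts:
        if c < 2:
            raise SchemaError(f"each node needs >= 2 states, got {c}")
    total = math.prod(counts)
    if total > cap:
        raise CapacityError(f"{total} joint configurations exceed the cap of {cap}")
    return list(itertools.product(*(range(c) for c in counts)))
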