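"""Synthetic cohort generator: covariates and trajectories from a known FCTBN.

Trajectories are sampled with the competing-exponentials (Gillespie) scheme:
given the current joint state, each node's active transition rate is computed
from the model; the time to the next event is exponential in the total rate
and the transitioning node is drawn proportionally to the rates.  Each draw
uses one rng stream in a fixed order (total-time draw, then node pick), so
cohorts are reproducible across platforms given a seed.

Generated cohorts emulate observational event-history data: binary condition
nodes, subject-level risk factors, and right-censoring at a finite horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, SchemaError
from .model import (
    BASELINE,
    GAIN,
    LOSS,
    CoefficientTable,
    NetworkStructure,
    Record,
    Subject,
    TrajectoryDataset,
)

__all__ = [
    "SimulationSpec",
    "generate_covariates",
    "sample_trajectory",
    "generate_cohort",
    "discretize_annual",
]


@dataclass
class SimulationSpec:
    """Everything needed to draw a cohort from a known generating model."""

    structure: NetworkStructure
    truth: CoefficientTable
    covariate_spec: list  # [(name, ("normal", mu, sigma)) | (name, ("categorical", {level: p}))]
    n_subjects: int
    horizon: float
    seed: int
    initial_state_dist: dict | None = None  # joint-state tuple -> probability; default all-zeros

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ConfigError("horizon must be positive")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        if self.initial_state_dist is not None:
            tot = sum(self.initial_state_dist.values())
            if abs(tot - 1.0) > 1e-9:
                raise ConfigError(f"initial state probabilities sum to {tot}, expected 1")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.covariate_spec)


def generate_covariates(spec: SimulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the n_subjects x m covariate matrix declared by the spec."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cols = []
    for name, dist in spec.covariate_spec:
        kind = dist[0]
        if kind == "normal":
            _, mu, sigma = dist
            cols.append(rng.normal(mu, sigma, size=spec.n_subjects))
        elif kind == "categorical":
            levels = dist[1]
            labels = list(levels.keys())
            probs = np.asarray([levels[k] for k in labels], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(f"categorical probabilities for {name!r} sum to {probs.sum()}")
            idx = rng.choice(len(labels), size=spec.n_subjects, p=probs)
            vals = np.asarray(labels, dtype=float) if all(
                isinstance(l, (int, float)) for l in labels
            ) else np.arange(len(labels), dtype=float)
            cols.append(vals[idx])
        else:
            raise ConfigError(f"unknown covariate distribution {kind!r}")
    if not cols:
        return np.empty((spec.n_subjects, 0))
    return np.column_stack(cols)


def _rate_table(table: CoefficientTable, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    """Precompute per-group linear-predictor contributions for one subject.

    Returns (base[node, dir], parent_contrib[node, dir, parent_slot], parent index lists)
    where contributions are on the log scale; frozen remission is handled by
    the caller.
    """
    structure = table.structure
    n = len(structure.nodes)
    zt = np.concatenate(([1.0], table.standardize_z(z)))
    dirs = (GAIN, LOSS)
    base = np.full((n, 2), -np.inf)
    max_p = max((len(structure.parents[x]) for x in structure.nodes), default=0)
    pc = np.zeros((n, 2, max_p))
    pidx: list[list[int]] = []
    nidx = {x: i for i, x in enumerate(structure.nodes)}
    for i, node in enumerate(structure.nodes):
        pidx.append([nidx[p] for p in structure.parents[node]])
        for di, d in enumerate(dirs):
            if d == LOSS and table.frozen_loss_rate is not None:
                continue
            base[i, di] = float(zt @ table.groups[(node, d, BASELINE)])
            for k, p in enumerate(structure.parents[node]):
                pc[i, di, k] = float(zt @ table.groups[(node, d, p)])
    return base, pc, pidx


def sample_trajectory(
    structure: NetworkStructure,
    truth: CoefficientTable,
    z: np.ndarray,
    horizon: float,
    initial_state: np.ndarray,
    rng: np.random.Generator,
) -> list[Record]:
    """Sample one subject's record list by competing exponentials.

    The final record is always censored at the horizon; if every rate is zero
    the trajectory is the single censored record of the full horizon.
    """
    if horizon <= 0:
        raise ConfigError("horizon must be positive")
    n = len(structure.nodes)
    state = np.asarray(initial_state, dtype=np.int8).copy()
    if state.shape != (n,):
        raise SchemaError("initial state length mismatch")
    base, pc, pidx = _rate_table(truth, np.asarray(z, dtype=float))
    frozen = truth.frozen_loss_rate

    records: list[Record] = []
    t = 0.0
    while True:
        rates = np.empty(n)
        for i in range(n):
            di = 0 if state[i] == 0 else 1
            if di == 1 and frozen is not None:
                rates[i] = frozen
                continue
            eta = base[i, di]
            for k, j in enumerate(pidx[i]):
                if state[j] == 1:
                    eta += pc[i, di, k]
            rates[i] = np.exp(eta)
        total = rates.sum()
        if total <= 0.0:
            records.append(Record(state.copy(), horizon - t, None, None, censored=True))
            return records
        dt = rng.exponential(1.0 / total)
        if t + dt >= horizon:
            records.append(Record(state.copy(), horizon - t, None, None, censored=True))
            return records
        u = rng.random() * total
        node_i = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        node_i = min(node_i, n - 1)
        new_state = 1 - int(state[node_i])
        records.append(Record(state.copy(), dt, structure.nodes[node_i], new_state))
        state[node_i] = new_state
        t += dt


def generate_cohort(spec: SimulationSpec) -> TrajectoryDataset:
    """Draw a full cohort: covariates first, then one trajectory per subject."""
    rng = np.random.default_rng(spec.seed)
    Z = generate_covariates(spec, rng)
    n_nodes = len(spec.structure.nodes)

    if spec.initial_state_dist is None:
        draw_initial = lambda: np.zeros(n_nodes, dtype=np.int8)
    else:
        states = [np.asarray(s, dtype=np.int8) for s in spec.initial_state_dist]
        probs = np.asarray(list(spec.initial_state_dist.values()), dtype=float)
        draw_initial = lambda: states[rng.choice(len(states), p=probs)]

    subjects = []
    for i in range(spec.n_subjects):
        init = draw_initial()
        recs = sample_trajectory(spec.structure, spec.truth, Z[i], spec.horizon, init, rng)
        subjects.append(Subject(id=f"s{i:06d}", z=Z[i], records=recs))
    ds = TrajectoryDataset(spec.structure.nodes, spec.covariate_names, subjects)
    ds.validate()
    return ds


def discretize_annual(dataset: TrajectoryDataset, n_years: int) -> np.ndarray:
    """Binary condition-by-year coding: 1 in year y iff the condition is in
    state 1 at any point during (y-1, y].

    Returns an array of shape (n_subjects, n_years, n_nodes) in dataset order.
    A condition acquired and remitted within the same year is still coded 1
    for that year, matching annual diagnosis coding.
    """
    n_nodes = len(dataset.nodes)
    out = np.zeros((len(dataset.subjects), n_years, n_nodes), dtype=np.int8)
    for si, subject in enumerate(dataset.subjects):
        t = 0.0
        for rec in subject.records:
            t0, t1 = t, t + rec.duration
            for ni in range(n_nodes):
                if rec.states[ni] == 1:
                    # year y (interval (y-1, y]) overlaps [t0, t1) iff t0 <= y < t1 + 1
                    y_first = max(1, int(np.ceil(t0 - 1e-12)))
                    y_last = min(n_years, int(np.ceil(t1 - 1e-12)))
                    if y_first <= y_last:
                        out[si, y_first - 1 : y_last, ni] = 1
            t = t1
    return out
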