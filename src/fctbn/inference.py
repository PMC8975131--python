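"""Exact inference on a fitted FCTBN for a given risk profile.

The node-wise conditional intensity matrices are amalgamated into the joint
intensity matrix over all 2^n binary configurations (nonzero rates only
between configurations differing in exactly one node), and distributions are
propagated through the matrix exponential, p(t) = p0 · exp(Qt).  Risk
trajectories, multi-year predictions with the ever-in-year convention, and a
rank-based AUC evaluation harness are built on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .ctmp import IntensityMatrix, enumerate_joint_states
from .errors import DataError, SchemaError
from .model import BASELINE, GAIN, LOSS, CoefficientTable, TrajectoryDataset, _augment
from .simulate import discretize_annual

__all__ = [
    "JointIntensity",
    "amalgamate",
    "propagate",
    "risk_trajectory",
    "predict_next_years",
    "auc_eval",
    "evaluate_auc_by_year",
]


@dataclass
class JointIntensity:
    """Joint intensity matrix over all binary configurations for one subject."""

    states: list[tuple]       # joint configurations, node order = structure order
    matrix: IntensityMatrix

    @property
    def Q(self) -> np.ndarray:
        return self.matrix.rates


def _group_contributions(table: CoefficientTable, z) -> dict:
    """Scalar log-rate contribution of every coefficient group at covariates z."""
    zt = _augment(table.standardize_z(np.asarray(z, dtype=float)))
    return {key: float(zt @ vec) for key, vec in table.groups.items()}


def amalgamate(table: CoefficientTable, z, cap: int = 4096) -> JointIntensity:
    """Build the joint intensity matrix from the node-wise conditional rates.

    The rate from joint state s to s' differing in node x alone is x's
    transition rate under s's parent configuration; states differing in more
    than one node have rate zero (the CTBN single-transition property).
    """
    structure = table.structure
    nodes = structure.nodes
    n = len(nodes)
    states = enumerate_joint_states([(x, 2) for x in nodes], cap=cap)
    index = {s: i for i, s in enumerate(states)}
    contrib = _group_contributions(table, z)
    pidx = [[nodes.index(p) for p in structure.parents[x]] for x in nodes]

    Q = np.zeros((len(states), len(states)))
    for s in states:
        i = index[s]
        for xi in range(n):
            direction = GAIN if s[xi] == 0 else LOSS
            if direction == LOSS and table.frozen_loss_rate is not None:
                rate = float(table.frozen_loss_rate)
            else:
                eta = contrib[(nodes[xi], direction, BASELINE)]
                for k, pj in enumerate(pidx[xi]):
                    if s[pj] == 1:
                        eta += contrib[(nodes[xi], direction, structure.parents[nodes[xi]][k])]
                rate = float(np.exp(eta))
            s2 = list(s)
            s2[xi] = 1 - s[xi]
            j = index[tuple(s2)]
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))  # diagonal balances each row
    return JointIntensity(states, IntensityMatrix(states, Q))


def propagate(p0: np.ndarray, joint: JointIntensity | np.ndarray, t: float,
              k: float = 0.0) -> np.ndarray:
    """Distribution at time t from initial distribution p0: p0 · exp(Q·(t−k))."""
    Q = joint.Q if isinstance(joint, JointIntensity) else np.asarray(joint, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (Q.shape[0],):
        raise SchemaError(f"p0 length {p0.shape} does not match {Q.shape[0]} states")
    if abs(p0.sum() - 1.0) > 1e-8 or np.any(p0 < -1e-12):
        raise DataError("p0 is not a probability vector")
    if t < k or k < 0:
        raise ValueError(f"need t >= k >= 0, got t={t}, k={k}")
    if t == k:
        return p0.copy()
    return p0 @ scipy.linalg.expm(Q * (t - k))


def _delta(joint: JointIntensity, baseline_state) -> np.ndarray:
    key = tuple(int(v) for v in baseline_state)
    try:
        i = joint.states.index(key)
    except ValueError:
        raise SchemaError(f"baseline state {key} is not a joint configuration") from None
    p0 = np.zeros(len(joint.states))
    p0[i] = 1.0
    return p0


def risk_trajectory(
    table: CoefficientTable,
    z,
    baseline_state,
    condition: str,
    time_grid,
    cap: int = 4096,
) -> np.ndarray:
    """P(condition = 1 at t | baseline configuration at 0, covariates z).

    Evaluated on an ascending time grid by stepping the joint distribution
    with cached matrix exponentials; at t=0 this is the baseline indicator.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0) or (grid.size and grid[0] < 0):
        raise ValueError("time grid must be ascending and nonnegative")
    joint = amalgamate(table, z, cap=cap)
    ci = table.structure.node_index(condition)
    mask = np.array([s[ci] == 1 for s in joint.states])
    p = _delta(joint, baseline_state)
    out = np.empty(grid.size)
    prev_t = 0.0
    cache: dict[float, np.ndarray] = {}
    for i, t in enumerate(grid):
        dt = t - prev_t
        if dt > 0:
            if dt not in cache:
                cache[dt] = scipy.linalg.expm(joint.Q * dt)
            p = p @ cache[dt]
        out[i] = float(p[mask].sum())
        prev_t = t
    return out


def _absorbing_in_condition(joint: JointIntensity, ci: int) -> np.ndarray:
    """Copy of Q with the transitions that leave {condition=1} removed.

    Zeroing exactly those rates makes the condition-present set absorbing, so
    mass on it after propagation equals the probability of having ever
    entered it — the ever-in-year convention.
    """
    Q = joint.Q.copy()
    for i, s in enumerate(joint.states):
        if s[ci] == 1:
            s2 = list(s)
            s2[ci] = 0
            j = joint.states.index(tuple(s2))
            Q[i, i] += Q[i, j]
            Q[i, j] = 0.0
    return Q


def predict_next_years(
    table: CoefficientTable,
    z,
    baseline_state,
    years: int,
    cap: int = 4096,
) -> np.ndarray:
    """Per-year, per-condition probability of being present during each year.

    Year y's probability for condition c is the chance of ever being in state
    1 during (y-1, y], computed by propagating the baseline distribution with
    the true generator to year y-1 and then for one year with c's remission
    transitions removed.  Returns an array (years, n_conditions).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    joint = amalgamate(table, z, cap=cap)
    n = len(table.structure.nodes)
    P1 = scipy.linalg.expm(joint.Q)
    Pc = [scipy.linalg.expm(_absorbing_in_condition(joint, ci)) for ci in range(n)]
    masks = [np.array([s[ci] == 1 for s in joint.states]) for ci in range(n)]
    out = np.empty((years, n))
    p = _delta(joint, baseline_state)
    for y in range(years):
        for ci in range(n):
            out[y, ci] = float((p @ Pc[ci])[masks[ci]].sum())
        p = p @ P1
    return out


def auc_eval(predicted, observed) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute 1/2.

    Raises :class:`DataError` when all outcomes belong to one class.
    """
    scores = np.asarray(predicted, dtype=float)
    labels = np.asarray(observed)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise SchemaError("scores and outcomes must be matching 1-d arrays")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise DataError("AUC is undefined with a single outcome class")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate_auc_by_year(
    table: CoefficientTable,
    dataset: TrajectoryDataset,
    years: int,
    cap: int = 4096,
) -> pd.DataFrame:
    """AUC of the model's multi-year risks against annually coded outcomes.

    For every subject the baseline is the first record's configuration and
    predictions are propagated from it; observed outcomes use the annual
    ever-in-year coding.  Conditions/years with a single outcome class get
    NaN.  Returns a DataFrame indexed by year with one column per condition.
    """
    observed = discretize_annual(dataset, years)
    preds = np.empty_like(observed, dtype=float)
    for si, subject in enumerate(dataset.subjects):
        baseline = subject.records[0].states
        preds[si] = predict_next_years(table, subject.z, baseline, years, cap=cap)
    out = np.full((years, len(dataset.nodes)), np.nan)
    for y in range(years):
        for ci in range(len(dataset.nodes)):
            labels = observed[:, y, ci]
            if 0 < labels.sum() < labels.size:
                out[y, ci] = auc_eval(preds[:, y, ci], labels)
    return pd.DataFrame(out, index=[f"year {y + 1}" for y in range(years)],
                        columns=list(dataset.nodes))
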