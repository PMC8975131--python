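"""The functional CTBN: covariate-dependent conditional intensities.

Each binary condition node x evolves as a conditional Markov process whose
transition rates are log-linear in a subject's covariate vector z, with
multiplicative contributions from currently-active (state-1) parents:

    log q_{x, i->j | u, z} = z̃·β_baseline + Σ_{parents p active in u} z̃·β_p,

where z̃ = (1, z).  Zeroing a whole parent group therefore removes the edge
p -> x without touching the node's base rate, which is what the group-lasso
learner exploits for structure learning.

The event-history log-likelihood of a trajectory dataset decomposes over
sojourns: during a sojourn of length t_d every node accrues exposure
q·t_d at its current (state, parent-config), and the transitioning node of a
non-censored sojourn contributes log q.  Both the likelihood and its analytic
gradient are evaluated through the compiled design in :mod:`fctbn.design`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ctmp import ConditionalIntensityMatrix, IntensityMatrix
from .errors import DataError, SchemaError

__all__ = [
    "GAIN",
    "LOSS",
    "BASELINE",
    "NetworkStructure",
    "CoefficientTable",
    "Record",
    "Subject",
    "TrajectoryDataset",
    "conditional_intensity",
    "build_subject_cims",
    "neg_log_likelihood",
    "nll_gradient",
    "parameter_count",
]

GAIN = "01"   # acquisition: state 0 -> 1
LOSS = "10"   # remission:   state 1 -> 0
BASELINE = "baseline"
DIRECTIONS = (GAIN, LOSS)


@dataclass(frozen=True)
class NetworkStructure:
    """Ordered condition nodes and per-node candidate parent sets.

    Cycles across nodes are permitted (the CTBN factorization does not require
    acyclicity); a node is never its own parent.  Parent-set size is capped to
    keep parameter growth linear under the multiplicative assumption.
    """

    nodes: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]
    max_parents: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if len(set(self.nodes)) != len(self.nodes):
            raise SchemaError("duplicate node names")
        if BASELINE in self.nodes:
            raise SchemaError(f"node name {BASELINE!r} is reserved")
        parents = {n: tuple(self.parents.get(n, ())) for n in self.nodes}
        for child, ps in parents.items():
            for p in ps:
                if p == child:
                    raise SchemaError(f"node {child!r} cannot be its own parent")
                if p not in self.nodes:
                    raise SchemaError(f"unknown parent {p!r} of {child!r}")
            if len(set(ps)) != len(ps):
                raise SchemaError(f"duplicate parents for {child!r}")
            if len(ps) > self.max_parents:
                raise SchemaError(
                    f"{child!r} has {len(ps)} parents, cap is {self.max_parents}"
                )
        object.__setattr__(self, "parents", parents)

    @classmethod
    def fully_connected(cls, nodes, max_parents: int | None = None) -> "NetworkStructure":
        """Every node is a candidate parent of every other node."""
        nodes = tuple(nodes)
        if max_parents is None:
            max_parents = max(len(nodes) - 1, 1)
        parents = {n: tuple(m for m in nodes if m != n) for n in nodes}
        return cls(nodes, parents, max_parents=max_parents)

    def node_index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise SchemaError(f"unknown node {node!r}") from None

    def n_edges_candidate(self) -> int:
        return sum(len(ps) for ps in self.parents.values())


def _augment(z: np.ndarray) -> np.ndarray:
    return np.concatenate(([1.0], np.asarray(z, dtype=float)))


def _group_to_std(vec: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Re-express an original-scale group vector on the standardized-z scale."""
    out = vec.copy()
    out[1:] = vec[1:] * scale
    out[0] = vec[0] + float(vec[1:] @ mean)
    return out


def _group_to_original(vec: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    out = vec.copy()
    out[1:] = vec[1:] / scale
    out[0] = vec[0] - float((vec[1:] / scale) @ mean)
    return out


@dataclass
class CoefficientTable:
    """Poisson-regression coefficients grouped by (child, direction, source).

    ``source`` is either ``"baseline"`` (the unpenalized intercept-rate group)
    or a parent node name (a penalized edge group).  Each group holds a vector
    of length m+1: intercept followed by one slope per covariate.

    If ``scaler`` is set, the coefficients apply to standardized covariates
    ``(z - mean) / scale``; :meth:`to_original_scale` converts back.  If
    ``frozen_loss_rate`` is not None the 1->0 direction carries no groups and
    every remission rate is that constant (progressive-disease mode).
    """

    structure: NetworkStructure
    covariates: tuple[str, ...]
    groups: dict[tuple[str, str, str], np.ndarray]
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    frozen_loss_rate: float | None = None

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        m1 = len(self.covariates) + 1
        for key, vec in self.groups.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (m1,):
                raise SchemaError(f"group {key} has length {vec.shape}, expected ({m1},)")
            if not np.all(np.isfinite(vec)):
                raise SchemaError(f"group {key} contains non-finite entries")
            self.groups[key] = vec
        if self.scaler is not None:
            mean, scale = self.scaler
            self.scaler = (np.asarray(mean, dtype=float), np.asarray(scale, dtype=float))

    # -- construction ------------------------------------------------------

    @classmethod
    def zeros(
        cls,
        structure: NetworkStructure,
        covariates,
        *,
        remission: bool = True,
        frozen_loss_rate: float | None = None,
        scaler=None,
    ) -> "CoefficientTable":
        covariates = tuple(covariates)
        m1 = len(covariates) + 1
        if not remission and frozen_loss_rate is None:
            frozen_loss_rate = 0.0
        groups: dict[tuple[str, str, str], np.ndarray] = {}
        directions = (GAIN,) if frozen_loss_rate is not None else (GAIN, LOSS)
        for node in structure.nodes:
            for d in directions:
                groups[(node, d, BASELINE)] = np.zeros(m1)
                for p in structure.parents[node]:
                    groups[(node, d, p)] = np.zeros(m1)
        return cls(structure, covariates, groups, scaler=scaler, frozen_loss_rate=frozen_loss_rate)

    def copy(self) -> "CoefficientTable":
        return CoefficientTable(
            self.structure,
            self.covariates,
            {k: v.copy() for k, v in self.groups.items()},
            scaler=self.scaler,
            frozen_loss_rate=self.frozen_loss_rate,
        )

    # -- introspection -----------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.covariates)

    @property
    def directions(self) -> tuple[str, ...]:
        return (GAIN,) if self.frozen_loss_rate is not None else (GAIN, LOSS)

    def penalized_keys(self) -> list[tuple[str, str, str]]:
        return [k for k in self.groups if k[2] != BASELINE]

    def penalty_groups(self) -> dict[tuple[str, str], list[tuple[str, str, str]]]:
        """Edge groups (child, parent) -> their per-direction coefficient keys."""
        out: dict[tuple[str, str], list] = {}
        for child, d, src in self.groups:
            if src == BASELINE:
                continue
            out.setdefault((child, src), []).append((child, d, src))
        return out

    def group_norm(self, child: str, parent: str) -> float:
        vecs = [self.groups[k] for k in self.groups if k[0] == child and k[2] == parent]
        if not vecs:
            raise SchemaError(f"no group for edge {parent!r}->{child!r}")
        return float(np.sqrt(sum(float(v @ v) for v in vecs)))

    def active_edges(self) -> set[tuple[str, str]]:
        """(parent, child) pairs with any nonzero coefficient in either direction."""
        out = set()
        for (child, _d, src), vec in self.groups.items():
            if src != BASELINE and np.any(vec != 0.0):
                out.add((src, child))
        return out

    def penalized_values(self) -> np.ndarray:
        """All penalized coefficients pooled into one vector (for the GMM)."""
        keys = sorted(self.penalized_keys())
        if not keys:
            return np.empty(0)
        return np.concatenate([self.groups[k] for k in keys])

    # -- scaling -----------------------------------------------------------

    def standardize_z(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.shape != (self.m,):
            raise SchemaError(f"covariate vector has shape {z.shape}, expected ({self.m},)")
        if self.scaler is None:
            return z
        mean, scale = self.scaler
        return (z - mean) / scale

    def to_original_scale(self) -> "CoefficientTable":
        """Equivalent table whose coefficients apply to raw covariates."""
        if self.scaler is None:
            return self.copy()
        mean, scale = self.scaler
        groups = {k: _group_to_original(v, mean, scale) for k, v in self.groups.items()}
        return CoefficientTable(
            self.structure, self.covariates, groups, scaler=None,
            frozen_loss_rate=self.frozen_loss_rate,
        )

    # -- rates -------------------------------------------------------------

    def linear_predictor(self, node: str, direction: str, active_parents, z) -> float:
        if direction not in DIRECTIONS:
            raise SchemaError(f"unknown direction {direction!r}")
        parents = self.structure.parents[self.structure.nodes[self.structure.node_index(node)]]
        for p in active_parents:
            if p not in parents:
                raise SchemaError(f"{p!r} is not a candidate parent of {node!r}")
        zt = _augment(self.standardize_z(np.asarray(z, dtype=float)))
        eta = float(zt @ self.groups[(node, direction, BASELINE)])
        for p in active_parents:
            eta += float(zt @ self.groups[(node, direction, p)])
        return eta

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.structure.nodes),
            "parents": {n: list(ps) for n, ps in self.structure.parents.items()},
            "max_parents": self.structure.max_parents,
            "covariates": list(self.covariates),
            "frozen_loss_rate": self.frozen_loss_rate,
            "scaler": None if self.scaler is None else
                      {"mean": self.scaler[0].tolist(), "scale": self.scaler[1].tolist()},
            "groups": {f"{c}|{d}|{s}": v.tolist() for (c, d, s), v in sorted(self.groups.items())},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CoefficientTable":
        structure = NetworkStructure(
            tuple(doc["nodes"]),
            {n: tuple(ps) for n, ps in doc["parents"].items()},
            max_parents=doc.get("max_parents", 4),
        )
        scaler = doc.get("scaler")
        if scaler is not None:
            scaler = (np.asarray(scaler["mean"]), np.asarray(scaler["scale"]))
        groups = {}
        for key, vec in doc["groups"].items():
            c, d, s = key.split("|")
            groups[(c, d, s)] = np.asarray(vec, dtype=float)
        return cls(structure, tuple(doc["covariates"]), groups,
                   scaler=scaler, frozen_loss_rate=doc.get("frozen_loss_rate"))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "CoefficientTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def conditional_intensity(table: CoefficientTable, node: str, direction: str,
                          active_parents, z) -> float:
    """Transition rate of ``node`` in ``direction`` given active parents and z.

    Multiplicative parent composition: the rate is the baseline rate times
    exp(z̃·β_p) for every active parent p.  With a frozen remission rate the
    1->0 direction returns that constant regardless of parents.
    """
    if direction == LOSS and table.frozen_loss_rate is not None:
        return float(table.frozen_loss_rate)
    return float(np.exp(table.linear_predictor(node, direction, active_parents, z)))


def rate_from_state(table: CoefficientTable, node: str, states: np.ndarray, z) -> float:
    """Active exit rate of ``node`` given the full joint state vector."""
    idx = table.structure.node_index(node)
    direction = GAIN if states[idx] == 0 else LOSS
    nidx = {n: i for i, n in enumerate(table.structure.nodes)}
    active = [p for p in table.structure.parents[node] if states[nidx[p]] == 1]
    return conditional_intensity(table, node, direction, active, z)


def build_subject_cims(table: CoefficientTable, z, structure: NetworkStructure | None = None):
    """Per-node conditional intensity matrices for one subject's covariates.

    Returns a mapping node -> list of :class:`ConditionalIntensityMatrix`,
    one per complete parent configuration (2^|parents| for binary parents).
    """
    structure = structure or table.structure
    out: dict[str, list[ConditionalIntensityMatrix]] = {}
    for node in structure.nodes:
        parents = structure.parents[node]
        cims = []
        for combo in itertools.product((0, 1), repeat=len(parents)):
            active = [p for p, s in zip(parents, combo) if s == 1]
            q01 = conditional_intensity(table, node, GAIN, active, z)
            q10 = conditional_intensity(table, node, LOSS, active, z)
            mat = IntensityMatrix([0, 1], np.array([[-q01, q01], [q10, -q10]]))
            cims.append(ConditionalIntensityMatrix(node, tuple(zip(parents, combo)), mat))
        out[node] = cims
    return out


# --------------------------------------------------------------------------
# trajectory data


@dataclass
class Record:
    """One observed sojourn: full state at interval start, duration, event.

    ``node``/``new_state`` are None on censored records.
    """

    states: np.ndarray
    duration: float
    node: str | None
    new_state: int | None
    censored: bool = False

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.duration <= 0:
            raise DataError(f"sojourn duration must be positive, got {self.duration}")
        if self.censored:
            if self.node is not None or self.new_state is not None:
                raise DataError("censored record must not carry an event")
        else:
            if self.node is None or self.new_state not in (0, 1):
                raise DataError("non-censored record needs a transitioning node and new state")


@dataclass
class Subject:
    id: str
    z: np.ndarray
    records: list[Record] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)


@dataclass
class TrajectoryDataset:
    """Subjects' covariates plus their time-ordered sojourn records."""

    nodes: tuple[str, ...]
    covariates: tuple[str, ...]
    subjects: list[Subject] = field(default_factory=list)
    time_unit: str = "years"

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.covariates = tuple(self.covariates)

    @property
    def n_records(self) -> int:
        return sum(len(s.records) for s in self.subjects)

    def validate(self) -> None:
        nidx = {n: i for i, n in enumerate(self.nodes)}
        for subject in self.subjects:
            if subject.z.shape != (len(self.covariates),):
                raise SchemaError(
                    f"subject {subject.id}: covariate vector length "
                    f"{subject.z.shape} != {len(self.covariates)}"
                )
            prev: Record | None = None
            for k, rec in enumerate(subject.records):
                if rec.states.shape != (len(self.nodes),):
                    raise SchemaError(f"subject {subject.id}: state vector length mismatch")
                if rec.censored and k != len(subject.records) - 1:
                    raise DataError(f"subject {subject.id}: censored record is not last")
                if not rec.censored:
                    if rec.node not in nidx:
                        raise SchemaError(f"subject {subject.id}: unknown node {rec.node!r}")
                    if rec.new_state == rec.states[nidx[rec.node]]:
                        raise DataError(
                            f"subject {subject.id}: event does not change node {rec.node!r}"
                        )
                if prev is not None:
                    expected = prev.states.copy()
                    expected[nidx[prev.node]] = prev.new_state
                    if not np.array_equal(expected, rec.states):
                        raise DataError(
                            f"subject {subject.id}: record {k} state vector inconsistent "
                            "with previous transition"
                        )
                prev = rec

    def subset(self, indices) -> "TrajectoryDataset":
        return TrajectoryDataset(
            self.nodes, self.covariates, [self.subjects[i] for i in indices], self.time_unit
        )

    def concat(self, other: "TrajectoryDataset") -> "TrajectoryDataset":
        if other.nodes != self.nodes or other.covariates != self.covariates:
            raise SchemaError("datasets have different schemas")
        return TrajectoryDataset(
            self.nodes, self.covariates, list(self.subjects) + list(other.subjects),
            self.time_unit,
        )


# --------------------------------------------------------------------------
# likelihood


def neg_log_likelihood(table: CoefficientTable, dataset: TrajectoryDataset,
                       structure: NetworkStructure | None = None) -> float:
    """Negative event-history log-likelihood of the dataset under the table."""
    from .design import compile_design

    structure = structure or table.structure
    design = compile_design(structure, dataset, scaler=table.scaler,
                            frozen_loss_rate=table.frozen_loss_rate,
                            covariates=table.covariates)
    return float(design.value(design.vector_from_table(table)))


def nll_gradient(table: CoefficientTable, dataset: TrajectoryDataset,
                 structure: NetworkStructure | None = None) -> CoefficientTable:
    """Analytic gradient of the negative log-likelihood, table-shaped."""
    from .design import compile_design

    structure = structure or table.structure
    design = compile_design(structure, dataset, scaler=table.scaler,
                            frozen_loss_rate=table.frozen_loss_rate,
                            covariates=table.covariates)
    _, grad = design.value_grad(design.vector_from_table(table))
    return design.table_from_vector(grad)


def parameter_count(structure: NetworkStructure, m: int, mode: str = "multiplicative") -> int:
    """Maximum coefficient count of the model.

    ``full`` conditions on every parent configuration (exponential in the
    largest parent set); ``multiplicative`` uses one additive group per parent
    (linear).  The factor 2 counts the two transition directions of a binary
    node.
    """
    max_p = max((len(ps) for ps in structure.parents.values()), default=0)
    n = len(structure.nodes)
    if mode == "full":
        return n * (m + 1) * 2 * 2**max_p
    if mode == "multiplicative":
        return n * (m + 1) * 2 * (max_p + 1)
    raise SchemaError(f"unknown mode {mode!r}")
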