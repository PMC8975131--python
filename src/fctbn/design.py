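"""Compiled design matrices for the FCTBN event-history likelihood.

The log-likelihood factorizes over (child node, transition direction) blocks:
each block is an independent Poisson regression with per-row exposure t_d and
a binary event indicator.  A block's rows are the sojourn records during which
the child sits in the direction's source state; its columns are the baseline
group followed by one group per candidate parent, each group being the
augmented covariate vector z̃ = (1, z) masked by whether that parent is active
(state 1) at interval start.

Compiling once and evaluating the likelihood/gradient as matrix products is
what makes FISTA and cross-validation affordable at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SchemaError
from .model import (
    BASELINE,
    GAIN,
    LOSS,
    CoefficientTable,
    NetworkStructure,
    TrajectoryDataset,
    _group_to_std,
)

__all__ = ["Block", "CompiledDesign", "compile_design"]


@dataclass
class Block:
    child: str
    direction: str
    X: np.ndarray          # rows x (n_groups * (m+1))
    y: np.ndarray          # 1.0 where this row's record is this child's event
    t: np.ndarray          # sojourn durations (exposure)
    cols: list             # group keys in column-block order


@dataclass
class CompiledDesign:
    structure: NetworkStructure
    covariates: tuple[str, ...]
    scaler: tuple[np.ndarray, np.ndarray] | None
    frozen_loss_rate: float | None
    blocks: list[Block]
    slices: dict = field(default_factory=dict)   # group key -> index array
    n_params: int = 0
    n_records: int = 0
    constant: float = 0.0                         # frozen-direction contribution

    # -- vector packing ----------------------------------------------------

    def vector_from_table(self, table: CoefficientTable) -> np.ndarray:
        x = np.zeros(self.n_params)
        convert = table.scaler is None and self.scaler is not None
        for key, idx in self.slices.items():
            vec = table.groups[key]
            if convert:
                vec = _group_to_std(vec, *self.scaler)
            elif table.scaler is not None and self.scaler is None:
                raise SchemaError("table is standardized but design is not")
            x[idx] = vec
        return x

    def table_from_vector(self, x: np.ndarray) -> CoefficientTable:
        groups = {key: np.asarray(x[idx], dtype=float).copy() for key, idx in self.slices.items()}
        return CoefficientTable(
            self.structure, self.covariates, groups,
            scaler=self.scaler, frozen_loss_rate=self.frozen_loss_rate,
        )

    def penalty_group_indices(self) -> dict[tuple[str, str], np.ndarray]:
        """Edge group (child, parent) -> packed indices across both directions."""
        out: dict[tuple[str, str], list] = {}
        for (child, _d, src), idx in self.slices.items():
            if src == BASELINE:
                continue
            out.setdefault((child, src), []).append(idx)
        return {k: np.concatenate(v) for k, v in out.items()}

    # -- likelihood --------------------------------------------------------

    def value(self, x: np.ndarray) -> float:
        nll = self.constant
        with np.errstate(over="ignore"):
            for b in self.blocks:
                eta = b.X @ x[b.col_index]
                nll += float((np.exp(eta) * b.t).sum() - b.y @ eta)
        return nll

    def value_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        nll = self.constant
        grad = np.zeros(self.n_params)
        with np.errstate(over="ignore"):
            for b in self.blocks:
                eta = b.X @ x[b.col_index]
                lam = np.exp(eta) * b.t
                nll += float(lam.sum() - b.y @ eta)
                grad[b.col_index] = b.X.T @ (lam - b.y)
        return nll, grad

    def block_value_grad(self, block: Block, beta: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore"):
            eta = block.X @ beta
            lam = np.exp(eta) * block.t
            f = float(lam.sum() - block.y @ eta)
            g = block.X.T @ (lam - block.y)
        return f, g

    def block_hessian(self, block: Block, beta: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            w = np.exp(block.X @ beta) * block.t
        return block.X.T @ (block.X * w[:, None])


def compile_design(
    structure: NetworkStructure,
    dataset: TrajectoryDataset,
    *,
    standardize: bool = False,
    scaler=None,
    frozen_loss_rate: float | None = None,
    covariates=None,
) -> CompiledDesign:
    """Flatten a trajectory dataset into per-(child, direction) design blocks.

    ``scaler`` overrides ``standardize``: pass the (mean, scale) of a training
    fold to evaluate held-out data on the same coordinates.  When
    ``frozen_loss_rate`` is set the 1->0 direction gets no blocks; its
    (constant-rate) likelihood contribution is folded into ``constant``.
    """
    if covariates is not None and tuple(covariates) != dataset.covariates:
        raise SchemaError("table and dataset declare different covariates")
    nodes = structure.nodes
    if tuple(dataset.nodes) != tuple(nodes):
        # allow dataset with same node set in same order only
        raise SchemaError("structure and dataset node lists differ")
    m = len(dataset.covariates)
    n_sub = len(dataset.subjects)

    Z = np.array([s.z for s in dataset.subjects], dtype=float).reshape(n_sub, m)
    if scaler is not None:
        mean, scale = (np.asarray(scaler[0], dtype=float), np.asarray(scaler[1], dtype=float))
    elif standardize and m > 0 and n_sub > 1:
        mean = Z.mean(axis=0)
        scale = Z.std(axis=0)
        scale[scale < 1e-12] = 1.0
    else:
        mean = scale = None
    if mean is not None:
        Z = (Z - mean) / scale
    Zt = np.concatenate([np.ones((n_sub, 1)), Z], axis=1)  # subjects x (m+1)

    # flatten records
    R = dataset.n_records
    states = np.empty((R, len(nodes)), dtype=np.int8)
    dur = np.empty(R)
    ev = np.full(R, -1, dtype=np.int64)
    subj = np.empty(R, dtype=np.int64)
    nidx = {n: i for i, n in enumerate(nodes)}
    r = 0
    for si, subject in enumerate(dataset.subjects):
        for rec in subject.records:
            states[r] = rec.states
            if rec.duration <= 0:
                raise DataError(f"subject {subject.id}: non-positive duration")
            dur[r] = rec.duration
            if not rec.censored:
                ev[r] = nidx[rec.node]
            subj[r] = si
            r += 1

    frozen_const = 0.0
    if frozen_loss_rate is not None:
        # constant exposure terms for the frozen 1->0 direction
        if frozen_loss_rate < 0:
            raise SchemaError("frozen remission rate must be >= 0")
        for i, node in enumerate(nodes):
            mask = states[:, i] == 1
            n_loss_events = int(((ev == i) & mask).sum())
            if frozen_loss_rate == 0.0:
                if n_loss_events:
                    raise DataError(
                        f"observed 1->0 transition of {node!r} but remission rate is frozen at 0"
                    )
            else:
                frozen_const += float(frozen_loss_rate * dur[mask].sum())
                frozen_const -= n_loss_events * float(np.log(frozen_loss_rate))

    directions = (GAIN,) if frozen_loss_rate is not None else (GAIN, LOSS)
    blocks: list[Block] = []
    slices: dict = {}
    offset = 0
    for i, node in enumerate(nodes):
        parents = structure.parents[node]
        for d in directions:
            src = 0 if d == GAIN else 1
            mask = states[:, i] == src
            rows = np.nonzero(mask)[0]
            base = Zt[subj[rows]]
            parts = [base]
            for p in parents:
                act = (states[rows, nidx[p]] == 1).astype(float)
                parts.append(base * act[:, None])
            X = np.concatenate(parts, axis=1) if parts else np.empty((len(rows), 0))
            y = (ev[rows] == i).astype(float)
            block = Block(node, d, X, y, dur[rows], [(node, d, BASELINE)] +
                          [(node, d, p) for p in parents])
            blocks.append(block)
            for key in block.cols:
                slices[key] = np.arange(offset, offset + m + 1)
                offset += m + 1

    design = CompiledDesign(
        structure=structure,
        covariates=dataset.covariates,
        scaler=None if mean is None else (mean, scale),
        frozen_loss_rate=frozen_loss_rate,
        blocks=blocks,
        slices=slices,
        n_params=offset,
        n_records=R,
        constant=frozen_const,
    )
    for b in blocks:
        b.col_index = np.concatenate([design.slices[k] for k in b.cols]) if b.cols else np.empty(0, int)
    return design
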