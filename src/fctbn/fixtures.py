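"""Versioned synthetic generating models used throughout tests and examples.

The default truth is a 5-condition network (traumatic brain injury, back
pain, post-traumatic stress disorder, depression, substance abuse) with one
standardized "age score" covariate and six directed edges — a qualitatively
realistic multimorbidity topology with acquisition hazard ratios of 2-3 per
active parent.  Baseline acquisition rates are 0.06-0.15 per year and the
reversible variant adds a flat remission rate of ~0.2 per year; the
progressive variant freezes remission at zero.  These are synthetic stand-ins
for (non-deposited) EHR cohorts, not estimates from real data.
"""

from __future__ import annotations

import numpy as np

from .model import BASELINE, GAIN, LOSS, CoefficientTable, NetworkStructure
from .simulate import SimulationSpec

__all__ = [
    "NODES",
    "TRUE_EDGES",
    "default_structure",
    "candidate_structure",
    "default_truth",
    "default_sim_spec",
    "small_truth",
    "small_sim_spec",
]

NODES = ("TBI", "BaPa", "PTSD", "Depr", "SuAb")

#: (parent, child) pairs of the generating model
TRUE_EDGES = (
    ("TBI", "PTSD"),
    ("TBI", "SuAb"),
    ("PTSD", "Depr"),
    ("PTSD", "SuAb"),
    ("Depr", "SuAb"),
    ("BaPa", "Depr"),
)

# (intercept = log base rate per year, slope on the age score)
_BASE_GAIN = {
    "TBI": (-2.8, 0.10),
    "BaPa": (-1.9, 0.20),
    "PTSD": (-2.5, 0.25),
    "Depr": (-2.3, 0.30),
    "SuAb": (-2.6, 0.20),
}

# (log hazard-ratio intercept, slope) of each parent's multiplicative effect
_EDGE_GAIN = {
    ("TBI", "PTSD"): (1.1, 0.0),
    ("TBI", "SuAb"): (0.9, 0.0),
    ("PTSD", "Depr"): (1.0, 0.3),
    ("PTSD", "SuAb"): (0.8, 0.0),
    ("Depr", "SuAb"): (0.9, -0.2),
    ("BaPa", "Depr"): (0.7, 0.0),
}

_BASE_LOSS = (-1.6, 0.0)  # flat remission, ~0.2/year


def default_structure() -> NetworkStructure:
    """The generating structure: only the six true edges as parents."""
    parents: dict[str, list[str]] = {n: [] for n in NODES}
    for p, c in TRUE_EDGES:
        parents[c].append(p)
    return NetworkStructure(NODES, {n: tuple(ps) for n, ps in parents.items()})


def candidate_structure() -> NetworkStructure:
    """The learner's search space: every node a candidate parent of every other."""
    return NetworkStructure.fully_connected(NODES)


def default_truth(remission: bool = True) -> CoefficientTable:
    """Ground-truth coefficients on the candidate structure.

    Using the fully connected candidate structure (with non-edge groups held
    at exactly zero) lets recovery experiments compare the fitted table to the
    truth group-by-group.
    """
    structure = candidate_structure()
    table = CoefficientTable.zeros(structure, ("age",), remission=remission)
    for node, vec in _BASE_GAIN.items():
        table.groups[(node, GAIN, BASELINE)] = np.asarray(vec, dtype=float)
    for (p, c), vec in _EDGE_GAIN.items():
        table.groups[(c, GAIN, p)] = np.asarray(vec, dtype=float)
    if remission:
        for node in NODES:
            table.groups[(node, LOSS, BASELINE)] = np.asarray(_BASE_LOSS, dtype=float)
    return table


def default_sim_spec(
    n_subjects: int = 5000,
    horizon: float = 10.0,
    seed: int = 42,
    remission: bool = True,
) -> SimulationSpec:
    """The standard recovery-experiment cohort: 5 nodes, 1 covariate."""
    return SimulationSpec(
        structure=candidate_structure(),
        truth=default_truth(remission=remission),
        covariate_spec=[("age", ("normal", 0.0, 1.0))],
        n_subjects=n_subjects,
        horizon=horizon,
        seed=seed,
    )


def small_truth(remission: bool = True) -> CoefficientTable:
    """3-node model (A->B, B->C true edges) for fast unit tests."""
    structure = NetworkStructure.fully_connected(("A", "B", "C"))
    table = CoefficientTable.zeros(structure, ("x",), remission=remission)
    table.groups[("A", GAIN, BASELINE)] = np.array([-1.2, 0.3])
    table.groups[("B", GAIN, BASELINE)] = np.array([-1.5, -0.2])
    table.groups[("C", GAIN, BASELINE)] = np.array([-1.8, 0.1])
    table.groups[("B", GAIN, "A")] = np.array([1.0, 0.2])
    table.groups[("C", GAIN, "B")] = np.array([0.9, 0.0])
    if remission:
        for n in ("A", "B", "C"):
            table.groups[(n, LOSS, BASELINE)] = np.array([-1.2, 0.0])
    return table


def small_sim_spec(n_subjects: int = 500, horizon: float = 6.0, seed: int = 7,
                   remission: bool = True) -> SimulationSpec:
    truth = small_truth(remission=remission)
    return SimulationSpec(
        structure=truth.structure,
        truth=truth,
        covariate_spec=[("x", ("normal", 0.0, 1.0))],
        n_subjects=n_subjects,
        horizon=horizon,
        seed=seed,
    )
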