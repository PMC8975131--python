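"""Dataset file format: one observed sojourn per row, plus sidecar metadata.

The CSV dialect (UTF-8, '.' decimal) has columns

    subject_id, z_<covariate>..., s_<node>..., t_d, event_node,
    event_new_state, censored

with the event columns empty on censored rows.  A sidecar JSON document
(``<name>.meta.json`` next to ``<name>.csv``) declares node order, covariate
names and the time unit, so a file round-trips losslessly and byte-stably.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx

from .errors import DataError, SchemaError
from .model import Record, Subject, TrajectoryDataset

__all__ = ["read_dataset", "write_dataset", "write_edge_list", "meta_path_for"]


def meta_path_for(path) -> Path:
    path = Path(path)
    return path.with_suffix(".meta.json") if path.suffix == ".csv" else Path(str(path) + ".meta.json")


def write_dataset(dataset: TrajectoryDataset, path) -> None:
    """Write the CSV file and its sidecar metadata document."""
    path = Path(path)
    meta = {
        "nodes": list(dataset.nodes),
        "covariates": [{"name": c, "type": "real"} for c in dataset.covariates],
        "time_unit": dataset.time_unit,
    }
    meta_path_for(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    header = (
        ["subject_id"]
        + [f"z_{c}" for c in dataset.covariates]
        + [f"s_{n}" for n in dataset.nodes]
        + ["t_d", "event_node", "event_new_state", "censored"]
    )
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for subject in dataset.subjects:
            zvals = [repr(float(v)) for v in subject.z]
            for rec in subject.records:
                row = (
                    [subject.id]
                    + zvals
                    + [str(int(s)) for s in rec.states]
                    + [repr(float(rec.duration))]
                )
                if rec.censored:
                    row += ["", "", "1"]
                else:
                    row += [rec.node, str(int(rec.new_state)), "0"]
                writer.writerow(row)


def read_dataset(path, meta_path=None) -> TrajectoryDataset:
    """Parse and validate a dataset file; errors carry offending row numbers."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else meta_path_for(path)
    if not meta_path.exists():
        raise SchemaError(f"missing sidecar metadata document {meta_path}")
    meta = json.loads(meta_path.read_text())
    nodes = tuple(meta["nodes"])
    covariates = tuple(c["name"] for c in meta["covariates"])

    expected = (
        ["subject_id"]
        + [f"z_{c}" for c in covariates]
        + [f"s_{n}" for n in nodes]
        + ["t_d", "event_node", "event_new_state", "censored"]
    )
    subjects: list[Subject] = []
    current: Subject | None = None
    bad_rows: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != expected:
            unknown = [c for c in (header or []) if c not in expected]
            if unknown:
                raise SchemaError(f"unknown columns {unknown} in {path}")
            raise SchemaError(f"header {header} does not match declared schema")
        nz, nn = len(covariates), len(nodes)
        for lineno, row in enumerate(reader, start=2):
            try:
                if len(row) != len(expected):
                    raise DataError(f"expected {len(expected)} fields, got {len(row)}")
                sid = row[0]
                z = [float(v) for v in row[1 : 1 + nz]]
                states = [int(v) for v in row[1 + nz : 1 + nz + nn]]
                if any(s not in (0, 1) for s in states):
                    raise DataError("state columns must be 0/1")
                t_d = float(row[1 + nz + nn])
                if t_d <= 0:
                    raise DataError(f"t_d must be positive, got {t_d}")
                ev_node, ev_state, censored = row[1 + nz + nn + 1 :]
                if censored == "1":
                    if ev_node or ev_state:
                        raise DataError("censored row must have empty event columns")
                    rec = Record(states, t_d, None, None, censored=True)
                elif censored == "0":
                    if ev_node not in nodes:
                        raise DataError(f"unknown event node {ev_node!r}")
                    rec = Record(states, t_d, ev_node, int(ev_state))
                else:
                    raise DataError(f"censored flag must be 0/1, got {censored!r}")
            except (DataError, ValueError) as exc:
                bad_rows.append(f"row {lineno}: {exc}")
                continue
            if current is None or current.id != sid:
                current = Subject(id=sid, z=z)
                subjects.append(current)
            current.records.append(rec)
    if bad_rows:
        raise DataError("malformed rows:\n  " + "\n  ".join(bad_rows))
    ds = TrajectoryDataset(nodes, covariates, subjects, time_unit=meta.get("time_unit", "years"))
    ds.validate()
    return ds


def write_edge_list(graph: nx.DiGraph, path) -> None:
    """Tab-delimited parent, child, weight export of an extracted structure."""
    with Path(path).open("w") as fh:
        fh.write("parent\tchild\tweight\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0)!r}\n")
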