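"""File formats and run manifests.

Datasets travel as CSV (observable, phenotype, mean, sd, units) with input
values in a JSON sidecar or supplied separately; ensembles and trajectories
as JSON-lines; run manifests as JSON documents recording config, seeds,
package version, and input hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .estimation import Dataset, Ensemble, EnsembleMember
from .model import ConfigurationError
from .trajectory import ParameterTrajectory, TrajectoryPoint

__all__ = [
    "read_dataset",
    "write_dataset",
    "ensemble_to_jsonl",
    "ensemble_from_jsonl",
    "trajectory_to_jsonl",
    "trajectory_from_jsonl",
    "trajectory_to_csv",
    "write_manifest",
    "sha256_file",
]

_COLUMNS = ["observable", "phenotype", "mean", "sd", "units"]


def read_dataset(path: str | Path, inputs: Mapping | None = None) -> Dataset:
    """Read a dataset CSV; input values come from ``inputs`` or a JSON
    sidecar ``<path>.inputs.json`` when present.

    Schema errors name the missing columns; validation errors carry the row
    number of the first offending value.
    """
    path = Path(path)
    table = pd.read_csv(path, skipinitialspace=True)
    table.columns = [c.strip() for c in table.columns]
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"dataset {path.name} missing columns: {missing}")
    table = table[_COLUMNS].copy()
    table["observable"] = table["observable"].astype(str).str.strip()
    table["phenotype"] = table["phenotype"].astype(str).str.strip()
    table["units"] = table["units"].fillna("").astype(str).str.strip()
    bad = table.index[table["sd"] <= 0]
    if len(bad):
        raise ConfigurationError(
            f"dataset {path.name}: non-positive sd at row {int(bad[0]) + 2}"
        )
    if inputs is None:
        sidecar = path.with_suffix(path.suffix + ".inputs.json")
        if sidecar.exists():
            inputs = json.loads(sidecar.read_text())
    inputs = {k: {u: float(x) for u, x in v.items()} for k, v in (inputs or {}).items()}
    return Dataset(table, inputs)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    dataset.table[_COLUMNS].to_csv(path, index=False)
    if dataset.inputs:
        sidecar = path.with_suffix(path.suffix + ".inputs.json")
        sidecar.write_text(json.dumps(dataset.inputs, indent=1, sort_keys=True))


def _member_to_doc(m: EnsembleMember) -> dict:
    return {
        "index": m.index,
        "theta": m.theta.tolist(),
        "cost": m.cost,
        "accepted": m.accepted,
        "flux_feasible": m.flux_feasible,
        "converged": m.converged,
        "state": m.state.tolist(),
        "outputs": np.asarray(m.outputs, float).tolist(),
        "observable_ids": list(m.observable_ids),
        "realization_seed": m.realization_seed,
    }


def _member_from_doc(doc: dict) -> EnsembleMember:
    return EnsembleMember(
        theta=np.array(doc["theta"]),
        cost=doc["cost"],
        accepted=doc["accepted"],
        flux_feasible=doc["flux_feasible"],
        converged=doc["converged"],
        state=np.array(doc["state"]),
        outputs=np.array(doc["outputs"]),
        observable_ids=tuple(doc["observable_ids"]),
        realization_seed=doc["realization_seed"],
        index=doc["index"],
    )


def ensemble_to_jsonl(ensemble: Ensemble, path: str | Path) -> None:
    """One member per line; a leading header line carries run metadata."""
    with open(path, "w") as fh:
        header = {
            "kind": "ensemble",
            "seed": ensemble.seed,
            "n_samples": ensemble.n_samples,
            "n_top": ensemble.n_top,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for m in ensemble.members:
            fh.write(json.dumps(_member_to_doc(m), sort_keys=True) + "\n")


def ensemble_from_jsonl(path: str | Path) -> Ensemble:
    with open(path) as fh:
        header = json.loads(fh.readline())
        members = [_member_from_doc(json.loads(line)) for line in fh if line.strip()]
    return Ensemble(
        members=members,
        seed=header["seed"],
        n_samples=header["n_samples"],
        n_top=header["n_top"],
    )


def trajectory_to_jsonl(traj: ParameterTrajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = {
            "kind": "trajectory",
            "direction": traj.direction,
            "lambda": traj.lam,
            "scheme": traj.scheme_name,
            "seeds": traj.seeds,
            "theta_ref": traj.theta_ref.tolist(),
            "observable_ids": list(traj.observable_ids),
            "completed": traj.completed,
            "member_index": traj.member_index,
            "repetition": traj.repetition,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for p in traj.points:
            doc = {
                "q": p.q,
                "theta": p.theta.tolist(),
                "state": p.state.tolist(),
                "outputs": np.asarray(p.outputs, float).tolist(),
                "X_d": p.X_d,
                "X_r": p.X_r,
                "inputs": p.inputs,
            }
            fh.write(json.dumps(doc, sort_keys=True) + "\n")


def trajectory_from_jsonl(path: str | Path) -> ParameterTrajectory:
    with open(path) as fh:
        header = json.loads(fh.readline())
        points = []
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            points.append(
                TrajectoryPoint(
                    q=doc["q"],
                    theta=np.array(doc["theta"]),
                    state=np.array(doc["state"]),
                    outputs=np.array(doc["outputs"]),
                    X_d=doc["X_d"],
                    X_r=doc["X_r"],
                    inputs=doc.get("inputs", {}),
                )
            )
    return ParameterTrajectory(
        direction=header["direction"],
        points=points,
        lam=header["lambda"],
        scheme_name=header["scheme"],
        seeds=header["seeds"],
        theta_ref=np.array(header["theta_ref"]),
        observable_ids=tuple(header["observable_ids"]),
        completed=header["completed"],
        member_index=header["member_index"],
        repetition=header.get("repetition", 0),
    )


def trajectory_to_csv(
    trajectories: Iterable[ParameterTrajectory],
    parameter_ids,
    path: str | Path,
) -> None:
    """Long-format CSV (q, parameter, value, repetition, direction)."""
    frames = [t.to_dataframe(parameter_ids) for t in trajectories]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: Mapping,
    inputs: Iterable[str | Path] = (),
    outputs: Iterable[str | Path] = (),
    overrides: Mapping | None = None,
) -> dict:
    """Write a deterministic JSON run manifest and return it.

    Timestamps are deliberately omitted so identical runs produce
    byte-identical manifests.
    """
    doc = {
        "command": command,
        "version": __version__,
        "config": {k: config[k] for k in sorted(config)},
        "overrides": {k: overrides[k] for k in sorted(overrides)} if overrides else {},
        "inputs": {
            str(p): sha256_file(p) for p in inputs if Path(p).exists()
        },
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc
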