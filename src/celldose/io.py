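"""Plain-text configuration, trajectory tables and run manifests.

Configs are YAML documents holding the model coefficient set, the cost
blocks, the initial state and (for proportion problems) the target
composition.  Numeric entries survive a write/read round trip exactly:
floats are serialised with Python's shortest round-trip representation.
Trajectory tables are comma-delimited with a ``#``-prefixed header comment
carrying the problem hash, so figures can be regenerated from tables alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ControlledODEModel, ModelValidationError
from .proportions import ProportionProblem
from .solver import CostSpec, OCProblem, OCSolution, SolverSettings

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "problem_to_dict",
    "problem_from_dict",
    "read_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_summary",
    "problem_hash",
    "RunManifest",
]


def _mat(a) -> list:
    return np.asarray(a, float).tolist()


def model_to_dict(model: ControlledODEModel) -> dict:
    d = {
        "n": model.n,
        "m": model.m,
        "A": _mat(model.A),
        "B": _mat(model.B),
        "C": [_mat(model.C[i]) for i in range(model.n)],
        "D": {
            f"{i},{j}": _mat(model.D[i, j])
            for i in range(model.n)
            for j in range(model.n)
            if np.any(model.D[i, j])
        },
        "time_scale": float(model.time_scale),
    }
    if model.state_labels:
        d["state_labels"] = list(model.state_labels)
    if model.drug_labels:
        d["drug_labels"] = list(model.drug_labels)
    return d


def model_from_dict(d: dict) -> ControlledODEModel:
    n, m = int(d["n"]), int(d["m"])
    D = {}
    for key, mat in (d.get("D") or {}).items():
        i, j = (int(s) for s in key.split(","))
        D[(i, j)] = np.asarray(mat, float)
    return ControlledODEModel.from_terms(
        np.asarray(d["A"], float),
        B=np.asarray(d["B"], float) if "B" in d else None,
        C=[np.asarray(c, float) for c in d.get("C", [])] or None,
        D=D or None,
        n=n,
        m=m,
        state_labels=d.get("state_labels"),
        drug_labels=d.get("drug_labels"),
        time_scale=float(d.get("time_scale", 1.0)),
    )


def problem_to_dict(problem: OCProblem | ProportionProblem) -> dict:
    if isinstance(problem, ProportionProblem):
        return {
            "kind": "proportions",
            "model": model_to_dict(problem.model),
            "target": _mat(problem.target),
            "W_state": _mat(problem.W_state),
            "W_control": _mat(problem.W_control),
            "T": float(problem.T),
            "r0": _mat(problem.r0),
            "control_bounds": [_mat(problem.control_bounds[0]), _mat(problem.control_bounds[1])],
        }
    cost = problem.cost
    if cost.time_varying:
        raise ModelValidationError("time-varying cost matrices are not serialisable")
    return {
        "kind": "counts",
        "model": model_to_dict(problem.model),
        "cost": {"M": _mat(cost.M), "Q": _mat(cost.Q), "R": _mat(cost.R), "T": float(cost.T)},
        "x0": _mat(problem.x0),
        "control_bounds": [_mat(problem.control_bounds[0]), _mat(problem.control_bounds[1])],
    }


def problem_from_dict(d: dict) -> OCProblem | ProportionProblem:
    kind = d.get("kind", "counts")
    model = model_from_dict(d["model"])
    bounds = d.get("control_bounds")
    bounds = (np.asarray(bounds[0], float), np.asarray(bounds[1], float)) if bounds else None
    if kind == "proportions":
        return ProportionProblem(
            model=model,
            target=np.asarray(d["target"], float),
            W_state=np.asarray(d["W_state"], float),
            W_control=np.asarray(d["W_control"], float),
            T=float(d["T"]),
            r0=np.asarray(d["r0"], float),
            control_bounds=bounds,
        )
    if kind != "counts":
        raise ModelValidationError(f"unknown problem kind {kind!r}")
    c = d["cost"]
    cost = CostSpec(
        M=np.asarray(c["M"], float),
        Q=np.asarray(c["Q"], float),
        R=np.asarray(c["R"], float),
        T=float(c["T"]),
    )
    return OCProblem(
        model=model, cost=cost, x0=np.asarray(d["x0"], float), control_bounds=bounds
    )


def write_config(obj, path) -> None:
    """Write a model or problem to a YAML config file."""
    if isinstance(obj, ControlledODEModel):
        payload = {"model": model_to_dict(obj)}
    else:
        payload = problem_to_dict(obj)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_config(path) -> OCProblem | ProportionProblem | ControlledODEModel:
    d = yaml.safe_load(Path(path).read_text())
    if set(d) == {"model"}:
        return model_from_dict(d["model"])
    return problem_from_dict(d)


def problem_hash(problem) -> str:
    """Stable short hash of the problem definition (for table headers)."""
    payload = json.dumps(problem_to_dict(problem), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_trajectory(sol: OCSolution, path, *, header: dict | None = None) -> None:
    """Write t, x_1..x_n, lam_1..lam_n, u_1..u_m as delimited text with a
    ``#`` comment block (manifest hash and scalars) above the header row."""
    df = sol.to_frame()
    lines = [f"# {k}: {v}" for k, v in (header or {}).items()]
    lines.append(f"# J: {sol.J!r}")
    lines.append(f"# converged: {sol.converged}")
    text = "\n".join(lines) + "\n" + df.to_csv(index=False, lineterminator="\n")
    Path(path).write_text(text)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_summary(data: dict, path) -> None:
    """Flat key-value summary document."""
    flat = {k: (float(v) if isinstance(v, (np.floating, np.integer)) else v) for k, v in data.items()}
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    seed: int | None = None
    settings: dict = field(default_factory=dict)
    problem_hash: str | None = None
    outputs: list[str] = field(default_factory=list)
    command: str | None = None

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "package": "celldose",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "seed": self.seed,
            "settings": self.settings,
            "problem_hash": self.problem_hash,
            "outputs": self.outputs,
            "command": self.command,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def settings_to_dict(settings: SolverSettings) -> dict:
    return {
        "tol": settings.tol,
        "bc_tol": settings.bc_tol,
        "max_nodes": settings.max_nodes,
        "initial_nodes": settings.initial_nodes,
        "singularity_cond": settings.singularity_cond,
    }
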