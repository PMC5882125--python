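"""Flat-file export of states, trajectories and dispersion curves."""

from __future__ import annotations

import csv
import hashlib
import json

import numpy as np

from .models import State
from .stability import DispersionResult

__all__ = ["write_state_csv", "write_dispersion_csv", "config_hash",
           "state_records"]


def state_records(state: State) -> list[dict]:
    """Long-format (field, index, value) records of every state field."""
    recs = []
    for name, v in state.fields():
        if v.ndim == 1:
            for i, val in enumerate(v):
                recs.append({"field": name, "index": i, "slot": "",
                             "value": float(val)})
        else:
            for i in range(v.shape[0]):
                for s in range(v.shape[1]):
                    recs.append({"field": name, "index": i, "slot": s,
                                 "value": float(v[i, s])})
    return recs


def write_state_csv(state: State, path) -> None:
    recs = state_records(state)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["field", "index", "slot", "value"])
        w.writeheader()
        w.writerows(recs)


def write_dispersion_csv(result: DispersionResult, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["k", "nu", "lambda"])
        for k, nu, lam in zip(result.k, result.nu_grid, result.lambda_k):
            w.writerow([int(k), float(nu), float(lam)])


def config_hash(config: dict) -> str:
    """Short content hash identifying a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)
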