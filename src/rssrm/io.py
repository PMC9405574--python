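"""Columnar text serialization for traces and fit results."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .basis import DesignMatrix
from .fitting import FitResult, PenaltySpec
from .izhikevich import SimulationTrace

__all__ = [
    "write_trace", "read_trace",
    "write_fit_result", "read_fit_result",
    "write_design", "read_design",
]

_TRACE_COLUMNS = "t I v u spike"


def write_trace(trace: SimulationTrace, path) -> None:
    """One row per sample (t, I, v, u, spike indicator) plus a header."""
    spike = np.zeros(trace.n_steps, dtype=int)
    spike[trace.spike_indices] = 1
    header = (
        f"behavior: {trace.name}\n"
        f"dt_ms: {trace.dt!r}\n"
        f"n_steps: {trace.n_steps}\n"
        f"columns: {_TRACE_COLUMNS}"
    )
    data = np.column_stack([trace.t, trace.I, trace.v, trace.u, spike])
    np.savetxt(path, data, header=header, fmt="%.10g")


def read_trace(path) -> SimulationTrace:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    data = np.loadtxt(path)
    t, I, v, u, spike = data.T
    dt = float(meta.get("dt_ms", t[1] - t[0]))
    return SimulationTrace(
        t=t, I=I, v=v, u=u,
        spike_times=t[spike.astype(bool)],
        dt=dt,
        name=meta.get("behavior", ""),
    )


def write_design(design: DesignMatrix, path) -> None:
    """Columnar text: label header, target-row header, one row per sample."""
    header = (
        "columns: " + "\t".join(str(c) for c in design.column_labels) + "\n"
        "target_rows: " + " ".join(str(r) for r in design.target_rows)
    )
    np.savetxt(path, design.X, header=header, fmt="%.10g")


def read_design(path) -> DesignMatrix:
    labels, rows = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() == "columns":
                labels = value.strip().split("\t")
            elif key.strip() == "target_rows":
                rows = np.array(value.split(), dtype=int)
    X = np.atleast_2d(np.loadtxt(path))
    return DesignMatrix(X=X, column_labels=labels, target_rows=rows)


def write_fit_result(result: FitResult, path) -> None:
    payload = {
        "intercept": float(result.intercept),
        "penalty": {
            "l1": result.penalty.l1,
            "l2": result.penalty.l2,
            "zero_tol": result.penalty.zero_tol,
        },
        "nonzero_count": result.nonzero_count,
        "objective_value": result.objective_value,
        "converged": result.converged,
        "column_labels": [str(c) for c in result.column_labels],
        "weights": [float(w) for w in result.weights],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_fit_result(path) -> FitResult:
    payload = yaml.safe_load(Path(path).read_text())
    return FitResult(
        intercept=payload["intercept"],
        weights=np.asarray(payload["weights"], dtype=float),
        column_labels=list(payload["column_labels"]),
        penalty=PenaltySpec(**payload["penalty"]),
        nonzero_count=payload["nonzero_count"],
        objective_value=payload["objective_value"],
        converged=payload["converged"],
    )
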