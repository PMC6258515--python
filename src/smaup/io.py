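"""Plain-text serialization: variable CSVs, null-vector caches, reports.

Everything the tool reads or writes is diffable text: GAL for weights
(handled in :mod:`smaup.weights`), CSV for variables / tables / null
vectors, JSON for reports and configuration.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import NullDistribution, _load_packaged_table
from .sar import AreaVariable

EXPECTED_GRID = {
    "rho": (-0.9, -0.7, -0.5, -0.3, 0.0, 0.3, 0.5, 0.7, 0.9),
    "alpha": (0.01, 0.05, 0.1),
    "N": (25, 100, 225, 400, 625, 900),
}


def read_variable_csv(path) -> AreaVariable:
    """Read an areal variable from a CSV with header ``area_id,value``."""
    df = pd.read_csv(path)
    if not {"area_id", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns area_id,value")
    df = df.sort_values("area_id")
    ids = df["area_id"].to_numpy()
    if not np.array_equal(ids, np.arange(len(ids))):
        raise ValueError(f"{path}: area_id must be contiguous 0..n-1")
    return AreaVariable(df["value"].to_numpy(dtype=float))


def write_variable_csv(y: AreaVariable, path) -> None:
    pd.DataFrame(
        {"area_id": np.arange(y.n), "value": y.values}
    ).to_csv(path, index=False)


def write_null(null: NullDistribution, path) -> None:
    """Cache a null vector as CSV with a JSON sidecar of its provenance."""
    path = Path(path)
    pd.DataFrame(
        {"m_value": null.m_values, "k_drawn": null.k_drawn}
    ).to_csv(path, index=False)
    sidecar = {
        "n_areas": null.n_areas,
        "rho": null.rho_label,
        "seed": null.seed,
        "n_instances": int(null.m_values.size),
        "acceptance_rate": null.acceptance_rate,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_null(path) -> NullDistribution:
    path = Path(path)
    df = pd.read_csv(path)
    if "m_value" not in df.columns:
        raise ValueError(f"{path}: expected column m_value")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return NullDistribution(
        n_areas=int(meta.get("n_areas", 0)),
        rho_label=float(meta.get("rho", float("nan"))),
        m_values=df["m_value"].to_numpy(dtype=float),
        seed=meta.get("seed"),
        k_drawn=df["k_drawn"].to_numpy() if "k_drawn" in df.columns else None,
        acceptance_rate=float(meta.get("acceptance_rate", float("nan"))),
    )


def load_critical_table(source="packaged") -> pd.DataFrame:
    """Load and validate the critical-value table (full 9 x 3 x 6 grid).

    ``source`` is either the string ``"packaged"`` or a path to a CSV with
    columns ``rho, alpha, N, value``.  Missing cells raise an error listing
    them.
    """
    df = (
        _load_packaged_table() if source == "packaged" else pd.read_csv(source)
    )
    required = {"rho", "alpha", "N", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"critical table needs columns {sorted(required)}")
    have = {
        (round(r, 6), round(a, 6), int(n))
        for r, a, n in zip(df["rho"], df["alpha"], df["N"])
    }
    missing = [
        (r, a, n)
        for r in EXPECTED_GRID["rho"]
        for a in EXPECTED_GRID["alpha"]
        for n in EXPECTED_GRID["N"]
        if (round(r, 6), round(a, 6), n) not in have
    ]
    if missing:
        raise ValueError(f"critical table missing cells: {missing}")
    return df


def run_report(command: str, inputs: dict, results: dict) -> dict:
    """Assemble a reproducible run report (all seeds live in ``inputs``)."""
    return {
        "command": command,
        "inputs": inputs,
        "results": results,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
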