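"""CSV/JSON writers for simulation and sweep artifacts.

CSV dialect: RFC 4180, '.' decimal separator, UTF-8, mandatory header
row, units embedded in column names.  Every time-series CSV is paired
with a JSON sidecar echoing the full parameter set, grid, tolerances
and conservation residuals, so the artifact is reproducible from the
sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import SweepResult
from .solver import SimulationResult, mass_balance_report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_timeseries_csv(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    result.to_dataframe().to_csv(path, index=False)
    return path


def write_profiles_csv(result: SimulationResult, path: str | Path,
                       species: str = "glucose") -> Path:
    """Spatial concentration profiles: rows = times, columns = cell centers."""
    profiles = (result.glucose_profiles if species == "glucose"
                else result.starch_profiles)
    path = Path(path)
    frame = pd.DataFrame(
        profiles,
        index=pd.Index(result.times, name="time_s"),
        columns=[f"z_{c:.6g}_m" for c in result.grid.centers],
    )
    frame.to_csv(path)
    return path


def write_sidecar_json(result: SimulationResult, path: str | Path,
                       extra: dict | None = None) -> Path:
    path = Path(path)
    report = mass_balance_report(result)
    payload = {
        "params": _jsonable(result.params_echo),
        "input_mass": result.input_mass,
        "final_fraction_absorbed": float(result.fraction_absorbed[-1]),
        "max_mass_balance_residual": report.max_residual,
    }
    if extra:
        payload.update(_jsonable(extra))
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_sweep_csv(sweep: SweepResult, long_path: str | Path,
                    matrix_path: str | Path | None = None) -> Path:
    long_path = Path(long_path)
    sweep.to_long_dataframe().to_csv(long_path, index=False)
    if matrix_path is not None and len(sweep.axes) == 2:
        sweep.to_matrix_dataframe().to_csv(Path(matrix_path))
    return long_path


def write_sweep_sidecar(sweep: SweepResult, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "axes": {k: np.asarray(v).tolist() for k, v in sweep.axes.items()},
        "evaluation_time": sweep.evaluation_time,
        "metadata": _jsonable(sweep.metadata),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
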