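"""File output for trajectories and reports (plain-text CSV throughout)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .solver import Trajectory

#: Grid fields written per snapshot (age-structured pools as totals).
SNAPSHOT_FIELDS = ("C_U", "C_T", "C_E", "S_T", "S_A", "D_N", "R", "M", "F", "P", "U")


def snapshot_frame(traj: Trajectory, t: float) -> pd.DataFrame:
    """Long-format table (r, z, one column per field) of a snapshot."""
    state = traj.state_at(t)
    R, Z = state.grid.meshgrid()
    data = {"r_cm": R.ravel(), "z_cm": Z.ravel()}
    for name in SNAPSHOT_FIELDS:
        if name in ("C_T", "S_T"):
            arr = getattr(state, name).total()
        else:
            arr = getattr(state, name)
        data[name] = arr.ravel()
    return pd.DataFrame(data)


def write_trajectory(traj: Trajectory, out_dir: str | Path) -> list[Path]:
    """Write one CSV grid per snapshot plus a solver-diagnostics table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in traj.times:
        path = out_dir / f"snapshot_day{t:g}.csv"
        snapshot_frame(traj, t).to_csv(path, index=False)
        written.append(path)
    d = traj.diagnostics
    diag = pd.DataFrame(
        {"dt_days": d.dt_history, "error_estimate": d.err_history}
    )
    diag_path = out_dir / "diagnostics.csv"
    with diag_path.open("w") as fh:
        fh.write(f"# accepted={d.n_accepted} rejected={d.n_rejected}\n")
        diag.to_csv(fh, index=False)
    written.append(diag_path)
    return written


def summary_stats(traj: Trajectory) -> pd.DataFrame:
    """Per-snapshot min/max/mean of every output field."""
    rows = []
    for t, state in zip(traj.times, traj.states):
        for name in SNAPSHOT_FIELDS:
            arr = (
                getattr(state, name).total()
                if name in ("C_T", "S_T")
                else getattr(state, name)
            )
            rows.append(
                {
                    "t_days": t,
                    "field": name,
                    "min": float(arr.min()),
                    "max": float(arr.max()),
                    "mean": float(arr.mean()),
                }
            )
    return pd.DataFrame(rows)
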