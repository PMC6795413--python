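"""State, trajectory and report serialization.

Text formats use the shortest round-trip decimal encoding (Python ``repr``
of a float), so write-then-read is lossless at full double precision —
bitwise-reproducibility claims rest on this.  NetCDF output goes through
xarray; the text formats are the primary interchange path.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .state import Layout, StateVector

__all__ = [
    "write_state_text",
    "read_state_text",
    "write_trajectory_text",
    "read_trajectory_text",
    "state_to_dataset",
    "trajectory_to_dataset",
]


def write_state_text(state: StateVector, path) -> None:
    """Delimited text: one row per (cell, variable), exact float encoding."""
    layout = state.layout
    with open(path, "w") as fh:
        fh.write("cell\tvariable\tvalue\n")
        for cell in range(layout.n_cells):
            for v in layout.variables:
                fh.write(f"{cell}\t{v}\t{state.get(cell, v)!r}\n")


def read_state_text(path) -> StateVector:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["cell", "variable", "value"]:
            raise ValueError(f"unexpected state header {header}")
        for line in fh:
            c, v, x = line.rstrip("\n").split("\t")
            rows.append((int(c), v, float(x)))
    n_cells = max(r[0] for r in rows) + 1
    variables = tuple(v for c, v, _ in rows if c == 0)
    layout = Layout(variables, n_cells)
    sv = StateVector(layout)
    for c, v, x in rows:
        sv.set(c, v, x)
    return sv


def write_trajectory_text(traj: np.ndarray, layout: Layout, path,
                          dt: Optional[float] = None) -> None:
    """Rows of (time index, cell, variable, value); lossless floats."""
    with open(path, "w") as fh:
        fh.write("time\tcell\tvariable\tvalue\n")
        for t in range(traj.shape[0]):
            for cell in range(layout.n_cells):
                for j, v in enumerate(layout.variables):
                    val = float(traj[t, cell * layout.n_vars + j])
                    fh.write(f"{t}\t{cell}\t{v}\t{val!r}\n")


def read_trajectory_text(path) -> Tuple[np.ndarray, Layout]:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["time", "cell", "variable", "value"]:
            raise ValueError(f"unexpected trajectory header {header}")
        for line in fh:
            t, c, v, x = line.rstrip("\n").split("\t")
            rows.append((int(t), int(c), v, float(x)))
    n_t = max(r[0] for r in rows) + 1
    n_cells = max(r[1] for r in rows) + 1
    variables = tuple(v for t, c, v, _ in rows if t == 0 and c == 0)
    layout = Layout(variables, n_cells)
    traj = np.empty((n_t, layout.n))
    for t, c, v, x in rows:
        traj[t, layout.index(c, v)] = x
    return traj, layout


def state_to_dataset(state: StateVector, dz=None):
    """xarray Dataset (layer, variable) with unit attributes."""
    import xarray as xr

    layout = state.layout
    data = state.values.reshape(layout.n_cells, layout.n_vars)
    ds = xr.Dataset(
        {
            v: ("layer", data[:, j])
            for j, v in enumerate(layout.variables)
        },
        coords={"layer": np.arange(layout.n_cells)},
    )
    for v in layout.variables:
        ds[v].attrs["units"] = (
            "mmol Si m-3" if v in ("SiOH4", "Opal") else "mmol N m-3"
        )
    if dz is not None:
        ds.attrs["layer_thickness_m"] = list(np.asarray(dz, float))
    return ds


def trajectory_to_dataset(traj: np.ndarray, layout: Layout, dt: float = None):
    import xarray as xr

    n_t = traj.shape[0]
    cube = traj.reshape(n_t, layout.n_cells, layout.n_vars)
    ds = xr.Dataset(
        {
            v: (("time", "layer"), cube[:, :, j])
            for j, v in enumerate(layout.variables)
        },
        coords={
            "time": np.arange(n_t),
            "layer": np.arange(layout.n_cells),
        },
    )
    if dt is not None:
        ds.attrs["dt_seconds"] = float(dt)
    return ds
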