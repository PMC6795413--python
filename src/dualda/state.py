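"""Flat state vectors over a (cell, variable) grid.

The nonlinear model, its tangent linear model and its adjoint all act on a
flat vector of length ``n_cells * n_variables``.  Ordering is cell-major:
all variables of cell 0 are contiguous, then cell 1, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class Layout:
    """Bijection between (cell, variable-name) pairs and flat positions."""

    variables: Tuple[str, ...]
    n_cells: int

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def n(self) -> int:
        return self.n_cells * len(self.variables)

    def index(self, cell: int, variable: str) -> int:
        return cell * self.n_vars + self.variables.index(variable)

    def unravel(self, flat: int) -> Tuple[int, str]:
        cell, v = divmod(flat, self.n_vars)
        return cell, self.variables[v]

    def cell_slice(self, cell: int) -> slice:
        return slice(cell * self.n_vars, (cell + 1) * self.n_vars)

    def var_indices(self, variable: str) -> np.ndarray:
        """Flat positions of one variable across all cells."""
        v = self.variables.index(variable)
        return np.arange(self.n_cells) * self.n_vars + v


class StateVector:
    """A flat numeric vector tied to a :class:`Layout`."""

    __slots__ = ("layout", "values")

    def __init__(self, layout: Layout, values=None):
        self.layout = layout
        if values is None:
            self.values = np.zeros(layout.n)
        else:
            v = np.asarray(values, dtype=np.float64).ravel()
            if v.size != layout.n:
                raise ValueError(
                    f"expected {layout.n} values for layout, got {v.size}"
                )
            self.values = v

    @classmethod
    def from_profiles(cls, layout: Layout, profiles: dict) -> "StateVector":
        """Build from per-variable values (scalar or per-cell sequence)."""
        sv = cls(layout)
        for name, val in profiles.items():
            sv.set_var(name, val)
        return sv

    def copy(self) -> "StateVector":
        return StateVector(self.layout, self.values.copy())

    def get(self, cell: int, variable: str) -> float:
        return float(self.values[self.layout.index(cell, variable)])

    def set(self, cell: int, variable: str, value: float) -> None:
        self.values[self.layout.index(cell, variable)] = value

    def var(self, variable: str) -> np.ndarray:
        """Per-cell profile of one variable (copy)."""
        return self.values[self.layout.var_indices(variable)].copy()

    def set_var(self, variable: str, value) -> None:
        self.values[self.layout.var_indices(variable)] = value

    def __len__(self) -> int:
        return self.values.size

    def __repr__(self):
        return (
            f"StateVector({self.layout.n_cells} cells x "
            f"{self.layout.n_vars} vars)"
        )


def as_values(x) -> np.ndarray:
    """Accept a StateVector, array or sequence; return a float64 vector."""
    if isinstance(x, StateVector):
        return x.values
    return np.asarray(x, dtype=np.float64).ravel()
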