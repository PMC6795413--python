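"""Observation records feeding the 4D-Var cost function.

Each record observes either a state variable directly or the chlorophyll
diagnostic (``chl_ratio * (PS + PL)``) at one (time index, cell) slot with a
Gaussian error standard deviation.  The container enforces positive error
stds and unique (time, cell, quantity) keys, and round-trips losslessly
through a delimited-text table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

CHLOROPHYLL = "chlorophyll"

__all__ = ["Observation", "ObservationSet", "CHLOROPHYLL", "snap_time"]


def snap_time(t_seconds: float, dt: float) -> int:
    """Snap a physical time to the nearest model step; ties round down."""
    return int(math.ceil(t_seconds / dt - 0.5))


@dataclass(frozen=True)
class Observation:
    time: int        # model step index (0 = initial time)
    cell: int
    quantity: str    # a state-variable name or "chlorophyll"
    value: float
    sigma: float     # error standard deviation, > 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(
                f"observation ({self.time},{self.cell},{self.quantity}): "
                f"error std must be > 0, got {self.sigma}"
            )
        if self.time < 0 or self.cell < 0:
            raise ValueError("time and cell indices must be >= 0")


class ObservationSet:
    """An ordered, key-unique collection of observations."""

    def __init__(self, records: Iterable[Observation] = (),
                 provenance: Optional[dict] = None):
        self.records: List[Observation] = []
        self._keys = set()
        self.provenance = dict(provenance or {})
        for r in records:
            self.append(r)

    def append(self, rec: Observation) -> None:
        key = (rec.time, rec.cell, rec.quantity)
        if key in self._keys:
            raise ValueError(f"duplicate observation key {key}")
        self._keys.add(key)
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def max_time(self) -> int:
        return max((r.time for r in self.records), default=0)

    def quantities(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for r in self.records:
            if r.quantity not in seen:
                seen.append(r.quantity)
        return tuple(seen)

    def by_time(self) -> Dict[int, List[Observation]]:
        out: Dict[int, List[Observation]] = {}
        for r in self.records:
            out.setdefault(r.time, []).append(r)
        return out

    def subset(self, quantity: str) -> "ObservationSet":
        return ObservationSet(
            (r for r in self.records if r.quantity == quantity),
            provenance=self.provenance,
        )

    # -- lossless text round-trip -----------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.time, r.cell, r.quantity, r.value, r.sigma)
             for r in self.records],
            columns=["time", "cell", "quantity", "value", "sigma"],
        )

    def write(self, path) -> None:
        """Tab-separated table with shortest round-trip decimal floats."""
        with open(path, "w") as fh:
            fh.write("time\tcell\tquantity\tvalue\tsigma\n")
            for r in self.records:
                fh.write(
                    f"{r.time}\t{r.cell}\t{r.quantity}\t"
                    f"{float(r.value)!r}\t{float(r.sigma)!r}\n"
                )

    @classmethod
    def read(cls, path) -> "ObservationSet":
        obs = cls()
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["time", "cell", "quantity", "value", "sigma"]:
                raise ValueError(f"unexpected observation header {header}")
            for line in fh:
                t, c, q, v, s = line.rstrip("\n").split("\t")
                obs.append(Observation(int(t), int(c), q, float(v), float(s)))
        return obs
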