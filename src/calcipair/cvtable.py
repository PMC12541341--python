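"""Collective-variable time series with bias and wall energies."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical internal column names
TIME_COL = "time"
BIAS_COL = "bias"
WALL_COL = "wall"

#: COLVAR-dialect names used on disk
BIAS_FILE_COL = "opes.bias"
WALL_FILE_COL = "wall.bias"


@dataclass
class CVRecordTable:
    """Time series of collective variables plus bias/wall energies.

    Backed by a :class:`pandas.DataFrame` with columns ``time`` (ps), one
    column per CV (units of the CV), ``bias`` and ``wall`` (kJ/mol).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if TIME_COL not in df.columns:
            raise ValueError("table must have a 'time' column")
        for col in (BIAS_COL, WALL_COL):
            if col not in df.columns:
                df = df.assign(**{col: 0.0})
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        time: np.ndarray,
        cvs: dict[str, np.ndarray],
        bias: np.ndarray | None = None,
        wall: np.ndarray | None = None,
    ) -> "CVRecordTable":
        n = len(time)
        cols: dict[str, np.ndarray] = {TIME_COL: np.asarray(time, dtype=float)}
        for name, values in cvs.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (n,):
                raise ValueError(f"CV column {name!r} has wrong length")
            cols[name] = values
        cols[BIAS_COL] = np.zeros(n) if bias is None else np.asarray(bias, dtype=float)
        cols[WALL_COL] = np.zeros(n) if wall is None else np.asarray(wall, dtype=float)
        return cls(pd.DataFrame(cols))

    @property
    def time(self) -> np.ndarray:
        return self.data[TIME_COL].to_numpy()

    @property
    def bias(self) -> np.ndarray:
        return self.data[BIAS_COL].to_numpy()

    @property
    def wall(self) -> np.ndarray:
        return self.data[WALL_COL].to_numpy()

    @property
    def cv_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in (TIME_COL, BIAS_COL, WALL_COL)]

    def cv(self, name: str) -> np.ndarray:
        if name not in self.cv_names:
            raise KeyError(f"no CV column {name!r}; available: {self.cv_names}")
        return self.data[name].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def tail_fraction(self, fraction: float) -> "CVRecordTable":
        """Last ``fraction`` of the rows (used to discard bias burn-in)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        start = int(round((1 - fraction) * len(self.data)))
        return CVRecordTable(self.data.iloc[start:].reset_index(drop=True))
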