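"""Box–Behnken design construction and coded/actual factor mapping.

A three-factor Box–Behnken design (BBD) places runs at the midpoints of the
edges of the factor cube — every pair of factors at the four (±1, ±1)
combinations with the third factor held at its centre — plus replicated
centre runs.  Factors are handled on two scales: the *coded* scale, where
the low/centre/high levels map to −1/0/+1, and the *actual* scale in
physical units (here ethanol fraction in %, sonication time in min and
solvent volume in mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpace",
    "DesignRun",
    "Design",
    "InvalidFactorSpaceError",
    "default_factor_space",
    "build_bbd",
    "coded_to_actual",
    "actual_to_coded",
]


class InvalidFactorSpaceError(ValueError):
    """Raised when a factor's lower bound is not strictly below its upper bound."""


@dataclass(frozen=True)
class FactorSpace:
    """Geometry of the factor box: names, actual bounds and units.

    ``low`` and ``high`` are the actual values of the coded −1 and +1
    levels; the coded 0 level is exactly ``(low + high) / 2``.
    """

    names: tuple[str, ...]
    low: tuple[float, ...]
    high: tuple[float, ...]
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.low) == len(self.high) == len(self.units) == n):
            raise InvalidFactorSpaceError("names, low, high and units must have equal length")
        for name, lo, hi in zip(self.names, self.low, self.high):
            if not lo < hi:
                raise InvalidFactorSpaceError(
                    f"factor {name!r}: lower bound {lo} must be < upper bound {hi}"
                )

    @property
    def n_factors(self) -> int:
        return len(self.names)

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.low, float) + np.asarray(self.high, float)) / 2.0

    @property
    def half_range(self) -> np.ndarray:
        return (np.asarray(self.high, float) - np.asarray(self.low, float)) / 2.0


def default_factor_space() -> FactorSpace:
    """The extraction factor box: 25–75 % ethanol, 30–50 min, 20–60 mL."""
    return FactorSpace(
        names=("ethanol", "time", "volume"),
        low=(25.0, 30.0, 20.0),
        high=(75.0, 50.0, 60.0),
        units=("%", "min", "mL"),
    )


def coded_to_actual(factor_space: FactorSpace, coded: Sequence[float]) -> np.ndarray:
    """Map coded coordinates to actual units: ``center + coded * half_range``.

    Values outside [−1, 1] are allowed (prediction grids may extrapolate).
    Accepts a single 3-vector or an (n, 3) array.
    """
    coded = np.asarray(coded, dtype=float)
    return factor_space.center + coded * factor_space.half_range


def actual_to_coded(factor_space: FactorSpace, actual: Sequence[float]) -> np.ndarray:
    """Exact inverse of :func:`coded_to_actual`."""
    actual = np.asarray(actual, dtype=float)
    return (actual - factor_space.center) / factor_space.half_range


@dataclass(frozen=True)
class DesignRun:
    """A single design run with its coded and actual coordinates."""

    run_id: int
    coded: tuple[float, ...]
    actual: tuple[float, ...]
    is_center: bool

    def __post_init__(self) -> None:
        if self.run_id < 1:
            raise ValueError("run_id must be a positive integer")
        center = all(c == 0 for c in self.coded)
        if center != self.is_center:
            raise ValueError("is_center must hold exactly when coded == (0, 0, 0)")


@dataclass(frozen=True)
class Design:
    """An ordered collection of design runs over a factor space."""

    factor_space: FactorSpace
    runs: tuple[DesignRun, ...] = field(default_factory=tuple)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_center(self) -> int:
        return sum(r.is_center for r in self.runs)

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([r.coded for r in self.runs], dtype=float)

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([r.actual for r in self.runs], dtype=float)

    @property
    def center_mask(self) -> np.ndarray:
        return np.array([r.is_center for r in self.runs], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        fs = self.factor_space
        cols: dict[str, list] = {"run": [r.run_id for r in self.runs]}
        for j in range(fs.n_factors):
            cols[f"coded_x{j + 1}"] = [r.coded[j] for r in self.runs]
        names = ("x1_ethanol_pct", "x2_time_min", "x3_volume_ml")
        for j, col in enumerate(names[: fs.n_factors]):
            cols[col] = [r.actual[j] for r in self.runs]
        cols["is_center"] = [r.is_center for r in self.runs]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_bbd(factor_space: FactorSpace, n_center: int = 5) -> Design:
    """Construct the 3-factor Box–Behnken design.

    The 12 non-centre runs enumerate the factor pairs (1,2), (1,3), (2,3),
    each at the four sign combinations in lexicographic order
    (−1,−1), (−1,+1), (+1,−1), (+1,+1), with the third factor at 0;
    the ``n_center`` centre replicates come last.  The ordering is fixed so
    the design is a pure function of its arguments.
    """
    if factor_space.n_factors != 3:
        raise InvalidFactorSpaceError("build_bbd implements the 3-factor BBD only")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    coded_rows: list[tuple[float, float, float]] = []
    for i, j in combinations(range(3), 2):
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                row = [0.0, 0.0, 0.0]
                row[i] = si
                row[j] = sj
                coded_rows.append(tuple(row))
    coded_rows.extend([(0.0, 0.0, 0.0)] * n_center)

    runs = []
    for k, coded in enumerate(coded_rows, start=1):
        actual = tuple(coded_to_actual(factor_space, coded))
        runs.append(
            DesignRun(
                run_id=k,
                coded=coded,
                actual=actual,
                is_center=all(c == 0 for c in coded),
            )
        )
    return Design(factor_space=factor_space, runs=tuple(runs))
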