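"""The packaged Poria cocos extraction dataset, its CSV schema and response groups.

The dataset is the 17-run, three-factor Box–Behnken experiment on
ultrasonic-assisted extraction of *Poria cocos*: per run it records the
mean ± SD (n = 3 replicates) of eight responses — four lanostane
triterpene acids (PA pachymic, TA trametenolic, TAA tsugaric A, DA
dehydrotrametenolic, all μg/g), total polysaccharides (TPs, mg GLU/g),
total phenolics (TPc, μg GAE/g), DPPH radical scavenging (DPPH_SC, %) and
FRAP total antioxidant capacity (T_AOC, μmol/g).

CSV schema (header mandatory, UTF-8, '.' decimal separator)::

    run, x1_ethanol_pct, x2_time_min, x3_volume_ml,
    <name>_mean, <name>_sd   for each response in RESPONSE_NAMES order
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .design import Design, DesignRun, FactorSpace, actual_to_coded, default_factor_space

__all__ = [
    "RESPONSE_NAMES",
    "RESPONSE_UNITS",
    "ResponseTable",
    "ResponseGroup",
    "SchemaError",
    "ChecksumError",
    "poria_dataset",
    "load_dataset",
    "write_dataset",
    "default_groups",
]

RESPONSE_NAMES: tuple[str, ...] = (
    "PA", "TA", "TAA", "DA", "TPs", "TPc", "DPPH_SC", "T_AOC",
)

RESPONSE_UNITS: dict[str, str] = {
    "PA": "ug/g",
    "TA": "ug/g",
    "TAA": "ug/g",
    "DA": "ug/g",
    "TPs": "mg GLU/g",
    "TPc": "ug GAE/g",
    "DPPH_SC": "%",
    "T_AOC": "umol/g",
}

FACTOR_COLUMNS = ("x1_ethanol_pct", "x2_time_min", "x3_volume_ml")

_PORIA_SHA256 = "81291904ff9af097a0158ad0dfd5c7f9a01a6539686ff88e4e6193703589244c"


class SchemaError(ValueError):
    """Raised when a dataset CSV violates the documented schema."""


class ChecksumError(RuntimeError):
    """Raised when the packaged dataset fixture fails its checksum."""


@dataclass(frozen=True)
class ResponseGroup:
    """A named subset of the response variables."""

    name: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class ResponseTable:
    """Run-level means and standard deviations for a designed experiment.

    ``means`` and ``sds`` are (n_runs, n_responses) arrays, columns in
    ``response_names`` order.  All modelling in the package operates on
    the run means; the SDs feed the pure-error and replicate-level
    reconstructions.
    """

    design: Design
    response_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    n_reps: int = 3
    units: dict[str, str] | None = None

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        n_runs, n_resp = means.shape
        if n_runs != self.design.n_runs:
            raise SchemaError(
                f"table has {n_runs} rows but the design has {self.design.n_runs} runs"
            )
        if sds.shape != means.shape or n_resp != len(self.response_names):
            raise SchemaError("means/sds shape must be (n_runs, n_responses)")
        if not np.all(np.isfinite(means)):
            raise SchemaError("all response means must be finite")
        if np.any(sds < 0) or not np.all(np.isfinite(sds)):
            raise SchemaError("all SDs must be finite and >= 0")

    @property
    def n_runs(self) -> int:
        return self.means.shape[0]

    @property
    def n_responses(self) -> int:
        return self.means.shape[1]

    def response_index(self, name: str) -> int:
        try:
            return self.response_names.index(name)
        except ValueError:
            raise KeyError(f"unknown response {name!r}; have {self.response_names}") from None

    def response(self, name: str) -> np.ndarray:
        return self.means[:, self.response_index(name)]

    def observed_range(self, name: str) -> tuple[float, float]:
        y = self.response(name)
        return float(y.min()), float(y.max())

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray | list] = {
            "run": [r.run_id for r in self.design.runs]
        }
        actual = self.design.actual_matrix
        for j, col in enumerate(FACTOR_COLUMNS):
            cols[col] = actual[:, j]
        for k, name in enumerate(self.response_names):
            cols[f"{name}_mean"] = self.means[:, k]
            cols[f"{name}_sd"] = self.sds[:, k]
        return pd.DataFrame(cols)


def default_groups() -> list[ResponseGroup]:
    """The two response groups used for optimization.

    Group 1 collects the four triterpene acids; Group 2 the
    polysaccharide, phenolic and antioxidant-activity responses.
    """
    return [
        ResponseGroup("Group 1", ("PA", "TA", "TAA", "DA")),
        ResponseGroup("Group 2", ("TPs", "TPc", "DPPH_SC", "T_AOC")),
    ]


def _design_from_actual(actual: np.ndarray, factor_space: FactorSpace) -> Design:
    runs = []
    for i, row in enumerate(actual, start=1):
        coded = actual_to_coded(factor_space, row)
        coded = tuple(float(c) for c in coded)
        runs.append(
            DesignRun(
                run_id=i,
                coded=coded,
                actual=tuple(float(v) for v in row),
                is_center=all(c == 0 for c in coded),
            )
        )
    return Design(factor_space=factor_space, runs=tuple(runs))


def _table_from_frame(
    df: pd.DataFrame,
    factor_space: FactorSpace,
    response_names: tuple[str, ...],
    n_reps: int = 3,
) -> ResponseTable:
    required = ["run", *FACTOR_COLUMNS]
    for name in response_names:
        required += [f"{name}_mean", f"{name}_sd"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based + header line
            raise SchemaError(f"non-numeric cell in column {col!r}, file line {row}")
    for name in response_names:
        sd = df[f"{name}_sd"].astype(float)
        if (sd < 0).any():
            row = int(df.index[sd < 0][0]) + 2
            raise SchemaError(f"negative SD in column {name}_sd, file line {row}")

    actual = df[list(FACTOR_COLUMNS)].to_numpy(dtype=float)
    design = _design_from_actual(actual, factor_space)
    means = df[[f"{n}_mean" for n in response_names]].to_numpy(dtype=float)
    sds = df[[f"{n}_sd" for n in response_names]].to_numpy(dtype=float)
    return ResponseTable(
        design=design,
        response_names=response_names,
        means=means,
        sds=sds,
        n_reps=n_reps,
        units={n: RESPONSE_UNITS.get(n, "") for n in response_names},
    )


def load_dataset(
    path,
    factor_space: FactorSpace | None = None,
    response_names: tuple[str, ...] = RESPONSE_NAMES,
    n_reps: int = 3,
    expected_runs: int | None = None,
) -> ResponseTable:
    """Load a response table from a schema-conforming CSV file."""
    df = pd.read_csv(path)
    if expected_runs is not None and len(df) != expected_runs:
        raise SchemaError(f"expected {expected_runs} rows, file has {len(df)}")
    return _table_from_frame(
        df, factor_space or default_factor_space(), tuple(response_names), n_reps
    )


def write_dataset(table: ResponseTable, path) -> None:
    """Write a response table to CSV in the documented schema."""
    table.to_frame().to_csv(path, index=False)


def poria_dataset() -> ResponseTable:
    """The packaged 17-run Poria cocos extraction dataset.

    The fixture is checksum-verified on load; values are the published
    run means ± SD at their printed 2-decimal precision.
    """
    ref = resources.files("poriaopt").joinpath("data/poria_uae.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _PORIA_SHA256:
        raise ChecksumError(
            f"packaged dataset checksum mismatch: {digest} != {_PORIA_SHA256}"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    return _table_from_frame(df, default_factor_space(), RESPONSE_NAMES, n_reps=3)
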