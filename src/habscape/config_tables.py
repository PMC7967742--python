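"""Parameter tables: packaged defaults and user-supplied overrides.

The package ships, as plain CSV, the scenario demand areas, neighborhood
weights, conversion allowance matrices, threat specifications and the
habitat-suitability/sensitivity table used throughout the pipeline. Users
may point any loader at their own files; every table is validated against
the same invariants on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import largest_remainder
from .grids import DEFAULT_CLASS_TABLE, ConversionMatrix, DemandVector

CLASS_NAMES = [n for _, n in DEFAULT_CLASS_TABLE]
CLASS_CODES = np.array([c for c, _ in DEFAULT_CLASS_TABLE])
THREAT_NAMES = [
    "urban",
    "rural_residential",
    "transportation",
    "mining",
    "cultivated",
    "saline_alkali",
]


def packaged(name: str) -> Path:
    """Path to a packaged data file."""
    return Path(str(resources.files("habscape.data") / name))


@dataclass
class ThreatSpec:
    """One threat factor: maximum effective distance, weight and decay law."""

    name: str
    d_max_km: float
    weight: float
    decay: str  # "linear" | "exponential"

    def __post_init__(self) -> None:
        if self.d_max_km <= 0:
            raise ValueError(f"threat {self.name}: d_max must be positive")
        if not 0 <= self.weight <= 1:
            raise ValueError(f"threat {self.name}: weight must be in [0, 1]")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"threat {self.name}: unknown decay {self.decay!r}")

    @property
    def d_max_m(self) -> float:
        return self.d_max_km * 1000.0


@dataclass
class SensitivityTable:
    """Habitat suitability H per class and sensitivity S per class x threat."""

    habitat: pd.Series  # index: class name
    sensitivity: pd.DataFrame  # index: class name, columns: threat name

    def __post_init__(self) -> None:
        for label, tbl in (("habitat", self.habitat), ("sensitivity", self.sensitivity)):
            vals = np.asarray(tbl, dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                bad = np.argwhere((vals < 0) | (vals > 1))[0]
                raise ValueError(
                    f"{label} values must be in [0, 1] (offending entry at {tuple(bad)})"
                )
        if float(self.habitat.get("construction", 0.0)) != 0.0:
            raise ValueError("construction land must have habitat suitability 0")

    def habitat_array(self, class_names: list[str] | None = None) -> np.ndarray:
        names = class_names or CLASS_NAMES
        return self.habitat.reindex(names).to_numpy(dtype=float)

    def sensitivity_array(
        self, threat: str, class_names: list[str] | None = None
    ) -> np.ndarray:
        names = class_names or CLASS_NAMES
        return self.sensitivity[threat].reindex(names).to_numpy(dtype=float)


def load_demand_table(path: str | Path | None = None) -> pd.DataFrame:
    """Scenario-by-class demand areas in hectares (hm2)."""
    df = pd.read_csv(path or packaged("demands_hm2.csv"))
    missing = set(CLASS_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"demand table is missing classes: {sorted(missing)}")
    if (df[CLASS_NAMES] < 0).any().any():
        raise ValueError("demand areas must be non-negative")
    return df.set_index("scenario")


def area_to_cells(
    area_hm2: np.ndarray,
    cell_size: float,
    total_cells: int | None = None,
) -> np.ndarray:
    """Convert per-class areas (hm2) to integer cell counts.

    With ``total_cells`` given, the areas are treated as proportions of the
    landscape and apportioned by largest remainder so the counts sum exactly
    to the landscape total. Otherwise counts are ``round(area*10000/cell^2)``
    with the rounding residue assigned to the largest class.
    """
    area = np.asarray(area_hm2, dtype=float)
    if total_cells is not None:
        return largest_remainder(area, int(total_cells))
    raw = area * 10000.0 / cell_size**2
    counts = np.rint(raw).astype(np.int64)
    residue = int(np.rint(raw.sum())) - int(counts.sum())
    counts[int(np.argmax(counts))] += residue
    return counts


def demand_vector(
    scenario: str,
    cell_size: float,
    total_cells: int | None = None,
    path: str | Path | None = None,
) -> DemandVector:
    """Build a DemandVector for one scenario from a demand table."""
    table = load_demand_table(path)
    if scenario not in table.index:
        raise KeyError(f"scenario {scenario!r} not in demand table")
    area = table.loc[scenario, CLASS_NAMES].to_numpy(dtype=float)
    return DemandVector(area_to_cells(area, cell_size, total_cells), CLASS_CODES.copy())


def load_neighborhood_weights(
    scenario: str, path: str | Path | None = None
) -> np.ndarray:
    """Per-class neighborhood weights (expansion capacities) for a scenario."""
    df = pd.read_csv(path or packaged("neighborhood_weights.csv")).set_index("scenario")
    if scenario not in df.index:
        raise KeyError(f"scenario {scenario!r} not in weight table")
    w = df.loc[scenario, CLASS_NAMES].to_numpy(dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("neighborhood weights must be in [0, 1]")
    return w


def load_conversion_matrix(which: str = "s1s2", path: str | Path | None = None) -> ConversionMatrix:
    """Conversion allowance matrix, either packaged ('s1s2'/'s3s4') or from a file."""
    if path is None:
        if which not in ("s1s2", "s3s4"):
            raise KeyError(f"no packaged conversion matrix named {which!r}")
        path = packaged(f"conversion_{which}.csv")
    df = pd.read_csv(path).set_index("from")
    allow = df.loc[CLASS_NAMES, CLASS_NAMES].to_numpy(dtype=np.int8)
    return ConversionMatrix(allow, CLASS_CODES.copy())


def load_threat_specs(path: str | Path | None = None) -> list[ThreatSpec]:
    df = pd.read_csv(path or packaged("threats.csv"))
    return [
        ThreatSpec(r.threat, float(r.max_distance_km), float(r.weight), r.decay)
        for r in df.itertuples()
    ]


def load_sensitivity(path: str | Path | None = None) -> SensitivityTable:
    df = pd.read_csv(path or packaged("sensitivity.csv")).set_index("class")
    missing = set(THREAT_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"sensitivity table missing threats: {sorted(missing)}")
    return SensitivityTable(df["habitat"], df[THREAT_NAMES])


@dataclass
class ParameterTables:
    demand: pd.DataFrame
    neighborhood: pd.DataFrame
    conversion: dict[str, ConversionMatrix]
    threats: list[ThreatSpec]
    sensitivity: SensitivityTable


def read_parameter_tables(directory: str | Path | None = None) -> ParameterTables:
    """Load every parameter table from ``directory`` (packaged defaults if None).

    A directory must contain files named like the packaged ones:
    demands_hm2.csv, neighborhood_weights.csv, conversion_s1s2.csv,
    conversion_s3s4.csv, threats.csv, sensitivity.csv.
    """
    d = Path(directory) if directory is not None else None

    def p(name: str) -> Path | None:
        return (d / name) if d is not None else None

    return ParameterTables(
        demand=load_demand_table(p("demands_hm2.csv")),
        neighborhood=pd.read_csv(
            p("neighborhood_weights.csv") or packaged("neighborhood_weights.csv")
        ).set_index("scenario"),
        conversion={
            "s1s2": load_conversion_matrix("s1s2", p("conversion_s1s2.csv")),
            "s3s4": load_conversion_matrix("s3s4", p("conversion_s3s4.csv")),
        },
        threats=load_threat_specs(p("threats.csv")),
        sensitivity=load_sensitivity(p("sensitivity.csv")),
    )
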