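"""Scenario configuration, execution and comparison.

A scenario bundles a demand source (Markov projection or a tabulated
demand row), per-class neighborhood weights, a conversion allowance
matrix and a set of restricted-area masks. Four scenarios ship with the
package: S1 business as usual, S2 fast cultivated-land expansion, S3
ecological security, S4 sustainable development.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import config_tables as ct
from .allocation import (
    AllocationResult,
    NeighborhoodWeights,
    run_allocation,
)
from .grids import ConversionMatrix, DemandVector, LandUseMap, RestrictedMask, write_raster
from .markov import TransitionMatrix, project_state, state_from_map
from .quality import (
    NO_SUBTYPE_MAPPING,
    QualityMap,
    classify_grades,
    degradation_index,
    derive_threat_sources,
    quality_map,
    summarize_quality,
)
from .suitability import SuitabilityModel, predict_suitability

PACKAGED_SCENARIOS = ("S1", "S2", "S3", "S4")
DEFAULT_N_STEPS = 13.0 / 8.0  # projection horizon over calibration interval

CHANGE_BINS = (-0.4, -0.1, 0.1, 0.4)
CHANGE_CLASS_NAMES = [
    "decrease > 0.4",
    "decrease 0.1-0.4",
    "stable",
    "increase 0.1-0.4",
    "increase > 0.4",
]


@dataclass
class ScenarioConfig:
    name: str
    demand_source: str  # "markov" | "table"
    weights: np.ndarray  # per-class neighborhood weights
    window: int
    conversion: ConversionMatrix
    restricted: list[str] = field(default_factory=list)  # "redline" | "farmland"
    demand_table: Path | None = None
    seed: int = 0
    long_name: str = ""

    def __post_init__(self) -> None:
        if self.demand_source not in ("markov", "table"):
            raise ValueError(f"demand_source must be markov|table, got {self.demand_source!r}")
        unknown = set(self.restricted) - {"redline", "farmland"}
        if unknown:
            raise ValueError(f"unknown restricted mask name(s): {sorted(unknown)}")


def load_scenario(name_or_path: str | Path) -> ScenarioConfig:
    """Load a packaged scenario ('S1'..'S4') or a user YAML file."""
    name = str(name_or_path)
    if name.upper() in PACKAGED_SCENARIOS:
        path = ct.packaged(f"scenarios/{name.lower()}.yaml")
        base = None
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise FileNotFoundError(f"scenario config not found: {path}")
        base = path.parent
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    def resolve(key: str, value: str) -> Path:
        p = Path(value)
        if not p.is_absolute() and base is not None and (base / p).exists():
            p = base / p
        elif not p.exists():
            packaged = ct.packaged(value)
            if packaged.exists():
                p = packaged
        if not p.exists():
            raise FileNotFoundError(f"scenario field {key!r}: file not found: {value}")
        return p

    scen_name = cfg["name"]
    demand_table = resolve("demand_table", cfg.get("demand_table", "demands_hm2.csv"))
    neigh = cfg.get("neighborhood", {})
    weights_path = resolve(
        "neighborhood.weights_table",
        neigh.get("weights_table", "neighborhood_weights.csv"),
    )
    if "weights" in neigh:  # inline override
        weights = np.array([neigh["weights"][n] for n in ct.CLASS_NAMES], dtype=float)
    else:
        weights = ct.load_neighborhood_weights(scen_name, weights_path)
    conv = cfg.get("conversion_matrix", "s1s2")
    if conv in ("s1s2", "s3s4"):
        conversion = ct.load_conversion_matrix(conv)
    else:
        conversion = ct.load_conversion_matrix(path=resolve("conversion_matrix", conv))
    return ScenarioConfig(
        name=scen_name,
        demand_source=cfg.get("demand_source", "table"),
        weights=weights,
        window=int(neigh.get("window", 3)),
        conversion=conversion,
        restricted=list(cfg.get("restricted", []) or []),
        demand_table=demand_table,
        seed=int(cfg.get("seed", 0)),
        long_name=cfg.get("long_name", ""),
    )


def _extend_subtype(lu: LandUseMap, subtype: np.ndarray | None) -> np.ndarray | None:
    """Carry a subtype raster onto a simulated map.

    Construction cells without an inherited subtype become urban; unused
    cells without one become saline-alkali (the dominant unused subtype in
    the delta).
    """
    if subtype is None:
        return None
    sub = np.asarray(subtype).copy()
    constr = lu.codes == lu.code_of("construction")
    unused = lu.codes == lu.code_of("unused")
    sub[constr & ~np.isin(sub, (1, 2, 3, 4))] = 1
    sub[unused & ~np.isin(sub, (5, 6))] = 5
    sub[~constr & ~unused] = 0
    return sub


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    allocation: AllocationResult
    quality: QualityMap
    grade_table: pd.DataFrame
    summary: dict


def run_scenario(
    config: ScenarioConfig,
    lu_base: LandUseMap,
    model: SuitabilityModel,
    drivers,
    *,
    threats: list[ct.ThreatSpec] | None = None,
    sensitivity: ct.SensitivityTable | None = None,
    transition: TransitionMatrix | None = None,
    n_steps: float = DEFAULT_N_STEPS,
    redline: RestrictedMask | None = None,
    farmland: RestrictedMask | None = None,
    subtype: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    tol: int | None = None,
    max_iter: int = 300,
    out_dir: str | Path | None = None,
) -> ScenarioResult:
    """Simulate one scenario and score the resulting habitat quality.

    Deterministic given the scenario seed. The redline mask freezes cells
    outright; the farmland mask only freezes cells currently under
    cultivation (it protects cultivated land specifically).
    """
    threats = threats if threats is not None else ct.load_threat_specs()
    sensitivity = sensitivity if sensitivity is not None else ct.load_sensitivity()
    valid_total = int((~lu_base.nodata_mask).sum())

    if config.demand_source == "markov":
        if transition is None:
            raise ValueError("scenario demands a Markov projection but no transition matrix was given")
        demand = project_state(state_from_map(lu_base), transition, n_steps)
    else:
        demand = ct.demand_vector(
            config.name, lu_base.cell_size, valid_total, config.demand_table
        )

    frozen = np.zeros(lu_base.shape, dtype=bool)
    if "redline" in config.restricted:
        if redline is None:
            raise ValueError("scenario restricts the ecological redline but no redline mask was given")
        frozen |= redline.frozen
    if "farmland" in config.restricted:
        if farmland is None:
            raise ValueError("scenario restricts permanent farmland but no farmland mask was given")
        frozen |= farmland.frozen & (lu_base.codes == lu_base.code_of("cultivated"))

    sp = predict_suitability(model, drivers)
    alloc = run_allocation(
        sp,
        lu_base,
        demand,
        allow=config.conversion,
        weights=NeighborhoodWeights(config.weights, config.window),
        frozen=frozen,
        seed=config.seed,
        tol=tol,
        max_iter=max_iter,
    )

    lu_sim = alloc.landuse
    sub_sim = _extend_subtype(lu_sim, subtype)
    sources = derive_threat_sources(
        lu_sim,
        sub_sim,
        mapping=None if sub_sim is not None else NO_SUBTYPE_MAPPING,
        threat_names=[t.name for t in threats],
    )
    D = degradation_index(sources, threats, sensitivity, lu_sim, beta, normalize=True)
    Q = quality_map(D, lu_sim, sensitivity)
    _, grade_table = classify_grades(Q)
    stats = summarize_quality(Q)
    summary = {
        "scenario": config.name,
        "mean": stats["mean"],
        "sd": stats["sd"],
        **{g: p for g, p in stats["grades"].items()},
        "iterations": alloc.iterations,
        "residual_gap": int(alloc.residual_gap.max()),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_raster(lu_sim, out_dir / f"landuse_{config.name}.tif")
        write_raster(
            Q.Q, out_dir / f"quality_{config.name}.tif",
            cell_size=lu_sim.cell_size, nodata_mask=Q.nodata_mask,
        )
        grade_table.to_csv(out_dir / f"grades_{config.name}.csv", index=False)
    return ScenarioResult(config, alloc, Q, grade_table, summary)


@dataclass
class ChangeMap:
    name: str
    delta: np.ndarray  # scenario Q - baseline Q
    change_class: np.ndarray  # 0..4 per CHANGE_CLASS_NAMES
    nodata_mask: np.ndarray


def compare_scenarios(
    baseline: QualityMap,
    scenario_maps: list[QualityMap],
    names: list[str],
    bins: tuple[float, ...] = CHANGE_BINS,
) -> tuple[list[ChangeMap], pd.DataFrame]:
    """Quality change maps against a baseline plus a scenario ranking.

    The ranking orders scenarios both by mean quality and by the combined
    share of the High and Higher grades.
    """
    edges = np.asarray(bins, dtype=float)
    changes = []
    rows = []
    for Q, name in zip(scenario_maps, names):
        if Q.Q.shape != baseline.Q.shape:
            raise ValueError(f"scenario {name}: shape differs from baseline")
        mask = Q.nodata_mask | baseline.nodata_mask
        delta = Q.Q - baseline.Q
        cls = np.full(delta.shape, -1, dtype=np.int8)
        cls[~mask] = np.digitize(delta[~mask], edges, right=False)
        changes.append(ChangeMap(name, delta, cls, mask))
        stats = summarize_quality(Q)
        rows.append(
            {
                "scenario": name,
                "mean": stats["mean"],
                "high_higher_pct": stats["grades"].get("High", 0.0)
                + stats["grades"].get("Higher", 0.0),
            }
        )
    ranking = pd.DataFrame(rows)
    ranking["rank_by_mean"] = ranking["mean"].rank(ascending=False).astype(int)
    ranking["rank_by_high_share"] = (
        ranking["high_higher_pct"].rank(ascending=False).astype(int)
    )
    return changes, ranking.sort_values("rank_by_mean").reset_index(drop=True)
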