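"""Synthetic landscape generation.

Builds fully aligned synthetic inputs for the whole pipeline: a stack of
15 spatially autocorrelated driver rasters mirroring the field's usual
categories (terrain, distance-to-feature accessibility surfaces,
socioeconomic and climate fields), a calibration pair of land-use maps
generated under a known class-transition matrix, a threat-subtype raster,
and a restricted-area mask. Because the true transition process and the
driver-to-class rule are known, every downstream stage (Markov
estimation, neural suitability, CA allocation, quality scoring) can be
tested against the generator as an oracle.

The land class of a cell at t0 is a deterministic monotone function of
the drivers: cells are ranked by a fixed "development potential" score
(a weighted combination of accessibility, elevation and population
surfaces) and the ranked sequence is cut into contiguous quantile bands
sized by the target class proportions — ordered from water (least
developed) to construction (most developed). This yields spatially
coherent patches and makes the class recoverable from the drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import distance_transform_edt, gaussian_filter

from ._util import largest_remainder, split_seed
from .config_tables import (
    CLASS_NAMES,
    SensitivityTable,
    ThreatSpec,
    load_sensitivity,
    packaged,
)
from .grids import DEFAULT_CLASS_TABLE, DriverStack, LandUseMap, RestrictedMask
from .quality import (
    DegradationMap,
    QualityMap,
    degradation_brute_force,
    quality_map,
)

TERRAIN = ["elevation", "slope", "aspect"]
DISTANCES = [
    "dist_builtup",
    "dist_town",
    "dist_railway",
    "dist_highway",
    "dist_state_road",
    "dist_provincial_road",
    "dist_county_road",
    "dist_river",
]
SOCIOECONOMIC = ["population", "gdp"]
CLIMATE = ["temperature", "precipitation"]
DRIVER_NAMES = TERRAIN + DISTANCES + SOCIOECONOMIC + CLIMATE

#: Class order along the development-potential gradient, least to most.
GRADIENT_ORDER = [
    "water",
    "wetland",
    "unused",
    "grassland",
    "forest",
    "garden",
    "cultivated",
    "construction",
]

# Persistence-dominated default transition process: unused erodes into
# cultivated and construction, cultivated loses ground to construction,
# wetland exchanges a little with water — the delta's observed dynamic.
_DEFAULT_P = np.array(
    [
        # cult  gard  forest grass constr water wetl  unused
        [0.92, 0.00, 0.01, 0.00, 0.05, 0.01, 0.00, 0.01],  # cultivated
        [0.05, 0.90, 0.02, 0.00, 0.03, 0.00, 0.00, 0.00],  # garden
        [0.03, 0.00, 0.94, 0.00, 0.02, 0.01, 0.00, 0.00],  # forest
        [0.04, 0.00, 0.02, 0.90, 0.02, 0.01, 0.01, 0.00],  # grassland
        [0.01, 0.00, 0.00, 0.00, 0.98, 0.00, 0.00, 0.01],  # construction
        [0.01, 0.00, 0.00, 0.00, 0.01, 0.95, 0.03, 0.00],  # water
        [0.01, 0.00, 0.00, 0.00, 0.01, 0.04, 0.93, 0.01],  # wetland
        [0.08, 0.00, 0.01, 0.01, 0.04, 0.01, 0.02, 0.83],  # unused
    ]
)

_DEFAULT_PROPORTIONS = {
    "cultivated": 0.285,
    "garden": 0.005,
    "forest": 0.027,
    "grassland": 0.007,
    "construction": 0.157,
    "water": 0.225,
    "wetland": 0.141,
    "unused": 0.153,
}

_DEFAULT_SEED_COUNTS = {
    "dist_builtup": 4,
    "dist_town": 10,
    "dist_railway": 2,
    "dist_highway": 3,
    "dist_state_road": 4,
    "dist_provincial_road": 6,
    "dist_county_road": 12,
    "dist_river": 3,
}

SUBTYPE_CODES = {
    "urban": 1,
    "rural_residential": 2,
    "transportation": 3,
    "mining": 4,
    "saline_alkali": 5,
    "other_unused": 6,
}


@dataclass
class SyntheticSpec:
    shape: tuple[int, int] = (120, 120)
    cell_size: float = 30.0
    seed: int = 20170101
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    P_true: np.ndarray = field(default_factory=lambda: _DEFAULT_P.copy())
    driver_smoothing: float = 6.0
    distance_seed_counts: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SEED_COUNTS)
    )
    restricted_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.P_true = np.asarray(self.P_true, dtype=float)
        props = np.array([self.proportions[n] for n in CLASS_NAMES])
        if abs(props.sum() - 1) > 1e-6:
            raise ValueError("class proportions must sum to 1")
        rows = self.P_true.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-9):
            raise ValueError("P_true must be row-stochastic")
        if not 0 <= self.restricted_fraction < 1:
            raise ValueError("restricted_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "SyntheticSpec":
        with open(path or packaged("synthetic_spec.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        kwargs = {}
        for key in (
            "cell_size",
            "seed",
            "proportions",
            "driver_smoothing",
            "distance_seed_counts",
            "restricted_fraction",
        ):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "shape" in cfg:
            kwargs["shape"] = tuple(cfg["shape"])
        if "P_true" in cfg:
            kwargs["P_true"] = np.asarray(cfg["P_true"], dtype=float)
        return cls(**kwargs)


def random_field(
    shape: tuple[int, int], smoothing_scale: float, seed: int
) -> np.ndarray:
    """Spatially autocorrelated random field rescaled to [0, 1]."""
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be non-negative")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(shape)
    if smoothing_scale > 0:
        g = gaussian_filter(g, smoothing_scale, mode="reflect")
    lo, hi = g.min(), g.max()
    return (g - lo) / (hi - lo if hi > lo else 1.0)


def distance_surface(
    shape: tuple[int, int], n_seeds: int, seed: int, cell_size: float = 30.0
) -> np.ndarray:
    """Euclidean distance (meters) to the nearest of n random seed cells."""
    if n_seeds < 1:
        raise ValueError("need at least one seed point")
    rng = np.random.default_rng(seed)
    flat = rng.choice(shape[0] * shape[1], size=n_seeds, replace=False)
    mask = np.ones(shape, dtype=bool)
    mask.ravel()[flat] = False  # False marks the seeds for the EDT
    return distance_transform_edt(mask) * cell_size


def generate_drivers(spec: SyntheticSpec) -> DriverStack:
    seeds = split_seed(spec.seed, len(DRIVER_NAMES))
    layers = []
    for name, s in zip(DRIVER_NAMES, seeds):
        if name in DISTANCES:
            layers.append(
                distance_surface(
                    spec.shape, spec.distance_seed_counts.get(name, 5), s, spec.cell_size
                )
            )
        elif name == "slope":
            layers.append(random_field(spec.shape, spec.driver_smoothing / 2, s))
        elif name == "aspect":
            layers.append(random_field(spec.shape, spec.driver_smoothing / 3, s))
        else:
            layers.append(random_field(spec.shape, spec.driver_smoothing, s))
    return DriverStack(list(DRIVER_NAMES), np.stack(layers))


def _normalize01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo if hi > lo else 1.0)


def development_score(drivers: DriverStack) -> np.ndarray:
    """Deterministic development-potential score driving class assignment."""
    return (
        0.45 * (1.0 - _normalize01(drivers.layer("dist_builtup")))
        + 0.25 * drivers.layer("population")
        + 0.15 * drivers.layer("elevation")
        + 0.15 * (1.0 - _normalize01(drivers.layer("dist_river")))
    )


def _assign_classes(score: np.ndarray, proportions: dict[str, float]) -> np.ndarray:
    """Cut the score's rank order into class bands sized by proportion."""
    n = score.size
    counts = largest_remainder(
        np.array([proportions[name] for name in GRADIENT_ORDER]), n
    )
    order = np.argsort(score.ravel(), kind="stable")
    codes = np.empty(n, dtype=np.int32)
    code_of = {name: c for c, name in DEFAULT_CLASS_TABLE}
    start = 0
    for name, cnt in zip(GRADIENT_ORDER, counts):
        codes[order[start : start + cnt]] = code_of[name]
        start += cnt
    return codes.reshape(score.shape)


def _transition(
    t0: np.ndarray,
    P: np.ndarray,
    frozen: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Apply the transition matrix to unrestricted cells with clustering.

    Per source class the number of converting cells per target equals the
    largest-remainder apportionment of P's row over the class's mutable
    cells, so realized transition frequencies track P almost exactly.
    Converting cells are chosen by affinity (smoothed density of the
    target class plus a little noise), which clusters conversions into
    patches near existing target-class area.
    """
    rng = np.random.default_rng(seed)
    t1 = t0.copy()
    codes = np.array([c for c, _ in DEFAULT_CLASS_TABLE])
    affinity = {
        c: gaussian_filter((t0 == c).astype(float), 2.0)
        + 0.01 * rng.random(t0.shape)
        for c in codes
    }
    for ai, a in enumerate(codes):
        cells = np.argwhere((t0 == a) & ~frozen)
        if len(cells) == 0:
            continue
        n_to = largest_remainder(P[ai], len(cells))
        available = np.ones(len(cells), dtype=bool)
        for bi, b in enumerate(codes):
            if b == a or n_to[bi] == 0:
                continue
            aff = affinity[b][cells[:, 0], cells[:, 1]]
            aff = np.where(available, aff, -np.inf)
            take = np.argsort(-aff, kind="stable")[: n_to[bi]]
            t1[cells[take, 0], cells[take, 1]] = b
            available[take] = False
    return t1


def generate_landscape_pair(
    spec: SyntheticSpec,
) -> tuple[DriverStack, LandUseMap, LandUseMap, np.ndarray, RestrictedMask]:
    """Drivers, t0/t1 land-use pair, threat-subtype raster, restricted mask."""
    s_drivers, s_trans, s_restr, s_sub = split_seed(spec.seed + 1, 4)
    drivers = generate_drivers(spec)
    score = development_score(drivers)
    t0_codes = _assign_classes(score, spec.proportions)

    # restricted blob: the highest-quantile region of a smooth field
    n = t0_codes.size
    n_frozen = int(round(spec.restricted_fraction * n))
    blob = random_field(spec.shape, max(spec.driver_smoothing, 4.0), s_restr)
    frozen = np.zeros(spec.shape, dtype=bool)
    if n_frozen > 0:
        thresh = np.partition(blob.ravel(), n - n_frozen)[n - n_frozen]
        frozen = blob >= thresh
        frozen_flat = np.flatnonzero(frozen.ravel())
        if len(frozen_flat) > n_frozen:  # break threshold ties exactly
            drop = frozen_flat[n_frozen:]
            frozen.ravel()[drop] = False

    t1_codes = _transition(t0_codes, spec.P_true, frozen, s_trans)
    lu0 = LandUseMap(t0_codes, list(DEFAULT_CLASS_TABLE), spec.cell_size)
    lu1 = LandUseMap(t1_codes, list(DEFAULT_CLASS_TABLE), spec.cell_size)

    subtype = _subtype_raster(lu1, s_sub)
    return drivers, lu0, lu1, subtype, RestrictedMask(frozen)


def _subtype_raster(lu: LandUseMap, seed: int) -> np.ndarray:
    """Partition construction into urban/rural/transport/mining and unused
    into saline-alkali/other, spatially coherently."""
    field_c = random_field(lu.shape, 4.0, seed)
    sub = np.zeros(lu.shape, dtype=np.int8)
    constr = lu.codes == lu.code_of("construction")
    if constr.any():
        vals = field_c[constr]
        qs = np.quantile(vals, [0.5, 0.75, 0.9])
        band = np.digitize(field_c, qs)  # 0..3
        sub[constr] = np.array(
            [
                SUBTYPE_CODES["urban"],
                SUBTYPE_CODES["rural_residential"],
                SUBTYPE_CODES["transportation"],
                SUBTYPE_CODES["mining"],
            ]
        )[band[constr]]
    unused = lu.codes == lu.code_of("unused")
    if unused.any():
        thresh = np.quantile(field_c[unused], 0.7)
        sub[unused] = np.where(
            field_c[unused] <= thresh,
            SUBTYPE_CODES["saline_alkali"],
            SUBTYPE_CODES["other_unused"],
        )
    return sub


def generate_quality_fixture(
    kind: str, shape: tuple[int, int] = (16, 16), cell_size: float = 30.0
) -> tuple[LandUseMap, dict[str, np.ndarray], list[ThreatSpec], SensitivityTable, QualityMap]:
    """Small land-use + threat fixtures with the expected quality raster.

    The expected raster is computed with the literal brute-force
    degradation sum, so these fixtures serve as oracles for the optimized
    path. Kinds: ``no_threat`` (all forest, no sources), ``single_threat``
    (all forest plus one construction source cell), ``worked`` (the
    hand-checkable case: one linear threat with d_max = 2 cells,
    sensitivity and suitability 1, giving Q = 0.5 at distance one cell).
    """
    sens = load_sensitivity()
    code_of = {name: c for c, name in DEFAULT_CLASS_TABLE}
    codes = np.full(shape, code_of["forest"], dtype=np.int32)
    if kind == "no_threat":
        lu = LandUseMap(codes, list(DEFAULT_CLASS_TABLE), cell_size)
        sources = {t: np.zeros(shape, dtype=bool) for t in sens.sensitivity.columns}
        specs = [ThreatSpec("urban", 10, 1.0, "exponential")]
    elif kind == "single_threat":
        codes[shape[0] // 2, shape[1] // 2] = code_of["construction"]
        lu = LandUseMap(codes, list(DEFAULT_CLASS_TABLE), cell_size)
        sources = {t: np.zeros(shape, dtype=bool) for t in sens.sensitivity.columns}
        sources["urban"] = lu.codes == code_of["construction"]
        specs = [ThreatSpec("urban", 10, 1.0, "exponential")]
    elif kind == "worked":
        codes[0, 0] = code_of["construction"]
        lu = LandUseMap(codes, list(DEFAULT_CLASS_TABLE), cell_size)
        sources = {"worked": lu.codes == code_of["construction"]}
        specs = [ThreatSpec("worked", 2 * cell_size / 1000.0, 1.0, "linear")]
        habitat = sens.habitat.map(lambda _: 1.0).astype(float)
        habitat["construction"] = 0.0  # the source cell itself is no habitat
        sens = SensitivityTable(
            habitat=habitat,
            sensitivity=sens.sensitivity.map(lambda _: 1.0).assign(worked=1.0),
        )
    elif kind == "all_construction":
        codes[:] = code_of["construction"]
        lu = LandUseMap(codes, list(DEFAULT_CLASS_TABLE), cell_size)
        sources = {"urban": np.ones(shape, dtype=bool)}
        specs = [ThreatSpec("urban", 10, 1.0, "exponential")]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    D = degradation_brute_force(sources, specs, sens, lu)
    expected = quality_map(D, lu, sens)
    return lu, sources, specs, sens, expected
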