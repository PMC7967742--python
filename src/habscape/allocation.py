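"""Cellular-automaton land allocation with self-adaptive inertia.

Each iteration scores every mutable cell for every land class as the
product of four factors — neural suitability probability, neighborhood
effect, a per-class inertia coefficient, and the binary conversion
allowance — then lets classes compete for cells (roulette-wheel draw by
default) until the per-class allocation matches the demand vector within
tolerance.

The inertia coefficient self-corrects: while a class's gap between demand
and allocation keeps shrinking it is left alone; when the gap worsens the
coefficient is scaled by the ratio of the last two gaps, boosting classes
that fall behind demand and damping classes that overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from sklearn.metrics import accuracy_score, cohen_kappa_score, confusion_matrix

from .grids import ConversionMatrix, DemandVector, LandUseMap, RestrictedMask
from .suitability import SuitabilityStack

INERTIA_CLAMP = (1e-3, 1e3)


@dataclass
class NeighborhoodWeights:
    """Per-class neighborhood weights and the (odd) window size."""

    omega: np.ndarray  # per class, canonical order
    window: int = 3

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.omega < 0) or np.any(self.omega > 1):
            raise ValueError("neighborhood weights must be in [0, 1]")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


@dataclass
class InertiaState:
    """Per-class inertia coefficients with the last two demand gaps.

    Gaps use the convention D = demand - allocated, so positive D means
    the class is under-allocated.
    """

    inertia: np.ndarray
    D_prev1: np.ndarray | None = None  # gap at iteration t-1
    D_prev2: np.ndarray | None = None  # gap at iteration t-2

    @classmethod
    def initial(cls, k: int) -> "InertiaState":
        return cls(np.ones(k))


def update_inertia(state: InertiaState) -> InertiaState:
    """Advance the inertia coefficients one iteration.

    Per class: keep the coefficient while the absolute gap is not growing;
    if an under-allocation (positive gap) worsens, multiply by
    D^{t-1}/D^{t-2} (> 1); if an over-allocation (negative gap) worsens,
    multiply by D^{t-2}/D^{t-1} (< 1). Coefficients are clamped to
    [1e-3, 1e3].
    """
    if state.D_prev1 is None or state.D_prev2 is None:
        return InertiaState(state.inertia.copy(), state.D_prev1, state.D_prev2)
    d1 = np.asarray(state.D_prev1, dtype=float)
    d2 = np.asarray(state.D_prev2, dtype=float)
    out = state.inertia.copy()
    worsening = np.abs(d1) > np.abs(d2)
    under = worsening & (d1 > d2) & (d2 > 0)
    over = worsening & (d1 < d2) & (d2 < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[under] *= d1[under] / d2[under]
        out[over] *= d2[over] / d1[over]
    out = np.clip(out, *INERTIA_CLAMP)
    return InertiaState(out, state.D_prev1, state.D_prev2)


def neighborhood_effect(
    lu: LandUseMap, class_code: int, weights: NeighborhoodWeights
) -> np.ndarray:
    """Neighborhood effect raster for one class.

    The share of class-``class_code`` cells among the N*N - 1 neighbors of
    each cell (center excluded), scaled by the class weight. Neighbors
    outside the raster or in nodata count as absent while the denominator
    stays N*N - 1.
    """
    n = weights.window
    kernel = np.ones((n, n))
    kernel[n // 2, n // 2] = 0.0
    indicator = ((lu.codes == class_code) & ~lu.nodata_mask).astype(float)
    counts = convolve(indicator, kernel, mode="constant", cval=0.0)
    idx = int(np.where(lu.class_codes == class_code)[0][0])
    return counts / (n * n - 1) * weights.omega[idx]


def combined_probability(
    sp: SuitabilityStack,
    omega: np.ndarray,
    inertia: InertiaState,
    allow: ConversionMatrix,
    lu_current: LandUseMap,
) -> np.ndarray:
    """Total transition score TProb = sp * omega * inertia * (1 - cost).

    ``omega`` is the (K, rows, cols) stack of neighborhood-effect rasters;
    the conversion cost is 1 - allow[current class, target class], so a
    forbidden transition scores exactly 0 and the self-transition (always
    allowed) is always scored.
    """
    codes = lu_current.class_codes
    index = {c: i for i, c in enumerate(codes)}
    safe_codes = np.where(lu_current.nodata_mask, codes[0], lu_current.codes)
    cur_idx = np.vectorize(index.get)(safe_codes)
    allow_per_cell = allow.allow[cur_idx]  # (rows, cols, K)
    tprob = sp.sp * np.asarray(omega)
    tprob = tprob * inertia.inertia[:, None, None]
    tprob = tprob * np.moveaxis(allow_per_cell, -1, 0)
    return tprob


@dataclass
class AllocationResult:
    landuse: LandUseMap
    iterations: int
    residual_gap: np.ndarray  # per-class |demand - allocated|, cells
    trajectory: list[float] = field(default_factory=list)  # max gap per iteration
    converged: bool = False


class AllocationInfeasibleError(RuntimeError):
    def __init__(self, message: str, diagnosis: pd.DataFrame | None = None):
        super().__init__(message)
        self.diagnosis = diagnosis


def _reconcile_demand(
    demand: DemandVector, lu: LandUseMap, frozen: np.ndarray
) -> np.ndarray:
    """Demand over mutable cells: full demand minus the frozen composition."""
    from ._util import largest_remainder

    codes = lu.class_codes
    valid = ~lu.nodata_mask
    frozen_counts = np.array(
        [((lu.codes == c) & valid & frozen).sum() for c in codes], dtype=np.int64
    )
    mutable_total = int((valid & ~frozen).sum())
    md = np.asarray(demand.counts, dtype=np.int64) - frozen_counts
    if md.sum() != mutable_total or np.any(md < 0):
        md = largest_remainder(np.clip(md, 0, None), mutable_total)
    return md


def run_allocation(
    sp: SuitabilityStack,
    lu_t: LandUseMap,
    demand: DemandVector,
    *,
    allow: ConversionMatrix,
    weights: NeighborhoodWeights,
    frozen: RestrictedMask | np.ndarray | None = None,
    seed: int = 0,
    tol: int | None = None,
    max_iter: int = 300,
    selection: str = "roulette",
    omega_floor: float = 1e-3,
) -> AllocationResult:
    """Iterate the CA competition until demands are met.

    ``demand`` covers the whole (non-nodata) landscape; the classes of
    frozen cells are subtracted internally. ``tol`` defaults to 0.1% of
    the mutable cell count. A cell only changes class when its current
    class is over-allocated and the drawn class is still under demand, so
    the maximum residual gap never increases across iterations.
    """
    if selection not in ("roulette", "argmax"):
        raise ValueError(f"unknown selection rule {selection!r}")
    codes = lu_t.class_codes
    k = len(codes)
    index = {c: i for i, c in enumerate(codes)}
    valid = ~lu_t.nodata_mask
    if frozen is None:
        frozen_arr = np.zeros(lu_t.shape, dtype=bool)
    else:
        frozen_arr = frozen.frozen if isinstance(frozen, RestrictedMask) else np.asarray(frozen, dtype=bool)
    frozen_arr = frozen_arr & valid
    mutable = valid & ~frozen_arr
    mutable_total = int(mutable.sum())
    if demand.total != int(valid.sum()):
        raise ValueError(
            f"demand total {demand.total} differs from landscape cell count {int(valid.sum())}"
        )
    order_map = {c: i for i, c in enumerate(np.asarray(demand.classes))}
    demand_aligned = DemandVector(
        np.array([demand.counts[order_map[c]] for c in codes]), codes
    )
    full_counts = lu_t.counts()
    if mutable_total == 0 and np.any(demand_aligned.counts != full_counts):
        raise AllocationInfeasibleError(
            "all cells are frozen but demand differs from the current composition"
        )
    md = _reconcile_demand(demand_aligned, lu_t, frozen_arr)

    work = lu_t.codes.copy()
    cur_idx_full = np.vectorize(index.get)(np.where(valid, work, codes[0]))
    mut_flat = np.flatnonzero(mutable.ravel())
    cur = cur_idx_full.ravel()[mut_flat].copy()
    cur_counts = np.bincount(cur, minlength=k).astype(np.int64)

    # feasibility: every deficit class needs enough convertible donor cells
    deficit = md - cur_counts
    rows = []
    feasible = True
    for p in range(k):
        if deficit[p] > 0:
            donors = sum(
                int(cur_counts[c])
                for c in range(k)
                if c != p and allow.allow[c, p] == 1
            )
            ok = donors >= deficit[p]
            feasible &= ok
            rows.append((str(codes[p]), int(deficit[p]), donors, ok))
    if mutable_total == 0 and np.any(deficit != 0):
        raise AllocationInfeasibleError(
            "all cells are frozen but demand differs from the current composition"
        )
    if not feasible:
        diag = pd.DataFrame(rows, columns=["class", "deficit", "donor_cells", "feasible"])
        raise AllocationInfeasibleError(
            "demand is unreachable under the conversion allowances", diag
        )

    if tol is None:
        tol = max(1, int(round(0.001 * mutable_total)))
    rng = np.random.default_rng(seed)
    sp_rows = sp.sp.reshape(k, -1)[:, mut_flat].T  # (n_mut, K)
    sp_rows = np.nan_to_num(sp_rows, nan=0.0)
    allow_f = allow.allow.astype(float)

    state = InertiaState.initial(k)
    trajectory: list[float] = []
    iterations = 0
    relaxed = False
    wlu = LandUseMap(work, list(lu_t.class_table), lu_t.cell_size, lu_t.nodata_mask)

    for _ in range(max_iter):
        D = md - cur_counts
        gap = int(np.max(np.abs(D)))
        if gap <= tol:
            break
        iterations += 1
        trajectory.append(float(gap))

        state = update_inertia(state)
        omega = np.stack(
            [neighborhood_effect(wlu, c, weights) for c in codes]
        )
        omega = np.maximum(omega, omega_floor)  # let absent classes nucleate
        om_rows = omega.reshape(k, -1)[:, mut_flat].T
        scores = sp_rows * om_rows * state.inertia[None, :] * allow_f[cur]
        receivable = D > 0
        col_mask = receivable[None, :] | (np.arange(k)[None, :] == cur[:, None])
        scores = scores * col_mask

        if selection == "argmax":
            tot = scores.sum(axis=1)
            proposed = np.argmax(scores, axis=1)
            proposed[tot <= 0] = cur[tot <= 0]
        else:
            cum = np.cumsum(scores, axis=1)
            tot = cum[:, -1]
            u = rng.random(len(cur)) * tot
            proposed = (u[:, None] >= cum).sum(axis=1)
            proposed = np.minimum(proposed, k - 1)
            proposed[tot <= 0] = cur[tot <= 0]

        changers = np.flatnonzero(proposed != cur)
        accepted = 0
        if len(changers):
            for i in rng.permutation(changers):
                c, p = cur[i], proposed[i]
                donor_ok = cur_counts[c] > md[c] or (relaxed and cur_counts[c] >= md[c])
                if donor_ok and cur_counts[p] < md[p]:
                    cur[i] = p
                    cur_counts[c] -= 1
                    cur_counts[p] += 1
                    accepted += 1
        relaxed = accepted == 0
        assert int(cur_counts.sum()) == mutable_total  # conservation
        work.ravel()[mut_flat] = codes[cur]
        state = InertiaState(state.inertia, md - cur_counts, state.D_prev1)

    D = md - cur_counts
    gap = int(np.max(np.abs(D))) if k else 0
    result_lu = LandUseMap(
        work, list(lu_t.class_table), lu_t.cell_size, lu_t.nodata_mask.copy()
    )
    return AllocationResult(
        landuse=result_lu,
        iterations=iterations,
        residual_gap=np.abs(D),
        trajectory=trajectory,
        converged=gap <= tol,
    )


@dataclass
class ValidationReport:
    overall: float
    kappa: float
    confusion: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"overall accuracy {self.overall:.4f}, kappa {self.kappa:.4f}"


def validate_map(simulated: LandUseMap, observed: LandUseMap) -> ValidationReport:
    """Cell-wise agreement between a simulated and an observed map.

    Overall accuracy is the fraction of agreeing cells; kappa is the
    chance-corrected agreement (p_o - p_e) / (1 - p_e) with the expected
    agreement p_e from the marginal products. When p_e = 1 (both maps
    constant and equal) kappa is undefined and reported as NaN.
    """
    if simulated.shape != observed.shape:
        raise ValueError("maps differ in shape")
    valid = ~simulated.nodata_mask & ~observed.nodata_mask
    a = simulated.codes[valid]
    b = observed.codes[valid]
    labels = np.asarray(simulated.class_codes)
    cm = confusion_matrix(b, a, labels=labels)
    overall = float(accuracy_score(b, a))
    n = cm.sum()
    p_e = float((cm.sum(0) / n) @ (cm.sum(1) / n))
    kappa = float("nan") if p_e >= 1.0 else float(cohen_kappa_score(b, a))
    names = [n_ for _, n_ in simulated.class_table]
    return ValidationReport(
        overall, kappa, pd.DataFrame(cm, index=names, columns=names)
    )
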