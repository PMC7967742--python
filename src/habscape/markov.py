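"""Markov-chain demand projection.

The transition model assumes the land system is a first-order Markov chain
over the K land classes: the state (per-class cell counts) at the next
time point is ``S_{t+1} = S_t P``, with ``P`` the row-stochastic matrix of
class-to-class transition probabilities estimated from a calibration pair
of land-use maps. Projecting over a horizon that is not an integer
multiple of the calibration interval uses a fractional matrix power (see
:func:`project_state`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import fractional_matrix_power

from ._util import largest_remainder
from .grids import DemandVector, LandUseMap, TransitionMatrix


@dataclass
class StateVector:
    """Per-class cell counts at one time point."""

    counts: np.ndarray
    classes: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = np.asarray(self.classes)
        if np.any(self.counts < 0):
            raise ValueError("state counts must be non-negative")


def state_from_map(lu: LandUseMap, year: int | None = None) -> StateVector:
    return StateVector(lu.counts(), lu.class_codes, year)


def crosstab_transitions(lu_t0: LandUseMap, lu_t1: LandUseMap) -> np.ndarray:
    """K x K matrix of cell counts: entry (a, b) = cells that went a -> b."""
    if lu_t0.shape != lu_t1.shape:
        raise ValueError("calibration maps differ in shape")
    if list(lu_t0.class_table) != list(lu_t1.class_table):
        raise ValueError("calibration maps differ in class table")
    if not np.array_equal(lu_t0.nodata_mask, lu_t1.nodata_mask):
        raise ValueError("calibration maps differ in nodata mask")
    valid = ~lu_t0.nodata_mask
    codes = lu_t0.class_codes
    # map codes to 0..K-1 indices, then 2-D histogram
    index = {c: i for i, c in enumerate(codes)}
    a = np.vectorize(index.get)(lu_t0.codes[valid])
    b = np.vectorize(index.get)(lu_t1.codes[valid])
    k = len(codes)
    return np.bincount(a * k + b, minlength=k * k).reshape(k, k)


def estimate_transition_matrix(
    crosstab: np.ndarray, interval_years: float = 1.0, classes: np.ndarray | None = None
) -> TransitionMatrix:
    """Row-normalize a transition crosstab into probabilities.

    Classes absent at t0 (zero row total) receive an identity row so the
    matrix stays row-stochastic.
    """
    crosstab = np.asarray(crosstab, dtype=float)
    k = crosstab.shape[0]
    if classes is None:
        classes = np.arange(1, k + 1)
    totals = crosstab.sum(axis=1)
    P = np.eye(k)
    present = totals > 0
    P[present] = crosstab[present] / totals[present, None]
    return TransitionMatrix(P, classes, interval_years)


def _matrix_power_fractional(P: np.ndarray, n: float) -> np.ndarray:
    """P**n for possibly fractional n, with a safe fallback.

    The principal fractional power can leave the stochastic cone (negative
    or complex entries). When that happens beyond 1e-9, fall back to linear
    interpolation between the bracketing integer powers and warn.
    """
    if float(n).is_integer():
        return np.linalg.matrix_power(P, int(n))
    Pn = fractional_matrix_power(P, n)
    if np.max(np.abs(np.imag(Pn))) <= 1e-9 and np.min(np.real(Pn)) >= -1e-9:
        Pn = np.clip(np.real(Pn), 0, None)
        return Pn / Pn.sum(axis=1, keepdims=True)
    warnings.warn(
        "fractional matrix power left the stochastic cone; "
        "falling back to interpolation between integer powers",
        RuntimeWarning,
        stacklevel=2,
    )
    lo = int(np.floor(n))
    frac = n - lo
    P_lo = np.linalg.matrix_power(P, lo)
    P_hi = np.linalg.matrix_power(P, lo + 1)
    return (1 - frac) * P_lo + frac * P_hi


def project_state(
    S_t: StateVector, P: TransitionMatrix, n_steps: float = 1.0
) -> DemandVector:
    """Project class demands ``S_t P**n`` and round to integer cell counts.

    Rounding uses the largest-remainder method so the projected total
    equals the input total exactly for every ``n_steps``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    Pn = _matrix_power_fractional(P.P, n_steps)
    raw = np.asarray(S_t.counts, dtype=float) @ Pn
    counts = largest_remainder(raw, int(S_t.counts.sum()))
    return DemandVector(counts, np.asarray(S_t.classes))
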