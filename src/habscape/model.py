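"""High-level Model/Results facade over the pipeline stages.

``LandUseModel`` is constructed from the calibration data (the t0/t1
land-use pair and the driver stack); ``fit`` estimates the class
transition matrix and trains the neural suitability surfaces, returning a
``LandUseModelResults`` that carries the estimates and diagnostics and
exposes scenario simulation and habitat-quality scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config_tables as ct
from .allocation import ValidationReport, validate_map
from .grids import DriverStack, LandUseMap, RestrictedMask, TransitionMatrix
from .markov import crosstab_transitions, estimate_transition_matrix
from .scenarios import (
    DEFAULT_N_STEPS,
    ScenarioConfig,
    ScenarioResult,
    load_scenario,
    run_scenario,
)
from .suitability import SuitabilityModel, fit_suitability


@dataclass
class LandUseModel:
    """Coupled land-use-change model built from a calibration map pair."""

    lu_t0: LandUseMap
    lu_t1: LandUseMap
    drivers: DriverStack
    interval_years: float = 8.0

    def fit(
        self,
        seed: int = 0,
        hidden_size: int = 12,
        sample_fraction: float = 0.05,
        epochs: int = 200,
    ) -> "LandUseModelResults":
        """Estimate the transition matrix and train the suitability network.

        The network is trained on the t1 map (the latest observed state),
        the transition matrix on the full t0 -> t1 crosstab.
        """
        crosstab = crosstab_transitions(self.lu_t0, self.lu_t1)
        transition = estimate_transition_matrix(
            crosstab, self.interval_years, self.lu_t0.class_codes
        )
        suit = fit_suitability(
            self.lu_t1,
            self.drivers,
            fraction=sample_fraction,
            hidden_size=hidden_size,
            epochs=epochs,
            seed=seed,
        )
        return LandUseModelResults(self, transition, suit, crosstab)


@dataclass
class LandUseModelResults:
    model: LandUseModel
    transition_matrix: TransitionMatrix
    suitability_model: SuitabilityModel
    crosstab: np.ndarray
    _validation: ValidationReport | None = field(default=None, repr=False)

    def simulate(
        self,
        scenario: str | ScenarioConfig,
        *,
        redline: RestrictedMask | None = None,
        farmland: RestrictedMask | None = None,
        subtype: np.ndarray | None = None,
        beta: np.ndarray | None = None,
        n_steps: float = DEFAULT_N_STEPS,
        **kwargs,
    ) -> ScenarioResult:
        """Run one scenario from the fitted state (base map = t1)."""
        config = scenario if isinstance(scenario, ScenarioConfig) else load_scenario(scenario)
        return run_scenario(
            config,
            self.model.lu_t1,
            self.suitability_model,
            self.model.drivers,
            transition=self.transition_matrix,
            n_steps=n_steps,
            redline=redline,
            farmland=farmland,
            subtype=subtype,
            beta=beta,
            **kwargs,
        )

    def validate(self, seed: int = 0, **kwargs) -> ValidationReport:
        """Hindcast t1 from t0 and compare with the observed t1 map.

        Uses the estimated one-interval transition matrix for demand and a
        business-as-usual parameter set (S1 weights and allowances).
        """
        from .markov import project_state, state_from_map

        s1 = load_scenario("S1")
        s1.seed = seed
        demand = project_state(
            state_from_map(self.model.lu_t0), self.transition_matrix, 1.0
        )
        from .allocation import NeighborhoodWeights, run_allocation
        from .suitability import predict_suitability

        sp = predict_suitability(self.suitability_model, self.model.drivers)
        alloc = run_allocation(
            sp,
            self.model.lu_t0,
            demand,
            allow=s1.conversion,
            weights=NeighborhoodWeights(s1.weights, s1.window),
            seed=seed,
            **kwargs,
        )
        self._validation = validate_map(alloc.landuse, self.model.lu_t1)
        return self._validation

    def summary(self) -> str:
        """Plain-text summary of the fitted components."""
        names = self.model.lu_t0.class_names
        P = pd.DataFrame(self.transition_matrix.P, index=names, columns=names)
        lines = [
            "Land-use change model",
            "=" * 60,
            f"landscape: {self.model.lu_t0.shape[0]} x {self.model.lu_t0.shape[1]} cells "
            f"@ {self.model.lu_t0.cell_size:g} m",
            f"calibration interval: {self.model.interval_years:g} years",
            f"suitability network: {len(self.suitability_model.input_names)} drivers -> "
            f"{self.suitability_model.hidden_size} hidden -> {len(names)} classes "
            f"(seed {self.suitability_model.rng_seed})",
            "",
            "Transition probability matrix (rows: from, columns: to):",
            P.round(4).to_string(),
        ]
        if self._validation is not None:
            lines += [
                "",
                f"hindcast validation: overall accuracy {self._validation.overall:.4f}, "
                f"kappa {self._validation.kappa:.4f}",
            ]
        return "\n".join(lines)

    def plot_quality(self, result: ScenarioResult, ax=None):  # pragma: no cover
        """Render a scenario's quality raster (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(result.quality.Q, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"habitat quality — {result.config.name}")
        plt.colorbar(im, ax=ax, label="Q")
        return ax
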