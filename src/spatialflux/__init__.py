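"""spatialflux: steady-state kinetics of spatially organized two-enzyme pathways.

Models a sequential two-enzyme pathway in a spherical bacterial cell, with
the enzymes either free in the cytosol, co-localized on a scaffold, or
encapsulated in a microcompartment organelle, and maps which organization
strategy maximizes pathway flux or minimizes intermediate leakage across
kinetic, transport and culture parameters.
"""

from __future__ import annotations

from .analytic import cytosol_concentration, solve_organized
from .calibration import (
    GrowthObservation,
    TiterObservation,
    flux_from_growth,
    flux_from_titer,
)
from .config import load_config, save_config, spec_from_dict, spec_to_dict
from .core import (
    EnzymeKinetics,
    ExternalConditions,
    Geometry,
    RateLaw,
    Strategy,
    SystemSpec,
    TransportParams,
    apply_fold_change,
    michaelis_menten_rate,
    reversible_interconversion_rate,
    vmax_from_copies,
)
from .design_space import (
    StrategyMap,
    SweepResult,
    kcatE0_path,
    optimal_strategy_map,
    resolve_param,
    set_param,
    sweep_1d,
)
from .errors import (
    ConvergenceError,
    InvalidParameterError,
    NotConvergedError,
    UnknownPresetError,
)
from .metrics import (
    StrategyComparison,
    compare_strategies,
    cytosol_gradient,
    flux_budget,
    intermediate_leakage,
    pathway_flux,
)
from .numeric import (
    RadialGrid,
    make_grid,
    solve_organized_numeric,
    solve_unorganized,
)
from .presets import PRESET_NAMES, preset
from .solution import SteadyStateSolution

__version__ = "0.1.0"


def solve_steady_state(spec: SystemSpec, method: str = "auto", **kwargs):
    """Solve a system with the route appropriate to its strategy.

    Organized strategies use the closed-form well-mixed-compartment solver
    (``method="numeric"`` forces the finite-volume route instead); the
    unorganized case always uses the finite-volume solver.
    """
    if spec.strategy.organized:
        if method == "numeric":
            return solve_organized_numeric(spec, **kwargs)
        return solve_organized(spec, **kwargs)
    return solve_unorganized(spec, **kwargs)


__all__ = [
    "EnzymeKinetics",
    "TransportParams",
    "Geometry",
    "ExternalConditions",
    "SystemSpec",
    "Strategy",
    "RateLaw",
    "SteadyStateSolution",
    "StrategyComparison",
    "StrategyMap",
    "SweepResult",
    "RadialGrid",
    "GrowthObservation",
    "TiterObservation",
    "michaelis_menten_rate",
    "reversible_interconversion_rate",
    "vmax_from_copies",
    "apply_fold_change",
    "preset",
    "PRESET_NAMES",
    "load_config",
    "save_config",
    "spec_to_dict",
    "spec_from_dict",
    "solve_steady_state",
    "solve_organized",
    "solve_organized_numeric",
    "solve_unorganized",
    "make_grid",
    "cytosol_concentration",
    "pathway_flux",
    "intermediate_leakage",
    "flux_budget",
    "cytosol_gradient",
    "compare_strategies",
    "sweep_1d",
    "optimal_strategy_map",
    "kcatE0_path",
    "set_param",
    "resolve_param",
    "flux_from_growth",
    "flux_from_titer",
    "ConvergenceError",
    "InvalidParameterError",
    "NotConvergedError",
    "UnknownPresetError",
]
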