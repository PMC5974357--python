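"""Derived per-cell quantities and pairwise strategy comparison.

All fluxes are per-cell rates in umol/cell/s.  ``pathway_flux`` is defined as
product formation — the total rate of the second reaction — which at steady
state equals substrate consumption minus intermediate leakage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .core import (
    STRATEGY_PREFERENCE,
    Strategy,
    SystemSpec,
    UM_CM3_TO_UMOL,
)
from .errors import ConvergenceError, NotConvergedError
from .solution import SteadyStateSolution

__all__ = [
    "flux_budget",
    "pathway_flux",
    "intermediate_leakage",
    "cytosol_gradient",
    "StrategyComparison",
    "compare_strategies",
    "OBJECTIVES",
]

_FOUR_PI = 4.0 * math.pi
OBJECTIVES = ("max_flux", "min_leakage")


def _require_converged(solution: SteadyStateSolution) -> None:
    if not solution.converged:
        raise NotConvergedError(
            f"solution not converged (residual {solution.residual_norm:.3e}); "
            "metrics refuse unconverged states"
        )


def flux_budget(
    solution: SteadyStateSolution, spec: Optional[SystemSpec] = None
) -> Dict[str, Optional[float]]:
    """All steady-state transport and reaction totals (umol/cell/s).

    Returns substrate membrane influx, compartment-boundary transfer of both
    species (None for the unorganized case), the volume-integrated reaction
    totals, and the membrane efflux of the intermediate.  At steady state the
    substrate entries agree with the first-reaction total and the S2 entries
    close the balance; the mutual agreement of these independently computed
    numbers is the solver's mass-conservation audit.
    """
    _require_converged(solution)
    spec = spec if spec is not None else solution.spec
    g = spec.geometry
    tr = spec.transport
    cond = spec.conditions

    influx_S1 = (
        _FOUR_PI * g.R_b**2 * tr.k_m_S1 * (cond.S1_out - solution.S1_at_Rb)
    ) * UM_CM3_TO_UMOL
    leak_S2 = (
        _FOUR_PI * g.R_b**2 * tr.k_m_S2 * (solution.S2_at_Rb - cond.S2_out)
    ) * UM_CM3_TO_UMOL

    if solution.method == "analytic":
        V_c = spec.compartment_volume
        r1_total = V_c * spec.rate1(
            solution.S1_compartment, solution.S2_compartment
        ) * UM_CM3_TO_UMOL
        r2_total = V_c * spec.rate2(solution.S2_compartment) * UM_CM3_TO_UMOL
        transfer_S1 = (
            _FOUR_PI * g.R_c**2 * spec.kc_S1
            * (solution.S1_at_Rc - solution.S1_compartment)
        ) * UM_CM3_TO_UMOL
        transfer_S2 = (
            _FOUR_PI * g.R_c**2 * spec.kc_S2
            * (solution.S2_compartment - solution.S2_at_Rc)
        ) * UM_CM3_TO_UMOL
    else:
        mask = solution.reactive
        S1 = solution.S1_profile[mask]
        S2 = solution.S2_profile[mask]
        w = solution.cv_volumes[mask]
        r1_total = float(np.sum(spec.rate1(S1, S2) * w)) * UM_CM3_TO_UMOL
        r2_total = float(np.sum(spec.rate2(S2) * w)) * UM_CM3_TO_UMOL
        if solution.i_interface is not None:
            i = solution.i_interface
            transfer_S1 = (
                _FOUR_PI * g.R_c**2 * spec.kc_S1
                * (solution.S1_profile[i] - solution.S1_profile[i - 1])
            ) * UM_CM3_TO_UMOL
            transfer_S2 = (
                _FOUR_PI * g.R_c**2 * spec.kc_S2
                * (solution.S2_profile[i - 1] - solution.S2_profile[i])
            ) * UM_CM3_TO_UMOL
        else:
            transfer_S1 = transfer_S2 = None

    return {
        "substrate_influx": influx_S1,
        "compartment_transfer_S1": transfer_S1,
        "compartment_transfer_S2": transfer_S2,
        "reaction1_total": r1_total,
        "reaction2_total": r2_total,
        "intermediate_leakage": leak_S2,
    }


def pathway_flux(
    solution: SteadyStateSolution,
    spec: Optional[SystemSpec] = None,
    check_tol: float = 1e-6,
) -> float:
    """Per-cell product formation rate (umol/cell/s).

    Computed as the volume integral of the second reaction; cross-checked
    against the independent boundary-transport balance (substrate influx
    minus intermediate leakage), which must agree within ``check_tol``
    relative for a trustworthy steady state.
    """
    budget = flux_budget(solution, spec)
    reaction = budget["reaction2_total"]
    balance = budget["substrate_influx"] - budget["intermediate_leakage"]
    # the balance route is a difference of transport terms, so the identity
    # can only hold to check_tol relative to their magnitude, not to the
    # (possibly strongly cancelling) net flux
    scale = max(
        abs(reaction),
        abs(balance),
        abs(budget["substrate_influx"]),
        abs(budget["intermediate_leakage"]),
        1e-300,
    )
    if abs(reaction - balance) / scale > check_tol:
        raise NotConvergedError(
            "pathway flux dual formulas disagree: "
            f"reaction integral {reaction:.6e} vs boundary balance {balance:.6e}"
        )
    return reaction


def intermediate_leakage(
    solution: SteadyStateSolution, spec: Optional[SystemSpec] = None
) -> float:
    """Membrane efflux of the intermediate, 4 pi R_b^2 k_m (S2(R_b) - S2_out)."""
    budget = flux_budget(solution, spec)
    return budget["intermediate_leakage"]


def cytosol_gradient(
    solution: SteadyStateSolution, eps: float = 1e-30
) -> Dict[str, float]:
    """Relative draw-down of each species across the cytosol shell.

    Returns ``(S(R_b) - S(R_c)) / max(S(R_b), eps)`` per species (signed; the
    intermediate is higher at the compartment boundary, giving a negative
    value).  A small magnitude for S1 supports the constant-far-field
    approximation of the substrate supply.
    """
    _require_converged(solution)
    if solution.S1_at_Rc is None:
        raise NotConvergedError("cytosol_gradient requires an organized solution")
    out = {}
    for sp, rb, rc in (
        ("S1", solution.S1_at_Rb, solution.S1_at_Rc),
        ("S2", solution.S2_at_Rb, solution.S2_at_Rc),
    ):
        out[sp] = (rb - rc) / max(rb, eps)
    return out


@dataclass
class StrategyComparison:
    """Objective values of each organization strategy and the winner."""

    objective: str
    values: Dict[Strategy, float]
    best: Strategy
    tie: bool
    partial: bool = False
    failures: Dict[Strategy, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "objective": self.objective,
            "values": {s.value: v for s, v in self.values.items()},
            "best": self.best.value,
            "tie": self.tie,
            "partial": self.partial,
            "failures": {s.value: msg for s, msg in self.failures.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _select_best(
    objective: str, values: Dict[Strategy, float], tie_tol: float
) -> tuple[Strategy, bool]:
    sense = 1.0 if objective == "max_flux" else -1.0
    opt = max(sense * v for v in values.values())
    tied = [
        s
        for s in STRATEGY_PREFERENCE
        if s in values and opt - sense * values[s] <= tie_tol * max(abs(opt), 1e-300)
    ]
    return tied[0], len(tied) > 1


def compare_strategies(
    spec: SystemSpec,
    objective: str = "max_flux",
    tie_tol: float = 1e-3,
    strategies: Iterable[Strategy] = tuple(Strategy),
    **solver_kwargs,
) -> StrategyComparison:
    """Solve the same system under each strategy and pick the optimum.

    ``objective`` is ``max_flux`` (product formation) or ``min_leakage``
    (intermediate efflux).  Strategies whose top objective values lie within
    ``tie_tol`` relative of the optimum are tied, and the tie is broken
    toward the least engineering effort: none > scaffold > organelle.  A
    strategy that fails to converge is excluded and the comparison is
    flagged partial.  The result is independent of evaluation order.
    """
    from . import solve_steady_state  # deferred: api imports solvers

    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}, got {objective!r}")
    values: Dict[Strategy, float] = {}
    failures: Dict[Strategy, str] = {}
    for strat in strategies:
        strat = Strategy(strat)
        try:
            sol = solve_steady_state(spec.with_strategy(strat), **solver_kwargs)
            values[strat] = (
                pathway_flux(sol) if objective == "max_flux" else intermediate_leakage(sol)
            )
        except (ConvergenceError, NotConvergedError) as exc:
            failures[strat] = str(exc)
    if not values:
        raise ConvergenceError("no strategy converged; comparison impossible")
    best, tie = _select_best(objective, values, tie_tol)
    return StrategyComparison(
        objective=objective,
        values=values,
        best=best,
        tie=tie,
        partial=bool(failures),
        failures=failures,
    )
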