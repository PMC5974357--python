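"""Parameter sweeps and 2D optimal-strategy maps.

These reproduce the design-space analysis: solve the same pathway under all
three organization strategies while one or two parameters vary, and color
each point of parameter space by the strategy that maximizes pathway flux or
minimizes intermediate leakage.

Parameters are addressed by dotted paths mirroring :class:`SystemSpec`
(``conditions.S1_out``, ``enzyme2.k_cat``, ``transport.k_c_S1``, ...), plus
the composite paths ``enzyme1.kcat_E0`` / ``enzyme2.kcat_E0`` that set the
activity product k_cat*E0 (uM/s over the cell volume) by scaling k_cat at
fixed copy number — the axis used in the published design spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Strategy, SystemSpec, vmax_from_copies
from .errors import InvalidParameterError
from .metrics import StrategyComparison, compare_strategies

__all__ = [
    "resolve_param",
    "set_param",
    "kcatE0_path",
    "kcat_E0",
    "SweepResult",
    "sweep_1d",
    "StrategyMap",
    "optimal_strategy_map",
]

_COMPOSITE = {"enzyme1.kcat_E0": 1, "enzyme2.kcat_E0": 2}


def kcat_E0(spec: SystemSpec, enzyme: int) -> float:
    """Activity product k_cat*E0 of one enzyme, as uM/s over the cell volume."""
    enz = {1: spec.enzyme1, 2: spec.enzyme2}.get(enzyme)
    if enz is None:
        raise InvalidParameterError(f"enzyme index must be 1 or 2, got {enzyme}")
    return vmax_from_copies(enz.k_cat, enz.copies, spec.cell_volume)


def kcatE0_path(spec: SystemSpec, enzyme: int, value: float) -> SystemSpec:
    """Return a spec whose enzyme activity k_cat*E0 equals ``value`` (uM/s).

    The product is set by scaling k_cat at fixed copy number, so the change
    is exactly proportional for any strategy.
    """
    if value <= 0:
        raise InvalidParameterError(f"k_cat*E0 must be > 0, got {value}")
    current = kcat_E0(spec, enzyme)
    enz = spec.enzyme1 if enzyme == 1 else spec.enzyme2
    new_enz = replace(enz, k_cat=enz.k_cat * value / current)
    return replace(spec, **{f"enzyme{enzyme}": new_enz})


def _walk(spec: SystemSpec, path: str):
    parts = path.split(".")
    if len(parts) != 2:
        raise InvalidParameterError(
            f"parameter path {path!r} must look like 'block.field'"
        )
    block_name, field_name = parts
    block = getattr(spec, block_name, None)
    if block is None or not hasattr(block, "__dataclass_fields__"):
        raise InvalidParameterError(f"unknown spec block {block_name!r} in {path!r}")
    if field_name not in {f.name for f in dc_fields(block)}:
        raise InvalidParameterError(
            f"unknown field {field_name!r} of block {block_name!r} in {path!r}"
        )
    return block_name, block, field_name


def resolve_param(spec: SystemSpec, path: str) -> float:
    """Read the scalar at a dotted parameter path (composites included)."""
    if path in _COMPOSITE:
        return kcat_E0(spec, _COMPOSITE[path])
    _, block, field_name = _walk(spec, path)
    return getattr(block, field_name)


def set_param(spec: SystemSpec, path: str, value: float) -> SystemSpec:
    """Return a new spec with the scalar at ``path`` replaced by ``value``."""
    if path in _COMPOSITE:
        return kcatE0_path(spec, _COMPOSITE[path], value)
    block_name, block, field_name = _walk(spec, path)
    return replace(spec, **{block_name: replace(block, **{field_name: value})})


# ----------------------------------------------------------------------
@dataclass
class SweepResult:
    """Per-strategy flux and leakage along a 1D parameter ladder."""

    parameter: str
    values: np.ndarray
    flux: Dict[Strategy, np.ndarray]
    leakage: Dict[Strategy, np.ndarray]
    converged: Dict[Strategy, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        cols = {self.parameter: self.values}
        for s in self.flux:
            cols[f"flux_{s.value}"] = self.flux[s]
            cols[f"leak_{s.value}"] = self.leakage[s]
            cols[f"converged_{s.value}"] = self.converged[s]
        return pd.DataFrame(cols)


def sweep_1d(
    spec: SystemSpec,
    parameter: str,
    values: Sequence[float],
    strategies: Iterable[Strategy] = tuple(Strategy),
    **solver_kwargs,
) -> SweepResult:
    """Solve every strategy at every value of one swept parameter.

    Deterministic; failed solves are recorded as NaN with a cleared
    convergence flag rather than aborting the sweep.
    """
    from . import solve_steady_state
    from .metrics import intermediate_leakage, pathway_flux

    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InvalidParameterError("sweep requires at least one value")
    strategies = [Strategy(s) for s in strategies]
    flux = {s: np.full(values.size, np.nan) for s in strategies}
    leak = {s: np.full(values.size, np.nan) for s in strategies}
    conv = {s: np.zeros(values.size, dtype=bool) for s in strategies}
    for i, v in enumerate(values):
        spec_v = set_param(spec, parameter, float(v))
        for s in strategies:
            try:
                sol = solve_steady_state(spec_v.with_strategy(s), **solver_kwargs)
                flux[s][i] = pathway_flux(sol)
                leak[s][i] = intermediate_leakage(sol)
                conv[s][i] = True
            except Exception:
                pass
    return SweepResult(
        parameter=parameter, values=values, flux=flux, leakage=leak, converged=conv
    )


# ----------------------------------------------------------------------
UNCONVERGED = "unconverged"


@dataclass
class StrategyMap:
    """2D grid of per-strategy objectives with the optimal strategy per cell.

    ``best[i, j]`` corresponds to ``y_values[i]`` and ``x_values[j]``; cells
    where any strategy failed to converge carry the distinct category
    ``"unconverged"``.
    """

    x_param: str
    x_values: np.ndarray
    y_param: str
    y_values: np.ndarray
    objective: str
    best: np.ndarray                      # (ny, nx) array of strategy strings
    flux: Dict[Strategy, np.ndarray]      # (ny, nx) each
    leakage: Dict[Strategy, np.ndarray]
    tie: np.ndarray = None                # (ny, nx) bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, yv in enumerate(self.y_values):
            for j, xv in enumerate(self.x_values):
                row = {
                    "x_value": xv,
                    "y_value": yv,
                    "best_strategy": self.best[i, j],
                }
                for s in Strategy:
                    row[f"flux_{s.value}"] = self.flux[s][i, j]
                    row[f"leak_{s.value}"] = self.leakage[s][i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Categorical heat map of the optimal strategy (log-log axes)."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        cats = [s.value for s in Strategy] + [UNCONVERGED]
        colors = {"organelle": "#4477aa", "scaffold": "#ee8833",
                  "none": "#bbbbbb", UNCONVERGED: "#ffffff"}
        code = np.zeros(self.best.shape, dtype=int)
        for k, c in enumerate(cats):
            code[self.best == c] = k
        if ax is None:
            _, ax = plt.subplots()
        ax.pcolormesh(
            self.x_values, self.y_values, code,
            cmap=ListedColormap([colors[c] for c in cats]),
            vmin=-0.5, vmax=len(cats) - 0.5, shading="nearest",
        )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(self.x_param)
        ax.set_ylabel(self.y_param)
        ax.set_title(f"optimal strategy: {self.objective}")
        return ax


def optimal_strategy_map(
    spec: SystemSpec,
    x: Tuple[str, Sequence[float]],
    y: Tuple[str, Sequence[float]],
    objective: str = "max_flux",
    tie_tol: float = 1e-3,
    **solver_kwargs,
) -> StrategyMap:
    """Evaluate :func:`compare_strategies` on a 2D parameter grid.

    ``x`` and ``y`` are (dotted path, grid values) pairs, typically
    log-spaced.  Cells are mutually independent, so the map is invariant to
    evaluation order; a cell where any strategy fails is flagged
    ``"unconverged"`` rather than interpolated.
    """
    x_param, x_values = x
    y_param, y_values = y
    x_values = np.asarray(list(x_values), dtype=float)
    y_values = np.asarray(list(y_values), dtype=float)
    ny, nx = y_values.size, x_values.size
    best = np.full((ny, nx), "", dtype=object)
    tie = np.zeros((ny, nx), dtype=bool)
    flux = {s: np.full((ny, nx), np.nan) for s in Strategy}
    leak = {s: np.full((ny, nx), np.nan) for s in Strategy}
    from . import solve_steady_state
    from .metrics import _select_best, intermediate_leakage, pathway_flux

    if objective not in ("max_flux", "min_leakage"):
        raise InvalidParameterError(f"unknown objective {objective!r}")
    for i, yv in enumerate(y_values):
        for j, xv in enumerate(x_values):
            cell = set_param(set_param(spec, x_param, float(xv)), y_param, float(yv))
            cell_flux: Dict[Strategy, float] = {}
            cell_leak: Dict[Strategy, float] = {}
            for s in Strategy:
                try:
                    sol = solve_steady_state(cell.with_strategy(s), **solver_kwargs)
                    cell_flux[s] = flux[s][i, j] = pathway_flux(sol)
                    cell_leak[s] = leak[s][i, j] = intermediate_leakage(sol)
                except Exception:
                    pass
            if len(cell_flux) < len(Strategy):
                best[i, j] = UNCONVERGED
            else:
                values = cell_flux if objective == "max_flux" else cell_leak
                winner, tied = _select_best(objective, values, tie_tol)
                best[i, j] = winner.value
                tie[i, j] = tied
    return StrategyMap(
        x_param=x_param,
        x_values=x_values,
        y_param=y_param,
        y_values=y_values,
        objective=objective,
        best=best,
        flux=flux,
        leakage=leak,
        tie=tie,
    )
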