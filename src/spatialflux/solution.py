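"""Steady-state solution container shared by the analytic and numeric solvers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import Strategy, SystemSpec
from .errors import InvalidParameterError

__all__ = ["SteadyStateSolution"]

_EPS = 1.0e-30


@dataclass
class SteadyStateSolution:
    """Converged steady state of one :class:`~spatialflux.core.SystemSpec`.

    Concentrations are uM, radii cm, per-cell fluxes umol/cell/s.  For the
    analytic (well-mixed compartment) route the cytosol profile is stored as
    Laplace coefficients ``S_i(r) = a_i + b_i / r``; for the finite-volume
    route the full radial profiles are stored (with the interface node
    duplicated so the concentration jump at ``R_c`` is visible).
    """

    spec: SystemSpec
    strategy: Strategy
    method: str                       # "analytic" or "finite_volume"
    converged: bool
    residual_norm: float
    solver_iterations: int

    # compartment (organizing volume) state; None for the unorganized case
    S1_compartment: Optional[float]
    S2_compartment: Optional[float]

    # boundary values of the cytosol profiles
    S1_at_Rb: float
    S2_at_Rb: float
    S1_at_Rc: Optional[float]
    S2_at_Rc: Optional[float]

    # per-cell fluxes
    pathway_flux: float               # product formation (second reaction)
    substrate_consumption: float      # first-reaction throughput
    intermediate_leakage: float       # membrane efflux of S2

    # analytic profile coefficients (a1, b1, a2, b2); None for numeric
    cytosol_profile_coefficients: Optional[Tuple[float, float, float, float]] = None

    # numeric radial data; None for analytic
    r: Optional[np.ndarray] = None
    S1_profile: Optional[np.ndarray] = None
    S2_profile: Optional[np.ndarray] = None
    cv_volumes: Optional[np.ndarray] = None      # cm^3 per node control volume
    reactive: Optional[np.ndarray] = None        # bool mask of enzyme-bearing nodes
    i_interface: Optional[int] = None            # outer-side index of the R_c node
    grid_warning: Optional[bool] = None

    residual_history: list = field(default_factory=list)

    # ------------------------------------------------------------------
    def cytosol_concentration(self, species: str, r) -> float | np.ndarray:
        """Evaluate the cytosol profile of ``species`` ("S1" or "S2") at radius ``r``.

        Only defined on the cytosol shell ``R_c <= r <= R_b`` of an organized
        solution solved analytically.
        """
        if self.cytosol_profile_coefficients is None:
            raise InvalidParameterError(
                "cytosol_concentration requires an analytic solution with profile coefficients"
            )
        geom = self.spec.geometry
        r_arr = np.asarray(r, dtype=float)
        lo = geom.R_c * (1.0 - 1e-12)
        hi = geom.R_b * (1.0 + 1e-12)
        if np.any(r_arr < lo) or np.any(r_arr > hi):
            raise InvalidParameterError(
                f"radius outside cytosol shell [{geom.R_c}, {geom.R_b}]"
            )
        a1, b1, a2, b2 = self.cytosol_profile_coefficients
        a, b = (a1, b1) if species == "S1" else (a2, b2)
        if species not in ("S1", "S2"):
            raise InvalidParameterError(f"species must be 'S1' or 'S2', got {species!r}")
        out = a + b / r_arr
        return float(out) if np.isscalar(r) else out

    # ------------------------------------------------------------------
    def profile_frame(self, n: int = 200) -> pd.DataFrame:
        """Radial profiles as a DataFrame with columns r_cm, S1_uM, S2_uM."""
        if self.r is not None:
            return pd.DataFrame(
                {"r_cm": self.r, "S1_uM": self.S1_profile, "S2_uM": self.S2_profile}
            )
        geom = self.spec.geometry
        r_cyt = np.linspace(geom.R_c, geom.R_b, n)
        s1 = self.cytosol_concentration("S1", r_cyt)
        s2 = self.cytosol_concentration("S2", r_cyt)
        # prepend the well-mixed compartment as a constant segment
        r_in = np.linspace(0.0, geom.R_c, max(2, n // 4), endpoint=True)
        frame = pd.DataFrame(
            {
                "r_cm": np.concatenate([r_in, r_cyt]),
                "S1_uM": np.concatenate([np.full_like(r_in, self.S1_compartment), s1]),
                "S2_uM": np.concatenate([np.full_like(r_in, self.S2_compartment), s2]),
            }
        )
        return frame

    # ------------------------------------------------------------------
    def to_json_dict(self) -> dict:
        from .config import spec_to_dict  # deferred: config imports core only

        def _opt(x):
            return None if x is None else float(x)

        d = {
            "strategy": self.strategy.value,
            "method": self.method,
            "converged": bool(self.converged),
            "residual_norm": float(self.residual_norm),
            "solver_iterations": int(self.solver_iterations),
            "S1_compartment_uM": _opt(self.S1_compartment),
            "S2_compartment_uM": _opt(self.S2_compartment),
            "S1_at_Rb_uM": float(self.S1_at_Rb),
            "S2_at_Rb_uM": float(self.S2_at_Rb),
            "S1_at_Rc_uM": _opt(self.S1_at_Rc),
            "S2_at_Rc_uM": _opt(self.S2_at_Rc),
            "pathway_flux_umol_per_cell_s": float(self.pathway_flux),
            "substrate_consumption_umol_per_cell_s": float(self.substrate_consumption),
            "intermediate_leakage_umol_per_cell_s": float(self.intermediate_leakage),
            "spec": spec_to_dict(self.spec),
        }
        if self.cytosol_profile_coefficients is not None:
            a1, b1, a2, b2 = self.cytosol_profile_coefficients
            d["cytosol_profile_coefficients"] = {
                "a1": a1, "b1": b1, "a2": a2, "b2": b2,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary table of the converged state."""
        rows = [
            ("strategy", self.strategy.value),
            ("method", self.method),
            ("converged", str(self.converged)),
            ("residual norm", f"{self.residual_norm:.3e}"),
            ("iterations", str(self.solver_iterations)),
            ("S1 in compartment [uM]",
             "-" if self.S1_compartment is None else f"{self.S1_compartment:.6g}"),
            ("S2 in compartment [uM]",
             "-" if self.S2_compartment is None else f"{self.S2_compartment:.6g}"),
            ("S1 at cell membrane [uM]", f"{self.S1_at_Rb:.6g}"),
            ("S2 at cell membrane [uM]", f"{self.S2_at_Rb:.6g}"),
            ("pathway flux [umol/cell/s]", f"{self.pathway_flux:.6e}"),
            ("substrate consumption [umol/cell/s]", f"{self.substrate_consumption:.6e}"),
            ("intermediate leakage [umol/cell/s]", f"{self.intermediate_leakage:.6e}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Steady-state solution", "=" * (width + 24)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)
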