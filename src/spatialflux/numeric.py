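"""Finite-volume boundary-value solver on the radial coordinate.

Solves the spherically symmetric steady-state reaction-diffusion system

    D lap(S1) - R1 = 0,    D lap(S2) + R1 - R2 = 0

with Robin (mass-transfer) conditions at the cell membrane, the symmetry
condition at the origin and, for the organized strategies, a permeability
jump condition at the compartment boundary ``R_c``.  The unorganized case
has reactions everywhere; the organized case has reactions only inside
``R_c`` (all enzyme copies in the compartment) and serves as the
full-resolution oracle for the well-mixed analytic route.

Discretization is a vertex-centered finite-volume scheme: nodes carry
control volumes bounded by mid-faces, diffusive face currents use central
differences (second order on the uniform per-region grids), the membrane
and compartment-boundary currents are applied exactly on their faces, and
the origin is handled naturally by a zero-area inner face.  Because the
face currents telescope, the discrete solution satisfies the integral mass
balances to nonlinear-solver tolerance, not merely to truncation order.

The nonlinear system is solved by a damped Newton iteration with the exact
sparse Jacobian.  Internally the unknowns are the draw-downs
``x1 = S1_out - S1`` and ``x2 = S2 - S2_out``: in transport-dominated
regimes the concentration changes are many orders of magnitude smaller
than the concentrations themselves, and this change of variable keeps the
converged residuals (and hence the conservation identities) near machine
precision instead of near ``eps * S_out``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from .core import RateLaw, Strategy, SystemSpec, UM_CM3_TO_UMOL
from .errors import ConvergenceError, InvalidParameterError
from .solution import SteadyStateSolution

__all__ = ["RadialGrid", "make_grid", "solve_unorganized", "solve_organized_numeric"]

_FOUR_PI = 4.0 * math.pi
MIN_GRID_POINTS = 50
DEFAULT_GRID_POINTS = 400


@dataclass(frozen=True)
class RadialGrid:
    """Ordered radial nodes from 0 to ``R_b`` with a node exactly at ``R_c``."""

    radii: np.ndarray
    i_rc: int

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(r) <= 0):
            raise InvalidParameterError("grid radii must be strictly increasing")
        object.__setattr__(self, "radii", r)

    @property
    def n_points(self) -> int:
        return self.radii.size

    @property
    def max_spacing(self) -> float:
        return float(np.max(np.diff(self.radii)))


def make_grid(geometry, n_points: int = DEFAULT_GRID_POINTS) -> RadialGrid:
    """Uniform-per-region radial grid with a node exactly at ``R_c``.

    Nodes are allocated to the [0, R_c] and [R_c, R_b] regions in proportion
    to their radial extents (with a floor per region), so doubling
    ``n_points`` halves the spacing.  Deterministic for fixed inputs.
    """
    if n_points < MIN_GRID_POINTS:
        raise InvalidParameterError(
            f"n_points must be >= {MIN_GRID_POINTS}, got {n_points}"
        )
    frac = geometry.R_c / geometry.R_b
    n_in = int(round(n_points * frac))
    n_in = min(max(n_in, 16), n_points - 16)
    inner = np.linspace(0.0, geometry.R_c, n_in)
    outer = np.linspace(geometry.R_c, geometry.R_b, n_points - n_in + 1)
    radii = np.concatenate([inner, outer[1:]])
    radii[n_in - 1] = geometry.R_c  # exact
    return RadialGrid(radii=radii, i_rc=n_in - 1)


# ----------------------------------------------------------------------
# rate laws with a C1 linear extension below S = 0 (Newton iterates may
# transiently undershoot; the converged physical solution is non-negative)

def _mm(S, V, K):
    S = np.asarray(S, dtype=float)
    return np.where(S >= 0.0, V * S / (K + np.maximum(S, 0.0)), V * S / K)


def _dmm(S, V, K):
    S = np.asarray(S, dtype=float)
    return np.where(S >= 0.0, V * K / (K + np.maximum(S, 0.0)) ** 2, V / K)


class _Discretization:
    """Assembled geometry and coefficients for one Newton solve."""

    def __init__(self, spec: SystemSpec, grid: RadialGrid, organized: bool):
        g = spec.geometry
        D = spec.transport.D
        radii = grid.radii
        if organized:
            # duplicate the interface node: inner side then outer side
            split = grid.i_rc + 1  # index of the outer-side R_c node
            r = np.concatenate([radii[: grid.i_rc + 1], radii[grid.i_rc:]])
        else:
            split = None
            r = radii.copy()
        n = r.size
        # face positions between consecutive nodes (R_c at the interface)
        fpos = 0.5 * (r[:-1] + r[1:])
        if organized:
            fpos[split - 1] = g.R_c
        # face transport coefficients per species (per steradian)
        dr = np.diff(r)
        with np.errstate(divide="ignore"):
            c = D * fpos**2 / np.where(dr > 0, dr, np.inf)
        c1 = c.copy()
        c2 = c.copy()
        if organized:
            c1[split - 1] = spec.kc_S1 * g.R_c**2
            c2[split - 1] = spec.kc_S2 * g.R_c**2
        # control volumes per steradian
        bounds = np.concatenate([[0.0], fpos, [g.R_b]])
        vol = (bounds[1:] ** 3 - bounds[:-1] ** 3) / 3.0
        # reactive mask and volumetric V_max over the reaction volume
        reactive = np.ones(n, dtype=bool)
        if organized:
            reactive[split:] = False
        self.spec = spec
        self.organized = organized
        self.split = split
        self.r = r
        self.n = n
        self.c1 = c1
        self.c2 = c2
        self.vol = vol
        self.reactive = reactive
        self.t_mem1 = spec.transport.k_m_S1 * g.R_b**2
        self.t_mem2 = spec.transport.k_m_S2 * g.R_b**2
        self.V1 = spec.vmax1
        self.K1 = spec.enzyme1.K_M
        self.V2 = spec.vmax2
        self.K2 = spec.enzyme2.K_M
        if spec.rate_law is RateLaw.REVERSIBLE_MM:
            self.V1r = spec.reverse1.vmax(spec.reaction_volume)
            self.K1r = spec.reverse1.K_M
        else:
            self.V1r = 0.0
            self.K1r = 1.0

    # -- residual -------------------------------------------------------
    def residual(self, x: np.ndarray) -> Tuple[np.ndarray, float, np.ndarray]:
        """Residual vector, global reference scale and per-row round-off floor.

        The floor is the attainable accuracy of each row given the magnitudes
        entering it (face coefficients times unknowns, source times volume);
        in strongly transport-limited corners of parameter space the residual
        cannot be driven below it, although the solution there is already
        exact to machine precision.
        """
        n = self.n
        x1, x2 = x[:n], x[n:]
        S1 = self.spec.conditions.S1_out - x1
        S2 = self.spec.conditions.S2_out + x2
        R1 = (_mm(S1, self.V1, self.K1) - _mm(S2, self.V1r, self.K1r)) * self.reactive
        R2 = _mm(S2, self.V2, self.K2) * self.reactive
        # face currents phi = D r^2 dS/dr (interface/membrane laws inline)
        phi1 = np.empty(n)
        phi2 = np.empty(n)
        phi1[:-1] = -self.c1 * (x1[1:] - x1[:-1])
        phi2[:-1] = self.c2 * (x2[1:] - x2[:-1])
        phi1[-1] = self.t_mem1 * x1[-1]
        phi2[-1] = -self.t_mem2 * x2[-1]
        q1 = -R1 * self.vol
        q2 = (R1 - R2) * self.vol
        F1 = phi1 + q1
        F1[1:] -= phi1[:-1]
        F2 = phi2 + q2
        F2[1:] -= phi2[:-1]
        ref = max(
            float(np.sum(np.abs(q1)) + abs(phi1[-1])),
            float(np.sum(np.abs(q2)) + abs(phi2[-1])),
            1e-300,
        )
        eps = np.finfo(float).eps
        mag1 = np.zeros(n)
        mag2 = np.zeros(n)
        span1 = self.c1 * (np.abs(x1[1:]) + np.abs(x1[:-1]))
        span2 = self.c2 * (np.abs(x2[1:]) + np.abs(x2[:-1]))
        mag1[:-1] += span1
        mag1[1:] += span1
        mag2[:-1] += span2
        mag2[1:] += span2
        mag1[-1] += abs(phi1[-1])
        mag2[-1] += abs(phi2[-1])
        mag1 += np.abs(q1)
        mag2 += np.abs(q2)
        floor = eps * np.concatenate([mag1, mag2])
        return np.concatenate([F1, F2]), ref, floor

    # -- Jacobian -------------------------------------------------------
    def jacobian(self, x: np.ndarray) -> csr_matrix:
        n = self.n
        x1, x2 = x[:n], x[n:]
        S1 = self.spec.conditions.S1_out - x1
        S2 = self.spec.conditions.S2_out + x2
        d1 = _dmm(S1, self.V1, self.K1) * self.reactive      # dR1/dS1
        d1r = _dmm(S2, self.V1r, self.K1r) * self.reactive   # d(reverse)/dS2
        d2 = _dmm(S2, self.V2, self.K2) * self.reactive      # dR2/dS2

        rows, cols, vals = [], [], []

        def add(r_, c_, v_):
            rows.append(r_)
            cols.append(c_)
            vals.append(v_)

        idx = np.arange(n)
        # S1 rows: F1_j = phi1_j - phi1_{j-1} + q1_j
        # face j (j<n-1): phi1_j = -c1_j (x1_{j+1} - x1_j)
        add(idx[:-1], idx[:-1], self.c1)          # d phi1_j / d x1_j
        add(idx[:-1], idx[1:], -self.c1)          # d phi1_j / d x1_{j+1}
        add(idx[1:], idx[1:], self.c1)            # -d phi1_{j-1} / d x1_j
        add(idx[1:], idx[:-1], -self.c1)          # -d phi1_{j-1} / d x1_{j-1}
        add(np.array([n - 1]), np.array([n - 1]), np.array([self.t_mem1]))
        # q1 = -R1 vol;  dq1/dx1 = +dR1/dS1 vol ; dq1/dx2 = +d1r vol
        add(idx, idx, d1 * self.vol)
        add(idx, idx + n, d1r * self.vol)

        # S2 rows (offset n): F2_j = phi2_j - phi2_{j-1} + q2_j
        add(idx[:-1] + n, idx[:-1] + n, -self.c2)
        add(idx[:-1] + n, idx[1:] + n, self.c2)
        add(idx[1:] + n, idx[1:] + n, -self.c2)
        add(idx[1:] + n, idx[:-1] + n, self.c2)
        add(np.array([2 * n - 1]), np.array([2 * n - 1]), np.array([-self.t_mem2]))
        # q2 = (R1 - R2) vol; d/dx1 = -d1 vol ; d/dx2 = (-d1r - d2) vol
        add(idx + n, idx, -d1 * self.vol)
        add(idx + n, idx + n, (-d1r - d2) * self.vol)

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return coo_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n)).tocsr()


def _scaled_norm(F: np.ndarray, ref: float, floor: np.ndarray, tol: float) -> float:
    # Each row is measured against the larger of the global reaction/transport
    # scale and (8/tol x) its own round-off floor, so a residual at the
    # attainable assembly precision counts as converged.
    denom = np.maximum(ref, 8.0 * floor / tol)
    return float(np.max(np.abs(F) / denom))


def _newton(disc: _Discretization, x0: np.ndarray, tol: float, max_iter: int):
    # Damped Newton, iterated past `tol` all the way to the round-off floor
    # (the first non-improving step): the telescoped conservation identities
    # are only as good as the final residual, so stopping at the first
    # crossing of `tol` would leave a coherent O(tol) imbalance behind.
    x = x0.copy()
    F, ref, floor = disc.residual(x)
    norm = _scaled_norm(F, ref, floor, tol)
    history = [norm]
    it = 0
    while norm > 0.0 and it < max_iter:
        J = disc.jacobian(x)
        step = spsolve(J, -F)
        lam = 1.0
        accepted = False
        while lam >= 2.0 ** -40:
            x_new = x + lam * step
            F_new, ref_new, floor_new = disc.residual(x_new)
            norm_new = _scaled_norm(F_new, ref_new, floor_new, tol)
            if norm_new < norm * (1.0 - 1e-4 * lam):
                x, F, norm = x_new, F_new, norm_new
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            break  # residual floor reached
        history.append(norm)
        it += 1
    if norm >= tol:
        raise ConvergenceError(
            f"Newton stopped after {it} iterations at residual {norm:.3e} "
            f"(tolerance {tol:.1e})",
            residual=norm,
            history=history,
        )
    return x, norm, it, history


def _build_solution(
    spec: SystemSpec,
    disc: _Discretization,
    x: np.ndarray,
    norm: float,
    iterations: int,
    history,
    grid_warning: Optional[bool],
) -> SteadyStateSolution:
    n = disc.n
    S1 = spec.conditions.S1_out - x[:n]
    S2 = spec.conditions.S2_out + x[n:]
    vol_cm3 = disc.vol * _FOUR_PI
    R1 = (_mm(S1, disc.V1, disc.K1) - _mm(S2, disc.V1r, disc.K1r)) * disc.reactive
    R2 = _mm(S2, disc.V2, disc.K2) * disc.reactive
    consumption = float(np.sum(R1 * vol_cm3)) * UM_CM3_TO_UMOL
    flux = float(np.sum(R2 * vol_cm3)) * UM_CM3_TO_UMOL
    g = spec.geometry
    leak = (
        _FOUR_PI * g.R_b**2 * spec.transport.k_m_S2 * (S2[-1] - spec.conditions.S2_out)
    ) * UM_CM3_TO_UMOL
    if disc.organized:
        split = disc.split
        w = vol_cm3[:split]
        s1_comp = float(np.sum(S1[:split] * w) / np.sum(w))
        s2_comp = float(np.sum(S2[:split] * w) / np.sum(w))
        s1_rc, s2_rc = float(S1[split]), float(S2[split])
        i_interface = split
    else:
        s1_comp = s2_comp = None
        s1_rc = s2_rc = None
        i_interface = None
    return SteadyStateSolution(
        spec=spec,
        strategy=spec.strategy,
        method="finite_volume",
        converged=True,
        residual_norm=norm,
        solver_iterations=iterations,
        S1_compartment=s1_comp,
        S2_compartment=s2_comp,
        S1_at_Rb=float(S1[-1]),
        S2_at_Rb=float(S2[-1]),
        S1_at_Rc=s1_rc,
        S2_at_Rc=s2_rc,
        pathway_flux=flux,
        substrate_consumption=consumption,
        intermediate_leakage=leak,
        r=disc.r.copy(),
        S1_profile=S1,
        S2_profile=S2,
        cv_volumes=vol_cm3,
        reactive=disc.reactive.copy(),
        i_interface=i_interface,
        grid_warning=grid_warning,
        residual_history=list(history),
    )


def _solve(
    spec: SystemSpec,
    grid: Optional[RadialGrid],
    organized: bool,
    tol: float,
    max_iter: int,
    x0: Optional[np.ndarray],
    verify_grid: bool,
) -> SteadyStateSolution:
    if grid is None:
        grid = make_grid(spec.geometry)
    disc = _Discretization(spec, grid, organized)
    if x0 is None:
        x0 = np.zeros(2 * disc.n)
    x, norm, iters, history = _newton(disc, x0, tol, max_iter)
    grid_warning: Optional[bool] = None
    if verify_grid:
        fine = make_grid(spec.geometry, 2 * grid.n_points)
        fine_sol = _solve(spec, fine, organized, tol, max_iter, None, False)
        coarse = _build_solution(spec, disc, x, norm, iters, history, None)
        scale = max(abs(fine_sol.pathway_flux), 1e-300)
        grid_warning = abs(coarse.pathway_flux - fine_sol.pathway_flux) / scale > 0.01
    return _build_solution(spec, disc, x, norm, iters, history, grid_warning)


def solve_unorganized(
    spec: SystemSpec,
    grid: Optional[RadialGrid] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    verify_grid: bool = False,
) -> SteadyStateSolution:
    """Steady state with enzymes distributed through the whole cell.

    Reactions are active on the full domain 0..R_b with volumetric rates
    computed over the cell volume; the symmetry condition holds at the
    origin and Robin membrane conditions at R_b.  The converged solution is
    independent of the Newton starting point (bath conditions by default).

    Set ``verify_grid`` to re-solve on a doubled grid and flag the solution
    (``grid_warning``) if the pathway flux moves by more than 1%.
    """
    if spec.strategy is not Strategy.NONE:
        raise InvalidParameterError("solve_unorganized requires strategy 'none'")
    return _solve(spec, grid, False, tol, max_iter, None, verify_grid)


def solve_organized_numeric(
    spec: SystemSpec,
    grid: Optional[RadialGrid] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    init_from_analytic: bool = True,
    verify_grid: bool = False,
) -> SteadyStateSolution:
    """Spatially resolved steady state of an organized pathway.

    Unlike the closed-form route, the compartment interior is resolved on
    the grid (reaction terms active for r < R_c) with the permeability jump
    condition at R_c, so this solver doubles as the oracle for the
    well-mixed-compartment assumption.
    """
    if not spec.strategy.organized:
        raise InvalidParameterError(
            "solve_organized_numeric requires strategy 'organelle' or 'scaffold'"
        )
    if grid is None:
        grid = make_grid(spec.geometry)
    x0 = None
    if init_from_analytic:
        from .analytic import solve_organized  # deferred to avoid cycle at import

        try:
            guess = solve_organized(spec)
            split = grid.i_rc + 1
            r = np.concatenate([grid.radii[: grid.i_rc + 1], grid.radii[grid.i_rc:]])
            S1g = np.empty(r.size)
            S2g = np.empty(r.size)
            S1g[:split] = guess.S1_compartment
            S2g[:split] = guess.S2_compartment
            a1, b1, a2, b2 = guess.cytosol_profile_coefficients
            S1g[split:] = a1 + b1 / r[split:]
            S2g[split:] = a2 + b2 / r[split:]
            x0 = np.concatenate(
                [spec.conditions.S1_out - S1g, S2g - spec.conditions.S2_out]
            )
        except ConvergenceError:
            x0 = None
    return _solve(spec, grid, True, tol, max_iter, x0, verify_grid)
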