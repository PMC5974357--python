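"""Closed-form steady-state solver for the organized strategies.

With all enzymes confined to a well-mixed sphere of radius ``R_c`` inside the
cell, the cytosol shell ``R_c <= r <= R_b`` is reaction-free, so each species
satisfies Laplace's equation there and its profile is ``S(r) = a + b/r``.  The
radial current of a species through any shell is then constant, and the three
transport steps in series (cell membrane, cytosol diffusion, compartment
boundary) act as additive resistances:

    Omega = 1/(4 pi R_b^2 k_m) + (1/R_c - 1/R_b)/(4 pi D) + 1/(4 pi R_c^2 k_c)

so the compartment concentrations satisfy the scalar balances

    S1_c = S1_out - I1 * Omega_1,   I1 = V_c * R1(S1_c, S2_c)
    S2_c = S2_out + I2 * Omega_2,   I2 = V_c * (R1(S1_c, S2_c) - R2(S2_c))

with ``V_c`` the compartment volume and ``I`` in uM*cm^3/s.  Both balances are
monotone in their unknown, so they are solved by nested Brent bracketing
(outer in ``S1_c``, inner in ``S2_c``), which converges unconditionally and
independently of any initial guess.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .core import Strategy, SystemSpec, UM_CM3_TO_UMOL
from .errors import ConvergenceError, InvalidParameterError
from .solution import SteadyStateSolution

__all__ = ["solve_organized", "cytosol_concentration"]

_FOUR_PI = 4.0 * math.pi


def _resistance(spec: SystemSpec, k_m: float, k_c: float) -> float:
    """Series transport resistance (s/cm^3, per 4*pi*current) bath -> compartment."""
    g = spec.geometry
    D = spec.transport.D
    return (
        1.0 / (_FOUR_PI * g.R_b**2 * k_m)
        + (1.0 / g.R_c - 1.0 / g.R_b) / (_FOUR_PI * D)
        + 1.0 / (_FOUR_PI * g.R_c**2 * k_c)
    )


def solve_organized(
    spec: SystemSpec, tol: float = 1e-10, max_iter: int = 200
) -> SteadyStateSolution:
    """Steady state of an organelle- or scaffold-organized pathway.

    Parameters
    ----------
    spec : system specification with ``strategy`` organelle or scaffold.
    tol : relative residual below which the solution is flagged converged.
    max_iter : iteration cap handed to the bracketing root finder.

    Returns
    -------
    SteadyStateSolution with the well-mixed compartment concentrations, the
    ``a + b/r`` cytosol profile coefficients and the per-cell fluxes.
    """
    if not spec.strategy.organized:
        raise InvalidParameterError(
            "solve_organized requires strategy 'organelle' or 'scaffold'; "
            "use the finite-volume solver for the unorganized case"
        )
    tr = spec.transport
    cond = spec.conditions
    V_c = spec.compartment_volume
    omega1 = _resistance(spec, tr.k_m_S1, spec.kc_S1)
    omega2 = _resistance(spec, tr.k_m_S2, spec.kc_S2)

    evals = {"n": 0}

    def I1_of(s1c: float, s2c: float) -> float:
        return V_c * spec.rate1(s1c, s2c)

    def inner_residual(s2c: float, s1c: float) -> float:
        i2 = I1_of(s1c, s2c) - V_c * spec.rate2(s2c)
        return s2c - cond.S2_out - i2 * omega2

    def solve_inner(s1c: float) -> float:
        # H(0) = -S2_out - I2(0)*omega2 <= 0 always (no S2 means no reverse or
        # enzymatic consumption), and H is strictly increasing in S2_c.
        evals["n"] += 1
        h0 = inner_residual(0.0, s1c)
        if h0 == 0.0:
            return 0.0
        hi = max(cond.S2_out, 1.0)
        while inner_residual(hi, s1c) < 0.0:
            hi *= 4.0
            if hi > 1e30:  # pragma: no cover - physically unreachable
                raise ConvergenceError("inner bracket expansion failed", residual=hi)
        # xtol far below any concentration of interest: the root may be many
        # orders smaller than the bracket, so rtol alone must control it
        return brentq(
            inner_residual, 0.0, hi, args=(s1c,),
            xtol=1e-30, rtol=8.9e-16, maxiter=max_iter,
        )

    def outer_residual(s1c: float) -> float:
        s2c = solve_inner(s1c)
        return s1c - cond.S1_out + I1_of(s1c, s2c) * omega1

    g0 = outer_residual(0.0)
    if g0 == 0.0:
        s1c = 0.0
    else:
        hi = max(cond.S1_out, 1.0)
        while outer_residual(hi) < 0.0:
            hi *= 4.0
            if hi > 1e30:  # pragma: no cover
                raise ConvergenceError("outer bracket expansion failed", residual=hi)
        s1c = brentq(
            outer_residual, 0.0, hi,
            xtol=1e-30, rtol=8.9e-16, maxiter=max_iter,
        )
    s2c = solve_inner(s1c)

    # currents (uM cm^3 / s)
    I1 = I1_of(s1c, s2c)
    R2v = V_c * spec.rate2(s2c)
    I2 = I1 - R2v

    # scaled residuals of the two balances; each is measured against the
    # larger of its concentration scale and the round-off floor of its own
    # evaluation (the I * omega products can dwarf the balance they close,
    # e.g. for nearly sealed compartments)
    eps = 2.3e-16
    fwd1 = V_c * spec.rate1(s1c, 0.0)
    rev1 = fwd1 - I1  # reverse contribution, 0 for the irreversible law
    scale1 = max(abs(cond.S1_out), abs(s1c), abs(I1) * omega1, 1e-30)
    scale2 = max(abs(cond.S2_out), abs(s2c), abs(I2) * omega2, 1e-30)
    floor1 = eps * (abs(s1c) + cond.S1_out + (abs(fwd1) + abs(rev1)) * omega1)
    floor2 = eps * (
        abs(s2c) + cond.S2_out + (abs(fwd1) + abs(rev1) + abs(R2v)) * omega2
    )
    res = max(
        abs(s1c - cond.S1_out + I1 * omega1) / max(scale1, 8 * floor1 / tol),
        abs(s2c - cond.S2_out - I2 * omega2) / max(scale2, 8 * floor2 / tol),
    )

    g = spec.geometry
    D = tr.D
    # Laplace coefficients: outward current through any shell is 4*pi*D*b
    b1 = -I1 / (_FOUR_PI * D)
    b2 = I2 / (_FOUR_PI * D)
    S1_Rb = cond.S1_out + D * b1 / (tr.k_m_S1 * g.R_b**2)
    S2_Rb = cond.S2_out + D * b2 / (tr.k_m_S2 * g.R_b**2)
    a1 = S1_Rb - b1 / g.R_b
    a2 = S2_Rb - b2 / g.R_b
    S1_Rc = a1 + b1 / g.R_c
    S2_Rc = a2 + b2 / g.R_c

    return SteadyStateSolution(
        spec=spec,
        strategy=spec.strategy,
        method="analytic",
        converged=res < tol,
        residual_norm=res,
        solver_iterations=evals["n"],
        S1_compartment=s1c,
        S2_compartment=s2c,
        S1_at_Rb=S1_Rb,
        S2_at_Rb=S2_Rb,
        S1_at_Rc=S1_Rc,
        S2_at_Rc=S2_Rc,
        pathway_flux=V_c * spec.rate2(s2c) * UM_CM3_TO_UMOL,
        substrate_consumption=I1 * UM_CM3_TO_UMOL,
        intermediate_leakage=I2 * UM_CM3_TO_UMOL,
        cytosol_profile_coefficients=(a1, b1, a2, b2),
    )


def cytosol_concentration(solution: SteadyStateSolution, species: str, r):
    """Evaluate the analytic ``a + b/r`` cytosol profile at radius ``r`` (cm)."""
    return solution.cytosol_concentration(species, r)
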