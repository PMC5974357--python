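"""Domain types, unit conventions, rate laws and scenario transformations.

The package models a two-enzyme pathway (S1 --E1--> S2 --E2--> product) in a
spherically symmetric bacterial cell of radius ``R_b``.  The pathway can be
left unorganized (enzymes uniform in the cytosol), co-localized on a scaffold,
or encapsulated in a microcompartment organelle; the organizing volume is a
single concentric sphere of radius ``R_c`` holding all enzyme copies.  A
scaffold is an organelle whose boundary permeability is set high enough to
approximate free diffusion.

Unit system (fixed package-wide):

========================  ==========
length                    cm
time                      s
concentration             uM
diffusivity               cm^2/s
permeability              cm/s
per-cell flux             umol/cell/s
========================  ==========
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Tuple, Union

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "N_AVOGADRO",
    "MOL_PER_CM3_TO_UM",
    "UM_CM3_TO_UMOL",
    "SCAFFOLD_PERMEABILITY",
    "Strategy",
    "RateLaw",
    "EnzymeKinetics",
    "TransportParams",
    "Geometry",
    "ExternalConditions",
    "SystemSpec",
    "michaelis_menten_rate",
    "reversible_interconversion_rate",
    "vmax_from_copies",
    "sphere_volume",
    "apply_fold_change",
    "FOLD_CHANGE_TARGETS",
]

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214e23
#: 1 mol/cm^3 expressed in uM (1 mol/cm^3 = 1e3 mol/L = 1e9 uM).
MOL_PER_CM3_TO_UM = 1.0e9
#: 1 uM * cm^3 expressed in umol (1e-9 mol = 1e-3 umol).
UM_CM3_TO_UMOL = 1.0e-3
#: Boundary permeability (cm/s) used as the free-diffusion surrogate for a scaffold.
SCAFFOLD_PERMEABILITY = 1.0e3


class Strategy(str, Enum):
    """Spatial organization strategy of the pathway enzymes."""

    ORGANELLE = "organelle"
    SCAFFOLD = "scaffold"
    NONE = "none"

    @property
    def organized(self) -> bool:
        return self is not Strategy.NONE


#: Deterministic tie-break preference: least engineering effort first.
STRATEGY_PREFERENCE = (Strategy.NONE, Strategy.SCAFFOLD, Strategy.ORGANELLE)


class RateLaw(str, Enum):
    IRREVERSIBLE_MM = "irreversible_mm"
    REVERSIBLE_MM = "reversible_mm"


ArrayLike = Union[float, np.ndarray]


def _maybe_scalar(x: np.ndarray, scalar: bool) -> ArrayLike:
    return float(x) if scalar else x


def michaelis_menten_rate(S: ArrayLike, V_max: float, K_M: float) -> ArrayLike:
    """Irreversible Michaelis-Menten rate ``V_max * S / (K_M + S)`` in uM/s.

    Parameters
    ----------
    S : concentration (uM), scalar or array, must be >= 0.
    V_max : maximum rate (uM/s), >= 0.
    K_M : Michaelis constant (uM), > 0.
    """
    if V_max < 0:
        raise InvalidParameterError(f"V_max must be >= 0, got {V_max}")
    if K_M <= 0:
        raise InvalidParameterError(f"K_M must be > 0, got {K_M}")
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise InvalidParameterError("substrate concentration must be >= 0")
    return _maybe_scalar(V_max * S_arr / (K_M + S_arr), np.isscalar(S))


def reversible_interconversion_rate(
    S1: ArrayLike,
    S2: ArrayLike,
    forward: Tuple[float, float],
    reverse: Tuple[float, float],
) -> ArrayLike:
    """Net rate of a reversible interconversion S1 <-> S2 (uM/s).

    Opposing Michaelis-Menten terms: the forward term acts on ``S1`` with
    ``forward = (V_max, K_M)`` and the reverse term acts on ``S2`` with
    ``reverse = (V_max, K_M)``.  With reverse ``V_max = 0`` this reduces
    exactly to :func:`michaelis_menten_rate`.
    """
    fwd = michaelis_menten_rate(S1, *forward)
    rev = michaelis_menten_rate(S2, *reverse)
    out = np.asarray(fwd, dtype=float) - np.asarray(rev, dtype=float)
    return _maybe_scalar(out, np.isscalar(S1) and np.isscalar(S2))


def sphere_volume(radius: float) -> float:
    """Volume of a sphere (cm^3)."""
    return 4.0 / 3.0 * math.pi * radius**3


def vmax_from_copies(k_cat: float, copies: float, volume: float) -> float:
    """Maximum volumetric rate (uM/s) of ``copies`` enzymes confined to ``volume``.

    ``V_max = k_cat * copies / (N_A * volume)``, converted from mol/cm^3/s to uM/s.
    Linear in ``k_cat`` and ``copies``, inverse in ``volume``.
    """
    if volume <= 0:
        raise InvalidParameterError(f"volume must be > 0, got {volume}")
    if k_cat < 0 or copies < 0:
        raise InvalidParameterError("k_cat and copies must be >= 0")
    return k_cat * copies / (N_AVOGADRO * volume) * MOL_PER_CM3_TO_UM


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten kinetics of one pathway enzyme.

    Attributes
    ----------
    k_cat : turnover rate of one active site (1/s), >= 0.
    K_M : Michaelis constant (uM), > 0.
    copies : enzyme molecules per cell, >= 0.
    """

    k_cat: float
    K_M: float
    copies: float

    def __post_init__(self):
        if self.k_cat < 0:
            raise InvalidParameterError(f"k_cat must be >= 0, got {self.k_cat}")
        if self.K_M <= 0:
            raise InvalidParameterError(f"K_M must be > 0, got {self.K_M}")
        if self.copies < 0:
            raise InvalidParameterError(f"copies must be >= 0, got {self.copies}")

    def vmax(self, volume: float) -> float:
        """V_max (uM/s) when all copies are confined to ``volume`` (cm^3)."""
        return vmax_from_copies(self.k_cat, self.copies, volume)

    @property
    def capacity(self) -> float:
        """Absolute per-cell turnover capacity k_cat * copies / N_A (umol/cell/s)."""
        return self.k_cat * self.copies / N_AVOGADRO * 1.0e6


@dataclass(frozen=True)
class TransportParams:
    """Transport coefficients for the two tracked metabolites.

    ``k_m_*`` are cell-membrane permeabilities, ``k_c_*`` are permeabilities of
    the organelle (compartment) boundary; ``D`` is the common cytosolic
    diffusivity.  All strictly positive.
    """

    D: float
    k_m_S1: float
    k_m_S2: float
    k_c_S1: float
    k_c_S2: float

    def __post_init__(self):
        for name in ("D", "k_m_S1", "k_m_S2", "k_c_S1", "k_c_S2"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class Geometry:
    """Cell radius ``R_b`` and organizing-volume radius ``R_c`` (cm), 0 < R_c < R_b."""

    R_b: float
    R_c: float

    def __post_init__(self):
        if not (0 < self.R_c < self.R_b):
            raise InvalidParameterError(
                f"geometry requires 0 < R_c < R_b, got R_c={self.R_c}, R_b={self.R_b}"
            )

    @property
    def cell_volume(self) -> float:
        return sphere_volume(self.R_b)

    @property
    def compartment_volume(self) -> float:
        return sphere_volume(self.R_c)


@dataclass(frozen=True)
class ExternalConditions:
    """Bulk-medium concentrations (uM), held constant: substrate and intermediate."""

    S1_out: float
    S2_out: float = 0.0

    def __post_init__(self):
        if self.S1_out < 0 or self.S2_out < 0:
            raise InvalidParameterError("external concentrations must be >= 0")


@dataclass(frozen=True)
class SystemSpec:
    """Complete parameter bundle defining one solvable steady-state model.

    ``reverse1`` supplies the reverse kinetics of the first enzyme for the
    reversible rate law (an interconversion S1 <-> S2, as for carbonic
    anhydrase in the carboxysome); the second reaction is always treated as
    irreversible since its product is not tracked.
    """

    enzyme1: EnzymeKinetics
    enzyme2: EnzymeKinetics
    transport: TransportParams
    geometry: Geometry
    conditions: ExternalConditions
    strategy: Strategy = Strategy.ORGANELLE
    rate_law: RateLaw = RateLaw.IRREVERSIBLE_MM
    reverse1: Optional[EnzymeKinetics] = None

    def __post_init__(self):
        # allow strings in constructors/config
        if not isinstance(self.strategy, Strategy):
            object.__setattr__(self, "strategy", Strategy(self.strategy))
        if not isinstance(self.rate_law, RateLaw):
            object.__setattr__(self, "rate_law", RateLaw(self.rate_law))
        if self.rate_law is RateLaw.REVERSIBLE_MM and self.reverse1 is None:
            raise InvalidParameterError(
                "reversible_mm rate law requires reverse1 kinetics"
            )

    # -- geometry / volumes -------------------------------------------------
    @property
    def cell_volume(self) -> float:
        return self.geometry.cell_volume

    @property
    def compartment_volume(self) -> float:
        return self.geometry.compartment_volume

    @property
    def reaction_volume(self) -> float:
        """Volume (cm^3) hosting the enzymes under the current strategy."""
        if self.strategy.organized:
            return self.compartment_volume
        return self.cell_volume

    # -- effective transport ------------------------------------------------
    @property
    def kc_S1(self) -> float:
        """Compartment-boundary permeability to S1; pinned high for a scaffold."""
        if self.strategy is Strategy.SCAFFOLD:
            return SCAFFOLD_PERMEABILITY
        return self.transport.k_c_S1

    @property
    def kc_S2(self) -> float:
        if self.strategy is Strategy.SCAFFOLD:
            return SCAFFOLD_PERMEABILITY
        return self.transport.k_c_S2

    # -- volumetric rate laws ------------------------------------------------
    @property
    def vmax1(self) -> float:
        """V_1 (uM/s) over the reaction volume of the current strategy."""
        return self.enzyme1.vmax(self.reaction_volume)

    @property
    def vmax2(self) -> float:
        return self.enzyme2.vmax(self.reaction_volume)

    @property
    def K_eq(self) -> Optional[float]:
        """Haldane equilibrium ratio S2/S1 of the first reaction, if reversible."""
        if self.reverse1 is None:
            return None
        vf = self.enzyme1.k_cat * self.enzyme1.copies / self.enzyme1.K_M
        vr = self.reverse1.k_cat * self.reverse1.copies / self.reverse1.K_M
        if vr == 0:
            return math.inf
        return vf / vr

    def rate1(self, S1: ArrayLike, S2: ArrayLike = 0.0) -> ArrayLike:
        """Net volumetric rate (uM/s) of the first reaction at (S1, S2)."""
        fwd = (self.vmax1, self.enzyme1.K_M)
        if self.rate_law is RateLaw.REVERSIBLE_MM:
            rev = (self.reverse1.vmax(self.reaction_volume), self.reverse1.K_M)
            return reversible_interconversion_rate(S1, S2, fwd, rev)
        return michaelis_menten_rate(S1, *fwd)

    def rate2(self, S2: ArrayLike) -> ArrayLike:
        """Volumetric rate (uM/s) of the second (product-forming) reaction."""
        return michaelis_menten_rate(S2, self.vmax2, self.enzyme2.K_M)

    def with_strategy(self, strategy: Union[Strategy, str]) -> "SystemSpec":
        return replace(self, strategy=Strategy(strategy))


#: Recognized targets for :func:`apply_fold_change`.
FOLD_CHANGE_TARGETS = (
    "k_cat_both",
    "K_M_both",
    "k_cat_enzyme1",
    "k_cat_enzyme2",
    "K_M_enzyme1",
    "K_M_enzyme2",
    "k_cat_E0_enzyme1",
    "k_cat_E0_enzyme2",
)


def apply_fold_change(spec: SystemSpec, target: str, factor: float) -> SystemSpec:
    """Return a new spec with a kinetic parameter *improved* by ``factor``.

    "Improvement" multiplies k_cat-like targets and divides K_M targets (a
    smaller Michaelis constant is the better enzyme).  ``k_cat_E0`` targets
    scale k_cat at fixed copy number, i.e. they scale the activity product
    k_cat * E0.  The input spec is unchanged.
    """
    if factor <= 0:
        raise InvalidParameterError(f"fold-change factor must be > 0, got {factor}")
    if target not in FOLD_CHANGE_TARGETS:
        raise InvalidParameterError(
            f"unknown fold-change target {target!r}; expected one of {FOLD_CHANGE_TARGETS}"
        )
    e1, e2 = spec.enzyme1, spec.enzyme2
    if target in ("k_cat_both", "k_cat_enzyme1", "k_cat_E0_enzyme1"):
        e1 = replace(e1, k_cat=e1.k_cat * factor)
    if target in ("k_cat_both", "k_cat_enzyme2", "k_cat_E0_enzyme2"):
        e2 = replace(e2, k_cat=e2.k_cat * factor)
    if target in ("K_M_both", "K_M_enzyme1"):
        e1 = replace(e1, K_M=e1.K_M / factor)
    if target in ("K_M_both", "K_M_enzyme2"):
        e2 = replace(e2, K_M=e2.K_M / factor)
    return replace(spec, enzyme1=e1, enzyme2=e2)
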