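"""Literature parameter presets for the two worked pathways.

``pdu``
    Native 1,2-propanediol utilization in the Pdu microcompartment of
    *Salmonella enterica*: S1 = 1,2-propanediol, S2 = propionaldehyde,
    enzyme 1 = PduCDE (diol dehydratase), enzyme 2 = PduP/Q.

``mevalonate``
    Heterologous mevalonate synthesis: S1 = acetoacetyl-CoA (approximated as a
    constant far-field concentration), S2 = HMG-CoA, enzyme 1 = HMGS,
    enzyme 2 = HMGR.  Only kinetics, copy numbers and membrane permeabilities
    differ from the Pdu case; geometry, diffusivity, shell permeability and
    external concentrations are shared.
"""

from __future__ import annotations

from dataclasses import replace

from .core import (
    EnzymeKinetics,
    ExternalConditions,
    Geometry,
    Strategy,
    SystemSpec,
    TransportParams,
)
from .errors import UnknownPresetError

__all__ = ["preset", "PRESET_NAMES"]


def _pdu() -> SystemSpec:
    return SystemSpec(
        enzyme1=EnzymeKinetics(k_cat=3.0e2, K_M=5.0e2, copies=1.5e3),   # PduCDE
        enzyme2=EnzymeKinetics(k_cat=55.0, K_M=1.5e4, copies=2.5e3),    # PduP/Q
        transport=TransportParams(
            D=1.0e-5,
            k_m_S1=1.0e-2,
            k_m_S2=1.0e-2,
            k_c_S1=1.0e-5,
            k_c_S2=1.0e-5,
        ),
        geometry=Geometry(R_b=5.0e-5, R_c=1.0e-5),
        conditions=ExternalConditions(S1_out=5.5e4, S2_out=0.0),
        strategy=Strategy.ORGANELLE,
    )


def _mevalonate() -> SystemSpec:
    base = _pdu()
    return replace(
        base,
        enzyme1=EnzymeKinetics(k_cat=1.83, K_M=5.0, copies=5.0e5),      # HMGS
        enzyme2=EnzymeKinetics(k_cat=0.023, K_M=1.0e2, copies=5.0e5),   # HMGR
        transport=replace(base.transport, k_m_S1=1.0e-4, k_m_S2=1.0e-4),
    )


_BUILDERS = {"pdu": _pdu, "mevalonate": _mevalonate}

PRESET_NAMES = tuple(sorted(_BUILDERS))


def preset(name: str) -> SystemSpec:
    """Return a fresh :class:`SystemSpec` for a named literature preset."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {PRESET_NAMES}"
        ) from None
    return builder()
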