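# spatialflux

Steady-state kinetics of a two-enzyme pathway in a spherical bacterial
cell, under three spatial-organization strategies: enzymes free in the
cytosol, co-localized on a **scaffold**, or encapsulated in a
**microcompartment organelle**.  The package answers a concrete metabolic
engineering question: *given a pathway's kinetics, its metabolites'
transport properties and the culture conditions, which organization
strategy maximizes pathway flux — or minimizes loss of the intermediate to
the medium?*

## The model

A substrate S1 enters a cell of radius `R_b` from a constant external
medium, is converted by enzyme 1 to an intermediate S2 (which can leak back
across the membrane), and by enzyme 2 to product.  At steady state, in
spherical symmetry:

    D ∇²S1 − R1 = 0,   D ∇²S2 + R1 − R2 = 0,   R_i = V_i S_i/(K_i + S_i)

with reactions confined to the enzyme-bearing region — the whole cell, or a
concentric organizing sphere of radius `R_c` — Robin mass-transfer
conditions `D dS/dr = k_m (S_out − S)` at the membrane, an analogous
condition with shell permeability `k_c` at an organelle boundary, and
symmetry at the origin.  A scaffold is an organelle whose boundary
permeability approximates free diffusion (`k_c = 10³ cm/s`).

Organized cases are solved in closed form (well-mixed compartment + series
transport resistances + bracketed root finding); the unorganized case and
full-resolution validation use a conservative finite-volume Newton solver.
Literature parameter presets are built in for native 1,2-propanediol
utilization in the Pdu microcompartment (`pdu`) and for scaffolded
mevalonate synthesis (`mevalonate`).  See `docs/methods.md` for the
complete model description and numerical choices.

## Worked example

```python
import spatialflux as sf

pdu = sf.preset("pdu")                      # Salmonella Pdu MCP parameters
for strategy in sf.Strategy:
    sol = sf.solve_steady_state(pdu.with_strategy(strategy))
    print(f"{strategy.value:10s} flux {sf.pathway_flux(sol):.3e}  "
          f"leakage {sf.intermediate_leakage(sol):.3e}  (umol/cell/s)")
```

prints

```
organelle  flux 1.644e-13  leakage 4.850e-13  (umol/cell/s)
scaffold   flux 4.305e-17  leakage 7.405e-13  (umol/cell/s)
none       flux 3.623e-17  leakage 7.405e-13  (umol/cell/s)
```

Encapsulation boosts the Pdu pathway's product flux by a factor ~4.5×10³
over free enzymes (the intermediate is concentrated around PduP/Q, whose
K_M is a steep 15 mM), while scaffolding — co-localization without a
diffusion barrier — gains almost nothing and leaks the most intermediate.
A converted growth observation for this system (`sf.flux_from_growth`,
~2.9×10⁻¹³ umol/cell/s) sits right at the encapsulated prediction.

Design-space queries use the same objects:

```python
import numpy as np

comp = sf.compare_strategies(pdu, "max_flux")         # -> organelle
sweep = sf.sweep_1d(pdu, "conditions.S1_out", [1e3, 1e4, 1e5])
smap  = sf.optimal_strategy_map(
    pdu,
    ("enzyme1.kcat_E0", 10.0**np.arange(1, 8)),
    ("enzyme2.kcat_E0", 10.0**np.arange(-1, 6)),
    objective="max_flux",
)
smap.plot()                                            # categorical heat map
```

The same operations are available from a shell:

```sh
spatialflux solve --preset pdu --strategy organelle --out run/
spatialflux sweep --preset mevalonate --parameter conditions.S1_out \
    --log-range 5e2 5e4 10 --out sweep.csv
spatialflux map --preset pdu --x-parameter enzyme1.kcat_E0 \
    --x-range 1e1 1e7 25 --y-parameter enzyme2.kcat_E0 \
    --y-range 1e-1 1e5 25 --objective min_leakage --out map.csv
spatialflux calibrate --mode titer --titer 1e4 --duration 172800
```

Every output file embeds the fully resolved parameter set in its header,
and identical configs produce byte-identical files.

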