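# Methods

## The model

`spatialflux` computes steady states of a sequential two-enzyme pathway

    S1  --E1-->  S2  --E2-->  product

inside a spherically symmetric bacterial cell of radius `R_b`, with the
substrate `S1` supplied from a well-stirred external medium and the
intermediate `S2` free to escape across the cell membrane.  Three ways of
organizing the enzymes are compared on identical kinetic and transport
parameters:

- **none** — all enzyme copies distributed uniformly through the cell volume;
- **scaffold** — all copies co-localized in a concentric sphere of radius
  `R_c` with no diffusion barrier around it;
- **organelle** — the same sphere bounded by a semi-permeable shell
  (a bacterial-microcompartment-like boundary with mass-transfer coefficient
  `k_c` per species).

Both species obey steady-state reaction-diffusion equations in spherical
symmetry.  In the enzyme-bearing region

    D lap(S1) - R1 = 0
    D lap(S2) + R1 - R2 = 0,      R_i = V_i S_i / (K_i + S_i)

and `D lap(S) = 0` in the enzyme-free cytosol.  `V_i` is the volumetric
maximum rate of all copies of enzyme *i* over the volume that hosts them
(`(4/3) pi R_c^3` when organized, the cell volume otherwise):
`V_i = k_cat,i * N_i / (N_A * V)`.  Boundary conditions are Robin
(mass-transfer) laws at the cell membrane,
`D dS/dr(R_b) = k_m (S_out - S(R_b))`, the analogous law with `k_c` at the
compartment boundary, and symmetry at the origin.  A single concentric
compartment stands in for the several microcompartments of a real cell; a
scaffold is modeled as a compartment whose boundary permeability is set to
the free-diffusion surrogate value `k_c = 1e3 cm/s`.

Units are fixed package-wide: cm, s, uM, cm^2/s, cm/s, and per-cell fluxes
in umol/cell/s (1 uM·cm^3 = 1e-3 umol; N_A = 6.02214e23/mol).

Reported quantities: **pathway flux** is the per-cell product-formation rate
(the volume total of the second reaction); at steady state it equals
substrate consumption minus **intermediate leakage**, the membrane efflux
`4 pi R_b^2 k_m (S2(R_b) - S2_out)`.  Where a figure-of-merit could equally
have been substrate consumption, this package deliberately uses product
formation; with an irreversible second step the two differ exactly by the
leakage term.

## Analytic route (organized strategies)

With all enzymes inside `R_c` the cytosol shell is reaction-free, so each
species profile is harmonic, `S(r) = a + b/r`, and the radial current
through every shell is the same.  Treating the compartment as well mixed,
the membrane, the cytosol shell and the compartment boundary act as series
resistances

    Omega = 1/(4 pi R_b^2 k_m) + (1/R_c - 1/R_b)/(4 pi D) + 1/(4 pi R_c^2 k_c)

and the steady state reduces to two scalar balances for the compartment
concentrations,

    S1_c = S1_out - I1 Omega_1,   I1 = V_c R1(S1_c, S2_c)
    S2_c = S2_out + I2 Omega_2,   I2 = V_c (R1 - R2(S2_c)).

Both are monotone in their own unknown, so they are solved by nested Brent
bracketing (outer in `S1_c`, inner in `S2_c`) with adaptive upper brackets.
This converges unconditionally, needs no initial guess or damping schedule,
and handles the optional reversible first reaction (below) through the same
nesting.  Default tolerance: 1e-10 relative residual on both balances.

## Finite-volume route (unorganized case and validation)

The unorganized case, where reactions occur everywhere, has no closed form;
it is solved on a radial grid by Newton iteration over a vertex-centered
finite-volume discretization.  The same discretization, with the reaction
terms active only for `r < R_c`, a duplicated node at the interface and the
`k_c` jump condition applied on the interface face, resolves the organized
cases in full spatial detail and serves as the oracle for the well-mixed
assumption of the analytic route.

Numerical choices, and why:

- **Vertex-centered finite volumes** (nodes at vertices, fluxes on
  mid-faces) are algebraically a second-order central-difference scheme on
  the uniform per-region grids, but their face currents telescope: at
  convergence, membrane influx equals the volume-integrated reaction total
  to the *nonlinear-solver* tolerance rather than to truncation order.  The
  three-way mass-conservation audits are therefore meaningful solver
  diagnostics, not grid-limited approximations.  The origin needs no
  special-casing (the inner face of the first cell has zero area), and the
  Robin conditions are imposed exactly on the boundary faces.
- **Draw-down variables.**  The unknowns are `x1 = S1_out - S1` and
  `x2 = S2 - S2_out`.  In transport-dominated regimes (Pdu: membrane
  draw-down ~2 uM against `S_ext` = 5.5e4 uM) raw concentrations leave
  round-off residuals of order `eps * S_ext * D f^2/h`, which caps the
  conservation identities near 1e-5 relative; the draw-down form keeps them
  near machine precision (observed ~1e-12).
- **Newton with the exact sparse Jacobian**, damped by step halving, run
  past the tolerance to the first non-improving step so no coherent O(tol)
  imbalance is left in the conservation identities.  Michaelis-Menten terms
  are extended linearly (C1) below S = 0 so transiently undershooting
  iterates remain well defined; converged solutions are non-negative.
- **Round-off-aware convergence flag.**  In nearly sealed compartments
  (`k_c` ~ 1e-9 cm/s) the residual floor `eps * (coefficient * unknown)`
  exceeds any fixed relative tolerance even though the solution is exact to
  representation; each residual row is therefore measured against
  `max(problem scale, 8 * floor / tol)`.  The same guard is applied to the
  two analytic balances.
- **Grid.**  Default 400 nodes allocated to `[0, R_c]` and `[R_c, R_b]` in
  proportion to length (floor of 16 per region), a node exactly at `R_c`.
  Halving the spacing moves the Pdu unorganized flux by ~4e-8 relative; the
  optional `verify_grid` flag re-solves on a doubled grid and warns at >1%.
  400 nodes keeps a full 3-strategy comparison under ~50 ms, which is what
  makes 25 x 25 design-space maps desk-scale.

A closed-form oracle for the unorganized solver exists in the linear regime
`S << K_M`: the linearized system has modified-spherical-Bessel (sinh/r)
solutions, against which the solver agrees to <0.5% (test suite).

## Reversible first reaction

The default rate law is irreversible Michaelis-Menten for both steps.  For
pathways whose first step is a reversible interconversion (the
carbonic-anhydrase step of the carboxysome is the motivating case), the
first reaction can be switched to opposing Michaelis-Menten terms,
`R1 = V_f S1/(K_f + S1) - V_r S2/(K_r + S2)`, by supplying reverse kinetics.
With zero reverse rate this reduces *exactly* to the irreversible law.  The
functional form is this package's choice, validated by its limit properties:
the qualitative carboxysome behavior follows — an irreversible first step
plus a tight shell accumulates intermediate without bound (S2_c ~ 1/k_c),
while a reversible step cannot push the compartment past its interconversion
balance point `S2_eq` with `V_r S2_eq/(K_r + S2_eq) = V_f S1_c/(K_f + S1_c)`,
a fundamental cap on the attainable local concentration.  Boundedness
requires that balance point to exist (the reverse branch must be able to
match the operating forward rate below its own saturation); otherwise the
reversible law degenerates to effectively irreversible behavior.

## Parameter presets

Two literature systems are built in (Methods tables of the source
literature for the Pdu microcompartment of *S. enterica* and for scaffolded
mevalonate synthesis):

| parameter | pdu | mevalonate |
|---|---|---|
| enzyme 1 (k_cat 1/s, K_M uM, copies) | PduCDE: 300, 500, 1.5e3 | HMGS: 1.83, 5, 5e5 |
| enzyme 2 (k_cat 1/s, K_M uM, copies) | PduP/Q: 55, 1.5e4, 2.5e3 | HMGR: 0.023, 100, 5e5 |
| k_m (cm/s, both species) | 1e-2 | 1e-4 |
| k_c (cm/s, both species) | 1e-5 | 1e-5 |
| D (cm^2/s); R_b, R_c (cm) | 1e-5; 5e-5, 1e-5 | same |
| S1_out (uM); S2_out | 5.5e4; 0 | same |

The mevalonate preset inherits every unlisted value from the Pdu system,
including the external concentration (the constant-far-field approximation
of intracellularly produced acetoacetyl-CoA) and the shell permeability.

## Design-space analysis

`compare_strategies` solves all three strategies on shared parameters and
selects the optimum for one of two objectives: maximum pathway flux or
minimum intermediate leakage.  Values within 1e-3 relative of the optimum
are treated as tied, and ties break toward the least engineering effort
(none > scaffold > organelle).  The tolerance matters: for mevalonate-like
kinetics the scaffold's flux advantage over free enzymes is only ~2e-4
relative, inside the tie band, so maps color such regions "none" even where
the scaffold's raw flux is (marginally) highest.  `sweep_1d` and
`optimal_strategy_map` evaluate this comparison along one or two dotted
parameter paths (log-spaced grids by default, spanning the baseline by a
few decades; exact figure axis ranges in the source literature are not
recoverable, so ranges are user-configurable).  The composite path
`enzymeN.kcat_E0` sets the activity product k_cat*E0 (uM/s over the cell
volume) by scaling k_cat at fixed copy number.  Cells where any strategy
fails to converge are flagged "unconverged", never interpolated.

## Calibration conversions

To place literature observations on the model's per-cell axis:
growth observations convert as `flux = (cell_mass/doubling_time) /
mass_fraction / molar_mass` — the mass-accumulation convention (no ln 2
factor), which reproduces the source arithmetic from its stated inputs —
and titers as `flux = titer / (duration * cell_density)`.  The molar mass
of 1,2-propanediol (76.09 g/mol) is fixed as the default substrate mass.

## Known limitations

- The well-mixed-compartment analytic route is quantitatively wrong by a
  few percent where the organizing volume hosts steep internal source
  gradients against a low local intermediate level; for the Pdu scaffold
  the finite-volume flux is 4.0% above the well-mixed value (the other
  preset/strategy combinations agree to 1e-4 or better).  The finite-volume
  route exists precisely to quantify this.
- The external medium is an infinite reservoir; batch-culture depletion is
  represented only parametrically by sweeping `S1_out`.
- Only two species are tracked; product export, cofactors, competing
  cytosolic reactions, and multiple discrete organelles are out of scope,
  as are transient (non-steady-state) dynamics.
- Membrane and shell permeabilities are taken as given parameters; nothing
  here estimates them from chemical structure.
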