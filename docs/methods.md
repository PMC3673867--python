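# Methods

## The modelling problem

*Geobacter sulfurreducens* in a microbial fuel cell (MFC) can deliver
electrons to the anode three ways: directly through outer-membrane c-type
cytochromes (DET), through an exogenous mediator that strips electrons from
NADH (MET), or both at once (Mixed).  The package asks, on a stoichiometric
model of the organism's metabolism, how much current each coupling can
sustain and which reactions supply the reducing equivalents — a pure
constraint-based (flux-balance) question, deliberately ignoring mediator
chemistry, anode kinetics and all ohmic/polarization losses.  Every
electrical figure the package produces is therefore a stoichiometric upper
bound.

## Flux balance analysis and its constraint space

A model is the polyhedron `S·v = 0, lb ≤ v ≤ ub` over reaction fluxes `v`
(mmol/gDW/h).  FBA maximizes a weighted flux combination by linear
programming; flux variability analysis (FVA) then reports, per reaction,
the minimum and maximum flux attainable while the objective stays at its
optimum `Z*`.  Implementation choices:

* Backend: HiGHS through `scipy.optimize.linprog`, behind a single abstract
  solver interface (matrix, bounds, costs, sense → status, vertex, value).
  Solver tolerances are requested at 1e-9; returned solutions are asserted
  mass-balanced to 1e-6 per metabolite.
* Objective fixing uses `c·v ≥ f·Z* − max(1e-6, 1e-6·|Z*|)` rather than an
  equality; strict equality is brittle under simplex tolerances.  The
  fraction `f` defaults to 1.  The slack propagates into FVA bounds scaled
  by the flux sensitivities (about 100× on the miniature fixture), which is
  why cross-checks against an exact-fixing implementation use a 1e-3
  tolerance.
* Degenerate optima are endemic in metabolic LPs; the witness vertex a
  solver returns is arbitrary and is not part of any contract here.  Only
  objective values and FVA interval endpoints are.
* The default "effectively infinite" bound is ±1000 mmol/gDW/h
  (configurable).  A tighter artificial cap keeps loop fluxes visibly
  implausible without degrading solver conditioning.

## Futile-cycle elimination (the FATMIN pipeline)

Mass balance alone does not forbid internal cycles that carry flux without
net production; they violate a Kirchhoff-like loop law.  In FVA they show
up as ranges saturating the artificial cap, and for a highly connected
currency metabolite such as NADH they corrupt any attempt to read supply
capabilities from flux ranges.  The pipeline implemented here removes the
loop contributions for one *target metabolite* at a time:

1. FBA (`Z*`), then FVA at fixed `Z*`.
2. Weighted ranges: each reaction's flux range times its signed target
   stoichiometry, giving per-reaction target-production intervals.
3. Reactions whose weighted bounds exceed a threshold `T` in magnitude
   become targets.  `T` defaults to 100 mmol/gDW/h and must exceed any
   realistic flux for the model at hand, so it is a parameter.
4. An artificial metabolite is added as a product to every producing branch
   of every target, with coefficient equal to that branch's target
   stoichiometry — not 1 — so the added drain (`FluxMin`) measures
   *metabolite production* in the metabolite's own units and steps 2 and 7
   stay commensurable.  A unit-coefficient network is the special case.
5. `FluxMin` is minimized at fixed `Z*`.  Reversible targets whose lower
   weighted bound also breaches `−T` are conceptually split into forward
   and backward halves; because the consuming half contributes nothing to
   the drain it is simply clamped to zero *during this minimization only*.
   Production committed to the objective cannot shrink, so exactly the
   cyclic components collapse.
6. FVA on the augmented network with both constraints active: `Z*` fixed
   and `FluxMin ≤ minimum + 1e-6` (an equality-like cap), all original
   bounds restored.  Re-fixing `Z*` alongside the drain cap is the stricter
   of the two readings of the procedure and is the one implemented.
7. Weighted ranges recomputed: loop-free and jointly feasible.

Properties the test suite enforces: augmentation alone changes no FVA bound
(the artificial metabolite drains freely); post-pipeline ranges are subsets
of pre-pipeline ranges; planted cycles collapse to `[0, 0]`; a cycle
superimposed on a productive path is reduced to exactly the productive
component; several target metabolites are handled by sequential runs, each
introducing its own uniquely named artificial metabolite and drain.

Caveats.  A target that is a *pure* consumer above `T` has no producing
branch to tag; it is pinned indirectly once the producers feeding it
collapse.  If clamping a split target's consuming direction makes the
minimization infeasible, the threshold was set below a flux the objective
genuinely needs — the error surfaces explicitly rather than being absorbed.
The pipeline removes rays and linealities (unbounded cycle directions), not
the full vertex description of the optimal polytope: the resulting ranges
still describe a bounding box, not the polytope's shape.

## Electrode coupling and the COI objective

Electron extraction is modelled by pseudo-reactions: `1NADHmfc` /
`2NADHmfc` commit NADH to a mediator and reoxidize it at the anode (MET),
and `3Cytcmfc` drains the extracellular electron-disposal token produced by
the cytochrome-c reductase reaction (DET).  The ids follow the published
reaction tables for traceability.  The compound objective is

    biomass·1 + COI_MET·v(2NADHmfc) + COI_DET·v(3Cytcmfc)

where the COI (coefficient of importance) is the priority of electron
transfer relative to growth.  Sweeping COI over 1…3000 traces the
transition from growth-dominated to electron-dominated metabolic states;
by LP parametrics the electron component is non-decreasing and the growth
component non-increasing in COI.  Mixed mode uses equal COIs by default.
One transfer cycle carries two electrons (one NADH oxidation, or one
cytochrome-reductase turnover yielding two reduced cytochrome equivalents);
scan rows keep drain fluxes in cycle units and expose the ×2 electron
equivalents separately, which is the convention under which the published
amperage table is internally consistent.

The trade-off frontier fixes `biomass ≥ g` (an inequality, so unreachable
exact values cannot cause infeasibility) on a uniform growth grid and
maximizes the drain flux.  The reported internal NADH consumption at each
point comes from a loop-cleaned witness: with the frontier fluxes pinned,
every NADH-producing branch is tagged and the tagged production minimized —
the FATMIN minimization applied to all producers — before consuming fluxes
are summed.  Without this, planted loops would inflate the figure by up to
the flux cap.

## Electrochemical conversion layer

* Current: `I = flux × 96485 / 3.6e6` A/gDW per mmol e⁻/gDW/h.  The exact
  ratio is used everywhere, not the rounded 0.0268.
* Coulombic efficiency: `CE% = 100 × e_flux / (8 × acetate_uptake)`; full
  oxidation of one acetate yields 8 electrons.  Acetate is assumed the sole
  substrate.
* EMF at pH 7 formal potentials: cathode O₂/H₂O +0.51 V; anode −0.320 V
  (NAD⁺/NADH, MET) or +0.254 V (cytochrome c, DET), giving 0.83 V and
  0.256 V.  For Mixed mode the published power figures are reproducible
  only by applying the MET couple's 0.83 V to the *total* current; that
  convention is the default, with a channel-resolved alternative
  (`mixed_power_per_channel`) available.
* Biofilm areal figures convert to biomass-specific ones by dividing by
  `protein_density / protein_fraction` gDW/m².

## The synthetic fixtures and what they do (not) show

`figure5_network` is the canonical loop demonstration: a source (10
mmol/gDW/h, pinned so tests have concrete numbers), two parallel routes to
a target metabolite, a drain objective, two closed two-reaction cycles
through the target, and two structurally dead paths.  Where the published
sketch leaves the dead paths' attachment open, they are wired as an inlet
from an unsourced metabolite and an outlet to an unsinked one, which forces
their zero flux through mass balance alone.

`mini_geobacter` is a 14-reaction acetate-fed respiring network built so
every headline behaviour of the full organism has a hand-computable
analogue (derivations in its docstring): lumped acetate oxidation (4 NADH
per acetate, matching 8 electrons), lumped oxidative phosphorylation
(P/O = 2), a cytochrome branch ending in Fe(III) reduction, a biomass
equation, non-growth ATP maintenance (0.45 mmol/gDW/h), the published
uptake caps (acetate 18, Fe(III) 568 mmol/gDW/h) and one planted NADH
futile loop.  Its ground truths: maximal growth 1.19625 1/h, MET electron
ceiling 71.775 and DET ceiling 72 cycles/gDW/h, uptake-sweep slope exactly
4 cycles per acetate.  In COI sweeps the biomass term uses weight 3600 —
the fixture's frontier trades 60 cycle units per unit growth, so this
places the growth/electron crossover at COI 60, inside the canonical
1…3000 sweep; it plays the role of the unit-conversion factor that a
genome-scale biomass equation hides in its gram-scaled coefficients.

`random_loop_network` generates seeded backbone-plus-planted-cycle
networks (≤ 60 reactions) with the loop membership returned as ground
truth, including a superposition variant where a cycle rides on the
productive producer.

What the fixtures do not emulate: genome-scale redundancy (hundreds of
alternative NADH producers), realistic growth magnitudes (the miniature
biomass equation is not gram-scaled, so 1.19625 1/h is a toy number),
compartmentalized proton accounting, and the published organism-specific
flux values.  Passing tests therefore demonstrate the correctness of the
algorithms and conversions, not numerical agreement with the genome-scale
network, which requires loading that SBML model through the same public
API (`tests/test_acceptance.py` picks it up from
`data/g_sulfurreducens.xml` when present).

## Verification strategy

Two independent routes check every LP-derived claim: a brute-force vertex
enumeration oracle (null-space parametrisation of `S·v = 0`, all d-subsets
of bound constraints; tractable to ~20 reactions and ~5 degrees of
freedom) for the small fixtures, and COBRApy as an independent FBA/FVA
implementation for the miniature network.  The electrochemistry layer is
pinned against the published comparison table's own internal arithmetic.
Problem sizes in the shipped tests and the acceptance script — the toy
network, 14-reaction miniature, and 50 planted-loop instances of 10–16
reactions — were chosen so the whole suite solves a few thousand small LPs,
which completes in well under a minute.

## Known limitations

* No gene–protein–reaction rules, knockouts, or strain-design search.
* No thermodynamic (ΔG-based) loop removal; the pipeline is purely
  LP-based and targeted at one metabolite at a time.
* No quadratic/nonlinear programming; no Nernst corrections for
  non-standard conditions.
* SBML support covers Level 2 kinetic-law bounds and Level 3 `fbc`
  bounds/objectives; multi-objective `fbc` documents are reduced to the
  single active objective.
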