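"""Deterministic desk-scale fixture networks with known ground truth.

Three families:

* :func:`figure5_network` — the canonical futile-cycle demonstration: two
  productive routes to a target metabolite plus two closed cycles whose FVA
  ranges saturate the artificial flux cap until the loop-removal pipeline
  collapses them.
* :func:`mini_geobacter` — a ~15-reaction acetate-fed respiring network
  with NADH producers/consumers, a cytochrome-c reductase branch and one
  planted NADH futile loop, supporting all three fuel-cell modes end to
  end with hand-computable optima (derivations in the docstring).
* :func:`random_loop_network` — seeded random networks with planted cycles
  through a target metabolite, for property tests: the generator returns
  the loop membership as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from voltflux.errors import ModelValidationError
from voltflux.model_core import MetabolicModel, Metabolite, Reaction


@dataclass
class LoopSpec:
    """Specification/ground truth for a random planted-loop network.

    ``loop_members`` is filled by the generator: one list of reaction ids
    per planted cycle, whose stoichiometric columns sum to zero over the
    internal metabolites (a closed cycle).  ``share_backbone=True`` plants
    the first cycle through the productive target-producing reaction, the
    superposition case where loop flux rides on top of productive flux.
    """

    n_reactions: int = 20
    n_loops: int = 2
    seed: int = 0
    share_backbone: bool = False
    loop_members: List[List[str]] = field(default_factory=list)


def figure5_network(source_bound: float = 10.0, cap: float = 1000.0) -> MetabolicModel:
    """Toy network: two routes producing C, two futile cycles, two dead paths.

    All reactions are irreversible.  ``SRC`` feeds A at up to
    ``source_bound``; ``R1`` and ``R2`` are alternative A→C routes; cycles
    5 and 6 are the reaction pairs (``R5A``/``R5B``) and (``R6A``/``R6B``)
    exchanging C with D and E; ``R3``/``R4`` are structurally dead paths (an
    inlet from an unsourced metabolite and an outlet to an unsinked one)
    that carry no flux with the directions as written.  The objective is
    the C drain, so the optimum is ``source_bound``.

    With the drain objective fixed, FVA reports both cycles free up to
    ``cap``; augmenting every producer of C makes the drain flux equal
    ``v1 + v2 + v5 + v6`` and its minimum at the fixed optimum is
    ``source_bound`` with both cycles at zero.
    """
    model = MetabolicModel(id="figure5_toy")
    for met in "ACDEXY":
        model.add_metabolite(Metabolite(met, compartment="c"))
    rxns = [
        Reaction("SRC", {"A": 1.0}, 0.0, source_bound, name="substrate source"),
        Reaction("R1", {"A": -1.0, "C": 1.0}, 0.0, cap, name="route 1"),
        Reaction("R2", {"A": -1.0, "C": 1.0}, 0.0, cap, name="route 2"),
        Reaction("R5A", {"D": -1.0, "C": 1.0}, 0.0, cap, name="cycle 5 producing leg"),
        Reaction("R5B", {"C": -1.0, "D": 1.0}, 0.0, cap, name="cycle 5 return leg"),
        Reaction("R6A", {"E": -1.0, "C": 1.0}, 0.0, cap, name="cycle 6 producing leg"),
        Reaction("R6B", {"C": -1.0, "E": 1.0}, 0.0, cap, name="cycle 6 return leg"),
        Reaction("R3", {"X": -1.0, "C": 1.0}, 0.0, cap, name="dead path 3 (X unsourced)"),
        Reaction("R4", {"C": -1.0, "Y": 1.0}, 0.0, cap, name="dead path 4 (Y unsinked)"),
        Reaction("DRAIN", {"C": -1.0}, 0.0, cap, name="target drain"),
    ]
    for rxn in rxns:
        model.add_reaction(rxn)
    model.objective = {"DRAIN": 1.0}
    model.validate()
    return model


FIGURE5_CYCLE_REACTIONS = ("R5A", "R5B", "R6A", "R6B")
FIGURE5_PRODUCTION_REACTIONS = ("R1", "R2")


def mini_geobacter(
    acetate_uptake: float = 18.0,
    ngam: float = 0.45,
    fe3_uptake: float = 568.0,
    cap: float = 1000.0,
    with_nadh_loop: bool = True,
) -> MetabolicModel:
    """Miniature acetate-fed respiring network supporting all three modes.

    Structure (all coefficients integral; uptake is a negative exchange
    flux):

    * ``EX_ac`` / ``ACt`` — acetate exchange (lb = −uptake) and transport.
    * ``ACOX: ac + 4 nad → 4 nadh + 2 co2`` — lumped oxidation; one acetate
      yields 4 NADH = 8 electrons, matching full oxidation.
    * ``ETC: nadh + mqn7 + 2 adp → nad + mql7 + 2 atp`` — lumped oxidative
      phosphorylation (P/O = 2).
    * ``CYOR1m: 2 ficytcc + mql7 → 2 focytcc + h_edm + mqn7`` — cytochrome-c
      reductase producing the extracellular electron-disposal token.
    * ``FERCYT: fe3 + focytcc → fe2 + ficytcc`` — Fe(III) reduction closing
      the cytochrome cycle, with ``EX_fe3`` capped at −``fe3_uptake``.
    * ``BIOMASS: 10 ac + 20 atp + 10 nadh → 20 adp + 10 nad`` (flux in 1/h).
    * ``ATPM: atp → adp`` with lower bound ``ngam``.
    * one NADH futile loop ``NADHL1``/``NADHL2`` (NADH ⇄ via a dummy redox
      pair), both capped at ``cap``.

    Hand-computed ground truth at uptake u = 18, ngam = 0.45 (let g =
    growth, a = ACOX flux, n = ETC flux; balances: a = u − 10g,
    n = 4a − 10g = 72 − 50g, ATP: 2n ≥ 20g + ngam):

    * max growth  g* = (8u − ngam)/120 = 143.55/120 = **1.19625 1/h**;
    * MET ceiling: NADH to mediator M = 4a − n with 2n ≥ ngam, so
      M* = 72 − ngam/2 = **71.775 mmol/gDW/h** (143.55 electron mmol);
    * DET ceiling: all NADH through ETC, h_edm flux = **72 mmol/gDW/h**
      (144 electron mmol, CE 100%), FERCYT = 144 ≤ fe3 cap.
    """
    model = MetabolicModel(id="mini_geobacter")
    mets = [
        ("ac_e", "e"), ("ac", "c"), ("co2", "c"),
        ("nad", "c"), ("nadh", "c"), ("atp", "c"), ("adp", "c"),
        ("mqn7", "c"), ("mql7", "c"), ("ficytcc", "c"), ("focytcc", "c"),
        ("fe3", "e"), ("fe2", "e"), ("h_edm", "e"),
    ]
    for mid, comp in mets:
        model.add_metabolite(Metabolite(mid, compartment=comp))
    rxns = [
        Reaction("EX_ac", {"ac_e": -1.0}, -acetate_uptake, 0.0, reversible=True,
                 name="acetate exchange"),
        Reaction("ACt", {"ac_e": -1.0, "ac": 1.0}, 0.0, cap, name="acetate transport"),
        Reaction("ACOX", {"ac": -1.0, "nad": -4.0, "nadh": 4.0, "co2": 2.0},
                 0.0, cap, name="lumped acetate oxidation"),
        Reaction("EX_co2", {"co2": -1.0}, -cap, cap, reversible=True,
                 name="CO2 exchange"),
        Reaction("ETC", {"nadh": -1.0, "mqn7": -1.0, "adp": -2.0,
                         "nad": 1.0, "mql7": 1.0, "atp": 2.0},
                 0.0, cap, name="lumped oxidative phosphorylation"),
        Reaction("CYOR1m", {"ficytcc": -2.0, "mql7": -1.0,
                            "focytcc": 2.0, "h_edm": 1.0, "mqn7": 1.0},
                 0.0, cap, name="cytochrome-c reductase"),
        Reaction("FERCYT", {"fe3": -1.0, "focytcc": -1.0, "fe2": 1.0, "ficytcc": 1.0},
                 0.0, cap, name="Fe(III) reductase"),
        Reaction("EX_fe3", {"fe3": -1.0}, -fe3_uptake, 0.0, reversible=True,
                 name="Fe(III) exchange"),
        Reaction("EX_fe2", {"fe2": -1.0}, 0.0, cap, name="Fe(II) exchange"),
        Reaction("EX_h_edm", {"h_edm": -1.0}, 0.0, cap,
                 name="free proton/electron-token escape"),
        Reaction("ATPM", {"atp": -1.0, "adp": 1.0}, ngam, cap,
                 name="non-growth ATP maintenance"),
        Reaction("BIOMASS", {"ac": -10.0, "atp": -20.0, "nadh": -10.0,
                             "adp": 20.0, "nad": 10.0},
                 0.0, cap, name="biomass synthesis"),
    ]
    if with_nadh_loop:
        model.add_metabolite(Metabolite("qx", compartment="c"))
        model.add_metabolite(Metabolite("qxh", compartment="c"))
        rxns += [
            Reaction("NADHL1", {"nadh": -1.0, "qx": -1.0, "nad": 1.0, "qxh": 1.0},
                     0.0, cap, name="futile loop: NADH-consuming leg"),
            Reaction("NADHL2", {"qxh": -1.0, "nad": -1.0, "qx": 1.0, "nadh": 1.0},
                     0.0, cap, name="futile loop: NADH-producing leg"),
        ]
    for rxn in rxns:
        model.add_reaction(rxn)
    model.objective = {"BIOMASS": 1.0}
    model.biomass_reaction_id = "BIOMASS"
    model.validate()
    return model


MINI_GEOBACTER_LOOP = ("NADHL1", "NADHL2")


def random_loop_network(spec: LoopSpec) -> Tuple[MetabolicModel, LoopSpec]:
    """Seeded random network with planted cycles through a target metabolite.

    A linear productive backbone ``SRC → b0 → … → tgt → DRAIN`` (source
    capped at 10, drain is the objective) is decorated with ``n_loops``
    planted cycles of length 2 or 3 through ``tgt``, each capped at 1000 so
    FVA saturates visibly.  With ``share_backbone`` the first cycle returns
    from ``tgt`` into the last backbone intermediate, superimposing loop
    flux on the productive producer.  Returns the model and the spec with
    ``loop_members`` filled in.
    """
    if spec.n_loops < 0 or spec.n_reactions < 4 + 2 * spec.n_loops:
        raise ModelValidationError(
            f"spec infeasible: {spec.n_reactions} reactions cannot host "
            f"{spec.n_loops} loops plus a backbone"
        )
    if spec.n_reactions > 60:
        raise ModelValidationError("n_reactions must be <= 60 for oracle tractability")
    rng = np.random.default_rng(spec.seed)
    cap = 1000.0
    model = MetabolicModel(id=f"random_loops_seed{spec.seed}")
    model.add_metabolite(Metabolite("tgt", compartment="c"))
    loop_members: List[List[str]] = []

    budget = spec.n_reactions - 2 - 2 * spec.n_loops  # SRC + DRAIN reserved
    # 3-cycles cost one extra reaction each; spend leftover budget on them first
    lengths = []
    extra = budget - 1  # backbone needs at least one producing reaction
    for _ in range(spec.n_loops):
        if extra > 0 and rng.random() < 0.5:
            lengths.append(3)
            extra -= 1
        else:
            lengths.append(2)
    n_chain = budget - sum(L - 2 for L in lengths)  # backbone interior reactions
    assert n_chain >= 1

    # backbone: SRC -> b0 -> ... -> b_{k-1} -> tgt -> DRAIN
    chain_mets = [f"b{i}" for i in range(n_chain)]
    for m in chain_mets:
        model.add_metabolite(Metabolite(m, compartment="c"))
    model.add_reaction(Reaction("SRC", {chain_mets[0]: 1.0}, 0.0, 10.0))
    for i in range(n_chain - 1):
        model.add_reaction(
            Reaction(f"B{i}", {chain_mets[i]: -1.0, chain_mets[i + 1]: 1.0}, 0.0, cap)
        )
    producer = f"B{n_chain - 1}"
    model.add_reaction(Reaction(producer, {chain_mets[-1]: -1.0, "tgt": 1.0}, 0.0, cap))
    model.add_reaction(Reaction("DRAIN", {"tgt": -1.0}, 0.0, cap))

    for k, length in enumerate(lengths):
        if k == 0 and spec.share_backbone:
            # superposition: the cycle returns from tgt into the backbone,
            # so the productive producer also carries the loop flux
            members = [producer, f"L{k}ret"]
            model.add_reaction(
                Reaction(f"L{k}ret", {"tgt": -1.0, chain_mets[-1]: 1.0}, 0.0, cap)
            )
            loop_members.append(members)
            continue
        if length == 2:
            y = f"y{k}"
            model.add_metabolite(Metabolite(y, compartment="c"))
            model.add_reaction(Reaction(f"L{k}a", {y: -1.0, "tgt": 1.0}, 0.0, cap))
            model.add_reaction(Reaction(f"L{k}b", {"tgt": -1.0, y: 1.0}, 0.0, cap))
            loop_members.append([f"L{k}a", f"L{k}b"])
        else:
            y, z = f"y{k}", f"z{k}"
            model.add_metabolite(Metabolite(y, compartment="c"))
            model.add_metabolite(Metabolite(z, compartment="c"))
            model.add_reaction(Reaction(f"L{k}a", {y: -1.0, "tgt": 1.0}, 0.0, cap))
            model.add_reaction(Reaction(f"L{k}b", {"tgt": -1.0, z: 1.0}, 0.0, cap))
            model.add_reaction(Reaction(f"L{k}c", {z: -1.0, y: 1.0}, 0.0, cap))
            loop_members.append([f"L{k}a", f"L{k}b", f"L{k}c"])

    model.objective = {"DRAIN": 1.0}
    model.validate()
    out_spec = LoopSpec(
        n_reactions=len(model.reactions),
        n_loops=spec.n_loops,
        seed=spec.seed,
        share_backbone=spec.share_backbone,
        loop_members=loop_members,
    )
    return model, out_spec
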