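"""FATMIN: flux variability analysis with target-flux minimization.

Ordinary FVA on a loop-containing network reports implausibly high flux
ranges for reactions participating in futile cycles — internal cycles that
carry flux without net production, violating a Kirchhoff-like loop law that
plain mass-balance constraints do not enforce.  FATMIN removes those loop
contributions for all reactions touching one *target metabolite* (NADH in
the motivating application) without shrinking the genuine optimal solution
space:

1. FBA for the optimum ``Z*``; FVA at fixed ``Z*``.
2. Convert each reaction's flux range into a target-metabolite flux range
   (range × stoichiometric coefficient).
3. Reactions whose weighted bounds exceed a threshold ``T`` in absolute
   value are *target reactions*; where the lower weighted bound exceeds
   ``-T`` downward, the reaction is conceptually split and only its
   producing branch participates (operationally: its consuming direction is
   clamped to zero during the minimization step only).
4. Add an artificial metabolite to every producing branch of every target
   (coefficient = its target-metabolite production stoichiometry) plus a
   drain reaction ``FluxMin``, whose flux is then the total targeted
   production.
5. Minimize ``FluxMin`` at fixed ``Z*``: cyclic components collapse to
   zero because production committed to the objective cannot.
6. FVA on the augmented network with ``FluxMin`` capped at that minimum
   (and ``Z*`` still fixed), original bounds restored.
7. Re-derive the weighted ranges: now loop-free and feasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from voltflux.errors import UnknownIdError
from voltflux.lp_engine import (
    FluxRange,
    LPSolver,
    ScipyHighsSolver,
    flux_variability,
    minimize_reaction_flux,
    optimize,
)
from voltflux.model_core import MetabolicModel, Metabolite, Reaction

_DEFAULT_SOLVER = ScipyHighsSolver()

#: Default target threshold T, mmol/gDW/h.  Must exceed any realistic flux
#: value for the model at hand, so it is configurable.
DEFAULT_THRESHOLD = 100.0


class WeightedFluxRange(dict):
    """Per-reaction target-metabolite flux intervals ``(wmin, wmax)``.

    ``w = coefficient × v``; positive values are net production of the
    target metabolite.
    """

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(rid, lo, hi) for rid, (lo, hi) in self.items()],
            columns=["reaction", "wmin", "wmax"],
        ).set_index("reaction")


@dataclass
class FatminResult:
    """Outcome of the full pipeline."""

    target_reactions: List[Tuple[str, bool]]
    fluxmin_minimum: float
    ranges: WeightedFluxRange
    pre_ranges: WeightedFluxRange
    flux_ranges: FluxRange
    pre_flux_ranges: FluxRange
    threshold: float
    objective_value: float
    metabolite: str
    artificial_metabolite_id: str = "F"
    fluxmin_id: str = "FluxMin"
    augmented_model: Optional[MetabolicModel] = None


def weighted_ranges(
    model: MetabolicModel, ranges: FluxRange, metabolite: str
) -> WeightedFluxRange:
    """Target-metabolite flux range per reaction containing the metabolite.

    For coefficient ``c`` and flux range ``[vmin, vmax]`` the weighted range
    is ``sorted(c·vmin, c·vmax)``; reactions not containing the metabolite
    are excluded.
    """
    if metabolite not in model.metabolites:
        raise UnknownIdError(f"unknown metabolite {metabolite!r}")
    out = WeightedFluxRange()
    for rid, rxn in model.reactions.items():
        coeff = rxn.stoichiometry.get(metabolite, 0.0)
        if coeff == 0.0 or rid not in ranges:
            continue
        vmin, vmax = ranges[rid]
        lo, hi = sorted((coeff * vmin, coeff * vmax))
        out[rid] = (lo, hi)
    return out


def identify_targets(
    wranges: Mapping[str, Tuple[float, float]], threshold: float = DEFAULT_THRESHOLD
) -> List[Tuple[str, bool]]:
    """Reactions whose weighted flux bounds exceed ``threshold`` in magnitude.

    Returns ``(reaction_id, needs_split)`` pairs; ``needs_split`` is set when
    the magnitude of the *lower* weighted bound exceeds the threshold, i.e.
    the reaction can also consume (or produce in reverse) beyond ``T`` and
    must have its consuming direction suppressed during the minimization.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    targets: List[Tuple[str, bool]] = []
    for rid, (wmin, wmax) in wranges.items():
        if abs(wmin) > threshold or abs(wmax) > threshold:
            targets.append((rid, abs(wmin) > threshold))
    return targets


def _unique_id(model: MetabolicModel, base: str, taken) -> str:
    if base not in taken:
        return base
    k = 1
    while f"{base}_{k}" in taken:
        k += 1
    new = f"{base}_{k}"
    warnings.warn(
        f"id {base!r} already exists in model {model.id!r}; using {new!r}",
        stacklevel=3,
    )
    return new


def augment_network(
    model: MetabolicModel,
    targets: List[Tuple[str, bool]],
    metabolite: str,
    artificial_metabolite_id: str = "F",
    fluxmin_id: str = "FluxMin",
    drain_cap: float = 1e7,
) -> Tuple[MetabolicModel, str, str]:
    """Add the artificial metabolite and its ``FluxMin`` drain.

    Every producing branch of every target reaction gains the artificial
    metabolite with coefficient equal to its target-metabolite production
    stoichiometry, so the drain flux measures metabolite production in the
    metabolite's own units.  The feasible set projected onto the original
    reactions is unchanged because the artificial metabolite drains freely.

    Returns ``(augmented_model, artificial_metabolite_id, fluxmin_id)``
    (ids may acquire a suffix on collision).
    """
    out = model.copy()
    f_id = _unique_id(model, artificial_metabolite_id, out.metabolites)
    drain_id = _unique_id(model, fluxmin_id, out.reactions)
    out.add_metabolite(Metabolite(f_id, name="artificial target tracker",
                                  compartment="c"))
    if not targets:
        warnings.warn(
            "augment_network called with no targets: the drain is inert",
            stacklevel=2,
        )
    n_tagged = 0
    for rid, _needs_split in targets:
        if rid not in out.reactions:
            raise UnknownIdError(f"unknown target reaction {rid!r}")
        rxn = out.reactions[rid]
        coeff = rxn.stoichiometry.get(metabolite, 0.0)
        if coeff == 0.0:
            raise UnknownIdError(
                f"target reaction {rid!r} does not contain metabolite {metabolite!r}"
            )
        can_produce_fwd = coeff > 0 and rxn.upper_bound > 0
        can_produce_bwd = coeff < 0 and rxn.lower_bound < 0
        if not (can_produce_fwd or can_produce_bwd):
            # pure consumer: no producing branch to tag; mass balance of the
            # targeted producers still pins it once their loops collapse
            continue
        rxn.stoichiometry[f_id] = coeff
        n_tagged += 1
    drain = Reaction(
        id=drain_id,
        stoichiometry={f_id: -1.0},
        lower_bound=0.0,
        upper_bound=drain_cap,
        reversible=False,
        name="artificial-metabolite drain (targeted production)",
    )
    out.add_reaction(drain)
    if targets and n_tagged == 0:
        warnings.warn("no target reaction has a producing branch", stacklevel=2)
    return out, f_id, drain_id


def _clamp_consuming_direction(
    model: MetabolicModel, targets: List[Tuple[str, bool]], metabolite: str
) -> MetabolicModel:
    """Zero the consuming direction of split targets (minimization step only)."""
    out = model.copy()
    for rid, needs_split in targets:
        if not needs_split:
            continue
        rxn = out.reactions[rid]
        coeff = rxn.stoichiometry.get(metabolite, 0.0)
        if coeff > 0:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        elif coeff < 0:
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
    return out


def run_fatmin(
    model: MetabolicModel,
    objective: Optional[Mapping[str, float]] = None,
    metabolite: str = "nadh",
    threshold: float = DEFAULT_THRESHOLD,
    fix_fraction: float = 1.0,
    solver: LPSolver = _DEFAULT_SOLVER,
) -> FatminResult:
    """Run the full FBA → FVA → FBA → FVA pipeline for one target metabolite.

    With no reaction exceeding the threshold the pipeline degenerates to
    plain fixed-objective FVA.  For several target metabolites, call once
    per metabolite: each run introduces its own artificial metabolite and
    drain, and augmentations compose.
    """
    model.validate()
    base = optimize(model, objective, solver=solver)
    pre_fva = flux_variability(model, objective, fix_fraction, solver=solver)
    pre_w = weighted_ranges(model, pre_fva, metabolite)
    targets = identify_targets(pre_w, threshold)
    if not targets:
        return FatminResult(
            target_reactions=[],
            fluxmin_minimum=0.0,
            ranges=pre_w,
            pre_ranges=pre_w,
            flux_ranges=pre_fva,
            pre_flux_ranges=pre_fva,
            threshold=threshold,
            objective_value=base.objective_value,
            metabolite=metabolite,
            augmented_model=None,
        )
    augmented, f_id, drain_id = augment_network(model, targets, metabolite)
    clamped = _clamp_consuming_direction(augmented, targets, metabolite)
    fluxmin_minimum = minimize_reaction_flux(
        clamped, drain_id, objective, fix_fraction, solver=solver
    )
    fluxmin_minimum = max(fluxmin_minimum, 0.0)
    drain_rxn = augmented.reactions[drain_id]
    if fluxmin_minimum >= drain_rxn.upper_bound - 1e-6:
        warnings.warn(
            f"FluxMin minimum {fluxmin_minimum:g} sits at its cap "
            f"{drain_rxn.upper_bound:g}; the cap is likely too small",
            stacklevel=2,
        )
    # original bounds restored (the clamp lived only on the minimization copy);
    # the minimal value becomes an equality-like cap on the drain
    final = augmented.copy()
    final.reactions[drain_id].upper_bound = fluxmin_minimum + 1e-6
    post_fva = flux_variability(final, objective, fix_fraction, solver=solver)
    post_w = weighted_ranges(final, post_fva, metabolite)
    return FatminResult(
        target_reactions=targets,
        fluxmin_minimum=fluxmin_minimum,
        ranges=post_w,
        pre_ranges=pre_w,
        flux_ranges=post_fva,
        pre_flux_ranges=pre_fva,
        threshold=threshold,
        objective_value=base.objective_value,
        metabolite=metabolite,
        artificial_metabolite_id=f_id,
        fluxmin_id=drain_id,
        augmented_model=final,
    )
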