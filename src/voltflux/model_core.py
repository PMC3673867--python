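"""Stoichiometric model data structures, I/O and editing operations.

A :class:`MetabolicModel` is the constraint space ``S·v = 0, lb <= v <= ub``
over reaction fluxes ``v`` (mmol/gDW/h; a biomass reaction is conventionally
read in 1/h).  Models are plain in-memory objects; all editing operations are
functional and return modified copies.

Two interchange formats are supported:

* SBML Level 2 (flux bounds as kinetic-law parameters) or Level 3 with the
  ``fbc`` package, read via libSBML; written as Level 3 + fbc.
* A line-oriented native text format, one reaction per line::

      # comment
      R1 : 2 A[c] + B[c] --> C[e] | 0 1000 | 1.0

  with ``-->`` (irreversible) or ``<==>`` (reversible) arrows, optional
  ``| lb ub`` bounds and optional ``| weight`` objective weight.  A leading
  ``[c] :`` compartment tag applies to all bare metabolites on the line,
  matching the bracket dialect used for printed reaction strings (e.g.
  ``[c] : akg + coa + nad --> co2 + nadh + succoa``).
"""

from __future__ import annotations

import copy
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from voltflux.errors import (
    ModelParseError,
    ModelValidationError,
    UnknownIdError,
)

logger = logging.getLogger(__name__)

#: Default "effectively infinite" flux bound, mmol/gDW/h.  Kept at 1000 (not
#: 10000) so that loop fluxes saturating it are visibly implausible without
#: stressing the solver.
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A chemical species in a compartment ('c' cytosol, 'e' extracellular)."""

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment must be non-empty"
            )


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds.

    Negative coefficients are consumed species, positive are produced.  The
    ``reversible`` flag records declared reversibility; the actual feasible
    direction is governed by the bounds.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    reversible: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(
                f"reaction {self.id!r}: stoichiometry must be non-empty"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass
class GrowthDefaults:
    """Default environmental constraints for acetate-fed *G. sulfurreducens*.

    Units are mmol/gDW/h throughout.  ``viability_fraction`` is the fraction
    of the maximum theoretical growth rate taken as the practically viable
    floor; ``reference_growth`` (1/h) is an experimentally achievable rate
    used as an alternative reference point.
    """

    acetate_uptake_max: float = 18.0
    ngam_atp: float = 0.45
    fe3_uptake_max: float = 568.0
    nh4_uptake_max: float = 0.468
    free_exchange_ids: Tuple[str, ...] = ("co2", "h2o", "k", "mg2", "pi", "so4")
    viability_fraction: float = 0.05
    reference_growth: float = 0.06

    def __post_init__(self) -> None:
        for name in ("acetate_uptake_max", "ngam_atp", "fe3_uptake_max", "nh4_uptake_max"):
            if getattr(self, name) < 0:
                raise ModelValidationError(f"{name} must be >= 0")
        if not (0 < self.viability_fraction <= 1):
            raise ModelValidationError("viability_fraction must be in (0, 1]")


class MetabolicModel:
    """Metabolites, reactions, an objective map and the implied matrix S."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective: Optional[Mapping[str, float]] = None,
        biomass_reaction_id: Optional[str] = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.objective: Dict[str, float] = dict(objective or {})
        self.biomass_reaction_id = biomass_reaction_id
        self.metadata: Dict[str, object] = {}
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, allow_new_metabolites: bool = False) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                if allow_new_metabolites:
                    self.add_metabolite(Metabolite(met_id))
                else:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- queries ----------------------------------------------------------

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S with one row per metabolite, one column per reaction."""
        met_ids = self.metabolite_ids
        rxn_ids = self.reaction_ids
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S, met_ids, rxn_ids

    def bounds(self) -> List[Tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions.values()]

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on structural defects."""
        if not self.reactions:
            raise ModelValidationError("model has no reactions")
        if not self.metabolites:
            raise ModelValidationError("model has no metabolites")
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower bound exceeds upper bound"
                )
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelValidationError(
                    f"objective references undeclared reaction {rid!r}"
                )
        if self.biomass_reaction_id and self.biomass_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} is not declared"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# editing operations (functional: return modified copies)
# ---------------------------------------------------------------------------

def set_flux_bounds(
    model: MetabolicModel, reaction_id: str, lb: float, ub: float
) -> MetabolicModel:
    """Return a copy of *model* with the bounds of one reaction replaced."""
    if reaction_id not in model.reactions:
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")
    if lb > ub:
        raise ModelValidationError(
            f"lower bound {lb} exceeds upper bound {ub} for {reaction_id!r}"
        )
    out = model.copy()
    rxn = out.reactions[reaction_id]
    rxn.lower_bound = lb
    rxn.upper_bound = ub
    return out


def split_reversible(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Decompose a reversible reaction into forward and backward halves.

    The forward copy keeps the stoichiometry with bounds ``[0, ub]``; the
    backward copy negates the stoichiometry with bounds ``[0, -lb]``.  Any
    feasible flux ``v`` of the original maps to ``(max(v, 0), max(-v, 0))``,
    so the feasible set projected on all other reactions is unchanged.
    """
    if reaction_id not in model.reactions:
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")
    rxn = model.reactions[reaction_id]
    if rxn.lower_bound >= 0:
        warnings.warn(
            f"reaction {reaction_id!r} is already irreversible; split is a no-op",
            stacklevel=2,
        )
        return model.copy()
    out = model.copy()
    del out.reactions[reaction_id]
    fwd = Reaction(
        id=f"{reaction_id}_fwd",
        stoichiometry=dict(rxn.stoichiometry),
        lower_bound=0.0,
        upper_bound=max(rxn.upper_bound, 0.0),
        reversible=False,
        name=rxn.name,
    )
    bwd = Reaction(
        id=f"{reaction_id}_bwd",
        stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
        lower_bound=0.0,
        upper_bound=-rxn.lower_bound,
        reversible=False,
        name=rxn.name,
    )
    out.add_reaction(fwd)
    out.add_reaction(bwd)
    if reaction_id in out.objective:
        w = out.objective.pop(reaction_id)
        out.objective[fwd.id] = w
        out.objective[bwd.id] = -w
    return out


def stoich_coefficient(
    model: MetabolicModel, reaction_id: str, metabolite_id: str
) -> float:
    """Signed coefficient of *metabolite_id* in *reaction_id* (0 if absent)."""
    if reaction_id not in model.reactions:
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")
    if metabolite_id not in model.metabolites:
        # The metabolite simply does not participate anywhere in this
        # reaction; an id absent from the whole model is still answerable.
        return float(model.reactions[reaction_id].stoichiometry.get(metabolite_id, 0.0))
    return float(model.reactions[reaction_id].stoichiometry.get(metabolite_id, 0.0))


def apply_growth_defaults(
    model: MetabolicModel,
    defaults: GrowthDefaults,
    *,
    acetate_exchange: Optional[str] = None,
    fe3_exchange: Optional[str] = None,
    nh4_exchange: Optional[str] = None,
    atpm_reaction: Optional[str] = None,
) -> MetabolicModel:
    """Apply uptake caps and the non-growth ATP maintenance constraint.

    Exchange reactions follow the convention that uptake is a negative flux,
    so an uptake cap ``u`` becomes a lower bound ``-u``.  Reactions that are
    not named are left untouched.
    """
    out = model.copy()
    caps = [
        (acetate_exchange, defaults.acetate_uptake_max),
        (fe3_exchange, defaults.fe3_uptake_max),
        (nh4_exchange, defaults.nh4_uptake_max),
    ]
    for rid, cap in caps:
        if rid is None:
            continue
        if rid not in out.reactions:
            raise UnknownIdError(f"unknown exchange reaction {rid!r}")
        out.reactions[rid].lower_bound = -cap
    if atpm_reaction is not None:
        if atpm_reaction not in out.reactions:
            raise UnknownIdError(f"unknown maintenance reaction {atpm_reaction!r}")
        out.reactions[atpm_reaction].lower_bound = defaults.ngam_atp
    return out


# ---------------------------------------------------------------------------
# native toy text format
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"-->|<==>|<->|->")
_TERM_RE = re.compile(
    r"^(?:\(?\s*([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*\)?\s+)?"  # coefficient
    r"([A-Za-z0-9_\-:.]+)"  # species token
    r"(?:\[([A-Za-z0-9_]+)\])?$"  # compartment
)


def _parse_side(
    text: str, sign: float, default_compartment: str, line_no: int
) -> Dict[Tuple[str, str], float]:
    out: Dict[Tuple[str, str], float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ModelParseError(f"line {line_no}: empty stoichiometry term")
        m = _TERM_RE.match(term)
        if not m:
            raise ModelParseError(f"line {line_no}: cannot parse term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        token, comp = m.group(2), m.group(3) or default_compartment
        key = (token, comp)
        out[key] = out.get(key, 0.0) + sign * coeff
    return out


def parse_toy_format(text: str, id: str = "model") -> MetabolicModel:
    """Parse the native one-reaction-per-line text format."""
    model = MetabolicModel(id=id)
    n_reactions = 0
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, _, rest = line.partition(":")
        if not _ARROW_RE.search(rest):
            raise ModelParseError(f"line {line_no}: missing reaction arrow in {raw!r}")
        rxn_id = head.strip()
        if not rxn_id:
            raise ModelParseError(f"line {line_no}: missing reaction id")
        default_comp = "c"
        rest = rest.strip()
        comp_match = re.match(r"^\[([A-Za-z0-9_]+)\]\s*:\s*", rest)
        if comp_match:
            default_comp = comp_match.group(1)
            rest = rest[comp_match.end():]
        parts = [p.strip() for p in rest.split("|")]
        eqn = parts[0]
        arrow = _ARROW_RE.search(eqn)
        assert arrow is not None
        reversible = arrow.group(0) in ("<==>", "<->")
        lhs, rhs = eqn[: arrow.start()], eqn[arrow.end():]
        stoich_keys = _parse_side(lhs, -1.0, default_comp, line_no)
        for key, coeff in _parse_side(rhs, +1.0, default_comp, line_no).items():
            stoich_keys[key] = stoich_keys.get(key, 0.0) + coeff
        if not stoich_keys:
            raise ModelParseError(f"line {line_no}: reaction with no metabolites")
        lb, ub = (-DEFAULT_BOUND, DEFAULT_BOUND) if reversible else (0.0, DEFAULT_BOUND)
        obj_weight: Optional[float] = None
        if len(parts) >= 2 and parts[1]:
            try:
                lb_s, ub_s = parts[1].split()
                lb, ub = float(lb_s), float(ub_s)
            except ValueError as exc:
                raise ModelParseError(
                    f"line {line_no}: bad bounds field {parts[1]!r}"
                ) from exc
        if len(parts) >= 3 and parts[2]:
            try:
                obj_weight = float(parts[2])
            except ValueError as exc:
                raise ModelParseError(
                    f"line {line_no}: bad objective weight {parts[2]!r}"
                ) from exc
        stoich: Dict[str, float] = {}
        for (token, comp), coeff in stoich_keys.items():
            met_id = token if comp == "c" else f"{token}_{comp}"
            # implicit declaration: bracket dialect distinguishes compartments
            if met_id not in model.metabolites:
                model.add_metabolite(Metabolite(met_id, name=token, compartment=comp))
            if coeff != 0.0:
                stoich[met_id] = coeff
        if not stoich:
            raise ModelParseError(
                f"line {line_no}: stoichiometry cancels to nothing"
            )
        model.add_reaction(
            Reaction(rxn_id, stoich, lb, ub, reversible=reversible or lb < 0)
        )
        n_reactions += 1
        if obj_weight is not None:
            model.objective[rxn_id] = obj_weight
    if n_reactions == 0:
        raise ModelValidationError("model has no reactions")
    biomass = [rid for rid in model.reactions if "biomass" in rid.lower()]
    if biomass:
        model.biomass_reaction_id = biomass[0]
    model.validate()
    return model


def write_toy_format(model: MetabolicModel) -> str:
    """Serialize to the native text format (inverse of :func:`parse_toy_format`)."""
    lines = [f"# voltflux model {model.id}"]
    for rxn in model.reactions.values():
        subs, prods = [], []
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            base = met.name
            if not base:
                suffix = f"_{met.compartment}"
                base = met_id[: -len(suffix)] if met_id.endswith(suffix) else met_id
            token = f"{base}[{met.compartment}]"
            mag = abs(coeff)
            term = token if mag == 1 else f"{mag:g} {token}"
            (subs if coeff < 0 else prods).append(term)
        arrow = "<==>" if rxn.reversible else "-->"
        eqn = f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()
        obj = model.objective.get(rxn.id)
        line = f"{rxn.id} : {eqn} | {rxn.lower_bound:g} {rxn.upper_bound:g}"
        if obj is not None:
            line += f" | {obj:g}"
        lines.append(line)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML I/O (libSBML; Level 2 kinetic-law bounds or Level 3 fbc on read,
# Level 3 + fbc on write)
# ---------------------------------------------------------------------------

def _sbml_read(document) -> MetabolicModel:
    import libsbml

    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = document.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"SBML parse error: {err.getMessage() if err else 'unknown element'}"
        )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise ModelParseError("SBML document contains no model element")
    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are outside the mass balance
        model.add_metabolite(
            Metabolite(sp.getId(), name=sp.getName() or "",
                       compartment=sp.getCompartment() or "c")
        )
    fbc = sbml_model.getPlugin("fbc")
    objective: Dict[str, float] = {}
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if ref.getSpecies() in model.metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if ref.getSpecies() in model.metabolites:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        if not stoich:
            logger.warning("skipping reaction %s with only boundary species", rx.getId())
            continue
        reversible = rx.getReversible()
        lb = -DEFAULT_BOUND if reversible else 0.0
        ub = DEFAULT_BOUND
        rfbc = rx.getPlugin("fbc")
        got_bounds = False
        if rfbc is not None:
            lb_id = rfbc.getLowerFluxBound()
            ub_id = rfbc.getUpperFluxBound()
            if lb_id:
                p = sbml_model.getParameter(lb_id)
                if p is not None:
                    lb, got_bounds = p.getValue(), True
            if ub_id:
                p = sbml_model.getParameter(ub_id)
                if p is not None:
                    ub, got_bounds = p.getValue(), True
        if not got_bounds and rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for k in range(kl.getNumParameters()):
                p = kl.getParameter(k)
                if p.getId().upper() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId().upper() == "UPPER_BOUND":
                    ub = p.getValue()
                elif p.getId().upper() == "OBJECTIVE_COEFFICIENT" and p.getValue() != 0:
                    objective[rx.getId()] = p.getValue()
        lb = max(lb, -DEFAULT_BOUND) if math.isinf(lb) else lb
        ub = min(ub, DEFAULT_BOUND) if math.isinf(ub) else ub
        model.add_reaction(
            Reaction(rx.getId(), stoich, lb, ub, reversible=reversible,
                     name=rx.getName() or "")
        )
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None:
            for j in range(active.getNumFluxObjectives()):
                fo = active.getFluxObjective(j)
                objective[fo.getReaction()] = fo.getCoefficient()
    model.objective = {k: v for k, v in objective.items() if k in model.reactions}
    biomass = [rid for rid in model.reactions if "biomass" in rid.lower()]
    if biomass:
        model.biomass_reaction_id = biomass[0]
        logger.info("assuming biomass reaction %r (id match)", biomass[0])
    elif len(model.objective) == 1:
        model.biomass_reaction_id = next(iter(model.objective))
        logger.info(
            "assuming biomass reaction %r (sole objective)", model.biomass_reaction_id
        )
    model.validate()
    return model


def read_sbml(source: str | Path) -> MetabolicModel:
    """Read a model from an SBML file path or an SBML string."""
    import libsbml

    reader = libsbml.SBMLReader()
    text = str(source)
    if "<sbml" in text:
        document = reader.readSBMLFromString(text)
    else:
        path = Path(source)
        if not path.exists():
            raise ModelParseError(f"no such file: {path}")
        document = reader.readSBMLFromFile(str(path))
    return _sbml_read(document)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write Level 3 + fbc SBML with explicit flux-bound parameters."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    document = libsbml.SBMLDocument(ns)
    document.setPackageRequired("fbc", False)
    sbml_model = document.createModel()
    sbml_model.setId(model.id)
    mfbc = sbml_model.getPlugin("fbc")
    mfbc.setStrict(False)
    compartments = {m.compartment for m in model.metabolites.values()}
    for comp in sorted(compartments):
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
    bound_params: Dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId(rxn.id)
        rx.setName(rxn.name or rxn.id)
        rx.setReversible(rxn.reversible or rxn.lower_bound < 0)
        rx.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(rxn.upper_bound))
    if model.objective:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, weight in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(weight)
        mfbc.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(document, str(path))


# ---------------------------------------------------------------------------
# front door
# ---------------------------------------------------------------------------

def load_model(source: str | Path) -> MetabolicModel:
    """Load a model from SBML or the native toy text format.

    Dispatch is by content: documents containing an ``<sbml`` element go to
    libSBML, anything else is parsed as the native format.
    """
    path: Optional[Path] = None
    text = str(source)
    if "\n" not in text and "<sbml" not in text:
        path = Path(text)
        if not path.exists():
            raise ModelParseError(f"no such file: {path}")
        text = path.read_text()
    if "<sbml" in text:
        return read_sbml(path if path is not None else text)
    return parse_toy_format(text, id=path.stem if path is not None else "model")


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write SBML for ``.xml``/``.sbml`` suffixes, native text otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        write_sbml(model, path)
    else:
        path.write_text(write_toy_format(model))
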