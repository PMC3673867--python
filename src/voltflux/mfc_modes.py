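"""Microbial-fuel-cell operation modes: electrode reactions and COI scans.

Three anode-coupling modes are modelled by grafting pseudo-reactions onto a
metabolic network:

* MET (mediated): an exogenous mediator strips electrons from NADH.
  ``1NADHmfc: nadh --> nadh_mfc`` and ``2NADHmfc: nadh_mfc --> nad + h_emm``
  with a free sink for ``h_emm``.
* DET (direct): outer-membrane c-type cytochromes reduce the anode.  The
  cytochrome-c reductase reaction of the host model must produce an
  extracellular electron-disposal token (``h_edm``); the electrode reaction
  ``3Cytcmfc: h_edm --> h_edm_out`` plus a sink captures it.
* MIXED: both, with (by default equal) weights.

Current extraction is modelled by a compound objective
``biomass + COI_MET·(2NADHmfc) + COI_DET·(3Cytcmfc)`` where the COI
(coefficient of importance) expresses the priority of electron transfer
relative to growth (weight 1).  Each transfer cycle carries two electrons;
scan rows keep drain fluxes in reaction units and expose electron
equivalents as a derived quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from voltflux.errors import ConfigurationError, InfeasibleProblemError
from voltflux.fatmin import augment_network
from voltflux.lp_engine import (
    FluxDistribution,
    LPSolver,
    ScipyHighsSolver,
    minimize_reaction_flux,
    optimize,
)
from voltflux.model_core import MetabolicModel, Metabolite, Reaction, set_flux_bounds

_DEFAULT_SOLVER = ScipyHighsSolver()

#: Electrons carried per electron-transfer cycle (one NADH oxidation or one
#: cytochrome-c reductase turnover both deliver two).
ELECTRONS_PER_CYCLE = 2

MET_REACTION_IDS = ("1NADHmfc", "2NADHmfc")
DET_REACTION_ID = "3Cytcmfc"


@dataclass
class ModeConfig:
    """Electron-transfer mode and its objective weights.

    ``coi_met`` weights the mediated channel (flux of ``2NADHmfc``),
    ``coi_det`` the direct channel (flux of ``3Cytcmfc``); biomass always
    carries ``biomass_weight`` (default 1).  DET implies ``coi_met = 0`` and
    MET implies ``coi_det = 0``; MIXED uses both (equal by default).
    """

    mode: str = "MET"
    coi_met: float = 0.0
    coi_det: float = 0.0
    biomass_weight: float = 1.0
    electrode_cap: float = 1000.0
    nadh_id: str = "nadh"
    nad_id: str = "nad"
    h_edm_id: str = "h_edm"

    def __post_init__(self) -> None:
        self.mode = self.mode.upper()
        if self.mode not in ("DET", "MET", "MIXED"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.coi_met < 0 or self.coi_det < 0:
            raise ConfigurationError("COI weights must be >= 0")
        if self.mode == "DET" and self.coi_met != 0:
            raise ConfigurationError("DET mode requires coi_met = 0")
        if self.mode == "MET" and self.coi_det != 0:
            raise ConfigurationError("MET mode requires coi_det = 0")

    @property
    def electrode_reaction_ids(self) -> Tuple[str, ...]:
        if self.mode == "MET":
            return MET_REACTION_IDS
        if self.mode == "DET":
            return (DET_REACTION_ID,)
        return MET_REACTION_IDS + (DET_REACTION_ID,)

    def with_coi(self, coi: float) -> "ModeConfig":
        """Copy with the mode's active channel weight(s) set to ``coi``."""
        met = coi if self.mode in ("MET", "MIXED") else 0.0
        det = coi if self.mode in ("DET", "MIXED") else 0.0
        return replace(self, coi_met=met, coi_det=det)


@dataclass
class ScanRow:
    """One optimization result in a COI / growth / uptake scan.

    ``met_flux`` and ``det_flux`` are drain-reaction fluxes (cycles,
    mmol/gDW/h); ``electron_flux`` is their sum in the same units.
    ``electron_equivalents`` applies the two-electrons-per-cycle factor.
    """

    control_value: float
    growth: float
    met_flux: float = 0.0
    det_flux: float = 0.0
    acetate_uptake: float = 0.0
    objective_value: float = 0.0
    nadh_consumed: Optional[float] = None

    @property
    def electron_flux(self) -> float:
        return self.met_flux + self.det_flux

    @property
    def electron_equivalents(self) -> float:
        return ELECTRONS_PER_CYCLE * self.electron_flux


def configure_mode(model: MetabolicModel, cfg: ModeConfig) -> MetabolicModel:
    """Graft the mode's electrode reactions and set the compound objective.

    Raises :class:`ConfigurationError` naming any missing prerequisite
    species.  Records ``electrons_per_cycle`` and the electrode reaction ids
    in ``model.metadata`` for the electrochemical conversion layer.
    """
    out = model.copy()
    missing = []
    if cfg.mode in ("MET", "MIXED"):
        missing += [m for m in (cfg.nadh_id, cfg.nad_id) if m not in out.metabolites]
    if cfg.mode in ("DET", "MIXED"):
        if cfg.h_edm_id not in out.metabolites:
            missing.append(cfg.h_edm_id)
    if missing:
        raise ConfigurationError(
            f"model {model.id!r} lacks species required for {cfg.mode} mode: "
            + ", ".join(repr(m) for m in missing)
        )
    cap = cfg.electrode_cap
    if cfg.mode in ("MET", "MIXED"):
        out.add_metabolite(Metabolite("nadh_mfc", name="NADH committed to mediator",
                                      compartment="c"))
        out.add_metabolite(Metabolite("h_emm", name="mediated electron sink token",
                                      compartment="e"))
        out.add_reaction(Reaction("1NADHmfc", {cfg.nadh_id: -1.0, "nadh_mfc": 1.0},
                                  0.0, cap, name="NADH capture by mediator"))
        out.add_reaction(Reaction("2NADHmfc",
                                  {"nadh_mfc": -1.0, cfg.nad_id: 1.0, "h_emm": 1.0},
                                  0.0, cap, name="mediator reoxidation at anode"))
        out.add_reaction(Reaction("EX_h_emm", {"h_emm": -1.0}, 0.0, cap,
                                  name="mediated-channel sink"))
    if cfg.mode in ("DET", "MIXED"):
        out.add_metabolite(Metabolite("h_edm_out", name="direct electron sink token",
                                      compartment="e"))
        out.add_reaction(Reaction(DET_REACTION_ID,
                                  {cfg.h_edm_id: -1.0, "h_edm_out": 1.0},
                                  0.0, cap, name="cytochrome channel to anode"))
        out.add_reaction(Reaction("EX_h_edm_out", {"h_edm_out": -1.0}, 0.0, cap,
                                  name="direct-channel sink"))
    objective: Dict[str, float] = {}
    if out.biomass_reaction_id:
        objective[out.biomass_reaction_id] = cfg.biomass_weight
    elif cfg.biomass_weight:
        warnings.warn(
            "model has no biomass reaction; objective has no growth term",
            stacklevel=2,
        )
    if cfg.mode in ("MET", "MIXED") and cfg.coi_met:
        objective["2NADHmfc"] = cfg.coi_met
    if cfg.mode in ("DET", "MIXED") and cfg.coi_det:
        objective[DET_REACTION_ID] = cfg.coi_det
    out.objective = objective
    out.metadata.update(
        electrons_per_cycle=ELECTRONS_PER_CYCLE,
        mode=cfg.mode,
        electrode_reaction_ids=cfg.electrode_reaction_ids,
    )
    return out


def _row_from_solution(
    model: MetabolicModel,
    sol: FluxDistribution,
    control_value: float,
    acetate_exchange: Optional[str],
) -> ScanRow:
    growth = sol.fluxes.get(model.biomass_reaction_id or "", 0.0)
    uptake = -sol.fluxes.get(acetate_exchange, 0.0) if acetate_exchange else 0.0
    return ScanRow(
        control_value=control_value,
        growth=growth,
        met_flux=sol.fluxes.get("2NADHmfc", 0.0),
        det_flux=sol.fluxes.get(DET_REACTION_ID, 0.0),
        acetate_uptake=uptake,
        objective_value=sol.objective_value,
    )


def coi_sweep(
    model: MetabolicModel,
    cfg: ModeConfig,
    coi_values: Sequence[float],
    acetate_exchange: Optional[str] = "EX_ac",
    solver: LPSolver = _DEFAULT_SOLVER,
) -> List[ScanRow]:
    """One FBA per COI value, with the mode's channel weight(s) set to it.

    An LP failure aborts with the partial results attached to the exception.
    """
    if any(c <= 0 for c in coi_values):
        raise ValueError("COI values must be positive")
    if list(coi_values) != sorted(coi_values):
        raise ValueError("COI values must be ascending")
    rows: List[ScanRow] = []
    for coi in coi_values:
        configured = configure_mode(model, cfg.with_coi(coi))
        try:
            sol = optimize(configured, solver=solver)
        except InfeasibleProblemError as exc:
            exc.partial_rows = rows  # type: ignore[attr-defined]
            raise
        rows.append(_row_from_solution(configured, sol, coi, acetate_exchange))
    return rows


def _loop_free_nadh_consumption(
    configured: MetabolicModel,
    sol_value_by_rid: Dict[str, float],
    nadh_id: str,
    solver: LPSolver,
) -> float:
    """Total NADH-consuming flux of a loop-cleaned witness.

    Pins the already-optimized fluxes in ``sol_value_by_rid`` via bounds,
    tags every NADH-producing branch with an artificial metabolite and
    minimizes the total tagged production (the FATMIN minimization applied
    to all producers), then sums the consuming weighted fluxes of the
    witness.  This strips futile NADH turnover from the reported figure.
    """
    pinned = configured.copy()
    for rid, v in sol_value_by_rid.items():
        rxn = pinned.reactions[rid]
        rxn.lower_bound = v - 1e-6
        rxn.upper_bound = v + 1e-6
    producers = [
        (rid, False)
        for rid, rxn in pinned.reactions.items()
        if rxn.stoichiometry.get(nadh_id, 0.0) > 0 and rxn.upper_bound > 0
        or rxn.stoichiometry.get(nadh_id, 0.0) < 0 and rxn.lower_bound < 0
    ]
    if not producers:
        return 0.0
    aug, _f_id, drain_id = augment_network(pinned, producers, nadh_id)
    # fluxes of record are pinned through bounds, so the fixed objective is
    # only needed for well-posedness; growth is the natural choice
    fix_obj = (
        {pinned.biomass_reaction_id: 1.0}
        if pinned.biomass_reaction_id
        else {next(iter(sol_value_by_rid)): 1.0}
    )
    _minimum, witness = minimize_reaction_flux(
        aug, drain_id, objective=fix_obj, solver=solver, return_witness=True,
    )
    consumed = 0.0
    for rid, rxn in aug.reactions.items():
        coeff = rxn.stoichiometry.get(nadh_id, 0.0)
        if coeff == 0.0 or rid == drain_id:
            continue
        consumed += max(0.0, -coeff * witness.fluxes[rid])
    return consumed


def tradeoff_frontier(
    model: MetabolicModel,
    cfg: ModeConfig,
    n_points: int = 11,
    acetate_exchange: Optional[str] = "EX_ac",
    report_nadh_consumed: bool = False,
    solver: LPSolver = _DEFAULT_SOLVER,
) -> List[ScanRow]:
    """Maximal electron transfer versus imposed growth (the trade-off line).

    Computes the unconstrained maximal growth ``gmax``, then for each growth
    value ``g`` on a uniform grid over ``[0, gmax]`` fixes ``biomass >= g``
    (an inequality, so unreachable exact values cannot cause infeasibility)
    and maximizes the mode's electron drain flux.  With
    ``report_nadh_consumed`` each row also carries the total NADH-consuming
    flux of a loop-cleaned witness (internal NADH demand at that state).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if model.biomass_reaction_id is None:
        raise ConfigurationError("tradeoff_frontier requires a biomass reaction")
    configured = configure_mode(model, cfg)
    biomass_id = configured.biomass_reaction_id
    gmax = optimize(
        configured, {biomass_id: 1.0}, solver=solver
    ).objective_value
    electron_obj = {rid: 1.0 for rid in cfg.electrode_reaction_ids
                    if rid in ("2NADHmfc", DET_REACTION_ID)}
    rows: List[ScanRow] = []
    for g in np.linspace(0.0, gmax, n_points):
        constrained = set_flux_bounds(
            configured, biomass_id, g,
            configured.reactions[biomass_id].upper_bound,
        )
        sol = optimize(constrained, electron_obj, solver=solver)
        row = _row_from_solution(constrained, sol, float(g), acetate_exchange)
        if report_nadh_consumed and cfg.nadh_id in constrained.metabolites:
            pins = {rid: sol.fluxes[rid] for rid in electron_obj}
            pins[biomass_id] = sol.fluxes[biomass_id]
            row.nadh_consumed = _loop_free_nadh_consumption(
                constrained, pins, cfg.nadh_id, solver
            )
        rows.append(row)
    return rows


def uptake_sweep(
    model: MetabolicModel,
    cfg: ModeConfig,
    uptake_values: Sequence[float],
    coi: float,
    acetate_exchange: str = "EX_ac",
    solver: LPSolver = _DEFAULT_SOLVER,
) -> Tuple[List[ScanRow], float]:
    """Electron output versus acetate uptake cap, plus the fitted slope.

    For each uptake value the exchange lower bound is set to ``-uptake``
    (uptake is a negative exchange flux) and FBA run with the COI objective.
    The slope is the least-squares slope of total drain flux against the
    uptake cap; the LP value function is piecewise linear in the cap, so in
    a single-regime sweep residuals vanish.
    """
    if list(uptake_values) != sorted(uptake_values):
        raise ValueError("uptake values must be ascending")
    if any(u < 0 for u in uptake_values):
        raise ValueError("uptake values must be >= 0")
    configured = configure_mode(model, cfg.with_coi(coi))
    rows: List[ScanRow] = []
    for u in uptake_values:
        ub = min(0.0, configured.reactions[acetate_exchange].upper_bound)
        capped = set_flux_bounds(configured, acetate_exchange, -u, ub)
        try:
            sol = optimize(capped, solver=solver)
        except InfeasibleProblemError as exc:
            exc.partial_rows = rows  # type: ignore[attr-defined]
            raise
        rows.append(_row_from_solution(capped, sol, u, acetate_exchange))
    xs = np.array([r.control_value for r in rows])
    ys = np.array([r.electron_flux for r in rows])
    slope = float(np.polyfit(xs, ys, 1)[0]) if len(rows) > 1 else float("nan")
    return rows, slope
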