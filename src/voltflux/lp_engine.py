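"""Linear-programming services: FBA, fixed-objective FVA, flux minimization.

All routines are contracts over an abstract solver interface
(:class:`LPSolver`); the default backend is scipy's HiGHS.  Feasibility and
optimality are requested at 1e-9 and asserted downstream at 1e-6.

Conventions
-----------
* ``optimize`` maximizes by default (FBA sense); infeasible and unbounded
  problems raise distinct exceptions, never a silent zero.
* FVA fixes the objective with an inequality ``c·v >= f·Z* - tol`` rather
  than strict equality, which is numerically brittle under simplex
  tolerances.  ``fix_fraction`` defaults to 1 (the optimum itself).
* Witness vertices at degenerate optima are solver-dependent and not part
  of any contract; only objective values and FVA bounds are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from voltflux.errors import (
    InfeasibleProblemError,
    SolverError,
    UnboundedProblemError,
    UnknownIdError,
)
from voltflux.model_core import MetabolicModel

#: Tolerance requested from the backend.
SOLVER_TOL = 1e-9
#: Tolerance asserted on returned solutions (mass balance, bounds).
FEASIBILITY_TOL = 1e-6


@dataclass
class FluxDistribution:
    """One optimal flux vector and its objective value ``Z_optimum``."""

    fluxes: Dict[str, float]
    objective_value: float

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


class FluxRange(dict):
    """Per-reaction ``[vmin, vmax]`` flux intervals from FVA.

    A ``dict`` mapping reaction id to a ``(vmin, vmax)`` tuple, with a
    DataFrame view for reporting.
    """

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(rid, lo, hi) for rid, (lo, hi) in self.items()],
            columns=["reaction", "vmin", "vmax"],
        ).set_index("reaction")


class LPSolver:
    """Abstract LP backend: matrix, bounds, costs, sense -> status, vertex, value."""

    def solve(
        self,
        c: np.ndarray,
        A_eq: Optional[np.ndarray],
        b_eq: Optional[np.ndarray],
        A_ub: Optional[np.ndarray],
        b_ub: Optional[np.ndarray],
        bounds: Sequence[Tuple[float, float]],
        sense: str,
    ) -> Tuple[str, Optional[np.ndarray], Optional[float]]:
        raise NotImplementedError


class ScipyHighsSolver(LPSolver):
    """HiGHS via :func:`scipy.optimize.linprog`."""

    def solve(self, c, A_eq, b_eq, A_ub, b_ub, bounds, sense):
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(
            sign * np.asarray(c, dtype=float),
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=list(bounds),
            method="highs",
            options={
                "presolve": True,
                "primal_feasibility_tolerance": SOLVER_TOL,
                "dual_feasibility_tolerance": SOLVER_TOL,
            },
        )
        if res.status == 0:
            return "optimal", res.x, sign * res.fun
        if res.status == 2:
            return "infeasible", None, None
        if res.status == 3:
            return "unbounded", None, None
        return f"error: {res.message}", None, None


_DEFAULT_SOLVER = ScipyHighsSolver()


def _objective_vector(
    model: MetabolicModel, objective: Optional[Mapping[str, float]]
) -> Tuple[np.ndarray, Dict[str, float]]:
    obj = dict(objective) if objective is not None else dict(model.objective)
    if not obj:
        raise ValueError("objective is empty: pass weights or set model.objective")
    rxn_ids = model.reaction_ids
    index = {r: i for i, r in enumerate(rxn_ids)}
    c = np.zeros(len(rxn_ids))
    for rid, weight in obj.items():
        if rid not in index:
            raise UnknownIdError(f"objective references unknown reaction {rid!r}")
        c[index[rid]] = weight
    return c, obj


def _check_solution(model: MetabolicModel, x: np.ndarray) -> None:
    S, _, _ = model.stoichiometric_matrix()
    residual = S @ x
    worst = float(np.max(np.abs(residual))) if residual.size else 0.0
    if worst > FEASIBILITY_TOL:
        raise SolverError(
            f"mass-balance residual {worst:.2e} exceeds tolerance {FEASIBILITY_TOL}"
        )
    for (lb, ub), v in zip(model.bounds(), x):
        if v < lb - FEASIBILITY_TOL or v > ub + FEASIBILITY_TOL:
            raise SolverError("returned flux violates bounds beyond tolerance")


def optimize(
    model: MetabolicModel,
    objective: Optional[Mapping[str, float]] = None,
    sense: str = "max",
    solver: LPSolver = _DEFAULT_SOLVER,
) -> FluxDistribution:
    """Flux balance analysis: optimize a weighted flux combination.

    Returns an optimal vertex and ``Z_optimum``.  Raises
    :class:`InfeasibleProblemError` or :class:`UnboundedProblemError` on the
    corresponding solver status (an unbounded status usually signals a loop
    with an open bound).
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c, _ = _objective_vector(model, objective)
    S, _, rxn_ids = model.stoichiometric_matrix()
    status, x, value = solver.solve(
        c, S, np.zeros(S.shape[0]), None, None, model.bounds(), sense
    )
    if status == "infeasible":
        raise InfeasibleProblemError(f"model {model.id!r}: constraints are infeasible")
    if status == "unbounded":
        raise UnboundedProblemError(
            f"model {model.id!r}: objective unbounded (missing flux bound?)"
        )
    if status != "optimal":
        raise SolverError(f"model {model.id!r}: solver failed ({status})")
    assert x is not None and value is not None
    _check_solution(model, x)
    return FluxDistribution(dict(zip(rxn_ids, map(float, x))), float(value))


def _fixed_objective_rows(
    c: np.ndarray, z_opt: float, fix_fraction: float, sense: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Inequality row(s) pinning the objective near its optimum.

    For maximization: ``c·v >= fix_fraction·Z* - tol`` expressed as
    ``-c·v <= -(fix_fraction·Z* - tol)``; mirrored for minimization.
    """
    tol = max(1e-6, 1e-6 * abs(z_opt))
    target = fix_fraction * z_opt
    if sense == "max":
        return -c[None, :], np.array([-(target - tol)])
    return c[None, :], np.array([target + tol])


def flux_variability(
    model: MetabolicModel,
    objective: Optional[Mapping[str, float]] = None,
    fix_fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    sense: str = "max",
    solver: LPSolver = _DEFAULT_SOLVER,
) -> FluxRange:
    """Fixed-objective FVA: per-reaction min/max flux at the optimum.

    Solves two LPs per reaction subject to ``objective >= fix_fraction·Z*``
    (for maximization).  ``fix_fraction`` must lie in (0, 1].
    """
    if not (0 < fix_fraction <= 1):
        raise ValueError("fix_fraction must be in (0, 1]")
    c, _ = _objective_vector(model, objective)
    base = optimize(model, objective, sense=sense, solver=solver)
    S, _, rxn_ids = model.stoichiometric_matrix()
    A_ub, b_ub = _fixed_objective_rows(c, base.objective_value, fix_fraction, sense)
    bounds = model.bounds()
    index = {r: i for i, r in enumerate(rxn_ids)}
    wanted = list(reactions) if reactions is not None else rxn_ids
    out = FluxRange()
    b_eq = np.zeros(S.shape[0])
    for rid in wanted:
        if rid not in index:
            raise UnknownIdError(f"unknown reaction id {rid!r}")
        e = np.zeros(len(rxn_ids))
        e[index[rid]] = 1.0
        lo_hi = []
        for direction in ("min", "max"):
            status, x, value = solver.solve(e, S, b_eq, A_ub, b_ub, bounds, direction)
            if status != "optimal":
                raise SolverError(
                    f"FVA {direction} failed for reaction {rid!r}: {status}"
                )
            lo_hi.append(float(value))
        vmin, vmax = lo_hi
        if vmax < vmin:  # numerically tied interval
            vmin, vmax = vmax, vmin
        out[rid] = (vmin, vmax)
    return out


def minimize_reaction_flux(
    model: MetabolicModel,
    reaction_id: str,
    objective: Optional[Mapping[str, float]] = None,
    fix_fraction: float = 1.0,
    sense: str = "max",
    solver: LPSolver = _DEFAULT_SOLVER,
    return_witness: bool = False,
):
    """Minimal attainable flux of one reaction at the fixed FBA optimum.

    Returns the minimum (a float), or ``(minimum, witness)`` with a full
    :class:`FluxDistribution` attaining it when ``return_witness`` is set.
    """
    if reaction_id not in model.reactions:
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")
    c, _ = _objective_vector(model, objective)
    base = optimize(model, objective, sense=sense, solver=solver)
    S, _, rxn_ids = model.stoichiometric_matrix()
    A_ub, b_ub = _fixed_objective_rows(c, base.objective_value, fix_fraction, sense)
    e = np.zeros(len(rxn_ids))
    e[rxn_ids.index(reaction_id)] = 1.0
    status, x, value = solver.solve(
        e, S, np.zeros(S.shape[0]), A_ub, b_ub, model.bounds(), "min"
    )
    if status == "infeasible":
        raise InfeasibleProblemError(
            f"fixing the objective at fraction {fix_fraction} leaves no feasible "
            f"flux for {reaction_id!r} (fix too tight for tolerance?)"
        )
    if status != "optimal":
        raise SolverError(f"minimization failed for {reaction_id!r}: {status}")
    assert x is not None and value is not None
    if return_witness:
        witness = FluxDistribution(
            dict(zip(rxn_ids, map(float, x))), float(c @ x)
        )
        return float(value), witness
    return float(value)
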