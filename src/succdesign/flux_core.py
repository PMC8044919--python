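"""Linear-programming analyses on metabolic networks.

All solves go through scipy's HiGHS backend.  FBA maximizes (or minimizes)
one reaction flux subject to steady state S.v = 0 and flux bounds; pFBA
then minimizes total absolute flux at the fixed optimum to obtain a unique,
reproducible wild-type reference; FVA reports per-reaction flux ranges with
the objective held at a fraction of its optimum.

Tolerances: the LP feasibility tolerance is 1e-9; reported checks (mass
balance, bound violations, range ordering) use 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicNetwork

FEASIBILITY_TOL = 1e-9
CHECK_TOL = 1e-6

__all__ = [
    "FluxSolution",
    "FVARange",
    "DeletionScreenRow",
    "solve_fba",
    "solve_pfba_reference",
    "flux_variability",
    "delete_reactions",
    "single_deletion_screen",
    "find_blocked",
    "essential_reactions",
    "set_exchange_bounds",
]

_HIGHS_OPTS = {"presolve": True, "primal_feasibility_tolerance": FEASIBILITY_TOL,
               "dual_feasibility_tolerance": FEASIBILITY_TOL}


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def as_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in order])


@dataclass
class FVARange:
    reaction_id: str
    min_flux: float
    max_flux: float
    fixed_objective_fraction: float

    def __post_init__(self) -> None:
        if self.min_flux > self.max_flux + CHECK_TOL:
            raise ValueError(
                f"FVA range for {self.reaction_id}: min {self.min_flux} > max {self.max_flux}"
            )

    @property
    def span(self) -> float:
        return self.max_flux - self.min_flux


@dataclass
class DeletionScreenRow:
    reaction_id: str
    mutant_growth: float
    relative_growth: float


def _status_name(status_code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(status_code, "infeasible")


def _lp_arrays(net: MetabolicNetwork):
    S = net.stoichiometric_matrix()
    bounds = net.bounds()
    return S, bounds


def solve_fba(
    net: MetabolicNetwork,
    objective: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction flux at steady state.

    Returns a :class:`FluxSolution`; on infeasibility the flux map is empty
    and ``status`` is ``"infeasible"``.
    """
    objective = objective or net.objective_reaction
    if objective is None or not net.has_reaction(objective):
        raise ValueError(f"objective reaction {objective!r} not in network")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    S, bounds = _lp_arrays(net)
    n = len(net.reactions)
    c = np.zeros(n)
    j = net.reaction_ids().index(objective)
    c[j] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs", options=_HIGHS_OPTS)
    status = _status_name(res.status)
    if status != "optimal":
        return FluxSolution({}, float("nan"), status)
    fluxes = dict(zip(net.reaction_ids(), res.x))
    return FluxSolution(fluxes, float(res.x[j]), "optimal")


def solve_pfba_reference(
    net: MetabolicNetwork,
    objective: str | None = None,
) -> FluxSolution:
    """Parsimonious FBA: fix the FBA optimum, then minimize total |v|.

    The optimum of the second LP is the deterministic wild-type flux
    reference used by MOMA downstream; raw FBA vertices are degenerate and
    would make adjustment distances irreproducible.
    """
    objective = objective or net.objective_reaction
    fba = solve_fba(net, objective)
    if fba.status != "optimal":
        return fba
    S, bounds = _lp_arrays(net)
    m, n = S.shape
    j = net.reaction_ids().index(objective)
    # v = p - q with p, q >= 0; minimize sum(p + q) with v_obj pinned.
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    split_bounds = []
    for lb, ub in bounds:
        split_bounds.append((max(0.0, lb), max(0.0, ub)))    # p side
    for lb, ub in bounds:
        split_bounds.append((max(0.0, -ub), max(0.0, -lb)))  # q side
    opt = fba.objective_value
    split_bounds[j] = (max(split_bounds[j][0], opt), min(split_bounds[j][1], max(opt, 0.0)) if opt >= 0 else split_bounds[j][1])
    if opt >= 0:
        split_bounds[j] = (opt, opt)
        split_bounds[n + j] = (0.0, 0.0)
    else:
        split_bounds[j] = (0.0, 0.0)
        split_bounds[n + j] = (-opt, -opt)
    c = np.ones(2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=split_bounds,
                  method="highs", options=_HIGHS_OPTS)
    if res.status != 0:
        return FluxSolution({}, float("nan"), _status_name(res.status))
    v = res.x[:n] - res.x[n:]
    return FluxSolution(dict(zip(net.reaction_ids(), v)), float(opt), "optimal")


def _with_objective_floor(net: MetabolicNetwork, objective: str, fraction: float) -> MetabolicNetwork:
    fba = solve_fba(net, objective)
    if fba.status != "optimal":
        raise ValueError(f"network infeasible; cannot hold objective at fraction {fraction}")
    floor = fraction * fba.objective_value
    floor -= 1e-7 * max(1.0, abs(floor))  # numerical slack on the pin
    out = net.copy()
    r = out.reaction(objective)
    r.lower_bound = max(r.lower_bound, floor)
    if r.lower_bound > r.upper_bound:
        r.upper_bound = r.lower_bound
    return out


def flux_variability(
    net: MetabolicNetwork,
    reaction_ids: Iterable[str] | None = None,
    objective_fraction: float = 1.0,
    objective: str | None = None,
) -> list[FVARange]:
    """Per-reaction flux ranges with the objective held at a fraction of
    its optimum (two LPs per reaction)."""
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    objective = objective or net.objective_reaction
    constrained = _with_objective_floor(net, objective, objective_fraction)
    ids = list(reaction_ids) if reaction_ids is not None else constrained.reaction_ids()
    unknown = [r for r in ids if not constrained.has_reaction(r)]
    if unknown:
        raise ValueError(f"unknown reactions in FVA request: {unknown}")
    out = []
    for rid in ids:
        lo = solve_fba(constrained, rid, sense="min")
        hi = solve_fba(constrained, rid, sense="max")
        if lo.status != "optimal" or hi.status != "optimal":
            raise ValueError(
                f"FVA infeasible for {rid} at objective fraction {objective_fraction}"
            )
        lo_v, hi_v = lo.objective_value, hi.objective_value
        if lo_v > hi_v:  # numerical jitter on pinned reactions
            lo_v, hi_v = hi_v, lo_v
        out.append(FVARange(rid, lo_v, hi_v, objective_fraction))
    return out


def delete_reactions(net: MetabolicNetwork, ids: Iterable[str]) -> MetabolicNetwork:
    """Return a copy with the given reactions constrained to zero flux."""
    ids = set(ids)
    unknown = sorted(i for i in ids if not net.has_reaction(i))
    if unknown:
        raise ValueError(f"cannot delete unknown reactions: {unknown}")
    out = net.copy()
    for rid in ids:
        r = out.reaction(rid)
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    return out


def single_deletion_screen(
    net: MetabolicNetwork,
    objective: str | None = None,
    gene_associated_only: bool = True,
) -> list[DeletionScreenRow]:
    """FBA growth of every single-reaction knockout relative to wild type."""
    objective = objective or net.objective_reaction
    wt = solve_fba(net, objective)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ValueError("wild-type network must be feasible with positive growth")
    rows = []
    for r in net.reactions:
        if gene_associated_only and r.gpr is None:
            continue
        mutant = solve_fba(delete_reactions(net, {r.id}), objective)
        growth = mutant.objective_value if mutant.status == "optimal" else 0.0
        growth = max(growth, 0.0)
        rel = min(growth / wt.objective_value, 1.0)
        rows.append(DeletionScreenRow(r.id, growth, rel))
    return rows


def find_blocked(net: MetabolicNetwork, tol: float = FEASIBILITY_TOL) -> set[str]:
    """Reactions whose FVA range at objective fraction 0 is identically zero."""
    blocked = set()
    for rng in flux_variability(net, objective_fraction=0.0):
        if abs(rng.min_flux) <= max(tol, 1e-9) and abs(rng.max_flux) <= max(tol, 1e-9):
            blocked.add(rng.reaction_id)
    return blocked


def essential_reactions(
    net: MetabolicNetwork,
    growth_cutoff: float = 0.05,
    objective: str | None = None,
) -> set[str]:
    """Reactions whose single deletion drops growth below
    ``growth_cutoff`` x wild type (screen over all reactions)."""
    if not 0.0 < growth_cutoff < 1.0:
        raise ValueError("growth_cutoff must lie strictly between 0 and 1")
    rows = single_deletion_screen(net, objective, gene_associated_only=False)
    return {r.reaction_id for r in rows if r.relative_growth < growth_cutoff}


def set_exchange_bounds(
    net: MetabolicNetwork,
    uptake: dict[str, float],
) -> MetabolicNetwork:
    """Copy with exchange lower bounds replaced (uptake given as a negative
    lower bound, e.g. ``{"EX_glyc_e": -13.3, "EX_o2_e": -20}``)."""
    out = net.copy()
    for rid, lb in uptake.items():
        if not out.has_reaction(rid):
            raise ValueError(f"unknown exchange reaction {rid!r}")
        out.reaction(rid).lower_bound = lb
    return out
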