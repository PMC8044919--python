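"""Knockout-candidate preprocessing and OptKnock design enumeration.

OptKnock is the bilevel program

    max_y  v_product
    s.t.   v solves  max_v { v_biomass : S v = 0,
                             lb_j y_j <= v_j <= ub_j y_j  (candidates),
                             lb_j <= v_j <= ub_j          (others) }
           sum_j (1 - y_j) <= K,     y binary

recast as a single-level MILP by replacing the inner LP with its dual
feasibility and strong-duality conditions.  The bilinear dual-bound terms
(mu_j * y_j) are linearized with McCormick envelopes under a big-M cap on
the duals (M = 2000, twice the default flux bound).  Enumeration adds an
integer cut sum_{j in S} y_j >= 1 after each accepted design, which
forbids the found set and any superset of it.
"""

from __future__ import annotations

import contextlib
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp


@contextlib.contextmanager
def _quiet_stdout():
    """Silence C-level stdout chatter from the MILP backend."""
    import ctypes

    sys_fd = 1
    saved = os.dup(sys_fd)
    try:
        with open(os.devnull, "w") as devnull:
            os.dup2(devnull.fileno(), sys_fd)
        yield
    finally:
        try:  # flush C stdio before restoring, or buffered chatter leaks
            ctypes.CDLL(None).fflush(None)
        except OSError:
            pass
        os.dup2(saved, sys_fd)
        os.close(saved)

from .flux_core import (
    delete_reactions,
    essential_reactions,
    find_blocked,
    solve_fba,
)
from .model_io import MetabolicNetwork

BIG_M = 2000.0
DUALITY_TOL = 1e-6
#: a design must beat the wild-type product flux by this much to count
#: (larger than LP solver noise, far below any physiological flux)
IMPROVEMENT_TOL = 1e-4

__all__ = [
    "KnockoutCandidateSet",
    "MutantDesign",
    "build_candidate_set",
    "optknock",
    "enumerate_designs",
    "product_flux_at_max_growth",
]


@dataclass
class KnockoutCandidateSet:
    candidates: list[str]                 # deterministic (sorted) order
    excluded: dict[str, str]              # reaction id -> reason

    def __post_init__(self) -> None:
        overlap = set(self.candidates) & set(self.excluded)
        if overlap:
            raise ValueError(f"reactions both candidate and excluded: {sorted(overlap)}")


@dataclass
class MutantDesign:
    knockouts: frozenset[str]
    source_model: str = "synthetic"
    predicted_product_flux: float = float("nan")
    predicted_growth: float = float("nan")
    duality_residual: float = 0.0

    @property
    def k(self) -> int:
        return len(self.knockouts)


def build_candidate_set(
    net: MetabolicNetwork,
    essential_cutoff: float = 0.05,
    experimental_list: str | Path | list[str] | None = None,
    extra_excluded: dict[str, str] | None = None,
) -> KnockoutCandidateSet:
    """Filter the network's reactions down to valid knockout targets.

    Excluded, in order: blocked reactions (zero FVA range), experimentally
    essential reactions from an optional list, computationally essential
    reactions (single-deletion growth below ``essential_cutoff`` x WT),
    reactions without a gene association, and exchange reactions.
    """
    exp_ids: list[str] = []
    if experimental_list is not None:
        if isinstance(experimental_list, (str, Path)):
            exp_ids = [
                ln.strip() for ln in Path(experimental_list).read_text().splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        else:
            exp_ids = list(experimental_list)
        missing = [r for r in exp_ids if not net.has_reaction(r)]
        if missing:
            warnings.warn(
                f"experimental essential ids not in network (ignored): {missing}",
                stacklevel=2,
            )
            exp_ids = [r for r in exp_ids if net.has_reaction(r)]

    excluded: dict[str, str] = {}
    blocked = find_blocked(net)
    essential = essential_reactions(net, essential_cutoff)
    for r in net.reactions:
        if r.id in blocked:
            excluded[r.id] = "blocked"
        elif r.gpr is None:
            excluded[r.id] = "no_gene"
        elif r.is_exchange:
            excluded[r.id] = "exchange"
        elif r.id in exp_ids:
            excluded[r.id] = "experimentally_essential"
        elif r.id in essential:
            excluded[r.id] = "computationally_essential"
        elif extra_excluded and r.id in extra_excluded:
            excluded[r.id] = extra_excluded[r.id]
    candidates = sorted(set(net.reaction_ids()) - set(excluded))
    return KnockoutCandidateSet(candidates, excluded)


def product_flux_at_max_growth(
    net: MetabolicNetwork,
    product: str,
    optimistic: bool = True,
    objective: str | None = None,
) -> tuple[float, float]:
    """(growth, product flux) with growth at its optimum and the product
    flux re-optimized over the remaining degeneracy (max by default)."""
    objective = objective or net.objective_reaction
    fba = solve_fba(net, objective)
    if fba.status != "optimal":
        return 0.0, 0.0
    growth = fba.objective_value
    pinned = net.copy()
    rb = pinned.reaction(objective)
    rb.lower_bound = max(rb.lower_bound, growth - 1e-7 * max(1.0, abs(growth)))
    if rb.lower_bound > rb.upper_bound:
        rb.upper_bound = rb.lower_bound
    second = solve_fba(pinned, product, sense="max" if optimistic else "min")
    prod = second.objective_value if second.status == "optimal" else 0.0
    return growth, prod


def _build_milp(
    net: MetabolicNetwork,
    candidates: list[str],
    K: int,
    min_biomass: float,
    product: str,
    integer_cuts: list[frozenset[str]],
    exact_cuts: list[frozenset[str]],
):
    rids = net.reaction_ids()
    n = len(rids)
    nc = len(candidates)
    S = net.stoichiometric_matrix()
    m = S.shape[0]
    lb = np.array([r.lower_bound for r in net.reactions])
    ub = np.array([r.upper_bound for r in net.reactions])
    j_bio = rids.index(net.objective_reaction)
    j_prod = rids.index(product)
    cand_j = np.array([rids.index(c) for c in candidates])
    cand_pos = {c: k for k, c in enumerate(candidates)}

    # variable layout: v(n) | y(nc) | lam(m) | mu_u(n) | mu_l(n) | wU(nc) | wL(nc)
    off_y = n
    off_lam = off_y + nc
    off_mu = off_lam + m
    off_ml = off_mu + n
    off_wu = off_ml + n
    off_wl = off_wu + nc
    nvar = off_wl + nc

    lo = np.concatenate([lb, np.zeros(nc), -np.inf * np.ones(m),
                         np.zeros(n), np.zeros(n), np.zeros(nc), np.zeros(nc)])
    hi = np.concatenate([ub, np.ones(nc), np.inf * np.ones(m),
                         BIG_M * np.ones(n), BIG_M * np.ones(n),
                         BIG_M * np.ones(nc), BIG_M * np.ones(nc)])
    integrality = np.zeros(nvar)
    integrality[off_y:off_y + nc] = 1

    rows, cols, vals, cl, cu = [], [], [], [], []
    nrow = 0

    def add_row(entries: list[tuple[int, float]], lo_v: float, hi_v: float) -> None:
        nonlocal nrow
        for c_, v_ in entries:
            rows.append(nrow)
            cols.append(c_)
            vals.append(v_)
        cl.append(lo_v)
        cu.append(hi_v)
        nrow += 1

    # primal steady state S v = 0
    for i in range(m):
        nz = np.nonzero(S[i])[0]
        if len(nz):
            add_row([(int(j), float(S[i, j])) for j in nz], 0.0, 0.0)
    # candidate primal bounds scaled by y
    for k, j in enumerate(cand_j):
        add_row([(int(j), 1.0), (off_y + k, -float(ub[j]))], -np.inf, 0.0)
        add_row([(int(j), 1.0), (off_y + k, -float(lb[j]))], 0.0, np.inf)
    # dual feasibility: S^T lam + mu_u - mu_l = e_biomass
    for j in range(n):
        entries = [(off_lam + i, float(S[i, j])) for i in np.nonzero(S[:, j])[0]]
        entries += [(off_mu + j, 1.0), (off_ml + j, -1.0)]
        rhs = 1.0 if j == j_bio else 0.0
        add_row(entries, rhs, rhs)
    # strong duality: v_bio = dual objective
    sd = [(j_bio, 1.0)]
    cand_set = set(cand_j.tolist())
    for j in range(n):
        if j in cand_set:
            continue
        if ub[j]:
            sd.append((off_mu + j, -float(ub[j])))
        if lb[j]:
            sd.append((off_ml + j, float(lb[j])))
    for k, j in enumerate(cand_j):
        if ub[j]:
            sd.append((off_wu + k, -float(ub[j])))
        if lb[j]:
            sd.append((off_wl + k, float(lb[j])))
    add_row(sd, 0.0, 0.0)
    # McCormick: w = mu * y with mu in [0, M], y binary
    for k, j in enumerate(cand_j):
        add_row([(off_wu + k, 1.0), (off_y + k, -BIG_M)], -np.inf, 0.0)
        add_row([(off_wu + k, 1.0), (off_mu + j, -1.0)], -np.inf, 0.0)
        add_row([(off_wu + k, 1.0), (off_mu + j, -1.0), (off_y + k, -BIG_M)],
                -BIG_M, np.inf)
        add_row([(off_wl + k, 1.0), (off_y + k, -BIG_M)], -np.inf, 0.0)
        add_row([(off_wl + k, 1.0), (off_ml + j, -1.0)], -np.inf, 0.0)
        add_row([(off_wl + k, 1.0), (off_ml + j, -1.0), (off_y + k, -BIG_M)],
                -BIG_M, np.inf)
    # knockout budget: 1 <= sum (1 - y) <= K
    add_row([(off_y + k, 1.0) for k in range(nc)], nc - K, nc - 1)
    # minimum growth
    add_row([(j_bio, 1.0)], min_biomass, np.inf)
    # integer cuts: at least one member of each found set stays active
    # (forbids the set and all of its supersets)
    for cut in integer_cuts:
        entries = [(off_y + cand_pos[c], 1.0) for c in cut if c in cand_pos]
        if entries:
            add_row(entries, 1.0, np.inf)
    # exact no-good cuts: forbid precisely this knockout assignment
    # (sum_{j in S} y_j + sum_{j not in S} (1 - y_j) >= 1)
    for cut in exact_cuts:
        in_cut = {cand_pos[c] for c in cut if c in cand_pos}
        entries = [(off_y + k, 1.0 if k in in_cut else -1.0) for k in range(nc)]
        add_row(entries, 1.0 - (nc - len(in_cut)), np.inf)

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, nvar))
    c = np.zeros(nvar)
    c[j_prod] = -1.0  # maximize product flux
    return c, A, np.array(cl), np.array(cu), Bounds(lo, hi), integrality, (off_y, nc, j_bio, j_prod)


def optknock(
    net: MetabolicNetwork,
    candidates: KnockoutCandidateSet | list[str],
    K: int,
    min_biomass: float,
    product: str,
    integer_cuts: list[frozenset[str]] | None = None,
    exact_cuts: list[frozenset[str]] | None = None,
    optimistic: bool = True,
    source_model: str | None = None,
    require_improvement: bool = True,
) -> MutantDesign | None:
    """Solve one OptKnock MILP; return the best design or ``None``.

    ``None`` is returned when the MILP is infeasible (e.g. fully cut) or
    — with ``require_improvement`` (the default) — when no feasible
    knockout set strictly beats the wild-type product flux.  With
    ``require_improvement=False`` product-neutral designs (product equal
    to wild type, as enumeration requests beyond the improving set
    return) are accepted too.  The returned design's growth and product
    flux are re-evaluated with plain FBA on the knocked network (product
    re-optimized at fixed maximal growth, maximization unless
    ``optimistic=False``), and the strong-duality residual of the
    accepted MILP solution is recorded.
    """
    cand_list = candidates.candidates if isinstance(candidates, KnockoutCandidateSet) else list(candidates)
    if not net.has_reaction(product):
        raise ValueError(f"product reaction {product!r} not in network")
    if K < 0:
        raise ValueError("K must be >= 0")
    label = source_model or net.id
    wt_growth, wt_prod = product_flux_at_max_growth(net, product, optimistic)
    if K == 0:
        return MutantDesign(frozenset(), label, wt_prod, wt_growth)

    c, A, cl, cu, bounds, integrality, meta = _build_milp(
        net, cand_list, K, min_biomass, product, integer_cuts or [], exact_cuts or []
    )
    off_y, nc, j_bio, j_prod = meta
    with _quiet_stdout():
        res = milp(
            c,
            constraints=LinearConstraint(A, cl, cu),
            bounds=bounds,
            integrality=integrality,
            options={"mip_rel_gap": 0.0, "presolve": True},
        )
    if res.status != 0 or res.x is None:
        return None
    y = res.x[off_y:off_y + nc]
    knocked = frozenset(cand_list[k] for k in range(nc) if y[k] < 0.5)
    if not knocked:
        return None

    mutant = delete_reactions(net, knocked)
    growth, prod = product_flux_at_max_growth(mutant, product, optimistic)
    residual = abs(res.x[j_bio] - growth)
    if require_improvement and prod <= wt_prod + IMPROVEMENT_TOL:
        return None
    if prod < wt_prod - IMPROVEMENT_TOL:
        return None
    if growth < min_biomass - 1e-6:
        return None
    return MutantDesign(knocked, label, prod, growth, residual)


def enumerate_designs(
    net: MetabolicNetwork,
    candidates: KnockoutCandidateSet | list[str],
    K: int,
    max_designs: int,
    product: str,
    min_biomass: float,
    forbidden_sets: list[frozenset[str]] | None = None,
    optimistic: bool = True,
    source_model: str | None = None,
    require_improvement: bool = True,
) -> list[MutantDesign]:
    """Enumerate up to ``max_designs`` distinct designs with <= K knockouts
    by repeatedly solving OptKnock under accumulating integer cuts.

    In-round cuts are superset-excluding (a found set suppresses all of its
    objective-neutral supersets); ``forbidden_sets`` — typically designs from
    earlier, smaller-k rounds — are excluded as exact assignments only, so
    informative supersets of earlier designs remain reachable.
    """
    if max_designs < 1:
        raise ValueError("max_designs must be >= 1")
    exact = list(forbidden_sets or [])
    cuts: list[frozenset[str]] = []
    out: list[MutantDesign] = []
    while len(out) < max_designs:
        design = optknock(
            net, candidates, K, min_biomass, product,
            integer_cuts=cuts, exact_cuts=exact,
            optimistic=optimistic, source_model=source_model,
            require_improvement=require_improvement,
        )
        if design is None or not design.knockouts:
            break
        out.append(design)
        cuts.append(design.knockouts)
    return out
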