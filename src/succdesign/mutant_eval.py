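"""Per-mutant evaluation: FBA phenotype, FVA growth-coupling class, MOMA.

A design is *growth-coupled* when the product exchange must carry flux at
the mutant's maximal growth rate: classification uses the FVA range of the
product at objective fraction 1.0 with the thresholds

    max flux < 0.1                 -> not growth-coupled
    max - min > 0.1                -> growth-coupled non-unique
    otherwise                      -> growth-coupled

A non-unique mutant is *rescued* when the FVA maximum and the plain-FBA
product flux agree to within 2 mmol gDW^-1 h^-1; coupled plus rescued
mutants form the overproducer set.

MOMA re-projects the wild-type reference flux state (parsimonious FBA)
onto the mutant's feasible region by Euclidean distance; the distance is
the 2-norm over the full flux vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from ._qp import solve_box_eq_qp
from .design_enum import MutantDesign
from .flux_core import (
    FVARange,
    FluxSolution,
    delete_reactions,
    flux_variability,
    solve_fba,
    solve_pfba_reference,
)
from .model_io import MetabolicNetwork

COUPLING_SPAN_THRESHOLD = 0.1   # mmol gDW^-1 h^-1
RESCUE_THRESHOLD = 2.0          # |FVA max - FBA product| below this rescues

__all__ = [
    "CouplingClass",
    "EvaluationRecord",
    "CampaignSummary",
    "classify_coupling",
    "moma",
    "evaluate_design",
    "evaluate_campaign",
]


class CouplingClass(str, Enum):
    GROWTH_COUPLED = "growth_coupled"
    NON_UNIQUE = "growth_coupled_non_unique"
    NOT_COUPLED = "not_growth_coupled"


@dataclass
class EvaluationRecord:
    design: MutantDesign
    fba_growth: float
    fba_product: float
    product_fva: FVARange | None
    coupling: CouplingClass
    rescued: bool
    moma_distance: float
    moma_growth: float

    @property
    def overproducer(self) -> bool:
        return self.coupling is CouplingClass.GROWTH_COUPLED or self.rescued


def classify_coupling(
    product_fva: FVARange, fba_product: float
) -> tuple[CouplingClass, bool]:
    """Apply the threshold partition to one product FVA range.

    Rescue applies only to the non-unique class and requires the absolute
    difference between the FVA maximum and the FBA product flux to be
    strictly below 2.
    """
    if product_fva.max_flux < COUPLING_SPAN_THRESHOLD:
        return CouplingClass.NOT_COUPLED, False
    if product_fva.span > COUPLING_SPAN_THRESHOLD:
        rescued = abs(product_fva.max_flux - fba_product) < RESCUE_THRESHOLD
        return CouplingClass.NON_UNIQUE, rescued
    return CouplingClass.GROWTH_COUPLED, False


def moma(
    net: MetabolicNetwork,
    knockouts: frozenset[str] | set[str],
    v_ref: FluxSolution,
) -> tuple[FluxSolution, float]:
    """Minimization of metabolic adjustment for one knockout set.

    Solves min ||v - v_ref||^2 over the mutant's flux polytope (knocked
    reactions pinned to zero) and returns the projected flux state and the
    Euclidean distance.  ``v_ref`` should come from
    :func:`~succdesign.flux_core.solve_pfba_reference` on the unmodified
    network so the distance is deterministic.
    """
    mutant = delete_reactions(net, knockouts) if knockouts else net
    rids = net.reaction_ids()
    S = mutant.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in mutant.reactions])
    ub = np.array([r.upper_bound for r in mutant.reactions])
    ref = v_ref.as_vector(rids)
    x = solve_box_eq_qp(ref, S, lb, ub)
    dist = float(np.linalg.norm(x - ref))
    fluxes = dict(zip(rids, x))
    growth = fluxes.get(net.objective_reaction, float("nan"))
    return FluxSolution(fluxes, growth, "optimal"), dist


def evaluate_design(
    net: MetabolicNetwork,
    design: MutantDesign,
    product: str,
    v_ref: FluxSolution | None = None,
) -> EvaluationRecord:
    """FBA + product FVA at maximal growth + MOMA for one design."""
    missing = [r for r in design.knockouts if not net.has_reaction(r)]
    if missing:
        raise ValueError(f"design knockouts not in network: {missing}")
    if v_ref is None:
        v_ref = solve_pfba_reference(net)
    mutant = delete_reactions(net, design.knockouts)
    fba = solve_fba(mutant)
    if fba.status != "optimal" or fba.objective_value <= 1e-9:
        moma_sol, dist = moma(net, design.knockouts, v_ref)
        return EvaluationRecord(
            design, 0.0, 0.0, None, CouplingClass.NOT_COUPLED, False,
            dist, moma_sol.objective_value,
        )
    growth = fba.objective_value
    fba_product = fba.fluxes[product]
    fva = flux_variability(mutant, [product], objective_fraction=1.0)[0]
    coupling, rescued = classify_coupling(fva, fba_product)
    moma_sol, dist = moma(net, design.knockouts, v_ref)
    return EvaluationRecord(
        design, growth, fba_product, fva, coupling, rescued, dist,
        moma_sol.objective_value,
    )


@dataclass
class CampaignSummary:
    records: list[EvaluationRecord]
    n_growth_coupled: int
    n_non_unique: int
    n_not_coupled: int
    n_rescued: int
    errors: list[tuple[MutantDesign, str]]

    @property
    def n_overproducers(self) -> int:
        return self.n_growth_coupled + self.n_rescued


def evaluate_campaign(
    net: MetabolicNetwork,
    designs: list[MutantDesign],
    product: str,
) -> CampaignSummary:
    """Evaluate every design; per-design failures are logged and skipped."""
    if not designs:
        raise ValueError("no designs to evaluate")
    v_ref = solve_pfba_reference(net)
    records: list[EvaluationRecord] = []
    errors: list[tuple[MutantDesign, str]] = []
    for d in designs:
        try:
            records.append(evaluate_design(net, d, product, v_ref))
        except Exception as exc:  # noqa: BLE001 - batch driver keeps going
            errors.append((d, str(exc)))
    by_class = {c: 0 for c in CouplingClass}
    rescued = 0
    for rec in records:
        by_class[rec.coupling] += 1
        rescued += rec.rescued
    return CampaignSummary(
        records,
        by_class[CouplingClass.GROWTH_COUPLED],
        by_class[CouplingClass.NON_UNIQUE],
        by_class[CouplingClass.NOT_COUPLED],
        rescued,
        errors,
    )
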