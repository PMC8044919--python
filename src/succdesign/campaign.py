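"""End-to-end design campaign driver.

One call runs the whole in-silico pipeline on a network: candidate
preprocessing, OptKnock enumeration over knockout sizes k = 1..K_max
(per-k rounds with cross-round deduplication, mirroring the per-round
enumeration protocol), FBA/FVA/MOMA evaluation with growth-coupling
classification, and random-forest target ranking with frequency, PCA and
co-occurrence summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design_enum import (
    KnockoutCandidateSet,
    MutantDesign,
    build_candidate_set,
    enumerate_designs,
)
from .flux_core import solve_fba
from .model_io import MetabolicNetwork
from .mutant_eval import CampaignSummary, evaluate_campaign
from .target_rank import (
    FrequencyReport,
    ImportanceReport,
    KnockoutFeatureMatrix,
    build_feature_matrix,
    cooccurrence_correlation,
    fit_rf,
    frequency_pca,
    knockout_frequency,
)

__all__ = ["CampaignResult", "run_design_campaign"]


@dataclass
class CampaignResult:
    network: MetabolicNetwork
    product: str
    wt_growth: float
    candidates: KnockoutCandidateSet
    designs: list[MutantDesign]
    evaluation: CampaignSummary
    feature_matrix: KnockoutFeatureMatrix
    importance: dict[str, ImportanceReport] = field(default_factory=dict)
    frequency: FrequencyReport | None = None

    @property
    def designs_per_k(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for d in self.designs:
            out[d.k] = out.get(d.k, 0) + 1
        return out


def run_design_campaign(
    net: MetabolicNetwork,
    product: str = "EX_succ_e",
    k_max: int = 4,
    per_round: int = 100,
    min_biomass_fraction: float = 0.05,
    essential_cutoff: float = 0.05,
    experimental_essentials: list[str] | None = None,
    rf_seed: int = 42,
    rf_trees: int = 200,
    responses: tuple[str, ...] = ("product", "growth", "distance"),
) -> CampaignResult:
    """Run preprocessing -> enumeration -> evaluation -> ranking.

    ``min_biomass_fraction`` is relative to the wild-type FBA optimum.
    Designs found in earlier (smaller-k) rounds are excluded from later
    rounds by integer cuts, so each returned knockout set is distinct.

    Rounds are filled to ``per_round`` designs even after the strictly
    product-improving sets are exhausted (mutants requested per round, as
    in the enumeration protocol the campaign mirrors); the later,
    product-neutral designs are what the coupling classifier sorts out as
    not growth-coupled, and they give the forest the contrast between
    anchored and unanchored knockout patterns.
    """
    wt = solve_fba(net)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ValueError("wild-type network must grow before designing knockouts")
    min_biomass = min_biomass_fraction * wt.objective_value

    candidates = build_candidate_set(
        net, essential_cutoff, experimental_list=experimental_essentials
    )
    designs: list[MutantDesign] = []
    cuts: list[frozenset[str]] = []
    for k in range(1, k_max + 1):
        found = enumerate_designs(
            net, candidates, k, per_round, product, min_biomass,
            forbidden_sets=cuts, source_model=net.id,
            require_improvement=False,
        )
        designs.extend(found)
        cuts.extend(d.knockouts for d in found)

    if not designs:
        raise ValueError("campaign produced no designs; nothing beats wild type")

    evaluation = evaluate_campaign(net, designs, product)
    evaluated = [rec.design for rec in evaluation.records]
    matrix = build_feature_matrix(evaluated, candidates.candidates, evaluation.records)

    importance: dict[str, ImportanceReport] = {}
    if matrix.features.shape[0] >= 10:
        for resp in responses:
            importance[resp] = fit_rf(matrix, resp, seed=rf_seed, n_trees=rf_trees)
    frequency = knockout_frequency(evaluated)
    return CampaignResult(
        net, product, wt.objective_value, candidates, designs, evaluation,
        matrix, importance, frequency,
    )
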