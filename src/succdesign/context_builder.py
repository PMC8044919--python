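"""Transcriptome integration: gene expression -> reaction states -> GIMME.

Gene-level log2 fold-changes are mapped to reaction activity through GPR
rules (AND = min of the gene scores, OR = max), then a context-specific
model is extracted with GIMME: an LP that minimizes flux through
low-expression reactions while holding biomass at a set fraction of the
unconstrained optimum.  Reactions that are neither expressed nor needed
at the optimum are pruned from the context model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .flux_core import _HIGHS_OPTS, delete_reactions, solve_fba, solve_pfba_reference
from .model_io import MetabolicNetwork

EXPRESSED, LOW, UNKNOWN = "expressed", "low", "unknown"
FLUX_EPS = 1e-9

__all__ = [
    "ExpressionProfile",
    "ReactionStateMap",
    "ContextModel",
    "ContextComparison",
    "load_expression",
    "reaction_states",
    "gimme_extract",
    "context_network",
    "compare_context_models",
]


@dataclass
class ExpressionProfile:
    condition_name: str
    values: dict[str, float]   # gene id -> log2 fold-change
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        bad = [g for g, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite log2FC for genes: {bad}")


@dataclass
class ReactionStateMap:
    states: dict[str, str]
    score: dict[str, float]
    threshold: float


@dataclass
class ContextModel:
    base: MetabolicNetwork
    kept_reactions: set[str]
    removed_reactions: set[str]
    inconsistency_score: float
    objective_fraction: float


def load_expression(path: str | Path, threshold: float = 1.0,
                    condition_name: str | None = None) -> ExpressionProfile:
    """Read a two-column TSV (``gene_id``, ``log2fc``) into a profile."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        warnings.warn(f"{path.name}: empty expression table", stacklevel=2)
        return ExpressionProfile(condition_name or path.stem, {}, threshold)
    cols = list(df.columns[:2])
    if "gene_id" in df.columns and "log2fc" in df.columns:
        cols = ["gene_id", "log2fc"]
    dup = df[cols[0]][df[cols[0]].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path.name}: duplicated gene ids: {sorted(dup.unique())}")
    vals = pd.to_numeric(df[cols[1]], errors="coerce")
    bad = df.index[vals.isna()]
    if len(bad):
        raise ValueError(
            f"{path.name}: non-numeric log2fc at row {int(bad[0]) + 2}"
        )
    values = dict(zip(df[cols[0]].astype(str), vals.astype(float)))
    return ExpressionProfile(condition_name or path.stem, values, threshold)


def reaction_states(
    net: MetabolicNetwork,
    profile: ExpressionProfile,
    mode: str = "absolute",
) -> ReactionStateMap:
    """Classify every reaction as expressed / low / unknown.

    A gene's score is |log2FC| in ``absolute`` mode (both up- and
    downregulated genes count as measured-expressed) or the signed value in
    ``up`` mode.  Genes absent from the profile default to the threshold
    itself, so missing data never pulls a complex below the cutoff.  GPR
    aggregation: AND -> min, OR -> max; the reaction is expressed when the
    aggregated score reaches the threshold.  Reactions without a GPR are
    ``unknown``.
    """
    if mode not in ("absolute", "up"):
        raise ValueError("mode must be 'absolute' or 'up'")
    thr = profile.threshold
    scores = {
        g: (abs(v) if mode == "absolute" else v) for g, v in profile.values.items()
    }
    states: dict[str, str] = {}
    score: dict[str, float] = {}
    for r in net.reactions:
        if r.gpr is None:
            states[r.id] = UNKNOWN
            score[r.id] = float("nan")
            continue
        s = r.gpr.aggregate(scores, default=thr)
        score[r.id] = s
        states[r.id] = EXPRESSED if s >= thr else LOW
    return ReactionStateMap(states, score, thr)


def gimme_extract(
    net: MetabolicNetwork,
    states: ReactionStateMap,
    objective_fraction: float = 0.9,
) -> ContextModel:
    """GIMME: minimize penalty-weighted flux through low-expression
    reactions subject to biomass >= fraction x optimum.

    Penalty for a low reaction is (threshold - score); |v| is linearized
    with an auxiliary t >= |v| per low reaction.  The kept set is the union
    of expressed reactions, reactions carrying flux at the LP optimum, and
    non-gene-associated reactions; everything else is removed.
    """
    if not 0.0 < objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in (0, 1]")
    wt = solve_fba(net)
    if wt.status != "optimal":
        raise ValueError("base network infeasible")
    floor = objective_fraction * wt.objective_value

    rids = net.reaction_ids()
    low = [r for r in rids if states.states.get(r) == LOW]
    S = net.stoichiometric_matrix()
    m, n = S.shape
    nl = len(low)
    low_pos = {r: k for k, r in enumerate(low)}

    bounds = net.bounds()
    j_bio = rids.index(net.objective_reaction)
    lb_bio = max(bounds[j_bio][0], floor)
    bounds = list(bounds)
    bounds[j_bio] = (lb_bio, max(bounds[j_bio][1], lb_bio))

    # variables: v (n) then t (nl); t_k >= |v_low_k|
    c = np.zeros(n + nl)
    for r, k in low_pos.items():
        c[n + k] = states.threshold - states.score[r]
    A_eq = np.hstack([S, np.zeros((m, nl))])
    A_ub = np.zeros((2 * nl, n + nl))
    for r, k in low_pos.items():
        j = rids.index(r)
        A_ub[2 * k, j] = 1.0
        A_ub[2 * k, n + k] = -1.0        # v_j - t_k <= 0
        A_ub[2 * k + 1, j] = -1.0
        A_ub[2 * k + 1, n + k] = -1.0    # -v_j - t_k <= 0
    var_bounds = bounds + [(0.0, None)] * nl
    res = linprog(
        c, A_ub=A_ub if nl else None, b_ub=np.zeros(2 * nl) if nl else None,
        A_eq=A_eq, b_eq=np.zeros(m), bounds=var_bounds,
        method="highs", options=_HIGHS_OPTS,
    )
    if res.status != 0:
        raise ValueError(
            f"GIMME LP infeasible at objective fraction {objective_fraction}; "
            "try a lower fraction"
        )
    v = res.x[:n]
    kept: set[str] = set()
    for j, rid in enumerate(rids):
        state = states.states.get(rid, UNKNOWN)
        if state in (EXPRESSED, UNKNOWN) or abs(v[j]) > FLUX_EPS:
            kept.add(rid)
    removed = set(rids) - kept
    return ContextModel(net, kept, removed, float(res.fun), objective_fraction)


def context_network(ctx: ContextModel) -> MetabolicNetwork:
    """The base network restricted to the kept reactions (removed
    reactions constrained to zero flux)."""
    return delete_reactions(ctx.base, ctx.removed_reactions)


@dataclass
class ContextComparison:
    shared: set[str]
    unique_to_a: set[str]
    unique_to_b: set[str]
    flux_differences: dict[str, float] = field(default_factory=dict)

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.shared), len(self.unique_to_a), len(self.unique_to_b)


def compare_context_models(a: ContextModel, b: ContextModel,
                           flux_tol: float = 1e-6) -> ContextComparison:
    """Shared / unique kept-reaction sets of two context models drawn from
    the same base, plus the per-reaction differences of their deterministic
    (parsimonious) optimal flux states."""
    if a.base is not b.base and set(a.base.reaction_ids()) != set(b.base.reaction_ids()):
        raise ValueError("context models derive from different base networks")
    shared = a.kept_reactions & b.kept_reactions
    ua = a.kept_reactions - b.kept_reactions
    ub = b.kept_reactions - a.kept_reactions
    fa = solve_pfba_reference(context_network(a))
    fb = solve_pfba_reference(context_network(b))
    diffs: dict[str, float] = {}
    if fa.status == "optimal" and fb.status == "optimal":
        for rid in a.base.reaction_ids():
            d = fa.fluxes.get(rid, 0.0) - fb.fluxes.get(rid, 0.0)
            if abs(d) > flux_tol:
                diffs[rid] = d
    return ContextComparison(shared, ua, ub, diffs)
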