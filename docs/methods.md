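# Methods

This note documents the models, numerical choices and design decisions
behind `succdesign`, and what the synthetic study can and cannot show
about real data.

## Constraint-based layer

All analyses operate on steady-state flux polytopes
{v : S v = 0, l ≤ v ≤ u}. Bounds are in mmol gDW⁻¹ h⁻¹ (biomass in
h⁻¹); absent bounds default to ±1000 (COBRA convention). Every LP runs
through scipy's HiGHS backend with feasibility tolerance 1e-9; reported
checks (mass-balance residuals, bound violations, FVA ordering) use
1e-6.

**FBA** maximizes one reaction flux. **pFBA** fixes that optimum and
minimizes Σ|v| via flux splitting (v = p − q, p,q ≥ 0); its optimum is
the wild-type reference used by MOMA, because raw FBA vertices are
degenerate and would make adjustment distances depend on solver
internals. **FVA** holds the objective at a fraction f of its optimum
(implemented as a lower bound on the objective reaction, backed off by
1e-7 relative slack so f = 1.0 does not become numerically infeasible)
and solves two LPs per reaction. Blocked reactions are those with FVA
range (0, 0) at f = 0; essential reactions are those whose single
deletion drops growth below a 5 % cutoff (the cutoff is a parameter; no
canonical value exists). An externally supplied list of experimentally
essential reactions can be layered on top — FBA systematically
overestimates the fitness of, e.g., respiration-deficient mutants, and
curated essentiality data are the standard correction.

## Expression integration (GIMME)

Gene scores are |log₂FC| by default: a gene measured as strongly up- or
downregulated is *measured expressed*; the threshold is 1.0. (An
`up`-only mode exists for the reading in which only upregulation counts;
absolute value is the default because downregulated genes were still
detected.) Genes absent from the table default to the threshold itself,
so missing data can never silence a complex — absence of evidence is
not evidence of low expression. GPR aggregation is AND → min,
OR → max; a reaction is expressed when its aggregate reaches the
threshold, and reactions without a GPR are never penalized.

GIMME minimizes Σ c_j |v_j| over the low set with penalty
c_j = threshold − score_j, subject to biomass ≥ 0.9 × optimum (the
original GIMME convention; the fraction is a parameter). |v| is
linearized with one auxiliary variable per low reaction. The context
model *keeps* every expressed or non-gene reaction plus every low
reaction that still carries flux (> 1e-9) at the LP optimum, and
*prunes* the rest — pruning (rather than mere penalization) is what
yields reduced context models with distinct reaction complements.

## OptKnock and enumeration

The bilevel program (outer: choose knockouts y maximizing product flux;
inner: the cell maximizes growth) is reformulated to one MILP via LP
duality: primal feasibility with knockout-scaled candidate bounds
(l_j y_j ≤ v_j ≤ u_j y_j), dual feasibility, and a strong-duality row.
The bilinear dual-bound terms μ_j y_j are McCormick-linearized with a
big-M cap of 2000 on the duals (twice the default bound). The MILP
(HiGHS, zero MIP gap) is followed by an FBA re-solve of the selected
knockout set — the reported growth is the re-solved optimum, the
reported product flux is re-optimized at that optimum (optimistic;
a pessimistic minimum is available), and the difference between MILP and
re-solved growth is recorded as the duality residual (≤ 1e-6 at every
accepted solution). At least one knockout is always required; a design
must beat the wild-type product flux by 1e-4 to count as improving
(larger than LP noise, far below any meaningful flux).

Enumeration adds, after each accepted set S, the integer cut
Σ_{j∈S} y_j ≥ 1, which forbids S and all of its supersets: a superset
with the same objective adds no information. Designs carried over from
earlier (smaller-k) rounds are excluded as *exact* assignments only, so
informative supersets of earlier designs remain reachable in later
rounds. The campaign driver runs rounds k = 1..K, each requesting a
fixed number of mutants, and — mirroring the enumeration protocol it
reproduces — keeps filling a round with product-neutral designs after
the strictly improving ones are exhausted. Those neutral designs are
exactly what the coupling classifier later sorts out as not
growth-coupled, and they give the forest the contrast between anchored
and unanchored knockout patterns; without them every row contains an
anchor and anchor presence carries no variance.

## Mutant evaluation

Classification thresholds, applied to the product FVA range at 100 % of
the mutant's growth optimum: FVA max < 0.1 → not growth-coupled;
range > 0.1 → growth-coupled non-unique, *rescued* when
|FVA max − FBA product| < 2 (strict inequalities); otherwise
growth-coupled. Boundary behaviour (max = 0.1, range = 0.1, diff = 2) is
pinned by tests.

MOMA solves min ‖v − v_ref‖² over the mutant polytope. No QP library is
assumed: the projection is computed by an ADMM splitting (OSQP's scheme
specialized to the identity Hessian — the x-update is one pre-factorized
Cholesky solve — with the customary heavier penalty, ×1000, on equality
rows). Periodically the iterate is *polished*: active bounds are fixed,
the reduced equality-constrained projection is solved exactly by least
squares, and optimality is certified through the projection variational
inequality (one LP: max (r−x)ᵀy over the polytope; gap ≈ 0 iff x is the
projection). The certificate is robust to the dual degeneracy that makes
naive active-set methods cycle on lethal-knockout polytopes. The
distance is the 2-norm over the full flux vector of the evaluated model
(not a growth-rate difference), with no rescaling.

## Random-forest ranking

The feature matrix is binary (1 = reaction knocked), one row per design,
aligned with the FBA product flux, FBA growth, and MOMA distance
responses. Zero-variance columns (never-knocked candidates) are dropped
before training — this is the whole of "feature selection". The 70/30
split is stratified by source model when several models contribute.
Forests use 500 trees by default and consider **all** features at each
split (`max_features=1.0`): knockout matrices have few, binary,
sparse-signal columns, and per-split feature subsampling both inflates
held-out error several-fold on planted-effect data and makes tree
structure depend on column order, breaking permutation equivariance of
the importances. The classic mtry = p/3 regression convention remains
available as a parameter. Importance is IncNodePurity — the total
weighted squared-error decrease over all splits on a feature, summed
over trees, computed by walking the fitted trees (sklearn's normalized
`feature_importances_` are rank-similar but not the same measure).

Frequency summaries count knockouts per reaction (overall, per source
model, per k); co-occurrence is the Pearson correlation between
frequency-by-k vectors (zero-variance reactions yield NaN off-diagonal);
the frequency PCA is an SVD of the centered matrix with the
largest-magnitude loading of each component made positive for sign
determinism.

## The synthetic network

The toy network (39 reactions, 27 metabolites, 44 genes, single
cytosolic compartment plus boundary species) abstracts glycerol
catabolism in *E. coli*: GlpK/GlpD and GldA/DhaKLM assimilation routes,
lower glycolysis (TPI, GAPD, PGK, PGM — the latter lumping PGM+ENO —
PYK) with the methylglyoxal bypass (MGSA, lumped to D-lactate) and PEP
synthase, the PDH/PFL/POX pyruvate node, PTAr/ACKr acetate and LDH_D
lactate branches, PPC anaplerosis, an oxidative TCA arm (CS lumping
aconitase, ICDHyr, AKGDH lumping succinyl-CoA synthetase, SUCDi),
fumarate reductase, fumarase and MDH with the MQO backup, and the
glyoxylate shunt. Redox and energy run through lumped NADH/ATP
pseudo-metabolites: NADH16 oxidizes NADH at 2 ATP per NADH against an
oxygen cap; SUCDi and MQO donate at quinone level, i.e. their electrons
are not captured — this asymmetry between the oxidative and reductive
succinate/fumarate steps is what differentiates FUM- from SUCDi-anchored
designs.

Biomass drains acetyl-CoA, oxaloacetate, DHAP and 2-oxoglutarate (one
each) plus 40 ATP. The ATP coefficient is the single calibrated number
in the generator: it places the wild type in an energy-limited regime in
which (i) PDH deletion costs a few percent of growth (PFL substitutes at
the price of exported formate), (ii) the FUM/GAPD/PGK/PGM/TPI deletions
cost distinctly more (11–22 %), and (iii) cutting the oxidative exit
from succinate (FUM) makes TCA flux terminate in secreted succinate at
the growth optimum, so the planted knockout set
{PDH, FUM, LDH_D, PTAr} is growth-coupled (FVA min = max > 0). That
certificate is re-verified by FVA in the test suite, never assumed.
Defaults: glycerol uptake 13.3, O₂ uptake 20 mmol gDW⁻¹ h⁻¹.

`EXPERIMENTAL_ESSENTIALS = {NADH16}` accompanies the network as its
curated-essentiality fixture: FBA keeps respiration-deficient mutants at
~25 % growth, but such strains are severely impaired in vivo, and
candidate preprocessing consumes exactly this kind of list.

**What the synthetic study does not show.** The toy's 25-candidate
design space is exhaustively searchable, so MILP correctness can be
oracle-checked — but nothing here measures scaling to genome-scale
models (thousands of reactions, hours-long MILPs). Lumped redox carriers
ignore proton stoichiometry and P/O ratios; expression profiles are
drawn from two clean uniform bands with no measurement noise structure;
planted phenotype tables are additive with Gaussian noise, so forest
recovery there says nothing about epistatic knockout interactions. Class
proportions (coupled / non-unique / not coupled) depend on the
enumeration depth and the toy's topology and are not comparable in
magnitude to genome-scale campaigns.

## Degenerate inputs and tie-breaking

Infeasible FBA returns an empty flux map with status `infeasible`
(screens record zero growth rather than raising). Lethal designs are
evaluated with growth 0, class not-coupled, and a still-computed MOMA
distance. Candidate order is sorted; enumeration order within an
objective tie is whatever the MILP returns, which is deterministic for a
fixed model and cut sequence. PCA on a rank-1 matrix pads a zero second
component; a rank-0 matrix is an error. GPR parsing follows COBRA
precedence (AND over OR), case-insensitive operators, and round-trips
through serialization by truth table.

## Problem sizes used in the checked study

The shipped study runs k = 1..4 with 25 designs per round (100 designs),
forests with 200 trees on the campaign matrix and 500 on planted tables,
and 20 planted-recovery seeds. These sizes make the full pipeline — and
its exhaustive oracles — comfortably reproducible on a laptop CPU while
leaving every qualitative conclusion unchanged at larger settings.
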