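"""Synthetic inputs: a toy glycerol-to-succinate network, expression
profiles, and planted-effect phenotype tables.

The toy network is a mass-balanced, single-compartment abstraction of
glycerol catabolism in *E. coli*: both glycerol-assimilation routes
(GlpK/GlpD via glycerol 3-phosphate, and GldA/DhaKLM via DHA), lower
glycolysis with the methylglyoxal bypass, the PDH/PFL/POX pyruvate node
with acetate and D-lactate by-product branches, PEP carboxylase
anaplerosis, the oxidative TCA arm ending in succinate dehydrogenase,
fumarate reductase as the reductive entry to succinate, and the
glyoxylate shunt.  Redox and energy run through lumped NADH/ATP pseudo-
metabolites with an oxygen-dependent regeneration reaction, so the
aerobic/anaerobic balance shapes the optima without a full electron-
transport chain.

The network is built so that succinate export is growth-coupled once the
oxidative exit from succinate is cut (FUM) and competing pyruvate sinks
are closed (PDH plus by-product branches): with fumarase gone, any TCA
flux past 2-oxoglutarate terminates in succinate, which then has no fate
but secretion, while ATP demand keeps TCA flux running at the growth
optimum.  That planted certificate is re-verified by FVA in the tests,
not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_io import (
    GeneRecord,
    MetaboliteRecord,
    MetabolicNetwork,
    ReactionRecord,
    parse_gpr,
)
from .context_builder import ExpressionProfile
from .flux_core import solve_fba

__all__ = [
    "ToyNetworkSpec",
    "PlantedPhenotypeSpec",
    "make_toy_network",
    "make_expression_profile",
    "make_phenotype_table",
    "PLANTED_COUPLING_SET",
]

#: Knockout set planted to growth-couple EX_succ_e in the default toy
#: network: cut PDH and fumarase, close the lactate and acetate branches.
PLANTED_COUPLING_SET = frozenset({"PDH", "FUM", "LDH_D", "PTAr"})

#: Reactions treated as experimentally essential for aerobic growth on
#: glycerol when preprocessing knockout candidates.  FBA grossly
#: overestimates the fitness of respiration-deficient mutants (NADH
#: dehydrogenase loss keeps ~25% growth in silico but cripples cells in
#: vivo), so candidate preprocessing removes them from consideration the
#: way curated essentiality data are used on genome-scale models.
EXPERIMENTAL_ESSENTIALS = frozenset({"NADH16"})


@dataclass
class ToyNetworkSpec:
    """Construction flags and environmental bounds for the toy network."""

    glpK_route: bool = True          # GLYK + G3PD2 (glycerol 3-phosphate)
    gldA_route: bool = True          # GLYCDx + DHAK (DHA)
    glycolysis: bool = True          # TPI, GAPD, PGK, PGM, PYK
    pdh: bool = True
    pfl: bool = True
    ldh: bool = True
    acetate_branch: bool = True      # PTAr + ACKr
    pox: bool = True
    oxidative_tca: bool = True       # AKGDH + SUCDi
    reductive_tca: bool = True       # FRD
    glyoxylate_shunt: bool = True    # ICL + MALS
    glycerol_bound: float = 13.3     # max uptake, mmol gDW^-1 h^-1
    o2_bound: float = 20.0           # max O2 uptake, mmol gDW^-1 h^-1
    biomass_atp: float = 40.0        # ATP per unit biomass (growth-limiting)


def _rxn(rid: str, stoich: dict[str, float], lb: float, ub: float,
         gpr: str = "", subsystem: str | None = None) -> ReactionRecord:
    return ReactionRecord(rid, stoich, lb, ub, parse_gpr(gpr), subsystem)


def make_toy_network(spec: ToyNetworkSpec | None = None) -> MetabolicNetwork:
    """Build the toy glycerol-to-succinate network for a given spec.

    Deterministic: the same spec always yields the same network.  Raises
    ``ValueError`` when the enabled routes cannot sustain growth.
    """
    spec = spec or ToyNetworkSpec()
    if not (spec.glpK_route or spec.gldA_route):
        raise ValueError("at least one glycerol assimilation route must be enabled")

    g, o2 = spec.glycerol_bound, spec.o2_bound
    B = 1000.0
    r: list[ReactionRecord] = []

    # Boundary and transport
    r.append(_rxn("EX_glyc_e", {"glyc_e": -1}, -g, B))
    r.append(_rxn("EX_o2_e", {"o2_e": -1}, -o2, B))
    r.append(_rxn("EX_succ_e", {"succ_c": -1}, 0, B))
    r.append(_rxn("EX_ac_e", {"ac_c": -1}, 0, B))
    r.append(_rxn("EX_lac__D_e", {"lac__D_c": -1}, 0, B))
    r.append(_rxn("EX_for_e", {"for_c": -1}, 0, B))
    r.append(_rxn("EX_co2_e", {"co2_c": -1}, -B, B))
    r.append(_rxn("GLYCt", {"glyc_e": -1, "glyc_c": 1}, -B, B, "glpF", "Transport"))
    r.append(_rxn("O2t", {"o2_e": -1, "o2_c": 1}, -B, B, "", "Transport"))

    # Glycerol assimilation
    if spec.glpK_route:
        r.append(_rxn("GLYK", {"glyc_c": -1, "atp_c": -1, "glyc3p_c": 1}, 0, B,
                      "glpK", "Glycerol metabolism"))
        r.append(_rxn("G3PD2", {"glyc3p_c": -1, "dhap_c": 1, "nadh_c": 1}, 0, B,
                      "glpD", "Glycerol metabolism"))
    if spec.gldA_route:
        r.append(_rxn("GLYCDx", {"glyc_c": -1, "dha_c": 1, "nadh_c": 1}, 0, B,
                      "gldA", "Glycerol metabolism"))
        r.append(_rxn("DHAK", {"dha_c": -1, "pep_c": -1, "dhap_c": 1, "pyr_c": 1},
                      0, B, "dhaK and dhaL and dhaM", "Glycerol metabolism"))

    # Lower glycolysis + methylglyoxal bypass + anaplerosis
    if spec.glycolysis:
        r.append(_rxn("TPI", {"dhap_c": -1, "g3p_c": 1}, -B, B, "tpiA", "Glycolysis"))
        r.append(_rxn("GAPD", {"g3p_c": -1, "dpg13_c": 1, "nadh_c": 1}, 0, B,
                      "gapA", "Glycolysis"))
        r.append(_rxn("PGK", {"dpg13_c": -1, "pg3_c": 1, "atp_c": 1}, 0, B,
                      "pgk", "Glycolysis"))
        r.append(_rxn("PGM", {"pg3_c": -1, "pep_c": 1}, 0, B,
                      "gpmA and eno", "Glycolysis"))  # lumps PGM + ENO
        r.append(_rxn("PYK", {"pep_c": -1, "pyr_c": 1, "atp_c": 1}, 0, B,
                      "pykF or pykA", "Glycolysis"))
    # Methylglyoxal route lumped: DHAP -> methylglyoxal -> D-lactate
    r.append(_rxn("MGSA", {"dhap_c": -1, "lac__D_c": 1}, 0, B,
                  "mgsA", "Methylglyoxal metabolism"))
    r.append(_rxn("PPS", {"pyr_c": -1, "atp_c": -2, "pep_c": 1}, 0, B,
                  "ppsA", "Anaplerosis"))
    r.append(_rxn("PPC", {"pep_c": -1, "co2_c": -1, "oaa_c": 1}, 0, B,
                  "ppc", "Anaplerosis"))

    # Pyruvate node and by-product branches
    if spec.pdh:
        r.append(_rxn("PDH", {"pyr_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
                      0, B, "aceE and aceF and lpd", "Pyruvate metabolism"))
    if spec.pfl:
        r.append(_rxn("PFL", {"pyr_c": -1, "accoa_c": 1, "for_c": 1}, 0, B,
                      "pflB", "Pyruvate metabolism"))
    if spec.pox:
        r.append(_rxn("POX", {"pyr_c": -1, "ac_c": 1, "co2_c": 1}, 0, B,
                      "poxB", "Pyruvate metabolism"))
    if spec.ldh:
        r.append(_rxn("LDH_D", {"pyr_c": -1, "nadh_c": -1, "lac__D_c": 1}, -B, B,
                      "ldhA", "Pyruvate metabolism"))
    if spec.acetate_branch:
        r.append(_rxn("PTAr", {"accoa_c": -1, "actp_c": 1}, -B, B,
                      "pta", "Pyruvate metabolism"))
        r.append(_rxn("ACKr", {"actp_c": -1, "ac_c": 1, "atp_c": 1}, -B, B,
                      "ackA", "Pyruvate metabolism"))

    # TCA, reductive branch, glyoxylate shunt
    r.append(_rxn("CS", {"accoa_c": -1, "oaa_c": -1, "icit_c": 1}, 0, B,
                  "gltA", "Citric acid cycle"))  # lumps CS + aconitase
    r.append(_rxn("ICDHyr", {"icit_c": -1, "akg_c": 1, "co2_c": 1, "nadh_c": 1},
                  0, B, "icd", "Citric acid cycle"))
    if spec.oxidative_tca:
        r.append(_rxn("AKGDH", {"akg_c": -1, "succ_c": 1, "co2_c": 1, "nadh_c": 1,
                                "atp_c": 1}, 0, B,
                      "sucA and sucB and lpd", "Citric acid cycle"))  # lumps AKGDH + SUCOAS
        # electrons go to the quinone pool, not NADH (as for MQO), so the
        # oxidative and reductive succinate/fumarate reactions are not
        # symmetric redox-wise
        r.append(_rxn("SUCDi", {"succ_c": -1, "fum_c": 1}, 0, B,
                      "sdhA and sdhB", "Citric acid cycle"))
    if spec.reductive_tca:
        r.append(_rxn("FRD", {"fum_c": -1, "nadh_c": -1, "succ_c": 1}, 0, B,
                      "frdA and frdB and frdC and frdD", "Citric acid cycle"))
    r.append(_rxn("FUM", {"fum_c": -1, "mal__L_c": 1}, -B, B,
                  "fumA or fumB or fumC", "Citric acid cycle"))
    r.append(_rxn("MDH", {"mal__L_c": -1, "oaa_c": 1, "nadh_c": 1}, -B, B,
                  "mdh", "Citric acid cycle"))
    # malate:quinone oxidoreductase: irreversible MDH backup whose
    # electrons bypass NADH (lower yield), as in E. coli
    r.append(_rxn("MQO", {"mal__L_c": -1, "oaa_c": 1}, 0, B,
                  "mqo", "Citric acid cycle"))
    if spec.glyoxylate_shunt:
        r.append(_rxn("ICL", {"icit_c": -1, "succ_c": 1, "glx_c": 1}, 0, B,
                      "aceA", "Glyoxylate shunt"))
        r.append(_rxn("MALS", {"glx_c": -1, "accoa_c": -1, "mal__L_c": 1}, 0, B,
                      "aceB", "Glyoxylate shunt"))

    # Energy and biomass
    r.append(_rxn("NADH16", {"nadh_c": -1, "o2_c": -0.5, "atp_c": 2}, 0, B,
                  "nuoA and nuoB", "Oxidative phosphorylation"))
    r.append(_rxn(
        "BIOMASS_toy",
        {"accoa_c": -1, "oaa_c": -1, "dhap_c": -1, "akg_c": -1,
         "atp_c": -spec.biomass_atp},
        0, B, "", "Biomass",
    ))

    met_ids: dict[str, None] = {}
    for rec in r:
        for m in rec.stoichiometry:
            met_ids.setdefault(m)
    mets = [
        MetaboliteRecord(m, "e" if m.endswith("_e") else "c")
        for m in met_ids
    ]
    net = MetabolicNetwork(mets, r, [], "BIOMASS_toy", id="toy_glyc_succ")

    wt = solve_fba(net)
    if wt.status != "optimal" or wt.objective_value <= 1e-6:
        raise ValueError("toy spec disables all routes to biomass precursors")
    return net


@dataclass
class PlantedPhenotypeSpec:
    """Random binary knockout designs with additive planted effects."""

    n_designs: int = 200
    candidates: tuple[str, ...] = tuple(f"R{i}" for i in range(10))
    effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    knock_probability: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_designs < 20:
            raise ValueError("n_designs must be >= 20")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.effects) - set(self.candidates)
        if unknown:
            raise ValueError(f"effect reactions outside candidate set: {sorted(unknown)}")


def make_expression_profile(
    net: MetabolicNetwork,
    low_genes: set[str] | frozenset[str],
    seed: int = 0,
    path: str | Path | None = None,
    condition_name: str = "synthetic",
    threshold: float = 1.0,
) -> ExpressionProfile:
    """Synthetic log2 fold-change profile over the network's genes.

    Genes in ``low_genes`` draw |log2FC| uniformly from [0, 0.5] (below the
    default threshold of 1); all others from [1.5, 6].  Signs are random.
    Deterministic for a fixed seed; optionally written as a two-column TSV.
    """
    genes = net.gene_ids()
    unknown = set(low_genes) - set(genes)
    if unknown:
        raise ValueError(f"low_genes not in network: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for gid in genes:
        mag = rng.uniform(0.0, 0.5) if gid in low_genes else rng.uniform(1.5, 6.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values[gid] = round(sign * mag, 4)
    profile = ExpressionProfile(condition_name, values, threshold)
    if path is not None:
        lines = ["gene_id\tlog2fc"]
        lines += [f"{gid}\t{values[gid]}" for gid in genes]
        Path(path).write_text("\n".join(lines) + "\n")
    return profile


def make_phenotype_table(spec: PlantedPhenotypeSpec):
    """Random designs with additive planted knockout effects on the
    product response; returns a ready :class:`KnockoutFeatureMatrix`."""
    from .target_rank import KnockoutFeatureMatrix

    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_designs, len(spec.candidates)
    X = (rng.random((n, p)) < spec.knock_probability).astype(int)
    beta = np.array([spec.effects.get(c, 0.0) for c in spec.candidates])
    response = X @ beta
    if spec.noise_sd > 0:
        response = response + rng.normal(0.0, spec.noise_sd, size=n)
    return KnockoutFeatureMatrix(
        features=X,
        candidates=list(spec.candidates),
        responses={"product": response.astype(float)},
        design_labels=[f"synthetic_{i}" for i in range(n)],
        source_models=["synthetic"] * n,
    )
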