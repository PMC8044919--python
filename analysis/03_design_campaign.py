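"""Enumerate succinate-overproducing knockout designs with OptKnock.

Candidate preprocessing removes blocked, essential (computational and
experimental), gene-less and exchange reactions; rounds over k = 1..4
each request up to 25 designs (integer-cut enumeration), de-duplicated
across rounds.

Writes: results/03_designs.tsv
"""

from pathlib import Path

from succdesign.design_enum import build_candidate_set, enumerate_designs
from succdesign.flux_core import solve_fba
from succdesign.synth_fixtures import EXPERIMENTAL_ESSENTIALS, make_toy_network

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

K_MAX = 4
PER_ROUND = 25
PRODUCT = "EX_succ_e"


def main() -> None:
    net = make_toy_network()
    wt = solve_fba(net)
    min_biomass = 0.05 * wt.objective_value

    cands = build_candidate_set(
        net, 0.05, experimental_list=sorted(EXPERIMENTAL_ESSENTIALS)
    )
    print(f"Candidates: {len(cands.candidates)} of {len(net.reactions)} reactions")
    for reason in ("blocked", "no_gene", "exchange",
                   "experimentally_essential", "computationally_essential"):
        ids = sorted(r for r, why in cands.excluded.items() if why == reason)
        if ids:
            print(f"  excluded ({reason}): {', '.join(ids)}")

    designs = []
    cuts = []
    for k in range(1, K_MAX + 1):
        found = enumerate_designs(
            net, cands, k, PER_ROUND, PRODUCT, min_biomass,
            forbidden_sets=cuts, source_model=net.id,
            require_improvement=False,
        )
        cuts.extend(d.knockouts for d in found)
        designs.extend(found)
        best = max((d.predicted_product_flux for d in found), default=0.0)
        print(f"Round k={k}: {len(found)} designs, best succinate {best:.3f}")

    with open(OUT / "03_designs.tsv", "w") as fh:
        fh.write("model_label\tk\tknockouts\tpred_succ\tpred_growth\n")
        for d in designs:
            fh.write(
                f"{d.source_model}\t{d.k}\t{';'.join(sorted(d.knockouts))}\t"
                f"{d.predicted_product_flux:.6f}\t{d.predicted_growth:.6f}\n"
            )
    print(f"{len(designs)} designs -> results/03_designs.tsv")


if __name__ == "__main__":
    main()
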