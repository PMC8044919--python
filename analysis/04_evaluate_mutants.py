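"""Evaluate every enumerated design by FBA, product FVA at maximal growth
(growth-coupling classification with the 0.1 / 0.1 / 2.0 thresholds), and
MOMA re-projection from the parsimonious wild-type reference.

Reads:  results/03_designs.tsv   (run 03_design_campaign.py first)
Writes: results/04_evaluation.tsv
"""

from pathlib import Path

from succdesign.design_enum import MutantDesign
from succdesign.mutant_eval import evaluate_campaign
from succdesign.synth_fixtures import make_toy_network

OUT = Path(__file__).resolve().parent.parent / "results"
PRODUCT = "EX_succ_e"


def main() -> None:
    designs_path = OUT / "03_designs.tsv"
    if not designs_path.exists():
        raise SystemExit("run analysis/03_design_campaign.py first")
    designs = []
    for ln in designs_path.read_text().splitlines()[1:]:
        label, k, kos, succ, growth = ln.split("\t")
        designs.append(MutantDesign(frozenset(kos.split(";")), label,
                                    float(succ), float(growth)))

    net = make_toy_network()
    summary = evaluate_campaign(net, designs, PRODUCT)
    print(f"{len(summary.records)} designs evaluated "
          f"({len(summary.errors)} errors)")
    print(f"growth-coupled: {summary.n_growth_coupled}; "
          f"non-unique: {summary.n_non_unique} (rescued: {summary.n_rescued}); "
          f"not coupled: {summary.n_not_coupled}")
    print(f"overproducer set (coupled + rescued): {summary.n_overproducers}")

    with open(OUT / "04_evaluation.tsv", "w") as fh:
        fh.write("knockouts\tk\tfba_growth\tfba_product\tfva_min\tfva_max\t"
                 "coupling\trescued\tmoma_distance\tmoma_growth\tmodel_label\n")
        for r in summary.records:
            lo = r.product_fva.min_flux if r.product_fva else 0.0
            hi = r.product_fva.max_flux if r.product_fva else 0.0
            fh.write(
                f"{';'.join(sorted(r.design.knockouts))}\t{r.design.k}\t"
                f"{r.fba_growth:.6f}\t{r.fba_product:.6f}\t{lo:.6f}\t{hi:.6f}\t"
                f"{r.coupling.value}\t{int(r.rescued)}\t"
                f"{r.moma_distance:.6f}\t{r.moma_growth:.6f}\t"
                f"{r.design.source_model}\n"
            )
    print("-> results/04_evaluation.tsv")


if __name__ == "__main__":
    main()
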