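"""Extract two GIMME context models from synthetic expression profiles and
compare them, mirroring the optimized-medium vs evolved-strain contrast:
one profile expresses everything, the other silences the GldA/DhaKLM
glycerol route plus the lactate and pyruvate-oxidase by-product genes.

Writes: results/02_expression_*.tsv, results/02_context_comparison.tsv
"""

from pathlib import Path

from succdesign.context_builder import (
    compare_context_models,
    context_network,
    gimme_extract,
    reaction_states,
)
from succdesign.flux_core import solve_fba
from succdesign.synth_fixtures import make_expression_profile, make_toy_network

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 20240917


def main() -> None:
    net = make_toy_network()
    base_growth = solve_fba(net).objective_value

    prof_a = make_expression_profile(
        net, set(), seed=SEED, path=OUT / "02_expression_condition_a.tsv",
        condition_name="condition_a",
    )
    low = {"gldA", "dhaK", "dhaL", "dhaM", "ldhA", "poxB"}
    prof_b = make_expression_profile(
        net, low, seed=SEED, path=OUT / "02_expression_condition_b.tsv",
        condition_name="condition_b",
    )

    ctx = {}
    for name, prof in (("a", prof_a), ("b", prof_b)):
        states = reaction_states(net, prof)
        ctx[name] = gimme_extract(net, states, objective_fraction=0.9)
        growth = solve_fba(context_network(ctx[name])).objective_value
        print(f"Context {name}: kept {len(ctx[name].kept_reactions)}, "
              f"removed {sorted(ctx[name].removed_reactions) or 'nothing'}; "
              f"growth {growth:.3f} vs base {base_growth:.3f}")

    cmp_ = compare_context_models(ctx["a"], ctx["b"])
    shared, ua, ub = cmp_.counts
    print(f"Shared reactions: {shared}; unique to a: {ua}; unique to b: {ub}")
    print(f"Reactions with flux differences > 1e-6: {len(cmp_.flux_differences)}")

    with open(OUT / "02_context_comparison.tsv", "w") as fh:
        fh.write("reaction_id\tstatus\tflux_difference\n")
        for rid in sorted(cmp_.shared):
            fh.write(f"{rid}\tshared\t{cmp_.flux_differences.get(rid, 0.0):.6f}\n")
        for rid in sorted(cmp_.unique_to_a):
            fh.write(f"{rid}\tunique_to_a\t\n")
        for rid in sorted(cmp_.unique_to_b):
            fh.write(f"{rid}\tunique_to_b\t\n")


if __name__ == "__main__":
    main()
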