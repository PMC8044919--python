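"""Rank knockout targets: random-forest importance (IncNodePurity) for the
succinate, growth and MOMA-distance responses, knockout frequencies,
per-k Pearson co-occurrence, and frequency PCA.

Reads:  results/03_designs.tsv, results/04_evaluation.tsv
Writes: results/05_importance_<response>.tsv, results/05_frequency.tsv,
        results/05_cooccurrence.tsv, results/05_pca.tsv
"""

from pathlib import Path

import pandas as pd

from succdesign.design_enum import MutantDesign
from succdesign.flux_core import FVARange
from succdesign.mutant_eval import CouplingClass, EvaluationRecord
from succdesign.target_rank import (
    build_feature_matrix,
    cooccurrence_correlation,
    fit_rf,
    frequency_pca,
    knockout_frequency,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    eval_path = OUT / "04_evaluation.tsv"
    if not eval_path.exists():
        raise SystemExit("run analysis/04_evaluate_mutants.py first")
    df = pd.read_csv(eval_path, sep="\t")
    designs, records = [], []
    for _, row in df.iterrows():
        d = MutantDesign(frozenset(str(row["knockouts"]).split(";")),
                         str(row["model_label"]))
        fva = FVARange("p", row["fva_min"], max(row["fva_min"], row["fva_max"]), 1.0)
        records.append(EvaluationRecord(
            d, row["fba_growth"], row["fba_product"], fva,
            CouplingClass(row["coupling"]), bool(row["rescued"]),
            row["moma_distance"], row["moma_growth"],
        ))
        designs.append(d)

    candidates = sorted({r for d in designs for r in d.knockouts})
    matrix = build_feature_matrix(designs, candidates, records)

    for resp in ("product", "growth", "distance"):
        report = fit_rf(matrix, resp, seed=SEED, n_trees=200)
        out = OUT / f"05_importance_{resp}.tsv"
        with open(out, "w") as fh:
            fh.write("reaction_id\tinc_node_purity\trank\n")
            for i, rid in enumerate(report.rank, 1):
                fh.write(f"{rid}\t{report.importances[rid]:.6f}\t{i}\n")
        print(f"{resp}: held-out MSE {report.test_mse:.4f}; "
              f"top targets {', '.join(report.rank[:5])}")

    freq = knockout_frequency(designs)
    freq_df = pd.DataFrame({
        "count": freq.counts,
        "fraction": freq.fractions,
        "above_average": freq.above_average.astype(int),
    }).sort_values("count", ascending=False)
    freq_df.to_csv(OUT / "05_frequency.tsv", sep="\t")
    print("Most frequent knockouts:",
          ", ".join(freq_df.head(5).index))

    corr = cooccurrence_correlation(freq.per_k)
    corr.to_csv(OUT / "05_cooccurrence.tsv", sep="\t")

    pca = frequency_pca(freq.per_k)
    with open(OUT / "05_pca.tsv", "w") as fh:
        fh.write("reaction_id\tpc1_score\tpc2_score\n")
        for rid, row in zip(pca.row_labels, pca.scores):
            fh.write(f"{rid}\t{row[0]:.6f}\t{row[1]:.6f}\n")
    print(f"Frequency PCA: first two components explain "
          f"{100 * pca.explained_variance.sum():.1f}% of the variance")


if __name__ == "__main__":
    main()
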