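"""target_rank: feature matrix, RF importance, frequency/PCA summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from succdesign.design_enum import MutantDesign
from succdesign.flux_core import FVARange
from succdesign.mutant_eval import CouplingClass, EvaluationRecord
from succdesign.synth_fixtures import PlantedPhenotypeSpec, make_phenotype_table
from succdesign.target_rank import (
    KnockoutFeatureMatrix,
    build_feature_matrix,
    cooccurrence_correlation,
    fit_rf,
    frequency_pca,
    knockout_frequency,
    predict_phenotype,
)


def fake_record(design, product=1.0, growth=0.5, distance=2.0):
    fva = FVARange("EX_succ_e", product, product, 1.0)
    return EvaluationRecord(
        design, growth, product, fva, CouplingClass.GROWTH_COUPLED, False,
        distance, growth,
    )


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

class TestFeatureMatrix:
    def test_single_design_row(self):
        d = MutantDesign(frozenset({"FUM"}))
        m = build_feature_matrix([d], ["FUM", "PDH"], [fake_record(d)])
        assert m.features.tolist() == [[1, 0]]
        assert m.responses["product"][0] == 1.0

    def test_row_sums_equal_k(self):
        designs = [
            MutantDesign(frozenset(s))
            for s in ({"A"}, {"A", "B"}, {"B", "C", "D"})
        ]
        recs = [fake_record(d) for d in designs]
        m = build_feature_matrix(designs, ["A", "B", "C", "D"], recs)
        assert m.features.sum(axis=1).tolist() == [d.k for d in designs]

    def test_knockout_outside_candidates_rejected(self):
        d = MutantDesign(frozenset({"ZZZ"}))
        with pytest.raises(ValueError, match="ZZZ"):
            build_feature_matrix([d], ["A"], [fake_record(d)])

    def test_non_binary_matrix_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            KnockoutFeatureMatrix(np.array([[2, 0]]), ["A", "B"], {"product": np.zeros(1)})


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

class TestFitRF:
    def test_perfect_single_feature(self, rng):
        X = (rng.random((60, 3)) < 0.5).astype(int)
        y = 5.0 * X[:, 1]
        m = KnockoutFeatureMatrix(X, ["A", "B", "C"], {"product": y})
        report = fit_rf(m, "product", seed=0, n_trees=100)
        assert report.rank[0] == "B"
        assert report.test_mse < 0.05

    def test_seed_reproducibility(self):
        table = make_phenotype_table(PlantedPhenotypeSpec(seed=7, effects={"R0": 2.0}))
        a = fit_rf(table, "product", seed=11, n_trees=60)
        b = fit_rf(table, "product", seed=11, n_trees=60)
        assert a.importances == b.importances
        assert a.test_mse == b.test_mse
        assert a.rank == b.rank

    def test_planted_two_effects_recovered(self):
        spec = PlantedPhenotypeSpec(
            n_designs=200, effects={"R0": 2.0, "R1": 2.0}, noise_sd=0.1, seed=3
        )
        report = fit_rf(make_phenotype_table(spec), "product", seed=3, n_trees=200)
        assert set(report.rank[:2]) == {"R0", "R1"}
        assert report.test_mse <= 5 * 0.1**2

    def test_zero_variance_features_dropped(self):
        X = np.zeros((30, 3), dtype=int)
        X[:15, 0] = 1
        y = X[:, 0] * 2.0
        m = KnockoutFeatureMatrix(X, ["A", "B", "C"], {"product": y})
        report = fit_rf(m, "product", seed=0, n_trees=50)
        assert report.dropped_features == ["B", "C"]
        assert report.n_features_used == 1

    def test_constant_response_warns_with_zero_importance(self):
        X = (np.arange(40) % 2).reshape(-1, 1) @ np.ones((1, 2), dtype=int)
        m = KnockoutFeatureMatrix(
            X.astype(int), ["A", "B"], {"product": np.ones(40)}
        )
        with pytest.warns(UserWarning, match="constant"):
            report = fit_rf(m, "product", seed=0, n_trees=20)
        assert all(v == 0 for v in report.importances.values())

    def test_importance_permutes_with_columns(self):
        spec = PlantedPhenotypeSpec(
            n_designs=120, effects={"R0": 3.0}, noise_sd=0.05, seed=9,
            candidates=("R0", "R1", "R2"),
        )
        table = make_phenotype_table(spec)
        rep = fit_rf(table, "product", seed=5, n_trees=80)
        permuted = KnockoutFeatureMatrix(
            table.features[:, [2, 0, 1]], ["R2", "R0", "R1"],
            table.responses, table.design_labels, table.source_models,
        )
        rep_p = fit_rf(permuted, "product", seed=5, n_trees=80)
        for name in ("R0", "R1", "R2"):
            assert rep_p.importances[name] == pytest.approx(
                rep.importances[name], rel=1e-9
            )


class TestPredict:
    @pytest.fixture()
    def planted_report(self):
        spec = PlantedPhenotypeSpec(
            n_designs=200, effects={"R0": 2.0, "R1": 2.0}, noise_sd=0.1, seed=4
        )
        table = make_phenotype_table(spec)
        return fit_rf(table, "product", seed=4, n_trees=200), table

    def test_all_zero_vector_predicts_baseline(self, planted_report):
        report, table = planted_report
        pred = predict_phenotype(report, np.zeros(report.n_features_used))
        assert abs(pred) < 0.5  # near the zero-effect baseline

    def test_unseen_double_knockout_adds_both_effects(self, planted_report):
        report, table = planted_report
        x = np.zeros(report.n_features_used)
        x[report.feature_order.index("R0")] = 1
        x[report.feature_order.index("R1")] = 1
        both = predict_phenotype(report, x)
        none = predict_phenotype(report, np.zeros_like(x))
        assert both - none == pytest.approx(4.0, abs=0.8)

    def test_prediction_within_training_range(self, planted_report):
        report, table = planted_report
        y = table.responses["product"]
        x = np.ones(report.n_features_used)
        assert y.min() - 1e-9 <= predict_phenotype(report, x) <= y.max() + 1e-9

    def test_wrong_length_rejected(self, planted_report):
        report, _ = planted_report
        with pytest.raises(ValueError, match="length"):
            predict_phenotype(report, np.zeros(report.n_features_used + 2))


# ---------------------------------------------------------------------------
# Frequencies, co-occurrence, PCA
# ---------------------------------------------------------------------------

class TestFrequency:
    def test_simple_counts(self):
        designs = [MutantDesign(frozenset({"A"})), MutantDesign(frozenset({"A", "B"}))]
        rep = knockout_frequency(designs)
        assert rep.counts["A"] == 2 and rep.counts["B"] == 1
        assert rep.fractions["A"] == pytest.approx(1.0)

    def test_per_k_row_sums_conserve_totals(self):
        designs = [
            MutantDesign(frozenset(s))
            for s in ({"A"}, {"A", "B"}, {"A", "B", "C"}, {"B", "C"})
        ]
        rep = knockout_frequency(designs)
        assert (rep.per_k.sum(axis=1) == rep.counts[rep.per_k.index]).all()

    def test_order_invariance(self):
        designs = [
            MutantDesign(frozenset(s)) for s in ({"A"}, {"B", "C"}, {"A", "C"})
        ]
        a = knockout_frequency(designs)
        b = knockout_frequency(designs[::-1])
        pd.testing.assert_series_equal(a.counts, b.counts)


class TestCooccurrence:
    def test_identical_vectors_correlate_perfectly(self):
        per_k = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["A", "B"], columns=[1, 2, 3])
        corr = cooccurrence_correlation(per_k)
        assert corr.loc["A", "B"] == pytest.approx(1.0)

    def test_antimonotone_vectors_anticorrelate(self):
        per_k = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["A", "B"], columns=[1, 2, 3])
        assert cooccurrence_correlation(per_k).loc["A", "B"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        per_k = pd.DataFrame([[1, 2, 3], [2, 2, 2]], index=["A", "B"], columns=[1, 2, 3])
        corr = cooccurrence_correlation(per_k)
        assert np.isnan(corr.loc["A", "B"])
        assert corr.loc["B", "B"] == 1.0

    def test_matches_direct_covariance_formula(self, rng):
        per_k = pd.DataFrame(rng.integers(0, 9, size=(5, 6)).astype(float))
        corr = cooccurrence_correlation(per_k)
        for i in range(5):
            for j in range(5):
                x, y = per_k.iloc[i].to_numpy(), per_k.iloc[j].to_numpy()
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert corr.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_single_k_level_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_correlation(pd.DataFrame([[1], [2]]))


class TestPCA:
    def test_rank_one_explains_everything(self):
        freq = pd.DataFrame(np.outer([1, 2, 3.0], [1, 1, 2.0]))
        res = frequency_pca(freq)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        X = rng.random((6, 4))
        res = frequency_pca(pd.DataFrame(X))
        Xc = X - X.mean(axis=0)
        eigval, eigvec = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        assert res.explained_variance[:2] == pytest.approx(
            eigval[:2] / eigval.sum(), abs=1e-9
        )
        for comp in range(2):
            v = eigvec[:, comp]
            got = res.loadings[:, comp]
            assert np.allclose(got, v, atol=1e-8) or np.allclose(got, -v, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        X = rng.random((5, 4))
        a = frequency_pca(pd.DataFrame(X))
        b = frequency_pca(pd.DataFrame(X.copy()))
        assert np.allclose(a.loadings, b.loadings)
        for comp in range(2):
            lead = np.argmax(np.abs(a.loadings[:, comp]))
            assert a.loadings[lead, comp] >= 0

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            frequency_pca(pd.DataFrame(np.ones((3, 3))))
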