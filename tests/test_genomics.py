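import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Ridge

from m6atlas import genomics
from m6atlas.io import GeneSetCollection, MutationTable, SegmentTable, toy_arm_table, toy_genome
from m6atlas.simulate import generate_cell_line_panel
from tests.conftest import make_expression


def _segs(rows):
    return SegmentTable(
        pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "log2_ratio"])
    )


def _muts(rows):
    return MutationTable(
        pd.DataFrame(rows, columns=["sample_id", "gene", "variant_classification"])
    )


class TestFGA:
    def test_neutral_genome_zero(self):
        fga = genomics.fraction_genome_altered(_segs([("T1", "chr1", 1, 1000, 0.0)]))
        assert fga["T1"] == 0.0

    def test_fully_amplified_one(self):
        fga = genomics.fraction_genome_altered(_segs([("T1", "chr1", 1, 1000, 1.0)]))
        assert fga["T1"] == 1.0

    def test_half_altered(self):
        fga = genomics.fraction_genome_altered(
            _segs([("T1", "chr1", 1, 500, 0.5), ("T1", "chr1", 501, 1000, 0.0)])
        )
        assert fga["T1"] == pytest.approx(0.5)

    def test_threshold_is_strict_exceedance(self):
        fga = genomics.fraction_genome_altered(
            _segs([("T1", "chr1", 1, 100, 0.2)]), threshold=0.2
        )
        assert fga["T1"] == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(2, 999))
    def test_split_invariance(self, cut):
        whole = _segs([("T1", "chr1", 1, 1000, 0.7), ("T1", "chr2", 1, 1000, 0.0)])
        split = _segs(
            [
                ("T1", "chr1", 1, cut - 1, 0.7),
                ("T1", "chr1", cut, 1000, 0.7),
                ("T1", "chr2", 1, 1000, 0.0),
            ]
        )
        a = genomics.fraction_genome_altered(whole)["T1"]
        b = genomics.fraction_genome_altered(split)["T1"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_sample_absent(self):
        fga = genomics.fraction_genome_altered(_segs([("T1", "chr1", 1, 10, 0.0)]))
        assert "T2" not in fga.index


class TestAneuploidy:
    def _arm_table(self):
        return toy_arm_table(toy_genome(2, 1000))

    def test_neutral_zero(self):
        s = genomics.aneuploidy_score(
            _segs([("T1", "chr1", 1, 1000, 0.0), ("T1", "chr2", 1, 1000, 0.0)]),
            self._arm_table(),
        )
        assert s["T1"] == 0

    def test_one_arm_amplified(self):
        s = genomics.aneuploidy_score(
            _segs([("T1", "chr1", 1, 500, 1.0), ("T1", "chr1", 501, 1000, 0.0)]),
            self._arm_table(),
        )
        assert s["T1"] == 1

    def test_arm_fraction_threshold(self):
        segs = _segs(
            [("T1", "chr1", 1, 200, 1.0), ("T1", "chr1", 201, 500, 0.0)]
        )  # 40% of chr1p altered
        assert genomics.aneuploidy_score(segs, self._arm_table(), arm_fraction=0.5)["T1"] == 0
        assert genomics.aneuploidy_score(segs, self._arm_table(), arm_fraction=0.3)["T1"] == 1


class TestTMB:
    def test_arithmetic(self):
        rows = [("T1", f"G{i}", "Missense_Mutation") for i in range(76)]
        assert genomics.tmb(_muts(rows))["T1"] == pytest.approx(2.0)

    def test_zero_and_absent_sample(self):
        t = genomics.tmb(_muts([("T1", "G1", "Silent")]), samples=["T1", "T2"])
        assert t["T1"] == 0.0 and t["T2"] == 0.0

    def test_nonsynonymous_filter(self):
        t = genomics.tmb(_muts([("T1", "G1", "Missense_Mutation"), ("T1", "G2", "Silent")]))
        assert t["T1"] == pytest.approx(1 / 38)

    def test_linear_in_count(self):
        rows1 = [("T1", f"G{i}", "Missense_Mutation") for i in range(10)]
        rows2 = rows1 + [("T1", f"H{i}", "Nonsense_Mutation") for i in range(10)]
        assert genomics.tmb(_muts(rows2))["T1"] == pytest.approx(2 * genomics.tmb(_muts(rows1))["T1"])

    def test_titv(self):
        df = pd.DataFrame(
            {
                "sample_id": ["T1"] * 3,
                "gene": ["A", "B", "C"],
                "variant_classification": ["Missense_Mutation"] * 3,
                "ref_allele": ["A", "C", "A"],
                "alt_allele": ["G", "T", "T"],  # two transitions, one transversion
            }
        )
        assert genomics.titv_ratio(MutationTable(df)) == pytest.approx(2.0)


class TestSignatureScores:
    def test_single_gene_set_equals_zscore(self):
        rng = np.random.default_rng(0)
        X = make_expression(rng.uniform(2, 8, (3, 10)))
        out = genomics.signature_scores(X, GeneSetCollection({"s": {"G0"}}))
        vals = X.values.loc["G0"]
        z = (vals - vals.mean()) / vals.std(ddof=0)
        np.testing.assert_allclose(out["s"], z, atol=1e-10)

    def test_two_gene_hand_computed(self):
        X = make_expression([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        out = genomics.signature_scores(X, GeneSetCollection({"s": {"G0", "G1"}}))
        z0 = (np.array([1, 2, 3]) - 2) / np.std([1, 2, 3])
        z1 = (np.array([2, 4, 6]) - 4) / np.std([2, 4, 6])
        np.testing.assert_allclose(out["s"], (z0 + z1) / 2, atol=1e-10)

    def test_cohort_mean_zero(self):
        rng = np.random.default_rng(1)
        X = make_expression(rng.uniform(2, 8, (6, 30)))
        out = genomics.signature_scores(X, GeneSetCollection({"all": set(X.gene_ids)}))
        assert out["all"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        X = make_expression(rng.uniform(2, 8, (5, 12)))
        a = genomics.signature_scores(X, GeneSetCollection({"s": {"G0", "G3", "G4"}}))
        b = genomics.signature_scores(X, GeneSetCollection({"s": {"G4", "G0", "G3"}}))
        np.testing.assert_allclose(a["s"], b["s"], atol=1e-12)

    def test_missing_set_warns_na(self):
        X = make_expression(np.random.default_rng(0).uniform(2, 8, (2, 5)))
        with pytest.warns(RuntimeWarning, match="no usable genes"):
            out = genomics.signature_scores(X, GeneSetCollection({"s": {"ABSENT"}}))
        assert out["s"].isna().all()


class TestRidgeDrugModel:
    def test_noiseless_recovery(self):
        expr, ic50, truth = generate_cell_line_panel(n_lines=200, n_genes=30,
                                                     noise_sd=0.0, seed=0)
        train = expr.sample_ids[:150]
        test = expr.sample_ids[150:]
        Xtr = make_expression(expr.values[train].to_numpy(), genes=expr.gene_ids,
                              samples=train)
        model = genomics.train_drug_model(Xtr, ic50.loc[train], "Cisplatin",
                                          lambda_grid=[1e-10], n_folds=3, seed=0)
        Xte = make_expression(expr.values[test].to_numpy(), genes=expr.gene_ids,
                              samples=test)
        pred = genomics.predict_ic50(model, Xte)
        np.testing.assert_allclose(pred, ic50.loc[test, "Cisplatin"], atol=1e-6)

    def test_full_shrinkage_predicts_training_mean(self):
        expr, ic50, _ = generate_cell_line_panel(n_lines=60, n_genes=10, seed=1)
        model = genomics.train_drug_model(expr, ic50, "Paclitaxel",
                                          lambda_grid=[1e12], n_folds=3, seed=0)
        pred = genomics.predict_ic50(model, expr)
        np.testing.assert_allclose(pred, ic50["Paclitaxel"].mean(), atol=1e-6)

    def test_intercept_contract(self):
        expr, ic50, _ = generate_cell_line_panel(n_lines=80, n_genes=12, seed=2)
        model = genomics.train_drug_model(expr, ic50, "Cisplatin", n_folds=4, seed=0)
        mean_profile = make_expression(
            expr.values.mean(axis=1).to_numpy()[:, None], genes=expr.gene_ids,
            samples=["MEAN"],
        )
        pred = genomics.predict_ic50(model, mean_profile)
        assert pred["MEAN"] == pytest.approx(ic50["Cisplatin"].mean(), abs=1e-8)

    def test_affine_rescaling_invariance(self):
        expr, ic50, _ = generate_cell_line_panel(n_lines=80, n_genes=12, seed=3)
        lam = [1.0]
        m1 = genomics.train_drug_model(expr, ic50, "Cisplatin", lambda_grid=lam,
                                       n_folds=4, seed=0)
        scaled_vals = expr.values.copy()
        scaled_vals.iloc[0] = scaled_vals.iloc[0] * 3.0 + 1.0
        expr2 = make_expression(scaled_vals.to_numpy(), genes=expr.gene_ids,
                                samples=expr.sample_ids)
        m2 = genomics.train_drug_model(expr2, ic50, "Cisplatin", lambda_grid=lam,
                                       n_folds=4, seed=0)
        p1 = genomics.predict_ic50(m1, expr)
        p2 = genomics.predict_ic50(m2, expr2)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_matches_sklearn_ridge(self):
        expr, ic50, _ = generate_cell_line_panel(n_lines=100, n_genes=15, seed=4)
        lam = 5.0
        model = genomics.train_drug_model(expr, ic50, "Cisplatin", lambda_grid=[lam],
                                          n_folds=4, seed=0)
        Xs = ((expr.values.to_numpy().T - model.train_mean.to_numpy())
              / model.train_sd.to_numpy())
        y = ic50["Cisplatin"].to_numpy()
        ref = Ridge(alpha=lam, fit_intercept=True).fit(Xs, y)
        np.testing.assert_allclose(model.coefficients, ref.coef_, atol=1e-8)

    def test_empty_gene_intersection(self):
        expr, ic50, _ = generate_cell_line_panel(n_lines=30, n_genes=5, seed=5)
        model = genomics.train_drug_model(expr, ic50, "Cisplatin", n_folds=3, seed=0)
        other = make_expression(np.random.default_rng(0).uniform(2, 8, (3, 4)),
                                genes=["X1", "X2", "X3"])
        with pytest.raises(ValueError, match="no genes shared"):
            genomics.predict_ic50(model, other)


class TestBurdenTable:
    def test_assembles_with_na_for_missing(self, cohort):
        X, _, segs, muts, _ = cohort
        bt = genomics.burden_table(segs, muts, toy_arm_table(), X.sample_ids)
        assert list(bt.data.columns) == ["fga", "aneuploidy_score", "tmb"]
        assert bt.data["fga"].between(0, 1).all()
        assert (bt.data["tmb"] >= 0).all()
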