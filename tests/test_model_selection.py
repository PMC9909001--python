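"""Design preparation, model enumeration, AICc weights, averaging, GVIF."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dispersal_pgls.model_selection import (
    ModelFormula,
    PredictorSpec,
    build_model_matrix,
    confidence_set,
    enumerate_models,
    fit_models,
    gvif,
    model_average,
    prepare_design,
    rank_models,
    variable_importance,
)
from dispersal_pgls.phylo import PGLSFit, phylo_covariance
from dispersal_pgls.simulate import simulate_tree


def continuous(*names, **kw):
    return [PredictorSpec(n, "continuous", **kw) for n in names]


class TestPrepareDesign:
    def test_log_then_zscore_hand_values(self):
        # logs {0, 2, 4}: mean 2, sample sd (n-1 denominator) = 2 -> {-1, 0, 1}
        table = pd.DataFrame({"x": [1.0, math.e**2, math.e**4]}, index=list("abc"))
        d = prepare_design(table, continuous("x", log_transform=True))
        np.testing.assert_allclose(d.X["x"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_categorical_expansion(self):
        table = pd.DataFrame(
            {"habitat": ["coasts", "open", "wetlands", "woodlands", "open"]},
            index=list("abcde"),
        )
        spec = PredictorSpec(
            "habitat", "categorical",
            levels=("coasts", "open", "wetlands", "woodlands"), reference="coasts",
        )
        d = prepare_design(table, [spec])
        assert d.column_groups["habitat"] == [
            "habitat[open]", "habitat[wetlands]", "habitat[woodlands]"
        ]
        np.testing.assert_allclose(d.X["habitat[open]"], [0, 1, 0, 0, 1])

    def test_standardized_moments(self, rng):
        table = pd.DataFrame({"x": rng.uniform(1, 50, 40)})
        d = prepare_design(table, continuous("x", log_transform=True))
        assert d.X["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert d.X["x"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_missing_rows_dropped_with_audit(self):
        table = pd.DataFrame(
            {"x": [1.0, np.nan, 3.0], "z": [1.0, 2.0, 3.0]}, index=list("abc")
        )
        d = prepare_design(table, continuous("x", "z"))
        assert d.dropped == ["b"]
        assert list(d.X.index) == ["a", "c"]

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="variance"):
            prepare_design(table, continuous("x"))

    def test_nonpositive_log_rejected(self):
        table = pd.DataFrame({"x": [1.0, -2.0, 3.0]})
        with pytest.raises(ValueError, match="non-positive"):
            prepare_design(table, continuous("x", log_transform=True))


def brute_force_enumeration(names, max_terms):
    """Independent oracle: enumerate (mains, interactions) pairs directly."""
    models = set()
    for r in range(len(names) + 1):
        for mains in itertools.combinations(names, r):
            if len(mains) > max_terms:
                continue
            pairs = list(itertools.combinations(mains, 2))
            for k in range(len(pairs) + 1):
                for inters in itertools.combinations(pairs, k):
                    if len(mains) + len(inters) <= max_terms:
                        models.add((mains, inters))
    return models


class TestEnumeration:
    def test_single_predictor_two_models(self):
        models = enumerate_models(continuous("a"))
        assert {m.label() for m in models} == {"1", "a"}

    def test_zero_cap_intercept_only(self):
        models = enumerate_models(continuous("a", "b"), max_terms=0)
        assert [m.label() for m in models] == ["1"]

    def test_three_continuous_matches_bruteforce(self):
        specs = continuous("a", "b", "c")
        got = {(m.mains, m.interactions) for m in enumerate_models(specs, max_terms=5)}
        assert got == brute_force_enumeration(["a", "b", "c"], 5)

    def test_marginality_and_cap(self):
        specs = continuous("a", "b", "c", "d", "e", "f")
        models = enumerate_models(specs, max_terms=5)
        for m in models:
            assert m.n_variables <= 5
            for x, z in m.interactions:
                assert x in m.mains and z in m.mains

    def test_categoricals_excluded_from_interactions(self):
        specs = continuous("a", "b") + [
            PredictorSpec("h", "categorical", levels=("u", "v", "w"))
        ]
        models = enumerate_models(specs, max_terms=5)
        for m in models:
            assert all("h" not in pair for pair in m.interactions)

    def test_deterministic_order(self):
        specs = continuous("a", "b", "c")
        l1 = [m.label() for m in enumerate_models(specs)]
        l2 = [m.label() for m in enumerate_models(specs)]
        assert l1 == l2 and l1[0] == "1"


def fake_fit(aicc_value, terms=("Intercept",), n=44, beta=None, se=None):
    p = len(terms)
    return PGLSFit(
        terms=tuple(terms),
        beta=np.array(beta if beta is not None else np.zeros(p)),
        se=np.array(se if se is not None else np.ones(p)),
        p_values=np.full(p, 0.5),
        lambda_=0.3,
        sigma2=1.0,
        loglik=-aicc_value / 2.0,
        k=p + 2,
        n=n,
        aicc=aicc_value,
        rss=1.0,
        r2=0.1,
    )


def fake_set(aiccs, formulas=None, **kw):
    if formulas is None:
        formulas = [ModelFormula(mains=(f"m{i}",)) for i in range(len(aiccs))]
    fitted = [(f, fake_fit(a, **kw)) for f, a in zip(formulas, aiccs)]
    return rank_models(fitted)


class TestRanking:
    def test_burnham_anderson_weights(self):
        ms = fake_set([100.0, 102.0])
        np.testing.assert_allclose(ms.delta_aicc, [0.0, 2.0])
        assert ms.weights[0] == pytest.approx(0.7311, abs=5e-5)
        assert ms.weights[1] == pytest.approx(0.2689, abs=5e-5)

    def test_equal_aicc_equal_weights(self):
        ms = fake_set([50.0, 50.0])
        np.testing.assert_allclose(ms.weights, [0.5, 0.5])

    def test_weights_sum_to_one(self, rng):
        ms = fake_set(list(100 + 10 * rng.random(12)))
        assert ms.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert ms.delta_aicc[0] == 0.0

    def test_differing_row_sets_rejected(self):
        f1 = (ModelFormula(mains=("a",)), fake_fit(10.0, n=44))
        f2 = (ModelFormula(mains=("b",)), fake_fit(11.0, n=40))
        with pytest.raises(ValueError, match="not comparable"):
            rank_models([f1, f2])

    def test_constant_shift_invariance(self):
        base = [100.0, 101.5, 104.0, 109.0]
        ms1, ms2 = fake_set(base), fake_set([a + 37.0 for a in base])
        np.testing.assert_allclose(ms1.delta_aicc, ms2.delta_aicc)
        np.testing.assert_allclose(ms1.weights, ms2.weights)
        assert confidence_set(ms1) == confidence_set(ms2)
        assert variable_importance(ms1) == pytest.approx(variable_importance(ms2))


class TestConfidenceSet:
    def make_with_weights(self, weights):
        # AICc values engineered to produce the requested weights
        aiccs = [-2.0 * math.log(w) for w in weights]
        ms = fake_set(aiccs)
        np.testing.assert_allclose(ms.weights, sorted(weights, reverse=True), atol=1e-9)
        return ms

    def test_prefix_cutoff(self):
        ms = self.make_with_weights([0.6, 0.3, 0.08, 0.02])
        assert confidence_set(ms, 0.95) == [0, 1, 2]

    def test_single_model(self):
        ms = self.make_with_weights([1.0])
        assert confidence_set(ms) == [0]

    def test_level_one_keeps_all(self):
        ms = self.make_with_weights([0.5, 0.3, 0.2])
        assert confidence_set(ms, 1.0) == [0, 1, 2]


class TestImportance:
    def test_everywhere_and_nowhere(self):
        formulas = [
            ModelFormula(mains=("a",)),
            ModelFormula(mains=("a", "b")),
        ]
        ms = fake_set([10.0, 12.0], formulas=formulas)
        imp = variable_importance(ms)
        assert imp["a"] == pytest.approx(1.0)
        assert imp["b"] == pytest.approx(ms.weights[1])

    def test_interaction_counts_for_membership(self):
        formulas = [
            ModelFormula(mains=("a", "b"), interactions=(("a", "b"),)),
            ModelFormula(mains=("c",)),
        ]
        ms = fake_set([10.0, 10.0], formulas=formulas)
        imp = variable_importance(ms)
        assert imp["a"] == pytest.approx(0.5)

    def test_direct_sum(self):
        # delta {0, 2*ln(0.7/0.3)} gives weights {0.7, 0.3}
        d = 2.0 * math.log(0.7 / 0.3)
        ms = fake_set([100.0, 100.0 + d])
        assert variable_importance(ms)["m0"] == pytest.approx(0.7, abs=1e-9)


class TestModelAverage:
    def two_model_set(self, betas, weights, term="x"):
        aiccs = [100.0, 100.0 - 2.0 * math.log(weights[1] / weights[0])]
        fitted = [
            (
                ModelFormula(mains=(term,)),
                fake_fit(aiccs[0], terms=("Intercept", term),
                         beta=[0.0, betas[0]], se=[0.1, 0.0]),
            ),
            (
                ModelFormula(mains=(term, "z")),
                fake_fit(aiccs[1], terms=("Intercept", term, "z"),
                         beta=[0.0, betas[1], 1.0], se=[0.1, 0.0, 0.2]),
            ),
        ]
        return rank_models(fitted)

    def test_conditional_weighted_mean(self):
        ms = self.two_model_set([1.0, 3.0], [0.75, 0.25])
        avg = model_average(ms)
        row = avg.set_index("term").loc["x"]
        assert row["estimate_conditional"] == pytest.approx(1.5, abs=1e-6)

    def test_full_average_shrinks_to_zero(self):
        # term z present only in the second model (weight 0.25) with beta 1.0
        ms = self.two_model_set([1.0, 1.0], [0.75, 0.25])
        avg = model_average(ms).set_index("term")
        assert avg.loc["z", "estimate_full"] == pytest.approx(0.25, abs=1e-6)
        assert avg.loc["z", "estimate_conditional"] == pytest.approx(1.0, abs=1e-6)

    def test_single_model_identity(self):
        fitted = [
            (
                ModelFormula(mains=("x",)),
                fake_fit(10.0, terms=("Intercept", "x"), beta=[0.5, 2.0], se=[0.1, 0.3]),
            )
        ]
        avg = model_average(rank_models(fitted)).set_index("term")
        assert avg.loc["x", "estimate_conditional"] == pytest.approx(2.0)
        assert avg.loc["x", "estimate_full"] == pytest.approx(2.0)
        assert avg.loc["x", "se_conditional"] == pytest.approx(0.3)

    def test_conditional_equals_full_for_shared_terms(self):
        ms = self.two_model_set([1.0, 3.0], [0.6, 0.4])
        avg = model_average(ms).set_index("term")
        assert avg.loc["x", "estimate_conditional"] == pytest.approx(
            avg.loc["x", "estimate_full"], abs=1e-9
        )


class TestGVIF:
    def design_from_matrix(self, M, names):
        table = pd.DataFrame(M, columns=names)
        return prepare_design(table, continuous(*names, standardize=True))

    def test_orthogonal_predictors_unity(self):
        n = 40
        x = np.tile([1.0, -1.0], n // 2)
        z = np.repeat([1.0, -1.0], n // 2)
        d = self.design_from_matrix(np.column_stack([x, z]), ["x", "z"])
        rep = gvif(d)
        np.testing.assert_allclose(rep.table["gvif"], [1.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(rep.table["corrected"], [1.0, 1.0], atol=1e-10)

    def test_dimensionality_correction_exponent(self):
        # GVIF = 4 with df = 1 corrects to 4^(1/2) = 2; its square (4) sits
        # in the moderate collinearity band
        assert 4.0 ** (1.0 / (2.0 * 1)) == pytest.approx(2.0)

    def test_known_correlation_matches_vif_regression_oracle(self, rng):
        """For single-column groups GVIF equals the classical VIF
        1/(1 - R^2_j) from regressing predictor j on the others."""
        n = 500
        z = rng.standard_normal(n)
        x = 0.8 * z + math.sqrt(1 - 0.64) * rng.standard_normal(n)
        w = rng.standard_normal(n)
        M = np.column_stack([x, z, w])
        d = self.design_from_matrix(M, ["x", "z", "w"])
        rep = gvif(d).table.set_index("predictor")
        Xs = (M - M.mean(0)) / M.std(0, ddof=1)
        for j, name in enumerate(["x", "z", "w"]):
            others = np.column_stack(
                [np.ones(n)] + [Xs[:, k] for k in range(3) if k != j]
            )
            beta = np.linalg.lstsq(others, Xs[:, j], rcond=None)[0]
            resid = Xs[:, j] - others @ beta
            r2 = 1.0 - resid @ resid / ((n - 1) * 1.0)
            assert rep.loc[name, "gvif"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)

    def test_aliased_columns_rejected(self, rng):
        x = rng.standard_normal(30)
        d = self.design_from_matrix(np.column_stack([x, x]), ["x", "z"])
        with pytest.raises(ValueError, match="aliased"):
            gvif(d)

    def test_categorical_group_df(self, rng):
        n = 60
        table = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "h": rng.choice(["u", "v", "w"], n),
            }
        )
        specs = [
            PredictorSpec("x", "continuous"),
            PredictorSpec("h", "categorical", levels=("u", "v", "w")),
        ]
        d = prepare_design(table, specs)
        rep = gvif(d).table.set_index("predictor")
        assert rep.loc["h", "df"] == 2
        assert rep.loc["h", "corrected"] == pytest.approx(
            rep.loc["h", "gvif"] ** 0.25, rel=1e-12
        )


class TestIntegrationWithPGLS:
    def test_true_predictor_dominates(self, rng):
        """With one strong true predictor and noise predictors, model
        selection puts the truth on top."""
        t = simulate_tree(44, depth=1.0, seed=21)
        C, taxa = phylo_covariance(t)
        n = len(taxa)
        table = pd.DataFrame(
            {
                "true": rng.standard_normal(n),
                "n1": rng.standard_normal(n),
                "n2": rng.standard_normal(n),
            },
            index=taxa,
        )
        specs = continuous("true", "n1", "n2")
        design = prepare_design(table, specs)
        from dispersal_pgls.phylo import lambda_transform

        eps = np.linalg.cholesky(
            lambda_transform(C, 0.4) + 1e-12 * np.eye(n)
        ) @ rng.standard_normal(n)
        y = 2.0 * design.X["true"].to_numpy() + eps
        fitted = fit_models(
            design, y, C, enumerate_models(specs, interactions=False)
        )
        ms = rank_models(fitted)
        imp = variable_importance(ms)
        assert imp["true"] == max(imp.values())
        assert imp["true"] > 0.95
        assert "true" in ms.formulas[0].mains
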