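"""Design construction, least squares, stepwise selection, prediction."""

import numpy as np
import pandas as pd
import pytest

from ampmyield import (ModelSpec, Term, build_design, default_candidate_pool,
                       dim_class, fit, fit_model, parse_model, predict_daily,
                       preset_model, stepwise_select)
from ampmyield.presets import PRESET_MODELS, format_model


def toy_records(n=12, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "milk_am": rng.uniform(8, 16, size=n),
        "content_am_fat": rng.uniform(3.5, 5.0, size=n),
        "dim": rng.integers(5, 330, size=n),
        "parity": rng.integers(1, 4, size=n),
        "month": rng.integers(1, 13, size=n),
        "yield_daily_fat": rng.uniform(800, 1400, size=n),
    })


def test_dim_class_boundaries():
    np.testing.assert_array_equal(
        dim_class([1, 30, 31, 60, 300, 301, 365]), [1, 1, 2, 2, 10, 11, 11]
    )


class TestBuildDesign:
    def test_covariate_nested_in_parity(self):
        rec = toy_records(9, seed=1)
        rec["parity"] = [1, 2, 3, 1, 2, 3, 1, 2, 3]
        spec = ModelSpec("fat", "am", (Term(("milk",), ("parity",)),))
        X, info = build_design(rec, spec)
        assert X.shape[1] == 1 + 3  # intercept + one column per parity
        for j, par in enumerate((1, 2, 3)):
            expected = np.where(rec["parity"] == par, rec["milk_am"], 0.0)
            np.testing.assert_allclose(X[:, 1 + j], expected)

    def test_pure_class_term_gives_indicators(self):
        rec = toy_records(9, seed=2)
        rec["parity"] = [1, 2, 3] * 3
        spec = ModelSpec("fat", "am", (Term((), ("parity",)),))
        X, info = build_design(rec, spec)
        assert X.shape[1] == 4
        np.testing.assert_allclose(X[:, 1:].sum(axis=1), 1.0)

    def test_hand_built_two_dim_class_matrix(self):
        rec = pd.DataFrame({
            "milk_am": [10.0, 12.0, 9.0, 11.0],
            "content_am_fat": [4.0, 4.4, 3.8, 4.2],
            "dim": [20, 25, 200, 210],  # classes 1, 1, 7, 7
            "parity": [1, 1, 2, 2],
            "month": [3, 3, 3, 3],
        })
        spec = ModelSpec("fat", "am", (Term(("q", "milk"), ("dim",)),))
        X, info = build_design(rec, spec)
        prod = rec["content_am_fat"] * rec["milk_am"]
        expected = np.column_stack([
            np.ones(4),
            np.where(np.array([True, True, False, False]), prod, 0.0),
            np.where(np.array([False, False, True, True]), prod, 0.0),
        ])
        np.testing.assert_allclose(X, expected)
        assert [c.cell for c in info] == [None, (1,), (7,)]

    def test_empty_cells_produce_no_column(self):
        rec = toy_records(6, seed=3)
        rec["parity"] = 2  # only one occupied parity cell
        spec = ModelSpec("fat", "am", (Term(("milk",), ("parity",)),))
        X, _ = build_design(rec, spec)
        assert X.shape[1] == 2

    def test_unknown_names_rejected(self):
        with pytest.raises(KeyError):
            Term(("protein",), ())
        with pytest.raises(KeyError):
            Term((), ("herd",))


class TestFitModel:
    def test_exact_linear_response_recovered(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = 2.0 + 3.5 * X[:, 1]
        fm = fit_model(X, y)
        np.testing.assert_allclose(fm.coefficients, [2.0, 3.5], atol=1e-10)
        assert fm.sse == pytest.approx(0.0, abs=1e-18)

    def test_duplicate_column_dropped_fit_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 1.0 + 2.0 * x + rng.normal(size=30)
        X1 = np.column_stack([np.ones(30), x])
        X2 = np.column_stack([np.ones(30), x, x])
        fm1, fm2 = fit_model(X1, y), fit_model(X2, y)
        assert fm2.p == fm1.p == 2
        assert len(fm2.dropped) == 1
        np.testing.assert_allclose(fm1.coefficients, fm2.coefficients)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            X = rng.normal(size=(50, 4))
            y = rng.normal(size=50)
            fm = fit_model(X, y)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(fm.coefficients, beta, atol=1e-8)

    def test_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_model(np.empty((0, 2)), np.empty(0))

    def test_nesting_never_increases_training_sse(self, calib):
        spec = ModelSpec("fat", "am", ())
        sses = [fit(calib, spec).sse]
        for term in (Term(("milk",), ()), Term(("q", "milk"), ()),
                     Term((), ("parity",)), Term(("q", "milk"), ("dim",))):
            spec = spec.with_term(term)
            sses.append(fit(calib, spec).sse)
        assert all(b <= a + 1e-6 for a, b in zip(sses, sses[1:]))

    def test_row_permutation_leaves_coefficients_unchanged(self, calib):
        spec = preset_model("fat", "am")
        fm = fit(calib, spec)
        rng = np.random.default_rng(7)
        perm = calib.iloc[rng.permutation(len(calib))].reset_index(drop=True)
        fm_p = fit(perm, spec)
        assert [c.label for c in fm.columns] == [c.label for c in fm_p.columns]
        np.testing.assert_allclose(fm.coefficients, fm_p.coefficients, atol=1e-8)


class TestPredict:
    def test_intercept_only_predicts_training_mean(self, calib):
        fm = fit(calib, ModelSpec("fat", "am", ()))
        pred = predict_daily(fm, calib)
        np.testing.assert_allclose(pred, calib["yield_daily_fat"].mean())

    def test_training_predictions_equal_fitted_values(self, calib):
        spec = preset_model("sfa", "pm")
        fm = fit(calib, spec)
        pred = predict_daily(fm, calib)
        resid = calib["yield_daily_sfa"].to_numpy() - pred
        assert float(resid @ resid) == pytest.approx(fm.sse, rel=1e-8)

    def test_hand_computed_linear_predictor(self):
        rec = toy_records(30, seed=8)
        rec["yield_daily_fat"] = (
            100.0 + 7.0 * rec["milk_am"] * rec["content_am_fat"]
        )
        fm = fit(rec, ModelSpec("fat", "am", (Term(("q", "milk"), ()),)))
        new = toy_records(5, seed=9)
        pred = predict_daily(fm, new)
        np.testing.assert_allclose(
            pred, 100.0 + 7.0 * new["milk_am"] * new["content_am_fat"],
            rtol=1e-8,
        )

    def test_unseen_class_level_raises_with_level_name(self, calib):
        fm = fit(calib, ModelSpec("fat", "am", (Term(("milk",), ("parity",)),)))
        odd = calib.head(5).copy()
        odd["parity"] = 7  # maps to class 3+, which is always seen
        predict_daily(fm, odd)  # parity 7 folds into 3+: fine
        fm.class_levels["parity"] = {1, 2}  # pretend 3+ never seen
        with pytest.raises(ValueError, match="parity"):
            predict_daily(fm, odd)


class TestStepwise:
    def pool(self):
        return (
            Term(("milk",), ()), Term(("q",), ()), Term(("q", "milk"), ()),
            Term((), ("parity",)), Term((), ("month",)),
            Term(("milk",), ("parity",)),
        )

    def planted_records(self, seed, n=300):
        rng = np.random.default_rng(seed)
        rec = toy_records(n, seed=seed)
        rec["yield_daily_fat"] = (
            200.0 + 9.0 * rec["milk_am"] * rec["content_am_fat"]
            + rng.normal(0, 30.0, size=n)
        )
        return rec

    def split3(self, seed):
        return (self.planted_records(seed), self.planted_records(seed + 500),
                self.planted_records(seed + 900))

    def test_planted_term_selected_first(self):
        calib, test, val = self.split3(11)
        spec, trace, _ = stepwise_select(
            self.pool(), calib, test, val, "fat", "am"
        )
        assert spec.terms[0] == Term(("q", "milk"), ())

    def test_trace_rmse_non_increasing(self):
        calib, test, val = self.split3(12)
        _, trace, _ = stepwise_select(self.pool(), calib, test, val, "fat", "am")
        rmses = [t["test_rmse"] for t in trace]
        assert all(b <= a for a, b in zip(rmses, rmses[1:]))

    def test_infinite_tolerance_keeps_intercept_only(self):
        calib, test, val = self.split3(13)
        spec, trace, _ = stepwise_select(
            self.pool(), calib, test, val, "fat", "am", rel_tol=np.inf
        )
        assert spec.terms == ()
        assert len(trace) == 1

    def test_zero_variance_response_gives_intercept_only(self):
        calib, test, val = self.split3(14)
        for df in (calib, test, val):
            df["yield_daily_fat"] = 1000.0
        spec, _, _ = stepwise_select(self.pool(), calib, test, val, "fat", "am")
        assert spec.terms == ()

    def test_val_set_untouched_by_selection(self):
        calib, test, val = self.split3(15)
        val_wrecked = val.copy()
        val_wrecked["yield_daily_fat"] = 0.0  # garbage VAL must not change spec
        spec1, _, _ = stepwise_select(self.pool(), calib, test, val, "fat", "am")
        spec2, _, _ = stepwise_select(
            self.pool(), calib, test, val_wrecked, "fat", "am"
        )
        assert spec1 == spec2


class TestPresets:
    def test_all_presets_parse_with_expected_structure(self):
        assert len(PRESET_MODELS) == 18
        for (trait, session), spec in PRESET_MODELS.items():
            assert spec.trait == trait and spec.session == session
            assert len(spec.terms) >= 3

    def test_fat_am_form(self):
        spec = preset_model("fat", "am")
        assert spec.terms == (
            Term(("q", "milk"), ("dim",)),
            Term((), ("parity",)),
            Term(("milk",), ("parity",)),
            Term(("q", "milk"), ("parity",)),
        )

    def test_format_parse_round_trip(self):
        for (trait, session), spec in PRESET_MODELS.items():
            again = parse_model(format_model(spec), trait, session)
            assert again == spec

    def test_wrong_session_token_rejected(self):
        with pytest.raises(ValueError):
            parse_model("a + b x (milk_PM x DIM)", "fat", "am")

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError):
            parse_model("a + b x (protein_AM x DIM)", "fat", "am")


def test_default_candidate_pool_contains_base_and_presets():
    preset_terms = preset_model("fat", "am").terms
    pool = default_candidate_pool(preset_terms)
    assert Term(("milk",), ()) in pool
    assert Term(("q", "milk"), ()) in pool
    for t in preset_terms:
        assert t in pool
    assert len(set(pool)) == len(pool)
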