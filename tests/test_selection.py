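"""Leave-one-out evaluation, Minimax criterion and exhaustive subset search."""

import numpy as np
import pytest

from takeoverpls.errors import ValidationError
from takeoverpls.plsglm import classify, fit_pls_glr, predict_proba
from takeoverpls.selection import (
    LOOEvaluation,
    exhaustive_subset_search,
    loo_evaluate,
    minimax_select,
    search_table,
    select_n_components,
)
from takeoverpls.simulate import SyntheticConfig, generate


def ev(fp, fn, subset=(0,), H=1, n=113):
    return LOOEvaluation(subset=tuple(subset), n_components=H, fp=fp, fn=fn, n=n)


def brute_force_select(cands):
    """One-line oracle for the documented tie-break cascade."""
    return min(cands, key=lambda e: (e.max_errors, e.total_errors,
                                     len(e.subset), e.n_components, e.bitmask))


class TestMinimaxSelect:
    def test_tie_on_max_broken_by_total_errors(self):
        # the two retained subset-search finalists: (max 21, total 36) vs
        # (max 21, total 33) -> the 33-error model wins
        a = ev(fp=21, fn=15, subset=(0, 1, 2, 3, 4, 5))
        b = ev(fp=21, fn=12, subset=(0, 1, 2, 3, 4))
        assert minimax_select([a, b]) is b

    def test_component_count_profile_prefers_first_minimum(self):
        # max errors {28, 28, 29, 31}, totals {45, 48, 54, 55} -> H = 1
        full = tuple(range(15))
        cands = [
            ev(fp=28, fn=17, subset=full, H=1),
            ev(fp=28, fn=20, subset=full, H=2),
            ev(fp=29, fn=25, subset=full, H=3),
            ev(fp=31, fn=24, subset=full, H=4),
        ]
        assert minimax_select(cands).n_components == 1

    def test_single_candidate_returned(self):
        only = ev(3, 4)
        assert minimax_select([only]) is only

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            minimax_select([])

    def test_matches_brute_force_scan_on_random_lists(self, rng):
        for _ in range(300):
            cands = []
            for _ in range(rng.integers(1, 12)):
                subset = tuple(sorted(rng.choice(8, rng.integers(1, 6),
                                                 replace=False)))
                cands.append(ev(int(rng.integers(0, 30)), int(rng.integers(0, 30)),
                                subset=subset, H=int(rng.integers(1, 4))))
            assert minimax_select(cands) == brute_force_select(cands)

    def test_trail_records_each_stage(self):
        trail = []
        minimax_select([ev(5, 5, subset=(0,)), ev(5, 5, subset=(1,))], trail)
        assert any("max_errors" in s for s in trail)
        assert any("bitmask" in s for s in trail)


class TestLOOEvaluate:
    def test_wide_margin_separation_classifies_perfectly(self):
        # single predictor with a wide class margin: every fold's fit puts
        # the held-out row on the right side
        x = np.concatenate([np.linspace(-3, -2, 10), np.linspace(2, 3, 10)])
        y = (x > 0).astype(int)
        result = loo_evaluate(x[:, None], y, n_components=1)
        assert (result.fp, result.fn) == (0, 0)

    def test_single_class_outcome_rejected(self, rng):
        X = rng.normal(size=(12, 2))
        with pytest.raises(ValidationError):
            loo_evaluate(X, np.ones(12), n_components=1)

    def test_counts_match_scripted_loo_loop(self, rng):
        X = rng.normal(size=(30, 3))
        beta = np.array([1.0, -0.5, 0.0])
        y = (rng.random(30) < 1 / (1 + np.exp(-X @ beta))).astype(int)
        result = loo_evaluate(X, y, subset=(0, 1), n_components=1)
        # independent scripted loop: delete, refit, predict, tally
        mistakes_fp = mistakes_fn = 0
        for i in range(30):
            model = fit_pls_glr(np.delete(X[:, :2], i, axis=0),
                                np.delete(y, i), 1)
            pred = classify(float(predict_proba(model, X[i, :2])[0]))
            mistakes_fp += int(pred == 1 and y[i] == 0)
            mistakes_fn += int(pred == 0 and y[i] == 1)
        assert (result.fp, result.fn) == (mistakes_fp, mistakes_fn)

    def test_row_permutation_leaves_evaluation_unchanged(self, rng, small_cohort):
        X = small_cohort.abilities.values
        y = small_cohort.success.values
        base = loo_evaluate(X, y, subset=(0, 1), n_components=1)
        perm = rng.permutation(len(y))
        shuffled = loo_evaluate(X[perm], y[perm], subset=(0, 1), n_components=1)
        assert (base.fp, base.fn) == (shuffled.fp, shuffled.fn)

    def test_two_component_evaluation_matches_scripted_loop(self, rng):
        X = rng.normal(size=(25, 3))
        y = (rng.random(25) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        result = loo_evaluate(X, y, n_components=2)
        errors = 0
        for i in range(25):
            model = fit_pls_glr(np.delete(X, i, axis=0), np.delete(y, i), 2)
            errors += int(classify(float(predict_proba(model, X[i])[0])) != y[i])
        assert result.total_errors == errors


class TestSelectNComponents:
    def test_single_latent_component_cohort_selects_h1(self):
        # all abilities load on one dominant common factor (rho = 0.8) that
        # drives the outcome: a single component suffices and extra
        # components only model noise
        cohort = generate(SyntheticConfig(
            n_participants=200, n_predictors=5, active_set=(0, 1, 2, 3, 4),
            effect_vector=(0.8,) * 5, predictor_correlation=0.8, seed=30))
        result = select_n_components(cohort.abilities, cohort.success, 3)
        assert result.selected_n_components == 1
        assert len(result.evaluations) == 3

    def test_h_max_one_is_identity(self, small_cohort):
        result = select_n_components(small_cohort.abilities,
                                     small_cohort.success, 1)
        assert result.selected_n_components == 1


class TestExhaustiveSearch:
    def test_enumeration_count_for_four_predictors(self, rng):
        X = rng.normal(size=(40, 4))
        y = (rng.random(40) < 1 / (1 + np.exp(-X[:, 0] * 2))).astype(int)
        result = exhaustive_subset_search(X, y, 1)
        assert len(result.evaluations) == 15

    def test_cap_refusal_mentions_override(self, rng):
        X = rng.normal(size=(30, 6))
        y = (rng.random(30) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        with pytest.raises(ValidationError, match="enumeration_cap"):
            exhaustive_subset_search(X, y, 1, enumeration_cap=5)

    def test_selection_attains_global_minimum(self, rng):
        X = rng.normal(size=(40, 5))
        y = (rng.random(40) < 1 / (1 + np.exp(-X @ np.array(
            [1.5, -1.0, 0.0, 0.0, 0.5])))).astype(int)
        result = exhaustive_subset_search(X, y, 1)
        assert result.selected.max_errors == min(
            e.max_errors for e in result.evaluations)
        assert result.selected == brute_force_select(result.evaluations)

    def test_informative_predictors_recovered(self):
        cohort = generate(SyntheticConfig(
            n_participants=150, n_predictors=8, active_set=(0, 3, 6),
            effect_vector=(1.2, -1.0, 0.9), predictor_correlation=0.2,
            target_success_rate=63 / 113, seed=42))
        result = exhaustive_subset_search(cohort.abilities, cohort.success, 1)
        assert {0, 3, 6} <= set(result.selected.subset)

    def test_duplicated_predictor_tie_broken_deterministically(self, rng):
        x = rng.normal(size=40)
        y = (rng.random(40) < 1 / (1 + np.exp(-2 * x))).astype(int)
        X = np.column_stack([x, x.copy()])  # two clones
        result = exhaustive_subset_search(X, y, 1)
        single = [e for e in result.evaluations if len(e.subset) == 1]
        assert single[0].fp == single[1].fp and single[0].fn == single[1].fn
        # clone ties resolve to the lowest bitmask among smallest subsets
        best = min(e.max_errors for e in result.evaluations)
        if result.selected.max_errors == best and len(result.selected.subset) == 1:
            assert result.selected.subset == (0,)

    def test_parallel_execution_is_bit_identical(self, rng):
        X = rng.normal(size=(30, 4))
        y = (rng.random(30) < 1 / (1 + np.exp(-X[:, 1]))).astype(int)
        serial = exhaustive_subset_search(X, y, 1, n_jobs=1)
        threaded = exhaustive_subset_search(X, y, 1, n_jobs=2)
        assert serial.evaluations == threaded.evaluations
        assert serial.selected == threaded.selected


def test_vectorized_path_matches_naive_loop(rng):
    from takeoverpls.selection import (_FoldCache, _loo_generic,
                                       _loo_h1_vectorized)

    X = rng.normal(size=(40, 4))
    y = (rng.random(40) < 1 / (1 + np.exp(-X @ np.array(
        [0.8, -0.6, 0.3, 0.0])))).astype(int)
    cache = _FoldCache(X, y)
    for cols in [(0,), (1, 2), (0, 1, 2, 3)]:
        batch = _loo_h1_vectorized(cache, cols)
        assert batch is not None
        np.testing.assert_array_equal(batch, _loo_generic(X, y, cols, 1))


def test_search_table_is_ranked_and_named(rng):
    X = rng.normal(size=(30, 3))
    y = (rng.random(30) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
    result = exhaustive_subset_search(X, y, 1)
    table = search_table(result, names=("a", "b", "c"))
    assert list(table.columns) == ["bitmask", "members", "n_components",
                                   "fp", "fn", "max_errors", "total_errors"]
    assert table["max_errors"].is_monotonic_increasing or (
        table["max_errors"].iloc[0] == table["max_errors"].min())
    assert table.iloc[0]["max_errors"] == result.selected.max_errors
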