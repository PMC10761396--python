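"""Consensus calling and model performance metrics."""

import pytest
from hypothesis import given, settings, strategies as st

from edscreen.calls import ActivityCall, flip_call, round_half_up
from edscreen.consensus import (
    compute_efficiency,
    compute_pct_correct,
    derive_final_insilico_call,
    summarize_performance,
)

from conftest import make_matrix, make_reference

P = ActivityCall.POSITIVE
W = ActivityCall.WEAK_POSITIVE
N = ActivityCall.NEGATIVE
I = ActivityCall.INCONCLUSIVE
O = ActivityCall.OUT_OF_DOMAIN


# ------------------------------------------------------------------ oracle

def oracle_metrics(model_calls, ref_calls, oad_policy="exclude", denominator="included"):
    """Brute-force per-model metric counter, independent of the library
    implementation: plain list iteration against the documented rules."""
    pos = (P, W)
    included = [
        (m, r) for m, r in zip(model_calls, ref_calls)
        if denominator == "panel" or r in (P, N)
    ]
    n_inc = len(included)
    distinct = [(m, r) for m, r in included if m in pos or m is N]
    n_oad = sum(1 for m, _ in included if m is O)
    correct = sum(
        1 for m, r in distinct if (m in pos) == (r in pos)
    )
    eff = round_half_up(100 * len(distinct) / n_inc) if n_inc else None
    denom = len(distinct) + (n_oad if oad_policy == "count_as_incorrect" else 0)
    pct = round_half_up(100 * correct / denom) if denom else None
    return eff, pct, n_inc, len(distinct), correct


call_strategy = st.sampled_from([P, W, N, I, O, ActivityCall.NOT_EVALUATED])
ref_strategy = st.sampled_from([P, N, I])


class TestMetricsAgainstOracle:
    @given(
        data=st.lists(st.tuples(call_strategy, ref_strategy), min_size=1, max_size=4),
        oad_policy=st.sampled_from(["exclude", "count_as_incorrect"]),
    )
    @settings(max_examples=400, deadline=None)
    def test_single_model_matches_brute_force(self, data, oad_policy):
        model_calls = [m for m, _ in data]
        ref_calls = [r for _, r in data]
        matrix = make_matrix({"m": model_calls})
        ref = make_reference(ref_calls)
        eff, pct, n_inc, n_dist, n_corr = oracle_metrics(model_calls, ref_calls, oad_policy)
        if n_inc == 0:
            with pytest.raises(ValueError):
                compute_efficiency("m", matrix, ref)
            return
        assert compute_efficiency("m", matrix, ref) == eff
        perf = compute_pct_correct("m", matrix, ref, oad_policy=oad_policy)
        assert perf.pct_correct == pct
        assert perf.pct_efficiency == eff
        assert (perf.n_included, perf.n_distinct, perf.n_correct) == (n_inc, n_dist, n_corr)

    @given(
        grid=st.lists(
            st.tuples(call_strategy, call_strategy, call_strategy),
            min_size=1, max_size=4,
        ),
        refs=st.lists(ref_strategy, min_size=4, max_size=4),
    )
    @settings(max_examples=150, deadline=None)
    def test_multi_model_matrices_match_brute_force(self, grid, refs):
        refs = refs[: len(grid)]
        cols = {f"m{j}": [row[j] for row in grid] for j in range(3)}
        matrix = make_matrix(cols)
        ref = make_reference(refs)
        for j in range(3):
            eff, pct, *_ = oracle_metrics(cols[f"m{j}"], refs)
            if all(r is I for r in refs):
                continue
            assert compute_pct_correct(f"m{j}", matrix, ref).pct_correct == pct
            assert compute_efficiency(f"m{j}", matrix, ref) == eff


class TestMetricProperties:
    @given(data=st.lists(st.tuples(call_strategy, ref_strategy), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_label_flip_symmetry(self, data):
        """Inverting every positive<->negative in both matrix and reference
        leaves efficiency and %-correct unchanged."""
        model_calls = [m for m, _ in data]
        ref_calls = [r for _, r in data]
        if not any(r in (P, N) for r in ref_calls):
            return
        base = compute_pct_correct("m", make_matrix({"m": model_calls}),
                                   make_reference(ref_calls))
        flipped = compute_pct_correct(
            "m",
            make_matrix({"m": [flip_call(c) for c in model_calls]}),
            make_reference([flip_call(c) for c in ref_calls]),
        )
        assert base.pct_correct == flipped.pct_correct
        assert base.pct_efficiency == flipped.pct_efficiency

    @given(data=st.lists(st.tuples(call_strategy, ref_strategy), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_oad_as_incorrect_never_scores_higher(self, data):
        model_calls = [m for m, _ in data]
        ref_calls = [r for _, r in data]
        if not any(r in (P, N) for r in ref_calls):
            return
        matrix, ref = make_matrix({"m": model_calls}), make_reference(ref_calls)
        strict = compute_pct_correct("m", matrix, ref, oad_policy="count_as_incorrect")
        lax = compute_pct_correct("m", matrix, ref, oad_policy="exclude")
        if strict.pct_correct is not None and lax.pct_correct is not None:
            assert strict.pct_correct <= lax.pct_correct

    def test_full_efficiency_iff_every_included_call_distinct(self):
        ref = make_reference([P, N, I, P])
        full = make_matrix({"m": [P, N, I, N]})  # the inconclusive chemical is excluded
        assert compute_efficiency("m", full, ref) == 100
        partial = make_matrix({"m": [P, I, I, N]})
        assert compute_efficiency("m", partial, ref) < 100

    def test_undefined_pct_correct_never_coerced(self):
        ref = make_reference([P, N])
        perf = compute_pct_correct("m", make_matrix({"m": [I, O]}), ref)
        assert perf.pct_correct is None
        assert perf.pct_efficiency == 0


class TestFinalCall:
    def test_majority_positive_with_linked_roles_is_high_confidence(self):
        matrix = make_matrix(
            {"b": [P], "a": [P], "n": [N]},
            roles={"b": "binding", "a": "activation", "n": "binding"},
        )
        fc = derive_final_insilico_call("c0", "ER", matrix)
        assert fc.call is P and fc.high_confidence

    def test_majority_positive_single_role_family_is_not_high_confidence(self):
        matrix = make_matrix(
            {"b1": [P], "b2": [P], "n": [N]},
            roles={"b1": "binding", "b2": "binding", "n": "antagonist"},
        )
        fc = derive_final_insilico_call("c0", "ER", matrix)
        assert fc.call is P and not fc.high_confidence

    def test_unanimous_negative(self):
        matrix = make_matrix({"a": [N], "b": [N]})
        fc = derive_final_insilico_call("c0", "ER", matrix)
        assert fc.call is N and not fc.high_confidence

    def test_exact_tie_is_inconclusive(self):
        matrix = make_matrix({"a": [P], "b": [P], "c": [N], "d": [N], "e": [I]})
        assert derive_final_insilico_call("c0", "ER", matrix).call is I

    def test_no_models_for_target_is_not_evaluated(self):
        matrix = make_matrix({"a": [P]})
        assert (
            derive_final_insilico_call("c0", "AR", matrix).call
            is ActivityCall.NOT_EVALUATED
        )

    def test_weak_positive_votes_as_positive(self):
        matrix = make_matrix({"a": [W], "b": [W], "c": [N]})
        assert derive_final_insilico_call("c0", "ER", matrix).call is P

    @given(calls=st.lists(call_strategy, min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_adding_inconclusive_model_never_changes_outcome(self, calls):
        base = make_matrix({f"m{i}": [c] for i, c in enumerate(calls)})
        extended = make_matrix({f"m{i}": [c] for i, c in enumerate(calls + [I])})
        assert (
            derive_final_insilico_call("c0", "ER", base).call
            is derive_final_insilico_call("c0", "ER", extended).call
        )
        # and never increases any model's efficiency: the new column has 0
        ref = make_reference([P])
        assert compute_efficiency(f"m{len(calls)}", extended, ref) == 0


class TestSummary:
    def test_single_row_summary_is_that_row(self):
        perf = compute_pct_correct("m", make_matrix({"m": [P, N]}), make_reference([P, N]))
        summary = summarize_performance([perf])
        ts = summary.per_target["ER"]
        assert ts.mean_pct_correct == ts.min_pct_correct == perf.pct_correct
        assert ts.n_models == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_performance([])
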