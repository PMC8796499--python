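import numpy as np
import pandas as pd
import pytest

from detanon import (
    AnonymisationConfig,
    MicrodataTable,
    SmallStratumError,
    anonymise,
    centroid_replace,
    check_k_anonymity,
    enforce_k_anonymity,
    impute,
    knn_neighbour_sets,
    rescale_recentre,
    stratify,
    zscore_standardise,
)
from detanon.anonymiser import StandardisationParams

from helpers import knn_oracle


def _table(cont=None, cat=None):
    data = {}
    roles = {}
    for name, vals in (cont or {}).items():
        data[name] = vals
        roles[name] = "continuous"
    for name, vals in (cat or {}).items():
        data[name] = vals
        roles[name] = "categorical"
    return MicrodataTable(pd.DataFrame(data), roles)


# ---------------------------------------------------------------------- impute

def test_median_imputation_fills_with_median_of_observed():
    t = _table(cont={"x": [1.0, np.nan, 3.0]})
    out = impute(t, AnonymisationConfig(continuous_imputation="median"))
    assert list(out.data["x"]) == [1.0, 2.0, 3.0]


def test_mean_imputation_and_categorical_extra_level():
    t = _table(cont={"x": [1.0, np.nan, 5.0]}, cat={"g": ["a", None, "b"]})
    out = impute(t, AnonymisationConfig(continuous_imputation="mean"))
    assert list(out.data["x"]) == [1.0, 3.0, 5.0]
    assert out.data["g"][1] == "(missing)"


def test_complete_case_drops_rows_with_any_missing_cell():
    t = _table(cont={"x": [1.0, np.nan, 5.0]}, cat={"g": ["a", "b", None]})
    cfg = AnonymisationConfig(continuous_imputation="complete_case",
                              categorical_imputation="complete_case")
    assert impute(t, cfg).n == 1


def test_table_without_missing_cells_is_returned_unchanged(small_table):
    out = impute(small_table, AnonymisationConfig())
    pd.testing.assert_frame_equal(out.data, small_table.data)


def test_entirely_missing_continuous_column_is_an_error():
    t = _table(cont={"x": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="entirely missing"):
        impute(t, AnonymisationConfig())


# --------------------------------------------------------------- standardise

def test_zscore_on_symmetric_triple():
    t = _table(cont={"x": [1.0, 2.0, 3.0]})
    out, params = zscore_standardise(t)
    assert list(out.data["x"]) == [-1.0, 0.0, 1.0]
    assert params.mu["x"] == 2.0 and params.s["x"] == 1.0


def test_zscore_is_idempotent_on_standardised_column():
    t = _table(cont={"x": [-1.0, 0.0, 1.0]})
    out, _ = zscore_standardise(t)
    assert np.allclose(out.data["x"], [-1.0, 0.0, 1.0])


def test_zscore_matches_straight_line_oracle():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(50, 3)) * [2.0, 5.0, 0.1] + [1.0, -3.0, 100.0]
    t = _table(cont={f"c{j}": x[:, j] for j in range(3)})
    out, params = zscore_standardise(t)
    for j in range(3):
        col = x[:, j]
        expected = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(out.data[f"c{j}"], expected, atol=1e-12)
        assert np.isclose(params.s[f"c{j}"], col.std(ddof=1))


def test_zero_variance_column_is_rejected_by_name():
    t = _table(cont={"flat": [2.0, 2.0, 2.0], "x": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="flat"):
        zscore_standardise(t)


# ----------------------------------------------------------------- stratify

def test_all_observed_level_combinations_form_the_strata():
    # 2 x 2 x 4 levels, all combinations observed -> 16 strata
    levels = [(a, b, c) for a in "xy" for b in "pq" for c in "1234"]
    rows = levels * 2
    t = _table(
        cont={"v": np.arange(len(rows), dtype=float)},
        cat={"A": [r[0] for r in rows], "B": [r[1] for r in rows],
             "C": [r[2] for r in rows]},
    )
    part = stratify(t, None)
    assert part.n_strata == 16
    idx = np.sort(np.concatenate(list(part.groups.values())))
    assert np.array_equal(idx, np.arange(t.n))  # disjoint cover


def test_unobserved_combinations_are_not_materialised():
    t = _table(cont={"v": [0.0, 1.0, 2.0]}, cat={"A": ["x", "x", "y"], "B": ["p", "p", "q"]})
    part = stratify(t, None)
    assert set(part.groups) == {("x", "p"), ("y", "q")}


def test_no_categorical_columns_gives_a_single_stratum():
    t = _table(cont={"v": [0.0, 1.0, 2.0]})
    part = stratify(t, None)
    assert part.n_strata == 1 and len(part.groups[()]) == 3


def test_stratifying_on_non_categorical_column_is_an_error(small_table):
    with pytest.raises(ValueError, match="x"):
        stratify(small_table, ["x"])


# ------------------------------------------------------------- k-anonymity

def test_k_anonymity_check_lists_violators_with_sizes():
    t = _table(cont={"v": np.arange(7.0)}, cat={"g": list("aaaaabb")})
    part = stratify(t, None)
    ok, violators = check_k_anonymity(part, 3)
    assert not ok and violators == [(("b",), 2)]
    ok, violators = check_k_anonymity(part, 1)  # strata are never empty
    assert ok and violators == []


def test_suppression_removes_violating_strata():
    t = _table(cont={"v": np.arange(7.0)}, cat={"g": list("aaaaabb")})
    part = stratify(t, None)
    repaired, new_part, dropped = enforce_k_anonymity(t, part, 3, "suppress")
    assert repaired.n == 5 and new_part.n_strata == 1
    assert list(dropped) == [5, 6]


def test_k_anonymous_input_is_a_no_op():
    t = _table(cont={"v": np.arange(7.0)}, cat={"g": list("aaaaabb")})
    part = stratify(t, None)
    repaired, new_part, dropped = enforce_k_anonymity(t, part, 2, "error")
    assert repaired is t and new_part is part and dropped.size == 0


def test_merge_map_can_repair_two_small_strata():
    t = _table(cont={"v": np.arange(9.0)}, cat={"g": list("aaaaabbcc")})
    part = stratify(t, None)
    repaired, new_part, _ = enforce_k_anonymity(
        t, part, 3, "merge_map", {"g": {"b": "bc", "c": "bc"}}
    )
    ok, _ = check_k_anonymity(new_part, 3)
    assert ok and set(new_part.groups) == {("a",), ("bc",)}


def test_error_policy_raises_and_insufficient_merge_raises():
    t = _table(cont={"v": np.arange(7.0)}, cat={"g": list("aaaaabb")})
    part = stratify(t, None)
    with pytest.raises(SmallStratumError):
        enforce_k_anonymity(t, part, 3, "error")
    with pytest.raises(SmallStratumError, match="still leaves"):
        enforce_k_anonymity(t, part, 3, "merge_map", {"g": {"b": "b2"}})


# ------------------------------------------------------------------- k-NN

def test_neighbour_sets_match_hand_worked_1d_example():
    pts = np.array([0.0, 1.0, 3.0, 7.0]).reshape(-1, 1)
    sets = knn_neighbour_sets(pts, 2)
    assert [list(s) for s in sets] == [[0, 1], [0, 1], [1, 2], [2, 3]]


def test_k1_sets_are_singletons_and_k_equals_n_is_whole_stratum():
    pts = np.arange(5.0).reshape(-1, 1)
    assert [list(s) for s in knn_neighbour_sets(pts, 1)] == [[i] for i in range(5)]
    assert all(list(s) == [0, 1, 2, 3, 4] for s in knn_neighbour_sets(pts, 5))


def test_equidistant_ties_break_by_ascending_row_index():
    pts = np.array([[0.0], [1.0], [-1.0], [1.0]])  # rows 1, 2, 3 all at distance 1
    sets = knn_neighbour_sets(pts, 2)
    assert list(sets[0]) == [0, 1]
    # duplicates: row 3 ties with row 1 at distance 0 of each other
    assert list(sets[3]) == [1, 3]  # self always included, then lowest index


def test_stratum_smaller_than_k_is_an_error():
    with pytest.raises(ValueError, match="smaller than k"):
        knn_neighbour_sets(np.zeros((2, 1)), 3)


@pytest.mark.parametrize("seed", range(10))
def test_neighbour_sets_agree_with_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 30))
    p = int(rng.integers(1, 4))
    # integer lattice points force plenty of exact distance ties
    pts = rng.integers(0, 4, size=(n, p)).astype(float)
    k = int(rng.integers(1, n + 1))
    got = [list(s) for s in knn_neighbour_sets(pts, k)]
    assert got == knn_oracle(pts, k)


# ---------------------------------------------------------------- centroids

def test_centroid_replacement_hand_example():
    pts = np.array([0.0, 1.0, 3.0, 7.0]).reshape(-1, 1)
    sets = knn_neighbour_sets(pts, 2)
    out = centroid_replace(pts, sets)
    assert np.allclose(out.ravel(), [0.5, 0.5, 2.0, 5.0])


def test_centroids_with_k1_or_identical_points_change_nothing():
    pts = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert np.array_equal(centroid_replace(pts, [np.array([0]), np.array([1])]), pts)
    same = np.ones((4, 2))
    sets = knn_neighbour_sets(same, 3)
    assert np.array_equal(centroid_replace(same, sets), same)


# ------------------------------------------------------------------ rescale

def test_rescaling_inverts_the_zscore_and_undoes_uniform_shrink():
    rng = np.random.default_rng(3)
    x = rng.normal(5, 3, 30)
    t = _table(cont={"x": x})
    z, params = zscore_standardise(t)
    out = rescale_recentre(z.continuous, params)
    assert np.allclose(out["x"], x, atol=1e-10)
    out = rescale_recentre(0.5 * z.continuous, params)
    assert np.allclose(out["x"], x, atol=1e-10)


def test_rescaled_column_reproduces_original_sd_exactly():
    rng = np.random.default_rng(4)
    params = StandardisationParams(
        mu=pd.Series({"x": 7.0}), s=pd.Series({"x": 2.5})
    )
    masked = pd.DataFrame({"x": rng.normal(0, 0.3, 50)})
    out = rescale_recentre(masked, params)
    assert np.isclose(out["x"].std(ddof=1), 2.5, rtol=1e-12)


def test_constant_masked_column_asks_for_a_smaller_k():
    params = StandardisationParams(mu=pd.Series({"x": 0.0}), s=pd.Series({"x": 1.0}))
    with pytest.raises(ValueError, match="smaller k"):
        rescale_recentre(pd.DataFrame({"x": [0.2, 0.2, 0.2]}), params)


# ------------------------------------------------------------- the pipeline

def test_k1_pipeline_is_the_identity(small_table):
    res = anonymise(small_table, AnonymisationConfig(k=1))
    assert np.allclose(res.anonymised.continuous, small_table.continuous, atol=1e-10)
    pd.testing.assert_frame_equal(res.anonymised.categorical, small_table.categorical)


def test_pipeline_is_deterministic_and_preserves_sd(small_table):
    cfg = AnonymisationConfig(k=5)
    a = anonymise(small_table, cfg).anonymised
    b = anonymise(small_table, cfg).anonymised
    pd.testing.assert_frame_equal(a.data, b.data)  # bit-identical rerun
    for c in small_table.continuous_columns:
        sd0 = small_table.data[c].std(ddof=1)
        assert abs(a.data[c].std(ddof=1) - sd0) / sd0 <= 1e-9


def test_categoricals_row_count_and_row_order_are_untouched(cohort500):
    res = anonymise(cohort500, AnonymisationConfig(k=7))
    assert res.anonymised.n == cohort500.n
    pd.testing.assert_frame_equal(res.anonymised.categorical, cohort500.categorical)
    assert (res.anonymised.continuous.to_numpy()
            != cohort500.continuous.to_numpy()).any()


def test_each_masked_row_is_the_mean_of_k_standardised_neighbours(cohort500):
    """Provenance: pre-scaling values are centroids of same-stratum rows."""
    k = 4
    res = anonymise(cohort500, AnonymisationConfig(k=k))
    z = ((cohort500.continuous - res.params.mu) / res.params.s).to_numpy()
    stratum_of = {}
    for key, rows in res.partition.groups.items():
        for r in rows:
            stratum_of[r] = key
    # rebuild the masked matrix from the stored neighbour sets alone ...
    masked = np.vstack([z[res.neighbour_sets[i]].mean(axis=0)
                        for i in range(cohort500.n)])
    for i in range(cohort500.n):
        ns = res.neighbour_sets[i]
        assert len(ns) == k and i in ns
        assert all(stratum_of[j] == stratum_of[i] for j in ns)
    # ... and push it through step 5: it must reproduce the output exactly
    sd_masked = masked.std(axis=0, ddof=1)
    expected = masked * (res.params.s.to_numpy() / sd_masked) + res.params.mu.to_numpy()
    assert np.allclose(res.anonymised.continuous.to_numpy(), expected, atol=1e-8)


def test_suppression_inside_pipeline_keeps_guarantees():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "x": rng.normal(size=23),
        "g": ["a"] * 10 + ["b"] * 10 + ["c"] * 3,
    })
    t = MicrodataTable(df, {"x": "continuous", "g": "categorical"})
    res = anonymise(t, AnonymisationConfig(k=5, small_stratum_policy="suppress"))
    assert res.anonymised.n == 20
    assert list(res.suppressed_rows) == [20, 21, 22]
    kept = t.data["x"][:20]
    sd0 = kept.std(ddof=1)
    assert abs(res.anonymised.data["x"].std(ddof=1) - sd0) / sd0 <= 1e-9


def test_k46_on_smallest_stratum_collapses_it_to_one_centroid(cohort500):
    sizes = {k: len(v) for k, v in
             anonymise(cohort500, AnonymisationConfig(k=3)).partition.groups.items()}
    smallest_key, smallest = min(sizes.items(), key=lambda kv: kv[1])
    res = anonymise(cohort500, AnonymisationConfig(k=smallest))
    rows = res.partition.groups[smallest_key]
    block = res.anonymised.continuous.to_numpy()[rows]
    assert np.allclose(block, block[0], atol=1e-12)  # all replaced by one centroid
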