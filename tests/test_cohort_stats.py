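import itertools

import numpy as np
import pandas as pd
import pytest

from manodrift.cohort_stats import (
    DIAGNOSIS_GROUPS,
    TABLE8_PUBLISHED,
    TABLE8_STRATUM_SIZES,
    build_flip_table,
    chisq_homogeneity,
    compact_letters,
    compare_conditions,
    kruskal_wallis,
    mann_whitney,
    normality_gate,
)
from manodrift.synthetic_cohort import CohortSpec, DriftModel, simulate_cohort


# ------------------------------------------------------------- rank tests


def test_kruskal_wallis_identical_groups():
    assert kruskal_wallis([[5, 5, 5]] * 5) == (0.0, 1.0)


def test_kruskal_wallis_hand_ranked_value():
    # ranks 1..9 across three separated groups: H = 12/(9*10) * (36+225+576)/3 - 30
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert h == pytest.approx(7.2)
    assert 0 < p < 0.05


def _kw_oracle(groups):
    """Rank-sum brute force with tie correction."""
    flat = np.concatenate(groups)
    order = flat.argsort(kind="mergesort")
    ranks = np.empty_like(flat, dtype=float)
    # mid-ranks for ties
    sorted_vals = flat[order]
    i = 0
    while i < len(flat):
        j = i
        while j < len(flat) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    n = len(flat)
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum() / (n**3 - n))
    return h / tie


@pytest.mark.parametrize("seed", range(20))
def test_kruskal_wallis_matches_brute_force_with_ties(seed):
    rng = np.random.default_rng(seed)
    groups = [list(rng.integers(0, 6, size=rng.integers(3, 9))) for _ in range(3)]
    if len(np.unique(np.concatenate(groups))) == 1:
        pytest.skip("degenerate draw")
    h, _ = kruskal_wallis(groups)
    assert h == pytest.approx(_kw_oracle(groups), abs=1e-10)


def test_mann_whitney_identical_samples_p_near_one():
    _, p = mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert p > 0.95


def test_mann_whitney_fully_separated_u_zero():
    u, p = mann_whitney(list(range(1, 11)), list(range(11, 21)))
    assert u == 0.0
    assert p < 0.001


@pytest.mark.parametrize("seed", range(25))
def test_mann_whitney_u_matches_pair_counting(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 10, size=rng.integers(2, 9))
    b = rng.integers(0, 10, size=rng.integers(2, 9))
    u, _ = mann_whitney(a, b)
    oracle = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    assert u == pytest.approx(oracle)


def test_two_group_kruskal_consistent_with_mann_whitney():
    """With two groups the tests are monotonically related: their p-values
    rank the same draws identically (both are rank-sum statistics)."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(1)
    p_kw_all, p_mw_all = [], []
    for _ in range(50):
        a = rng.normal(size=6)
        b = rng.normal(loc=rng.uniform(0, 2), size=7)
        p_kw_all.append(kruskal_wallis([a, b])[1])
        p_mw_all.append(mann_whitney(a, b)[1])
    rho, _ = spearmanr(p_kw_all, p_mw_all)
    assert rho > 0.999  # strictly monotone relation between the two tests


# ------------------------------------------------------------- chi-square


def test_chisq_identical_columns_is_zero():
    chi2, p, r = chisq_homogeneity([[10, 10], [5, 5], [8, 8]])
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert np.allclose(r, 0.0)


def test_chisq_2x2_closed_form_residuals():
    O = np.array([[33, 91], [14, 110]], dtype=float)
    chi2, p, r = chisq_homogeneity(O)
    row, col, n = O.sum(1), O.sum(0), O.sum()
    E = np.outer(row, col) / n
    assert chi2 == pytest.approx(((O - E) ** 2 / E).sum())
    expected_r = (O - E) / np.sqrt(E * (1 - row[:, None] / n) * (1 - col[None, :] / n))
    np.testing.assert_allclose(r, expected_r)
    assert r[0, 0] > 0 > r[1, 0]  # opposite signs within the diagnosis column


def test_chisq_matches_textbook_formula_on_random_table():
    rng = np.random.default_rng(7)
    O = rng.integers(1, 30, size=(3, 4)).astype(float)
    chi2, _, _ = chisq_homogeneity(O)
    E = np.outer(O.sum(1), O.sum(0)) / O.sum()
    assert chi2 == pytest.approx(((O - E) ** 2 / E).sum())


def test_chisq_zero_marginal_raises():
    with pytest.raises(ValueError):
        chisq_homogeneity([[0, 0], [3, 4]])


# ------------------------------------------------------- gate and letters


def test_normality_gate_takes_nonparametric_path_for_heavy_tails():
    rng = np.random.default_rng(0)
    assert not normality_gate(rng.standard_cauchy(200))
    assert normality_gate(rng.normal(size=200))


def test_compact_letters_separates_significant_pairs():
    p = {("a", "b"): 0.001, ("a", "c"): 0.2, ("b", "c"): 0.3}
    letters = compact_letters(["a", "b", "c"], [1.0, 3.0, 2.0], p)
    assert set(letters["a"]).isdisjoint(set(letters["b"]))
    assert set(letters["c"]) & (set(letters["a"]) | set(letters["b"]))
    for v in letters.values():
        assert v  # every group carries at least one letter


def test_compact_letters_all_equal_share_one_letter():
    p = {pair: 0.9 for pair in itertools.combinations("abcde", 2)}
    letters = compact_letters(list("abcde"), [1, 2, 3, 4, 5], p)
    assert len({v for v in letters.values()}) == 1


# ------------------------------------------------------------- flip table


def _per_study_frame(rows):
    return pd.DataFrame(rows, columns=["study_id", "condition", "label", "median_irp"])


def test_single_study_stays_in_its_stratum():
    rows = [("s1", c, "NEM", 9.0) for c in ("ftc", "nontc", "tc1")]
    ft = build_flip_table(_per_study_frame(rows))
    col = ("IRP <= 15", "NEM")
    assert all(ft.cross_tab.loc[c, col] == 1 for c in ("ftc", "nontc", "tc1"))
    assert ft.flips.irp_flips_up.sum() == 0 and ft.flips.irp_flips_down.sum() == 0


def test_stratum_sums_invariant_across_conditions():
    rng = np.random.default_rng(3)
    labels = ["NEM", "IEM", "EGJ_OO", "T2A", "AC"]
    rows = []
    base_irp = {f"s{i}": rng.uniform(5, 25) for i in range(12)}
    for c in ("ftc", "nontc", "tc1"):
        for sid, irp0 in base_irp.items():
            rows.append((sid, c, labels[rng.integers(len(labels))], irp0 + rng.normal(0, 3)))
    ft = build_flip_table(_per_study_frame(rows))
    sums = ft.cross_tab.T.groupby(level="stratum").sum().T
    for c in ("nontc", "tc1"):
        assert (sums.loc[c] == sums.loc["ftc"]).all()


def test_mismatched_study_sets_rejected():
    rows = [("s1", "ftc", "NEM", 9.0), ("s2", "nontc", "NEM", 9.0)]
    with pytest.raises(ValueError):
        build_flip_table(_per_study_frame(rows))


# -------------------------------------------- published-table fixture sums


def test_published_cross_tab_stratum_sizes_and_totals():
    t8 = TABLE8_PUBLISHED
    for stratum, size in TABLE8_STRATUM_SIZES.items():
        sums = t8[stratum].sum(axis=1)
        assert (sums == size).all(), stratum
    assert int(t8.sum(axis=1).iloc[0]) == 124
    assert (t8.sum(axis=1) == 124).all()


def test_published_reference_row_has_no_cross_stratum_leakage():
    t8 = TABLE8_PUBLISHED
    # under the reference condition, the normal stratum holds no elevated-IRP
    # diagnoses (EGJ-OO/achalasia) and vice versa
    assert t8.loc["ftc", ("IRP <= 15", "EGJ-OO")] == 0
    assert t8.loc["ftc", ("IRP <= 15", "Achalasia")] == 0
    assert t8.loc["ftc", ("IRP > 15", "NEM")] == 0


# ------------------------------------------------------ integrated compare


@pytest.fixture(scope="module")
def driftfree_comparison():
    spec = CohortSpec(
        n_per_archetype={"nem": 3, "iem": 2, "egjoo": 2}, seed=11, drift=DriftModel.none()
    )
    studies, _ = simulate_cohort(spec)
    return compare_conditions(studies)


def test_drift_free_cohort_identical_across_conditions(driftfree_comparison):
    cmp = driftfree_comparison
    assert (cmp.summaries.nunique(axis=1) == 1).all()
    assert cmp.letters == {}
    assert (cmp.diag_counts.nunique(axis=1) == 1).all()


def test_diagnosis_counts_conserve_cohort_size(driftfree_comparison):
    cmp = driftfree_comparison
    assert (cmp.diag_counts.sum(axis=0) == 7).all()
    sums = cmp.flip_table.cross_tab.T.groupby(level="stratum").sum().T
    assert (sums.sum(axis=1) == 7).all()
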