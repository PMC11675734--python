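"""Unit tests: Wilks' lambda, stepwise selection, canonical analysis."""

import numpy as np
import pytest
from scipy import stats

from selsig import (SdaParams, cda_fit, cda_refit_with_augmentation,
                    hierarchical_sda, mean_impute, sda_select, wilks_lambda)

from conftest import make_dataset


def two_groups(n1, n2):
    return np.array(["u"] * n1 + ["v"] * n2, dtype=object)


# ---------------------------------------------------------------------------
# Wilks' lambda
# ---------------------------------------------------------------------------

def test_wilks_empty_subset_is_one():
    x = np.random.default_rng(0).normal(size=(10, 3))
    assert wilks_lambda(x, two_groups(5, 5), subset=[]) == 1.0


def test_wilks_one_variable_t_identity():
    """For p = 1, two groups: Lambda = 1 / (1 + t^2/(n-2))."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        n1, n2 = rng.integers(4, 15, size=2)
        x = rng.normal(size=n1 + n2)
        x[n1:] += rng.normal() * 0.5
        lam = wilks_lambda(x[:, None], two_groups(n1, n2))
        t = stats.ttest_ind(x[:n1], x[n1:], equal_var=True).statistic
        assert lam == pytest.approx(1 / (1 + t * t / (n1 + n2 - 2)), abs=1e-10)


def test_wilks_invariant_to_within_group_permutation():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(12, 4))
    g = two_groups(6, 6)
    lam = wilks_lambda(x, g, subset=[0, 2])
    perm = np.concatenate([rng.permutation(6), 6 + rng.permutation(6)])
    assert wilks_lambda(x[perm], g, subset=[0, 2]) == pytest.approx(lam, abs=1e-12)


def test_wilks_singular_subset_raises():
    x = np.random.default_rng(3).normal(size=(10, 2))
    xx = np.column_stack([x[:, 0], x[:, 0]])
    with pytest.raises(np.linalg.LinAlgError):
        wilks_lambda(xx, two_groups(5, 5))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def test_perfect_separator_entered_first():
    """The variable with disjoint group supports wins the first entry."""
    rng = np.random.default_rng(4)
    n1 = n2 = 12
    x = rng.normal(size=(n1 + n2, 50))
    x[:n1, 17] = rng.uniform(0, 1, n1)
    x[n1:, 17] = rng.uniform(2, 3, n2)
    g = two_groups(n1, n2)
    # oracle: exhaustive single-variable Wilks' lambda scan
    lams = [wilks_lambda(x, g, subset=[j]) for j in range(50)]
    assert int(np.argmin(lams)) == 17
    res = sda_select(x, g)
    assert res.selected[0] == 17


def test_stepwise_first_pick_matches_exhaustive_scan():
    """Property: first entry = argmin of single-variable lambda, 100 draws."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n1, n2 = rng.integers(5, 12, size=2)
        p = rng.integers(2, 50)
        x = rng.normal(size=(n1 + n2, p))
        g = two_groups(n1, n2)
        lams = [wilks_lambda(x, g, subset=[j]) for j in range(p)]
        res = sda_select(x, g, SdaParams(slentry=1.0, slstay=1.0,
                                         entry_multiplicity="none",
                                         max_selected=1))
        assert res.selected[0] == int(np.argmin(lams))


def test_null_false_entry_rate_bounded():
    """With strict slentry on pure noise the mean selected count is tiny."""
    rng = np.random.default_rng(6)
    total = 0
    reps = 1000
    for _ in range(reps):
        x = rng.normal(size=(20, 10))
        res = sda_select(x, two_groups(10, 10),
                         SdaParams(slentry=1e-6, slstay=1e-6,
                                   entry_multiplicity="none"))
        total += len(res.selected)
    # expected false entries per replicate <= 10 * 1e-6; allow huge slack
    assert total / reps <= 0.01


def test_duplicate_column_never_entered():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(20, 5))
    x[:10, 0] += 3.0  # strong variable
    xx = np.column_stack([x, x[:, 0]])  # column 5 duplicates column 0
    res = sda_select(xx, two_groups(10, 10),
                     SdaParams(slentry=0.5, slstay=0.5,
                               entry_multiplicity="none"))
    assert 0 in res.selected
    assert 5 not in res.selected


def test_lambda_trace_nonincreasing_at_entries():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(30, 40))
    x[:15, :5] += 1.0
    res = sda_select(x, two_groups(15, 15), SdaParams(slentry=0.2, slstay=0.2,
                                                      entry_multiplicity="none"))
    lam_before = 1.0
    for _, ev in res.steps.iterrows():
        if ev["action"] == "enter":
            assert ev["wilks_lambda"] <= lam_before + 1e-12
        lam_before = ev["wilks_lambda"]
    assert len(res.selected) <= 30 - 2 - 2


def test_forced_in_enter_first_and_stay():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(24, 30))
    res = sda_select(x, two_groups(12, 12),
                     SdaParams(forced_in=(4, 9)))
    assert res.selected[:2] == [4, 9]
    assert {4, 9} <= set(res.selected)


# ---------------------------------------------------------------------------
# hierarchical reduction
# ---------------------------------------------------------------------------

def test_hierarchical_single_informative_chromosome(tiny_panel):
    """All final picks lie inside the pass-1 set of their chromosome."""
    ds, truth = tiny_panel
    groups = ds.animals["group"].to_numpy()
    res = hierarchical_sda(ds, groups)
    assert len(res.selected) < ds.n_animals
    # pass-1 containment: every final index appears in the round-1 trace
    r1 = set(res.steps.loc[(res.steps["round"] == 1)
                           & (res.steps["action"] != "remove"), "index"])
    assert set(res.selected) <= r1


def test_hierarchical_recovers_planted_cluster(tiny_panel):
    ds, truth = tiny_panel
    res = hierarchical_sda(ds, ds.animals["group"].to_numpy())
    sel_ids = truth.selected_snp_ids(ds.snps)
    picked = set(ds.snps["snp_id"].iloc[res.selected])
    assert picked & sel_ids


# ---------------------------------------------------------------------------
# canonical discriminant analysis
# ---------------------------------------------------------------------------

def test_cda_p1_collapses_to_t_test():
    rng = np.random.default_rng(10)
    n1, n2 = 9, 13
    x = rng.normal(size=(n1 + n2, 1))
    x[n1:] += 0.8
    g = two_groups(n1, n2)
    res = cda_fit(x, g)
    t, p = stats.ttest_ind(x[:n1, 0], x[n1:, 0], equal_var=True)
    s2 = ((n1 - 1) * x[:n1, 0].var(ddof=1)
          + (n2 - 1) * x[n1:, 0].var(ddof=1)) / (n1 + n2 - 2)
    d2 = (x[:n1, 0].mean() - x[n1:, 0].mean()) ** 2 / s2
    assert res.mahalanobis_d2 == pytest.approx(d2, abs=1e-10)
    assert res.hotelling_t2 == pytest.approx(t * t, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_cda_identical_means_null():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(40, 2))
    x2 = np.vstack([x, x])  # group v duplicates group u exactly
    res = cda_fit(x2, two_groups(40, 40))
    assert res.mahalanobis_d2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0
    assert 0.3 < res.assignment_error < 0.7


def test_cda_hand_worked_p2_example():
    """6 animals x 2 variables, hand matrix computation of D2 and T2."""
    x = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.8],
                  [4.0, 5.0], [5.0, 4.0], [4.3, 4.6]])
    g = two_groups(3, 3)
    m1 = x[:3].mean(axis=0)
    m2 = x[3:].mean(axis=0)
    xc = x.copy()
    xc[:3] -= m1
    xc[3:] -= m2
    w = xc.T @ xc
    s_pooled = w / 4
    d2_hand = (m2 - m1) @ np.linalg.solve(s_pooled, m2 - m1)
    res = cda_fit(x, g)
    assert res.mahalanobis_d2 == pytest.approx(d2_hand, abs=1e-10)
    assert res.hotelling_t2 == pytest.approx(1.5 * d2_hand, abs=1e-10)
    assert res.assignment_error == 0.0
    # scores have unit pooled within-group variance
    sc = res.scores.copy()
    sc[:3] -= sc[:3].mean()
    sc[3:] -= sc[3:].mean()
    assert (sc @ sc) / 4 == pytest.approx(1.0, abs=1e-10)
    # sign convention: second sorted label ('v') positive
    assert res.centroids["v"] > 0


def test_cda_affine_rescaling_invariance():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(30, 4))
    x[:15] += [1, 0, 0.5, 0]
    g = two_groups(15, 15)
    base = cda_fit(x, g)
    x2 = x * np.array([3.0, 0.5, 10.0, 1.0]) + np.array([5, -2, 0, 1])
    scaled = cda_fit(x2, g)
    assert np.allclose(scaled.scores, base.scores, atol=1e-8)
    assert scaled.mahalanobis_d2 == pytest.approx(base.mahalanobis_d2, abs=1e-8)


def test_cda_too_many_variables_raises():
    x = np.random.default_rng(13).normal(size=(10, 9))
    with pytest.raises(ValueError):
        cda_fit(x, two_groups(5, 5))


def test_refit_with_empty_fixed_equals_hierarchical(tiny_panel):
    ds, _ = tiny_panel
    groups = ds.animals["group"].to_numpy()
    sda1 = hierarchical_sda(ds, groups)
    cda1 = cda_fit(mean_impute(ds), groups, variable_idx=sda1.selected)
    sda2, cda2 = cda_refit_with_augmentation(ds, groups, fixed_set=[])
    assert sda2.selected == sda1.selected
    assert cda2.mahalanobis_d2 == pytest.approx(cda1.mahalanobis_d2, abs=1e-12)


def test_refit_augmentation_keeps_fixed_and_improves(tiny_panel):
    ds, truth = tiny_panel
    groups = ds.animals["group"].to_numpy()
    # deliberately weak fixed set: two neutral SNPs
    neutral = np.nonzero(~truth.selected)[0][:2].tolist()
    X = mean_impute(ds)
    before = cda_fit(X, groups, variable_idx=neutral)
    sda, after = cda_refit_with_augmentation(ds, groups, fixed_set=neutral)
    assert sda.selected[:2] == neutral
    assert set(neutral) <= set(after.variable_idx.tolist())
    assert after.assignment_error <= before.assignment_error
    assert after.mahalanobis_d2 >= before.mahalanobis_d2 - 1e-9
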