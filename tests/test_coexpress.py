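"""Co-expression network construction and planted-module recovery."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from proteoconcord.coexpress import (
    AbundanceMatrix,
    adjacency,
    detect_modules,
    eigenprotein,
    pick_soft_threshold,
    tom,
    trait_correlate,
)
from proteoconcord.synthetic import ModuleTruth, gen_expression


def _noise_matrix(n_prot=60, n_samp=30, seed=0):
    rng = np.random.default_rng(seed)
    return AbundanceMatrix(
        rng.standard_normal((n_prot, n_samp)),
        [f"p{i}" for i in range(n_prot)],
        [f"s{j}" for j in range(n_samp)],
    )


# --- adjacency -------------------------------------------------------------


def test_adjacency_arithmetic():
    x = np.linspace(0, 1, 10)
    mat = np.vstack([x, 0.5 * x + 0.4 * np.sin(6 * x)])
    cor = np.corrcoef(mat)[0, 1]
    unsigned = adjacency(mat, beta=4, signed=False)
    assert unsigned[0, 1] == pytest.approx(abs(cor) ** 4)
    assert adjacency(mat, beta=1)[0, 1] == pytest.approx(abs(cor))
    signed = adjacency(mat, beta=4, signed=True)
    assert signed[0, 1] == pytest.approx(((1 + cor) / 2) ** 4)
    # sign-blind: flipping one profile leaves unsigned adjacency unchanged
    flipped = np.vstack([mat[0], -mat[1]])
    assert adjacency(flipped, beta=4)[0, 1] == pytest.approx(unsigned[0, 1])
    assert np.all(np.diag(unsigned) == 1)


# --- TOM -------------------------------------------------------------------


def test_tom_three_node_hand_oracle():
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 1.0)
    t = tom(a)
    # (0.25 + 0.5) / (1 + 1 - 0.5)
    assert t[0, 1] == pytest.approx(0.5)
    assert np.all(np.diag(t) == 1)


def test_tom_no_edges():
    t = tom(np.eye(4))
    assert np.all(t[~np.eye(4, dtype=bool)] == 0)


def test_tom_bounds_and_symmetry_on_random_adjacency():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(3, 25))
        half = rng.uniform(0, 1, (n, n))
        a = (half + half.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom(a)
        assert np.all((t >= 0) & (t <= 1))
        assert np.allclose(t, t.T)


def test_tom_rejects_asymmetric():
    bad = np.array([[1.0, 0.2], [0.5, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        tom(bad)


# --- soft threshold --------------------------------------------------------


def test_soft_threshold_scan_reaches_target_on_most_planted_matrices():
    # frozen from replicate runs: the scan reaches signed R^2 >= 0.8 on a
    # clear majority of 20 planted-module matrices of 200 proteins
    reached = 0
    for seed in range(20):
        m, _, _ = gen_expression(ModuleTruth(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reached += pick_soft_threshold(m).target_reached
    assert reached >= 10


def test_soft_threshold_deterministic_and_warning_path():
    m, _, _ = gen_expression(ModuleTruth(seed=2))
    s1 = pick_soft_threshold(m)
    s2 = pick_soft_threshold(m)
    assert s1.chosen_power == s2.chosen_power and s1.r2_signed == s2.r2_signed
    # restricted power range on i.i.d. noise cannot fit a power law
    with pytest.warns(UserWarning, match="no power reached"):
        scan = pick_soft_threshold(_noise_matrix(), powers=(1, 2))
    assert not scan.target_reached


def test_soft_threshold_input_validation():
    with pytest.raises(ValueError, match="at least 20 proteins"):
        pick_soft_threshold(_noise_matrix(n_prot=5))


# --- eigenproteins ---------------------------------------------------------


def test_eigenprotein_single_protein_module():
    m = _noise_matrix(n_prot=3)
    labels = np.array([1, 0, 0])
    eig = eigenprotein(m, labels)
    profile = m.values[0]
    z = (profile - profile.mean()) / profile.std()
    assert abs(np.corrcoef(eig[0], z)[0, 1]) == pytest.approx(1.0)
    assert np.corrcoef(eig[0], z)[0, 1] > 0  # sign anchored to the member


def test_eigenprotein_duplicated_profile():
    rng = np.random.default_rng(5)
    profile = rng.standard_normal(25)
    vals = np.vstack([profile * s + o for s, o in [(1, 0), (2, 3), (0.5, -1)]])
    m = AbundanceMatrix(vals, ["a", "b", "c"], [f"s{j}" for j in range(25)])
    eig = eigenprotein(m, np.array([1, 1, 1]))
    assert np.corrcoef(eig[0], profile)[0, 1] == pytest.approx(1.0)


def test_eigenprotein_explains_most_variance():
    m, _, key = gen_expression(ModuleTruth(n_proteins=30, module_sizes=(30,), seed=8))
    labels = np.array(key["labels"])
    eig = eigenprotein(m, labels)[0]
    z = (m.values - m.values.mean(axis=1, keepdims=True)) / m.values.std(axis=1, keepdims=True)
    var_eig = ((z @ eig) ** 2).sum()
    for row in z:
        member = row / np.linalg.norm(row)
        assert var_eig >= ((z @ member) ** 2).sum() - 1e-9


# --- module detection ------------------------------------------------------


def _detect(m, beta=4, **kw):
    return detect_modules(1.0 - tom(adjacency(m, beta=beta)), m, **kw)


def test_planted_two_module_recovery():
    for seed in (0, 11, 17):
        truth = ModuleTruth(n_proteins=60, module_sizes=(30, 30), n_samples=50, seed=seed)
        m, _, key = gen_expression(truth)
        assignment = _detect(m)
        assert assignment.n_modules == 2
        assert adjusted_rand_score(key["labels"], assignment.labels) > 0.9


def test_pure_noise_mostly_unassigned():
    assignment = _detect(_noise_matrix(n_prot=100, n_samp=40, seed=3))
    assert np.mean(assignment.labels == 0) > 0.5


def test_module_one_is_largest():
    m, _, _ = gen_expression(ModuleTruth(n_proteins=80, module_sizes=(40, 25), seed=6, n_samples=40))
    assignment = _detect(m)
    sizes = [np.sum(assignment.labels == mod) for mod in range(1, assignment.n_modules + 1)]
    assert sizes == sorted(sizes, reverse=True)


def test_too_few_proteins_all_unassigned():
    m = _noise_matrix(n_prot=10)
    with pytest.warns(UserWarning, match="fewer proteins"):
        assignment = detect_modules(1.0 - tom(adjacency(m, beta=4)), m, min_module_size=20)
    assert assignment.n_modules == 0


def test_row_order_invariance_of_partition():
    truth = ModuleTruth(n_proteins=60, module_sizes=(30, 30), n_samples=50, seed=4)
    m, _, _ = gen_expression(truth)
    rng = np.random.default_rng(0)
    perm = rng.permutation(60)
    m_perm = AbundanceMatrix(m.values[perm], [m.protein_keys[i] for i in perm], m.sample_ids)
    l1, l2 = _detect(m).labels, _detect(m_perm).labels
    assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)


# --- trait correlation -----------------------------------------------------


def test_trait_correlate_extremes():
    rng = np.random.default_rng(2)
    profile = rng.standard_normal(10)
    [perfect] = trait_correlate(profile, profile.copy())
    assert perfect.r == pytest.approx(1.0) and perfect.p < 1e-12
    # orthogonalised profile: r = 0 exactly, t = 0, p = 1
    trait = rng.standard_normal(10)
    centered = trait - trait.mean()
    other = rng.standard_normal(10)
    other -= other.mean()
    other -= centered * (other @ centered) / (centered @ centered)
    [null] = trait_correlate(other, trait)
    assert abs(null.r) < 1e-12 and null.p == pytest.approx(1.0)


def test_trait_correlate_closed_form():
    # hand-checkable 4-sample input, verified against the direct formulas
    profile = np.array([1.0, 2.0, 3.0, 4.0])
    trait = np.array([1.0, 2.0, 3.0, 5.0])
    [res] = trait_correlate(profile, trait)
    r_direct = np.sum((profile - 2.5) * (trait - 2.75)) / np.sqrt(
        np.sum((profile - 2.5) ** 2) * np.sum((trait - 2.75) ** 2)
    )
    assert res.r == pytest.approx(r_direct)
    assert res.r2 == pytest.approx(r_direct**2)
    from scipy import stats

    t = r_direct * np.sqrt(2 / (1 - r_direct**2))
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 2))


def test_trait_correlate_validation_and_constant_profile():
    with pytest.raises(ValueError, match="constant"):
        trait_correlate(np.ones((1, 10)), np.ones(10))
    with pytest.raises(ValueError, match="at least 4"):
        trait_correlate(np.ones((1, 3)), np.array([1.0, 2.0, 3.0]))
    with pytest.warns(UserWarning, match="constant profile"):
        [res] = trait_correlate(np.ones(8), np.arange(8.0))
    assert np.isnan(res.r)


def test_sample_permutation_invariance_of_trait_correlation():
    truth = ModuleTruth(n_proteins=60, module_sizes=(30, 30), n_samples=50, seed=9)
    m, trait, _ = gen_expression(truth)
    assignment = _detect(m)
    cors = trait_correlate(assignment.eigenproteins, trait)
    perm = np.random.default_rng(1).permutation(50)
    m_perm = AbundanceMatrix(m.values[:, perm], m.protein_keys, [m.sample_ids[j] for j in perm])
    cors_perm = trait_correlate(_detect(m_perm).eigenproteins, trait[perm])
    assert sorted(round(abs(c.r), 10) for c in cors) == sorted(round(abs(c.r), 10) for c in cors_perm)


# --- cleaning --------------------------------------------------------------


def test_clean_drops_missing_and_constant_rows():
    rng = np.random.default_rng(0)
    vals = rng.standard_normal((5, 10))
    vals[0, :] = 1.0  # constant
    vals[1, :4] = np.nan  # 40% missing
    vals[2, 0] = np.nan  # 10% missing: imputed, kept
    m = AbundanceMatrix(vals, [f"p{i}" for i in range(5)], [f"s{j}" for j in range(10)])
    with pytest.warns(UserWarning):
        cleaned = m.clean()
    assert cleaned.protein_keys == ["p2", "p3", "p4"]
    assert not np.isnan(cleaned.values).any()
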