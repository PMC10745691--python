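"""Bray-Curtis, PCoA, PERMANOVA and Mantel, checked against closed
forms, exhaustive permutation enumeration, and scikit-bio."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from gutbrain.community import (
    DistanceMatrix,
    bray_curtis,
    mantel,
    pcoa,
    permanova,
)
from gutbrain.core_data import FeatureTable


def _ft(values):
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        [f"S{i}" for i in range(values.shape[0])],
        [f"F{j}" for j in range(values.shape[1])],
        values, "taxon", normalized=True,
    )


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"S{i}" for i in range(values.shape[0])]
    return DistanceMatrix(ids, values)


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_closed_forms():
    t = _ft([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [1.0, 0.0, 0.0]])
    d = bray_curtis(t).values
    assert d[0, 1] == pytest.approx(0.0)  # identical profiles
    assert d[0, 2] == pytest.approx(0.5)  # 1 - 2*0.5/2
    assert d[2, 3] == pytest.approx(1.0)  # disjoint supports


def test_bray_curtis_matches_direct_formula(rng):
    vals = rng.dirichlet(np.ones(6), size=5)
    d = bray_curtis(_ft(vals)).values
    for i in range(5):
        for j in range(5):
            expected = 1.0 - 2.0 * np.minimum(vals[i], vals[j]).sum() / (vals[i] + vals[j]).sum()
            assert d[i, j] == pytest.approx(expected, abs=1e-12)


def test_bray_curtis_requires_normalized_table():
    t = _ft([[0.5, 0.5], [0.3, 0.7]])
    t.normalized = False
    with pytest.raises(ValueError):
        bray_curtis(t)


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_degenerate_and_two_point():
    zero = _dm(np.zeros((3, 3)))
    res = pcoa(zero, k=2)
    np.testing.assert_allclose(res.coordinates, 0.0)

    two = _dm([[0.0, 0.8], [0.8, 0.0]])
    res2 = pcoa(two, k=1)
    np.testing.assert_allclose(np.abs(res2.coordinates[:, 0]), 0.4, atol=1e-12)


def test_pcoa_recovers_euclidean_configuration(rng):
    points = rng.normal(size=(8, 2))
    d = _dm(squareform(pdist(points)))
    res = pcoa(d, k=2)
    recovered = squareform(pdist(res.coordinates))
    np.testing.assert_allclose(recovered, d.values, atol=1e-8)
    assert res.n_negative_eigenvalues == 0


def test_pcoa_agrees_with_skbio(rng):
    skbio = pytest.importorskip("skbio")
    vals = rng.dirichlet(np.ones(10), size=12)
    d = bray_curtis(_ft(vals))
    ours = pcoa(d, k=3)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.sample_ids))
    their_var = theirs.proportion_explained.to_numpy()[:3]
    # skbio divides by the full eigenvalue sum (incl. negatives); compare
    # on our convention by recomputing from its eigenvalues
    their_eig = theirs.eigvals.to_numpy()
    their_pos = their_eig[their_eig > 1e-12]
    np.testing.assert_allclose(ours.variance_explained, their_pos[:3] / their_pos.sum(), atol=1e-6)
    for axis in range(2):
        a, b = ours.coordinates[:, axis], theirs.samples.to_numpy()[:, axis]
        assert abs(abs(np.corrcoef(a, b)[0, 1]) - 1.0) < 1e-6


def test_pcoa_truncates_with_warning():
    two = _dm([[0.0, 0.8], [0.8, 0.0]])
    with pytest.warns(UserWarning, match="truncating"):
        res = pcoa(two, k=5)
    assert res.coordinates.shape[1] == 1


# ---------------------------------------------------------------------------
# PERMANOVA


def _brute_force_permanova(dist, cov):
    """Independent implementation: explicit hat matrix and full trace."""
    n = len(cov)
    x = np.column_stack([np.ones(n), np.asarray(cov, dtype=float)])
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dist ** 2) @ j
    r2 = np.trace(h @ g @ h) / np.trace(g)
    df1, df2 = 1, n - 2
    f = (r2 / df1) / ((1 - r2) / df2)
    return r2, f


def test_permanova_r2_matches_explicit_hat_matrix(rng):
    vals = rng.dirichlet(np.ones(8), size=10)
    d = bray_curtis(_ft(vals))
    cov = rng.normal(size=10)
    res = permanova(d, cov, n_permutations=99, seed=0)
    r2, f = _brute_force_permanova(d.values, cov)
    assert res.r_squared == pytest.approx(r2, abs=1e-12)
    assert res.pseudo_f == pytest.approx(f, abs=1e-10)


def test_permanova_exact_p_matches_enumeration(rng):
    n = 5
    vals = rng.dirichlet(np.ones(6), size=n)
    d = bray_curtis(_ft(vals))
    cov = rng.normal(size=n)
    res = permanova(d, cov, method="exact")
    _, f_obs = _brute_force_permanova(d.values, cov)
    f_all = [
        _brute_force_permanova(d.values, cov[list(perm)])[1]
        for perm in itertools.permutations(range(n))
    ]
    expected_p = np.mean([f >= f_obs - 1e-12 for f in f_all])
    assert res.p_value == pytest.approx(expected_p)
    assert res.p_value >= 1.0 / len(f_all)


def test_permanova_binary_covariate_matches_group_sum_of_squares(rng):
    """On a two-group design the distance-based linear model must equal
    the classical between/within sum-of-squares partition."""
    n = 6
    vals = rng.dirichlet(np.ones(5), size=n)
    d = bray_curtis(_ft(vals))
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    res = permanova(d, groups, method="exact")
    d2 = d.values ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in ("a", "b"):
        idx = np.where(groups == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    r2 = (ss_total - ss_within) / ss_total
    assert res.r_squared == pytest.approx(r2, abs=1e-12)


def test_permanova_two_groups_of_two_exact_assignments(rng):
    vals = rng.dirichlet(np.ones(4), size=4)
    d = bray_curtis(_ft(vals))
    res = permanova(d, np.array(["a", "a", "b", "b"]), method="exact")
    assert res.n_permutations == 6  # 4!/(2!2!) distinct assignments
    assert res.p_value in {k / 6 for k in range(1, 7)}


def test_permanova_constant_distances_give_p_one():
    # all points equidistant: every labeling explains the same variance,
    # so R^2 sits at its permutation minimum and p = 1
    n = 5
    d = _dm(np.ones((n, n)) - np.eye(n))
    res = permanova(d, np.arange(n, dtype=float))
    assert res.p_value == 1.0
    assert res.r_squared == pytest.approx(1.0 / (n - 1))


def test_permanova_affine_covariate_invariance(rng):
    vals = rng.dirichlet(np.ones(8), size=12)
    d = bray_curtis(_ft(vals))
    cov = rng.normal(size=12)
    r1 = permanova(d, cov, n_permutations=99, seed=1).r_squared
    r2 = permanova(d, 3.0 + 2.5 * cov, n_permutations=99, seed=1).r_squared
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_permanova_rejects_constant_covariate(rng):
    vals = rng.dirichlet(np.ones(5), size=6)
    d = bray_curtis(_ft(vals))
    with pytest.raises(ValueError, match="zero-variance"):
        permanova(d, np.ones(6))


# ---------------------------------------------------------------------------
# Mantel


def test_mantel_trivial_correlations(rng):
    vals = rng.dirichlet(np.ones(6), size=6)
    d1 = bray_curtis(_ft(vals))
    assert mantel(d1, d1, n_permutations=99).statistic == pytest.approx(1.0)
    affine = DistanceMatrix(d1.sample_ids, np.where(np.eye(6), 0.0, 0.1 + 2.0 * d1.values))
    assert mantel(d1, affine, n_permutations=99).statistic == pytest.approx(1.0)


def test_mantel_exact_p_matches_full_enumeration(rng):
    n = 5
    d1 = bray_curtis(_ft(rng.dirichlet(np.ones(6), size=n)))
    d2 = bray_curtis(_ft(rng.dirichlet(np.ones(6), size=n)))
    res = mantel(d1, d2, method="exact")
    iu = np.triu_indices(n, 1)
    v1 = d1.values[iu]
    rs = []
    for perm in itertools.permutations(range(n)):
        m = d2.values[np.ix_(perm, perm)]
        rs.append(np.corrcoef(v1, m[iu])[0, 1])
    r_obs = rs[0]  # identity permutation comes first
    assert res.statistic == pytest.approx(r_obs)
    assert res.p_value == pytest.approx(np.mean([r >= r_obs - 1e-12 for r in rs]))


def test_mantel_statistic_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import mantel as sk_mantel

    n = 10
    d1 = bray_curtis(_ft(rng.dirichlet(np.ones(8), size=n)))
    d2 = bray_curtis(_ft(rng.dirichlet(np.ones(8), size=n)))
    ours = mantel(d1, d2, n_permutations=99, seed=0)
    theirs = sk_mantel(
        skbio.DistanceMatrix(d1.values, d1.sample_ids),
        skbio.DistanceMatrix(d2.values, d2.sample_ids),
        permutations=0,
    )[0]
    assert ours.statistic == pytest.approx(float(theirs), abs=1e-12)


def test_mantel_requires_shared_samples(rng):
    d1 = bray_curtis(_ft(rng.dirichlet(np.ones(4), size=4)))
    d2 = DistanceMatrix(["X0", "X1", "X2", "X3"], d1.values)
    with pytest.raises(ValueError, match="shared samples"):
        mantel(d1, d2)


def test_mantel_null_p_is_uniform(rng):
    """p-values under independent random matrices follow Uniform(0,1)."""
    from scipy.stats import kstest

    pvals = []
    for _ in range(200):
        d1 = bray_curtis(_ft(rng.dirichlet(np.ones(8), size=12)))
        d2 = bray_curtis(_ft(rng.dirichlet(np.ones(8), size=12)))
        pvals.append(mantel(d1, d2, n_permutations=99, seed=int(rng.integers(2**31))).p_value)
    stat = kstest(pvals, "uniform").statistic
    assert stat < 0.12  # 200 draws with p granularity 1/100
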