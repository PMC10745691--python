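"""Beta-diversity ordination and distance-based inference.

Implements the community-level stage of the pipeline: Bray-Curtis
dissimilarities between relative-abundance profiles, classical
principal-coordinates analysis (PCoA), a one-covariate PERMANOVA
(distance-based linear model with a permutation test), and the Mantel
test between two distance matrices.

Conventions shared by the permutation tests:

* random-permutation p-values use the +1 pseudo-count,
  p = (1 + #{T_perm >= T_obs}) / (1 + n_permutations), so p is never 0;
* when the sample is small enough (n <= ``exact_threshold``) the tests
  switch to exhaustive enumeration of all distinct permutations and
  report the exact p = #{T_perm >= T_obs} / count (identity included).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_data import FeatureTable

EXACT_ENUMERATION_MAX_N = 7  # 7! = 5040 permutations


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    variance_explained: np.ndarray  # (k,) fractions of positive eigenmass
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    n_negative_eigenvalues: int


@dataclass
class PermanovaResult:
    covariate_name: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int  # count of non-identity draws (random) or total enumerated (exact)
    method: str  # "permutation" | "exact"
    q_value: float | None = None


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


# ---------------------------------------------------------------------------


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, BC(x, y) = 1 - 2 sum min(x,y) / sum(x+y)."""
    if not table.normalized:
        raise ValueError("bray_curtis requires a normalized table")
    if (table.values.sum(axis=1) <= 0).any():
        raise ValueError("zero-sum sample row")
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def euclidean_distances(matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between rows (used for brain-volume ordination)."""
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix([str(i) for i in matrix.index], d)


def pcoa(d: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical scaling of a distance matrix.

    Eigendecomposes the Gower-centered matrix -1/2 J D^2 J; coordinates
    come from the ``k`` largest positive eigenvalues and
    ``variance_explained`` is each eigenvalue over the positive
    eigenvalue total. Negative eigenvalues (non-Euclidean distances)
    are dropped and counted.
    """
    n = d.n_samples
    g = _gower_center(d.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12 if eigval.size else 0.0
    positive = eigval > tol
    n_negative = int((eigval < -tol).sum())
    pos_vals = eigval[positive]
    pos_vecs = eigvec[:, positive]
    if k > pos_vals.size:
        if pos_vals.size < k and not np.allclose(d.values, 0):
            warnings.warn(
                f"requested {k} axes but only {pos_vals.size} positive eigenvalues; truncating",
                stacklevel=2,
            )
        k = pos_vals.size
    coords = pos_vecs[:, :k] * np.sqrt(pos_vals[:k])
    total = pos_vals.sum()
    var_exp = pos_vals[:k] / total if total > 0 else np.zeros(k)
    if k == 0:  # degenerate all-zero distances
        coords = np.zeros((n, 1))
        var_exp = np.zeros(1)
    return PcoaResult(list(d.sample_ids), coords, var_exp, pos_vals, n_negative)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    a = -0.5 * dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_columns(covariate: np.ndarray) -> np.ndarray:
    """Centered design columns for a numeric or categorical covariate
    (categoricals dummy-coded, first level dropped)."""
    cov = np.asarray(covariate)
    if cov.ndim != 1:
        raise ValueError("covariate must be one-dimensional")
    if cov.dtype.kind in "fiub":
        z = cov.astype(float)[:, None]
    else:
        levels = sorted(set(cov.tolist()))
        if len(levels) < 2:
            raise ValueError("zero-variance covariate")
        z = np.column_stack([(cov == lv).astype(float) for lv in levels[1:]])
    z = z - z.mean(axis=0)
    if np.allclose(z, 0):
        raise ValueError("zero-variance covariate")
    return z


def _permanova_stats(g: np.ndarray, z: np.ndarray, m_inv: np.ndarray, tr_g: float,
                     df1: int, df2: int) -> tuple[float, float]:
    # R^2 = tr(H G H)/tr(G); with G doubly centered and H = 11'/n + Z M Z'
    # (Z column-centered), tr(H G H) = tr((Z' G Z) M).
    zg = z.T @ g @ z
    r2 = float(np.trace(zg @ m_inv) / tr_g)
    f = (r2 / df1) / ((1.0 - r2) / df2)
    return r2, f


def permanova(
    d: DistanceMatrix,
    covariate,
    covariate_name: str = "covariate",
    n_permutations: int = 9999,
    seed: int | None = 0,
    method: str = "auto",
) -> PermanovaResult:
    """One-covariate PERMANOVA on a distance matrix.

    The covariate (numeric vector or categorical labels, aligned to
    ``d.sample_ids``) enters a distance-based linear model with
    intercept; R^2 is the fraction of Gower-centered distance variance
    captured by its hat matrix and pseudo-F = (R^2/df1)/((1-R^2)/df2).
    Significance comes from permuting covariate rows. ``method``:
    "permutation", "exact" (all distinct permutations), or "auto"
    (exact when n <= 7).
    """
    n = d.n_samples
    if n < 4:
        raise ValueError("permanova requires at least 4 samples")
    cov = np.asarray(covariate)
    if cov.shape[0] != n:
        raise ValueError("covariate not aligned to distance matrix")
    z = _design_columns(cov)
    df1 = np.linalg.matrix_rank(z)
    df2 = n - df1 - 1
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    g = _gower_center(d.values)
    tr_g = float(np.trace(g))
    if tr_g <= 0:
        # all pairwise distances equal (or zero): no partitionable variance
        return PermanovaResult(covariate_name, 0.0, 0.0, 1.0, n_permutations, "degenerate")
    m_inv = np.linalg.pinv(z.T @ z)
    r2_obs, f_obs = _permanova_stats(g, z, m_inv, tr_g, df1, df2)

    if method == "auto":
        method = "exact" if n <= EXACT_ENUMERATION_MAX_N else "permutation"
    if method == "exact":
        f_perm = []
        seen: set[tuple] = set()
        key_source = cov.tolist()
        for perm in itertools.permutations(range(n)):
            key = tuple(key_source[i] for i in perm)
            if key in seen:
                continue
            seen.add(key)
            _, f_p = _permanova_stats(g, z[list(perm)], m_inv, tr_g, df1, df2)
            f_perm.append(f_p)
        f_perm = np.asarray(f_perm)
        p = float((f_perm >= f_obs - 1e-12).sum() / f_perm.size)
        return PermanovaResult(covariate_name, r2_obs, f_obs, p, int(f_perm.size), "exact")

    rng = np.random.default_rng(seed)
    if z.shape[1] == 1:
        # batched quadratic form: tr(H_p G) reduces to z_p' G z_p * m_inv
        zvec = z[:, 0]
        perms = np.stack([rng.permutation(zvec) for _ in range(n_permutations)], axis=1)
        gz = g @ perms  # (n, n_permutations)
        quad = np.einsum("ip,ip->p", perms, gz)
        r2_perm = quad * m_inv[0, 0] / tr_g
        f_perm = (r2_perm / df1) / ((1.0 - r2_perm) / df2)
    else:
        f_perm = np.empty(n_permutations)
        for b in range(n_permutations):
            zp = z[rng.permutation(n)]
            _, f_perm[b] = _permanova_stats(g, zp, m_inv, tr_g, df1, df2)
    exceed = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(covariate_name, r2_obs, f_obs, p, n_permutations, "permutation")


def permanova_battery(
    d_by_name: dict[str, DistanceMatrix],
    covariates: dict[str, np.ndarray],
    n_permutations: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal PERMANOVA of each covariate against each distance matrix,
    with Benjamini-Hochberg q-values across the whole battery."""
    from .lms import bh_fdr

    rows = []
    for mat_name, d in d_by_name.items():
        for i, (cov_name, cov) in enumerate(covariates.items()):
            res = permanova(
                d, cov, covariate_name=cov_name, n_permutations=n_permutations,
                seed=seed + i, method="permutation",
            )
            rows.append({
                "matrix": mat_name, "covariate": cov_name,
                "r_squared": res.r_squared, "pseudo_f": res.pseudo_f,
                "p_value": res.p_value, "n_permutations": res.n_permutations,
            })
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = 0,
    method: str = "auto",
) -> MantelResult:
    """Mantel test: Pearson correlation of the two upper triangles,
    one-sided (greater) p by simultaneous row/column permutation of d2.

    Sample sets are intersected and aligned; at least 4 shared samples
    are required. ``method`` as in :func:`permanova`.
    """
    shared = [s for s in d1.sample_ids if s in set(d2.sample_ids)]
    if len(shared) < 4:
        raise ValueError("mantel requires at least 4 shared samples")
    i1 = [d1.sample_ids.index(s) for s in shared]
    i2 = [d2.sample_ids.index(s) for s in shared]
    m1 = d1.values[np.ix_(i1, i1)]
    m2 = d2.values[np.ix_(i2, i2)]
    n = len(shared)
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]
    if v1.std() == 0 or m2[iu].std() == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")

    def _r(mat2: np.ndarray) -> float:
        return float(np.corrcoef(v1, mat2[iu])[0, 1])

    r_obs = _r(m2)
    if method == "auto":
        method = "exact" if n <= EXACT_ENUMERATION_MAX_N else "permutation"
    if method == "exact":
        rs = np.array([
            _r(m2[np.ix_(perm, perm)])
            for perm in itertools.permutations(range(n))
        ])
        p = float((rs >= r_obs - 1e-12).sum() / rs.size)
        return MantelResult(r_obs, p, int(rs.size), "exact")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _r(m2[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, "permutation")
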