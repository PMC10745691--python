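"""Per-feature multivariable linear models of cognitive outcomes.

Each retained feature's transformed relative abundance enters an
ordinary-least-squares model of the outcome together with a fixed
covariate block (age at stool collection, maternal education, and
log10 sequencing depth by default); the abundance term's two-sided t
p-value is corrected across features with Benjamini-Hochberg.

Abundance transform: log2(x + delta) with delta = half the smallest
nonzero relative abundance in the whole table (recorded in the result
provenance); an arcsine-square-root alternative is available via
``method="arcsinsqrt"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_data import CohortTable

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "maternal_education", "log10_depth")


@dataclass
class AbundanceTransform:
    """A fitted abundance transform with its recorded pseudo-count."""

    method: str  # "log2" | "arcsinsqrt"
    delta: float  # pseudo-count (log2 only)

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if (x < 0).any() or (x > 1).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        if self.method == "log2":
            return np.log2(x + self.delta)
        if self.method == "arcsinsqrt":
            return np.arcsin(np.sqrt(x))
        raise ValueError(f"unknown transform method {self.method!r}")


def fit_transform(values: np.ndarray, method: str = "log2") -> AbundanceTransform:
    """Choose the pseudo-count from the whole table: half its smallest
    nonzero value. Errors on an all-zero table."""
    values = np.asarray(values, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all abundances are zero; cannot choose a pseudo-count")
    return AbundanceTransform(method=method, delta=0.5 * float(nonzero.min()))


def transform_abundance(
    x: np.ndarray, table_values: np.ndarray | None = None, method: str = "log2"
) -> tuple[np.ndarray, AbundanceTransform]:
    """Transform a relative-abundance vector; the pseudo-count comes
    from ``table_values`` (defaults to ``x`` itself)."""
    x = np.asarray(x, dtype=float)
    if table_values is None:
        table_values = x
    if x.max(initial=0.0) == 0.0:
        raise ValueError("all-zero feature; should have been prevalence-filtered")
    tr = fit_transform(table_values, method=method)
    return tr.apply(x), tr


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_feature_lms(
    cohort: CohortTable,
    outcome: str = "cognitive_score",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    transform: str = "log2",
) -> pd.DataFrame:
    """OLS of the outcome on [intercept, transformed abundance,
    covariates], fit independently per feature.

    Returns one row per feature: coefficient (score points per unit
    transformed abundance), std_error, t_statistic, p_value, BH
    q_value, n_samples, prevalence. The transform's pseudo-count is
    stored in ``result.attrs["transform_delta"]``.
    """
    y = cohort.outcome(outcome)
    cov = cohort.covariates(covariates).to_numpy()
    n = y.size
    p_cov = cov.shape[1]
    if n <= p_cov + 3:  # intercept + abundance + covariates, plus 1 residual df
        raise ValueError(f"n={n} too small for {p_cov} covariates")
    values = cohort.table.values
    tr = fit_transform(values, method=transform)
    rows = []
    skipped = []
    for j, fid in enumerate(cohort.table.feature_ids):
        x = values[:, j]
        if x.max() == 0.0:
            raise ValueError(f"all-zero feature {fid!r}; prevalence-filter first")
        tx = tr.apply(x)
        design = sm.add_constant(np.column_stack([tx, cov]), has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            skipped.append(fid)
            logger.warning("feature %s skipped: rank-deficient design", fid)
            continue
        fit = sm.OLS(y, design).fit()
        rows.append({
            "feature_id": fid,
            "coefficient": fit.params[1],
            "std_error": fit.bse[1],
            "t_statistic": fit.tvalues[1],
            "p_value": fit.pvalues[1],
            "n_samples": n,
            "prevalence": float((x > 0).mean()),
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = bh_fdr(result["p_value"].to_numpy())
    result.attrs["transform"] = transform
    result.attrs["transform_delta"] = tr.delta
    result.attrs["covariates"] = list(covariates)
    result.attrs["outcome"] = outcome
    result.attrs["skipped_features"] = skipped
    return result
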