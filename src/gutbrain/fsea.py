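"""Feature-set enrichment analysis (FSEA) of gene-function modules.

Tests whether a named set of gene functions (e.g. a neuroactive-potential
module such as glutamate synthesis) is associated with a cognitive
outcome more strongly than the background of all measured genes.

Per-gene statistic: the partial Pearson correlation between transformed
gene abundance and the outcome given age (both sides residualized on
age), with t = r * sqrt(n-2) / sqrt(1-r^2). The enrichment score is the
Hodges-Lehmann pseudomedian of the within-set correlations — the sign
gives the enrichment direction — and the p-value is a two-sided
Mann-Whitney U test of within-set vs background correlations (exact
when the smaller side has <= 8 values, normal approximation with tie
correction otherwise). Genes, not samples, are the exchangeability
unit. A battery applies Benjamini-Hochberg across sets and flags
significance at q < 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CohortTable, GeneSetCollection
from .lms import bh_fdr, fit_transform

logger = logging.getLogger(__name__)

EXACT_U_MAX_GROUP = 8
Q_SIGNIFICANT = 0.2


@dataclass
class GeneAssociation:
    gene_id: str
    statistic: float  # partial Pearson r given age
    t_statistic: float
    n_samples: int


@dataclass
class FseaResult:
    set_name: str
    es: float  # pseudomedian of within-set statistics
    median_correlation: float
    p_value: float
    set_size: int
    n_background: int
    q_value: float | None = None
    significant: bool | None = None


def _residualize(v: np.ndarray, age: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(age), age])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def gene_associations(
    cohort: CohortTable,
    outcome: str = "cognitive_score",
    statistic: str = "correlation",
) -> list[GeneAssociation]:
    """Per-gene association with the outcome, partialling out age.

    ``statistic`` selects whether downstream ranking uses the partial
    correlation r ("correlation") or its t-statistic ("t"); both are
    always computed and stored.
    """
    if cohort.table.feature_kind != "gene_function":
        raise ValueError("gene_associations expects a gene-function cohort")
    n = cohort.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")
    if statistic not in ("correlation", "t"):
        raise ValueError(f"unknown statistic {statistic!r}")
    age = np.array([r.age_months for r in cohort.records])
    y = _residualize(cohort.outcome(outcome), age)
    tr = fit_transform(cohort.table.values)
    out = []
    for j, gid in enumerate(cohort.table.feature_ids):
        gx = _residualize(tr.apply(cohort.table.values[:, j]), age)
        if gx.std() == 0 or y.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(gx, y)[0, 1])
        if abs(r) < 1.0:
            t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        else:
            t = np.inf * np.sign(r)
        out.append(GeneAssociation(gid, r, float(t), n))
    return out


def pseudomedian(values: Sequence[float]) -> float:
    """Hodges-Lehmann one-sample estimator: the median of all Walsh
    averages (v_i + v_j)/2 over i <= j."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("pseudomedian of an empty vector")
    i, j = np.triu_indices(v.size)
    return float(np.median((v[i] + v[j]) / 2.0))


def fsea_test(
    assocs: Sequence[GeneAssociation],
    gene_set: Sequence[str],
    set_name: str = "set",
    statistic: str = "correlation",
) -> FseaResult:
    """Rank-based enrichment of one gene set against all other genes.

    ES = pseudomedian of the within-set statistics; p from a two-sided
    Mann-Whitney U of within-set vs background statistics.
    """
    values = {
        a.gene_id: (a.statistic if statistic == "correlation" else a.t_statistic)
        for a in assocs
    }
    corrs = {a.gene_id: a.statistic for a in assocs}
    members = [g for g in gene_set if g in values]
    if not members:
        raise ValueError(f"gene set {set_name!r} has no genes in the measured background")
    member_set = set(members)
    background = [g for g in values if g not in member_set]
    if not background:
        raise ValueError(f"gene set {set_name!r} covers the whole background")
    inside = np.array([values[g] for g in members])
    outside = np.array([values[g] for g in background])
    method = "exact" if min(inside.size, outside.size) <= EXACT_U_MAX_GROUP else "asymptotic"
    p = float(
        stats.mannwhitneyu(inside, outside, alternative="two-sided", method=method).pvalue
    )
    return FseaResult(
        set_name=set_name,
        es=pseudomedian([corrs[g] for g in members]),
        median_correlation=float(np.median([corrs[g] for g in members])),
        p_value=min(p, 1.0),
        set_size=len(members),
        n_background=len(background),
    )


def fsea_battery(
    assocs: Sequence[GeneAssociation],
    sets: GeneSetCollection,
    statistic: str = "correlation",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Run :func:`fsea_test` per set, BH-correct across the battery.

    Per-set errors (e.g. empty intersection) are collected and returned
    alongside the result table rather than raised.
    """
    results: list[FseaResult] = []
    errors: dict[str, str] = {}
    for name in sets:
        try:
            results.append(fsea_test(assocs, sets[name], set_name=name, statistic=statistic))
        except ValueError as exc:
            errors[name] = str(exc)
            logger.warning("FSEA set %s skipped: %s", name, exc)
    if not results:
        raise ValueError("no testable gene sets in the battery")
    q = bh_fdr(np.array([r.p_value for r in results]))
    for res, qv in zip(results, q):
        res.q_value = float(qv)
        res.significant = bool(qv < Q_SIGNIFICANT)
    table = pd.DataFrame([
        {
            "set_name": r.set_name, "es": r.es,
            "median_correlation": r.median_correlation,
            "p_value": r.p_value, "q_value": r.q_value,
            "significant": r.significant,
            "set_size": r.set_size, "n_background": r.n_background,
        }
        for r in results
    ])
    return table, errors


def running_sum(
    assocs: Sequence[GeneAssociation], gene_set: Sequence[str]
) -> pd.DataFrame:
    """GSEA-style running-sum curve over rank positions (plotting aid
    only; carries no inferential weight).

    Genes are ranked by descending statistic; the curve steps up by
    1/n_set at set members and down by 1/n_background elsewhere.
    """
    member_set = set(gene_set)
    ranked = sorted(assocs, key=lambda a: -a.statistic)
    in_set = np.array([a.gene_id in member_set for a in ranked])
    n_in = int(in_set.sum())
    n_out = len(ranked) - n_in
    if n_in == 0 or n_out == 0:
        raise ValueError("running_sum needs both set and background genes")
    steps = np.where(in_set, 1.0 / n_in, -1.0 / n_out)
    return pd.DataFrame({
        "rank": np.arange(1, len(ranked) + 1),
        "gene_id": [a.gene_id for a in ranked],
        "in_set": in_set,
        "running_sum": np.cumsum(steps),
    })
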