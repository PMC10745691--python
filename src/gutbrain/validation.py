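"""Calibration and recovery studies on synthetic cohorts.

These are the package's own checks that the inference machinery behaves
as advertised: type-I error of the distance tests, uniformity of
per-feature and enrichment p-values under a null generator, absence of
spurious forest test-correlation, and power to recover planted effects.
Each study returns plain numbers so drivers and tests can assert on or
report them.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .community import bray_curtis, permanova
from .core_data import CohortTable, prevalence_filter
from .fsea import fsea_battery, fsea_test, gene_associations
from .lms import fit_feature_lms
from .rf import EnsembleConfig, run_ensemble
from .synthetic import SimConfig, simulate_cohort, simulate_null_cohort


def _cohort(records, table, pairing="concurrent"):
    kwargs = {"max_gap_days": 7.0} if pairing == "concurrent" else {"min_lead_months": 6.0}
    return CohortTable(records, table, (0.0, 120.0), pairing, **kwargs)


def permanova_null_rejection_rate(
    n_reps: int = 200,
    n_subjects: int = 30,
    n_species: int = 50,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of null cohorts where PERMANOVA of taxa vs cognitive
    score rejects at ``alpha``; should sit near ``alpha``."""
    rejections = 0
    for rep in range(n_reps):
        config = SimConfig(n_subjects=n_subjects, n_species=n_species,
                           seed=seed * 100_003 + rep, sparsity=0.5)
        taxa, _, records, _, _ = simulate_null_cohort(config)
        d = bray_curtis(taxa)
        score = np.array([r.cognitive_score for r in records])
        res = permanova(d, score, n_permutations=n_permutations,
                        seed=seed * 100_003 + rep, method="permutation")
        rejections += res.p_value <= alpha
    return rejections / n_reps, n_reps


def lm_null_pvalue_ks(
    n_subjects: int = 150,
    n_species: int = 220,
    seed: int = 0,
) -> tuple[float, int]:
    """KS distance from Uniform(0,1) of per-taxon LM p-values on a null
    cohort (~200 tested features)."""
    config = SimConfig(n_subjects=n_subjects, n_species=n_species, seed=seed,
                       sparsity=0.5)
    taxa, _, records, _, _ = simulate_null_cohort(config)
    cohort = _cohort(records, prevalence_filter(taxa, 0.15))
    result = fit_feature_lms(cohort)
    p = result["p_value"].to_numpy()
    return float(kstest(p, "uniform").statistic), int(p.size)


def fsea_null_pvalue_ks(
    n_reps: int = 500,
    set_size: int = 12,
    n_subjects: int = 150,
    n_genes: int = 160,
    seed: int = 0,
) -> tuple[float, int]:
    """KS distance from uniform of enrichment p-values for randomly
    drawn gene sets on a null cohort (gene labels are the
    exchangeability unit)."""
    config = SimConfig(n_subjects=n_subjects, n_species=60,
                       n_gene_functions=n_genes, seed=seed, sparsity=0.5)
    _, genes, records, _, _ = simulate_null_cohort(config)
    cohort = _cohort(records, prevalence_filter(genes, 0.10))
    assocs = gene_associations(cohort)
    ids = [a.gene_id for a in assocs]
    rng = np.random.default_rng(seed + 1)
    pvals = [
        fsea_test(assocs, list(rng.choice(ids, size=set_size, replace=False))).p_value
        for _ in range(n_reps)
    ]
    return float(kstest(pvals, "uniform").statistic), n_reps


def rf_null_mean_test_correlation(
    n_ensembles: int = 50,
    n_subjects: int = 40,
    n_species: int = 30,
    seed: int = 0,
) -> tuple[float, int]:
    """Mean held-out correlation across reduced ensembles fit to null
    cohorts; should straddle 0."""
    config_rf = EnsembleConfig(n_repetitions=2, n_folds=3, n_rng_states=1,
                               n_trees=25, predictors=("taxa",))
    means = []
    for rep in range(n_ensembles):
        config = SimConfig(n_subjects=n_subjects, n_species=n_species,
                           seed=seed * 90_001 + rep, sparsity=0.5)
        taxa, _, records, _, _ = simulate_null_cohort(config)
        cohort = _cohort(records, prevalence_filter(taxa, 0.15))
        res = run_ensemble(cohort, EnsembleConfig(
            **{**config_rf.__dict__, "base_seed": seed * 90_001 + rep}
        ))
        means.append(res.summary["mean_test_correlation"])
    return float(np.mean(means)), n_ensembles


def planted_taxon_recovery(
    n_seeds: int = 20,
    effect: float = 7.5,  # 0.5 SD of the score scale per SD of log abundance
    n_subjects: int = 300,
    n_species: int = 50,
    seed: int = 0,
) -> dict[str, float]:
    """Power study: how often a planted taxon effect reaches q < 0.2 in
    the per-feature LMs and a top-5 fitness-weighted importance rank in
    a reduced forest ensemble."""
    lm_hits = 0
    rf_hits = 0
    rf_cfg = dict(n_repetitions=5, n_folds=3, n_rng_states=2, n_trees=25,
                  predictors=("taxa",))
    for rep in range(n_seeds):
        config = SimConfig(
            n_subjects=n_subjects, n_species=n_species, seed=seed * 70_001 + rep,
            planted_taxa=(("Sp_000", effect),),
        )
        taxa, _, records, _, _ = simulate_cohort(config)
        cohort = _cohort(records, prevalence_filter(taxa, 0.15))
        lm = fit_feature_lms(cohort).set_index("feature_id")
        if "Sp_000" in lm.index and lm.loc["Sp_000", "q_value"] < 0.2 \
                and lm.loc["Sp_000", "coefficient"] > 0:
            lm_hits += 1
        res = run_ensemble(cohort, EnsembleConfig(
            base_seed=seed * 70_001 + rep, **rf_cfg
        ))
        if "Sp_000" in res.importance_series().index[:5]:
            rf_hits += 1
    return {
        "lm_recovery_rate": lm_hits / n_seeds,
        "rf_top5_rate": rf_hits / n_seeds,
        "n_seeds": n_seeds,
    }


def planted_geneset_recovery(
    n_seeds: int = 20,
    effect: float = 7.5,
    n_subjects: int = 300,
    seed: int = 0,
) -> dict[str, float]:
    """How often a positively linked gene set attains the smallest
    q-value in its enrichment battery."""
    hits = 0
    for rep in range(n_seeds):
        config = SimConfig(
            n_subjects=n_subjects, n_species=50, n_gene_functions=120,
            seed=seed * 50_021 + rep,
            planted_taxa=(("Sp_000", effect),),
            geneset_link=(("planted_set", 1),),
        )
        _, genes, records, _, sets = simulate_cohort(config)
        cohort = _cohort(records, prevalence_filter(genes, 0.10))
        assocs = gene_associations(cohort)
        table, _ = fsea_battery(assocs, sets)
        best = table.sort_values(["q_value", "p_value"]).iloc[0]
        hits += best["set_name"] == "planted_set"
    return {"geneset_top_rate": hits / n_seeds, "n_seeds": n_seeds}


def repeated_cv_record_count(
    n_subjects: int = 60,
    n_species: int = 30,
    n_trees: int = 25,
    seed: int = 0,
) -> tuple[int, int]:
    """Fit the full repeated-CV scheme (100 repetitions x 3 folds x 10
    RNG states) on a small cohort and return (records fitted, scheduled
    count)."""
    config = SimConfig(n_subjects=n_subjects, n_species=n_species, seed=seed,
                       planted_taxa=(("Sp_000", 7.5),))
    taxa, _, records, _, _ = simulate_cohort(config)
    # keep the design at the requested width: no prevalence filter here
    cohort = _cohort(records, taxa)
    cfg = EnsembleConfig(n_repetitions=100, n_folds=3, n_rng_states=10,
                         n_trees=n_trees, base_seed=seed, predictors=("taxa",),
                         include_age=False)
    res = run_ensemble(cohort, cfg)
    return len(res.records), cfg.total_models
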